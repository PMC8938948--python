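import logging
import random

import pytest

from seqstab.fixtures import hotspot_free_sequence, random_orf
from seqstab.motif_scanning import load_default_motifs

logging.disable(logging.WARNING)

# Trp and Met have no synonymous codons, so repair fixtures exclude Trp and
# avoid same-residue adjacency; the planted features are then the dominant
# hotspots and every one of them is removable by synonymous substitution.
_FIXTURE_AAS = "ACDEFGHIKLMNPQRSTVY"


@pytest.fixture(scope="session")
def pssms():
    return load_default_motifs()


def build_orf_fixture(i: int) -> tuple[str, tuple[int, int]]:
    """One repair fixture: 1.5-kb hotspot-free background with an embedded ORF.

    The ORF carries a planted lysine-run homopolymer (9 nt, flanked by Phe
    and His codons so synonymous edits can break it) and a duplicated 21-nt
    codon block (a direct-repeat pair wholly inside the ORF).
    """
    rng = random.Random(f"fix:{i}")
    aas: list[str] = []
    prev = ""
    while len(aas) < 90:
        aa = rng.choice(_FIXTURE_AAS)
        if aa != prev:
            aas.append(aa)
            prev = aa
    protein = "M" + "".join(aas)
    block = "".join(rng.choice("DEFHILNQRTVY") for _ in range(7))
    enc_block = random_orf(block, seed=i, stop=False)
    core = random_orf(protein, seed=i, stop=False)
    orf = (
        core[:30]
        + random_orf("F", seed=i, stop=False)
        + "AAAAAAAAA"
        + random_orf("H", seed=i + 1, stop=False)
        + core[30:120]
        + enc_block
        + core[120:210]
        + enc_block
        + core[210:]
        + "TAA"
    )
    assert len(orf) % 3 == 0
    background = hotspot_free_sequence(1500, seed=1000 + i)
    orf_start = 300
    sequence = background[:orf_start] + orf + background[orf_start + len(orf) :]
    return sequence, (orf_start, orf_start + len(orf))
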