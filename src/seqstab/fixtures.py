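"""Deterministic synthetic sequences with planted hotspots at known loci.

Every detector and the optimizer are exercised against sequences built
here: seeded random backgrounds, certified hotspot-free backgrounds, and
exact planting of SSR runs, direct-repeat pairs and motif consensus sites
at declared coordinates.  Flanks are repaired after planting so that the
maximal extent a detector should report equals the declared extent — the
declared coordinates *are* the ground truth, not an approximation.

All generators are pure functions of their arguments (including the
seed), so fixture corpora are reproducible byte-for-byte across runs and
platforms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .hotspot_detection import find_rmd_sites, find_ssr_sites
from .motif_scanning import MotifMatrix, PSSM, consensus, reverse_complement
from .oracles import brute_force_ssr_sites, has_repeated_kmer

__all__ = [
    "PlantedFeature",
    "PlantedTruth",
    "random_sequence",
    "hotspot_free_sequence",
    "plant_ssr",
    "plant_rmd",
    "plant_motif",
    "random_orf",
    "write_fixture_corpus",
]

_BASES = "ACGT"

# codons per amino acid under the standard code, used for ORF synthesis
_CODONS_BY_AA = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "*": ["TAA", "TAG", "TGA"],
}


@dataclass(frozen=True)
class PlantedFeature:
    kind: str  # "ssr" | "rmd" | "motif"
    start: int
    end: int
    params: dict

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class PlantedTruth:
    """Ground-truth record of everything planted into one sequence."""

    features: list[PlantedFeature] = field(default_factory=list)

    def add(self, feature: PlantedFeature) -> None:
        for existing in self.features:
            if existing.overlaps(feature.start, feature.end):
                raise ValueError(
                    f"planted {feature.kind} at [{feature.start}, {feature.end}) "
                    f"overlaps existing {existing.kind} at "
                    f"[{existing.start}, {existing.end})"
                )
        self.features.append(feature)

    def of_kind(self, kind: str) -> list[PlantedFeature]:
        return [f for f in self.features if f.kind == kind]


def random_sequence(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Seeded random DNA with the requested GC composition.

    The G+C count is fixed at ``round(length * gc_fraction)`` and positions
    are shuffled, so the realised GC fraction is exact to rounding rather
    than binomially noisy.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = random.Random(f"random_sequence:{seed}")
    n_gc = round(length * gc_fraction)
    bases = [rng.choice("GC") for _ in range(n_gc)]
    bases += [rng.choice("AT") for _ in range(length - n_gc)]
    rng.shuffle(bases)
    return "".join(bases)


def _first_duplicate_kmer_pos(seq: str, k: int = 16) -> int | None:
    seen: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        if kmer in seen:
            return i  # position of the second copy
        seen[kmer] = i
    return None


def hotspot_free_sequence(
    length: int, seed: int = 0, gc_fraction: float = 0.5, max_rounds: int = 500
) -> str:
    """Random DNA certified to contain no qualifying SSR and no repeated 16-mer.

    Starts from :func:`random_sequence` and repairs violations in place
    (one base inside each offending run or duplicated 16-mer is resampled)
    until the fast detectors find nothing; the final sequence is then
    re-certified with the exhaustive brute-force enumerators before being
    returned.  Because SSR runs arise at a density of a few percent in
    random DNA, a handful of repair rounds normally suffices.
    """
    if length < 16:
        raise ValueError("length must be at least 16")
    rng = random.Random(f"hotspot_free:{seed}")
    seq = list(random_sequence(length, gc_fraction, seed))
    for _ in range(max_rounds):
        text = "".join(seq)
        dirty = False
        for site in find_ssr_sites(text):
            mid = (site.start + site.end) // 2
            neighbours = {seq[mid]}
            if mid > 0:
                neighbours.add(seq[mid - 1])
            if mid + 1 < length:
                neighbours.add(seq[mid + 1])
            choices = [b for b in _BASES if b not in neighbours] or [
                b for b in _BASES if b != seq[mid]
            ]
            seq[mid] = rng.choice(choices)
            dirty = True
        if not dirty:
            dup = _first_duplicate_kmer_pos(text)
            if dup is not None:
                pos = dup + 8
                seq[pos] = rng.choice([b for b in _BASES if b != seq[pos]])
                dirty = True
        if not dirty:
            break
    else:
        raise RuntimeError(f"failed to build a hotspot-free sequence in {max_rounds} rounds")
    text = "".join(seq)
    # certify with the independent exhaustive enumerators
    if brute_force_ssr_sites(text) or has_repeated_kmer(text):
        raise RuntimeError("hotspot-free certification failed (repair loop bug)")
    return text


def _with_flank(seq: list[str], pos: int, forbidden: set[str]) -> None:
    """Force seq[pos] outside ``forbidden``, avoiding its neighbours too."""
    if seq[pos] not in forbidden:
        return
    avoid = set(forbidden)
    if pos > 0:
        avoid.add(seq[pos - 1])
    if pos + 1 < len(seq):
        avoid.add(seq[pos + 1])
    choices = [b for b in _BASES if b not in avoid] or [b for b in _BASES if b not in forbidden]
    seq[pos] = choices[0]


def plant_ssr(
    sequence: str,
    unit: str,
    n_copies: int,
    position: int,
    truth: PlantedTruth | None = None,
) -> tuple[str, PlantedTruth]:
    """Overwrite ``sequence[position:]`` with ``unit * n_copies``; repair flanks.

    The base immediately left of the run is forced to break the period-L
    extension (it may not equal the unit's last base), and the base
    immediately right may not equal the unit's first base, so the planted
    run's maximal extent equals the declared ``[position, position + L*N)``.
    """
    unit = unit.upper()
    length = len(unit)
    if not (1 <= length <= 15) or set(unit) - set(_BASES):
        raise ValueError("unit must be 1-15 nt over ACGT")
    qualifies = (n_copies >= 3 and length >= 2) or (n_copies >= 4 and length == 1)
    if not qualifies:
        raise ValueError(f"(L={length}, N={n_copies}) does not qualify as an SSR")
    span = length * n_copies
    end = position + span
    if position < 0 or end > len(sequence):
        raise ValueError("planted run does not fit in the sequence")
    truth = truth if truth is not None else PlantedTruth()
    truth.add(
        PlantedFeature("ssr", position, end, {"unit": unit, "n_copies": n_copies})
    )
    seq = list(sequence.upper())
    seq[position:end] = unit * n_copies
    if position > 0:
        _with_flank(seq, position - 1, {unit[-1]})
    if end < len(seq):
        _with_flank(seq, end, {unit[0]})
    return "".join(seq), truth


def plant_rmd(
    sequence: str,
    repeat_len: int,
    spacer: int,
    position: int,
    truth: PlantedTruth | None = None,
) -> tuple[str, PlantedTruth]:
    """Duplicate ``sequence[position:position+repeat_len]`` after ``spacer`` nt.

    The second copy replaces the content at ``position + repeat_len +
    spacer``; single flanking bases of the second copy are repaired so
    neither copy can be extended, making the declared length maximal.
    """
    if repeat_len < 16:
        raise ValueError("repeat_len must be at least 16")
    if spacer < 0:
        raise ValueError("spacer must be non-negative")
    second_start = position + repeat_len + spacer
    end = second_start + repeat_len
    if position < 0 or end > len(sequence):
        raise ValueError("planted repeat pair does not fit in the sequence")
    truth = truth if truth is not None else PlantedTruth()
    truth.add(
        PlantedFeature(
            "rmd",
            position,
            end,
            {
                "repeat_len": repeat_len,
                "spacer": spacer,
                "first_start": position,
                "second_start": second_start,
            },
        )
    )
    seq = list(sequence.upper())
    repeat = seq[position : position + repeat_len]
    seq[second_start:end] = repeat
    if position > 0 and second_start > 0:
        _with_flank(seq, second_start - 1, {seq[position - 1]})
    tail_first = position + repeat_len
    if end < len(seq) and tail_first < len(seq):
        _with_flank(seq, end, {seq[tail_first]})
    return "".join(seq), truth


def plant_motif(
    sequence: str,
    motif: MotifMatrix | PSSM,
    position: int,
    strand: str = "+",
    truth: PlantedTruth | None = None,
) -> tuple[str, PlantedTruth]:
    """Plant the motif's consensus (or its reverse complement) at ``position``."""
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    site = consensus(motif)
    if strand == "-":
        site = reverse_complement(site)
    end = position + len(site)
    if position < 0 or end > len(sequence):
        raise ValueError("planted motif does not fit in the sequence")
    truth = truth if truth is not None else PlantedTruth()
    truth.add(
        PlantedFeature("motif", position, end, {"motif": motif.name, "strand": strand})
    )
    seq = list(sequence.upper())
    seq[position:end] = site
    return "".join(seq), truth


def random_orf(protein: str, seed: int = 0, stop: bool = True) -> str:
    """Encode an amino-acid string codon-wise with a seeded choice per residue.

    Guarantees length divisible by 3 and no internal stop codon; appends a
    terminal stop unless ``stop=False``.
    """
    rng = random.Random(f"random_orf:{seed}")
    codons = []
    for aa in protein.upper():
        if aa == "*" or aa not in _CODONS_BY_AA:
            raise ValueError(f"invalid amino acid {aa!r} for ORF synthesis")
        codons.append(rng.choice(_CODONS_BY_AA[aa]))
    if stop:
        codons.append(rng.choice(_CODONS_BY_AA["*"]))
    return "".join(codons)


def write_fixture_corpus(
    outdir: str | Path,
    n_sequences: int = 10,
    length: int = 2000,
    seed: int = 0,
    motifs: Iterable[MotifMatrix | PSSM] = (),
) -> Path:
    """Write a planted corpus as FASTA plus a truth-table CSV; return the dir.

    Each sequence carries one planted SSR, one planted direct-repeat pair
    and (when motifs are supplied) one planted motif consensus, at evenly
    separated loci on a hotspot-free background.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    motifs = list(motifs)
    fasta_lines: list[str] = []
    truth_rows = ["seq_id,kind,start_1based,end_1based_inclusive,detail"]
    for idx in range(n_sequences):
        rng = random.Random(f"corpus:{seed}:{idx}")
        seq = hotspot_free_sequence(length, seed=seed * 1000 + idx)
        truth = PlantedTruth()
        unit = rng.choice(["AT", "CA", "AAG", "T", "GATC"])
        n_copies = 5 if len(unit) == 1 else 4
        seq, truth = plant_ssr(seq, unit, n_copies, length // 10, truth)
        seq, truth = plant_rmd(seq, 20, 30, length // 2, truth)
        if motifs:
            motif = motifs[idx % len(motifs)]
            strand = "+" if idx % 2 == 0 else "-"
            seq, truth = plant_motif(seq, motif, length - length // 5, strand, truth)
        seq_id = f"planted_{idx:03d}"
        fasta_lines.append(f">{seq_id}")
        fasta_lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
        for feat in truth.features:
            detail = ";".join(f"{k}={v}" for k, v in sorted(feat.params.items()))
            truth_rows.append(f"{seq_id},{feat.kind},{feat.start + 1},{feat.end},{detail}")
    (outdir / "corpus.fasta").write_text("\n".join(fasta_lines) + "\n")
    (outdir / "truth.csv").write_text("\n".join(truth_rows) + "\n")
    return outdir


def assert_detects_planted(sequence: str, truth: PlantedTruth) -> None:
    """Raise unless every planted SSR/RMD feature is detected at exact coords."""
    ssr = {(s.start, s.end, s.unit, s.n_copies) for s in find_ssr_sites(sequence)}
    for feat in truth.of_kind("ssr"):
        key = (feat.start, feat.end, feat.params["unit"], feat.params["n_copies"])
        if key not in ssr:
            raise AssertionError(f"planted SSR {key} not detected")
    rmd = {(s.first_start, s.second_start, s.repeat_len) for s in find_rmd_sites(sequence)}
    for feat in truth.of_kind("rmd"):
        key = (
            feat.params["first_start"],
            feat.params["second_start"],
            feat.params["repeat_len"],
        )
        if key not in rmd:
            raise AssertionError(f"planted RMD {key} not detected")
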