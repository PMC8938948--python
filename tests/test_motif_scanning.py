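"""MEME-minimal parsing, PSSM conversion and two-strand scanning."""

import io
import math

import numpy as np
import pytest
from Bio import motifs as bio_motifs

from seqstab.fixtures import hotspot_free_sequence, plant_motif
from seqstab.motif_scanning import (
    MemeParseError,
    MotifMatrix,
    consensus,
    load_default_motifs,
    parse_meme_minimal,
    ppm_to_pssm,
    reverse_complement,
    scan_sequence,
)
from seqstab.motif_scanning import _encode, _window_scores  # scanner internals

TWO_MOTIFS = """\
MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.30 C 0.20 G 0.20 T 0.30

MOTIF m1
letter-probability matrix: alength= 4 w= 3 nsites= 10000 E= 1e-3
 1.0 0.0 0.0 0.0
 0.0 1.0 0.0 0.0
 0.0 0.0 0.5 0.5

MOTIF m2
letter-probability matrix: alength= 4 w= 2 nsites= 2000 E= 0.5
 0.25 0.25 0.25 0.25
 0.10 0.20 0.30 0.40
"""


class TestParser:
    def test_two_blocks_with_background(self):
        motifs = parse_meme_minimal(TWO_MOTIFS)
        assert [m.name for m in motifs] == ["m1", "m2"]
        assert [m.width for m in motifs] == [3, 2]
        assert np.allclose(motifs[0].background, [0.3, 0.2, 0.2, 0.3])
        assert motifs[0].nsites == 10000 and motifs[1].evalue == 0.5

    def test_uniform_background_assumed_when_absent(self):
        text = TWO_MOTIFS.replace("Background letter frequencies\nA 0.30 C 0.20 G 0.20 T 0.30\n", "")
        motifs = parse_meme_minimal(text)
        assert np.allclose(motifs[0].background, 0.25)

    def test_width_mismatch_names_the_motif(self):
        bad = TWO_MOTIFS.replace("w= 3", "w= 4")
        with pytest.raises(MemeParseError, match="m1"):
            parse_meme_minimal(bad)

    def test_row_not_summing_to_one_names_row(self):
        bad = TWO_MOTIFS.replace(" 0.0 1.0 0.0 0.0", " 0.0 0.9 0.0 0.0")
        with pytest.raises(ValueError, match="m1"):
            parse_meme_minimal(bad)

    def test_non_nucleotide_alphabet_rejected(self):
        bad = TWO_MOTIFS.replace("alength= 4 w= 3", "alength= 20 w= 3")
        with pytest.raises(MemeParseError, match="alphabet"):
            parse_meme_minimal(bad)

    def test_bundled_motif_file_is_well_formed(self):
        from importlib import resources

        text = resources.files("seqstab.data").joinpath("methylation_motifs_synthetic.meme").read_text()
        motifs = parse_meme_minimal(text)
        assert len(motifs) >= 2
        for motif in motifs:
            assert np.allclose(motif.ppm.sum(axis=1), 1.0, atol=1e-3)

    def test_agrees_with_biopython_minimal_parser(self):
        """Independent cross-check of the PPM values against Bio.motifs."""
        ours = parse_meme_minimal(TWO_MOTIFS)
        theirs = bio_motifs.parse(io.StringIO(TWO_MOTIFS), "minimal")
        for mine, ref in zip(ours, theirs):
            ref_ppm = np.array([[ref.pwm[b][i] for b in "ACGT"] for i in range(ref.length)])
            assert np.allclose(mine.ppm, ref_ppm, atol=1e-9)


class TestPssmConversion:
    def test_uniform_ppm_scores_exactly_zero(self):
        motif = MotifMatrix("flat", 4, 10, 0.0, np.full((4, 4), 0.25))
        pssm = ppm_to_pssm(motif, pseudocount=0.0)
        assert np.all(pssm.scores == 0.0)

    def test_certain_base_approaches_two_bits(self):
        motif = MotifMatrix("hard", 1, 10, 0.0, np.array([[1.0, 0.0, 0.0, 0.0]]))
        pssm = ppm_to_pssm(motif, pseudocount=1e-12)
        assert pssm.scores[0][0] == pytest.approx(2.0, abs=1e-9)

    def test_growing_pseudocount_shrinks_magnitudes(self):
        motif = MotifMatrix("hard", 1, 10, 0.0, np.array([[0.9, 0.1, 0.0, 0.0]]))
        mags = [
            np.abs(ppm_to_pssm(motif, pseudocount=eps).scores).sum()
            for eps in (1e-6, 1e-3, 1e-1, 1.0)
        ]
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_zero_background_requires_pseudocount(self):
        motif = MotifMatrix("hard", 1, 10, 0.0, np.array([[1.0, 0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError):
            ppm_to_pssm(motif, background=np.array([1.0, 0.0, 0.0, 0.0]), pseudocount=0.0)


class TestScanning:
    def test_planted_consensus_scores_column_sum(self, pssms):
        pssm = pssms[0]
        background = hotspot_free_sequence(400, seed=21)
        seq, _ = plant_motif(background, pssm, 200, "+")
        hits = [h for h in scan_sequence(seq, [pssm]) if h.start == 200]
        assert len(hits) == 1
        assert hits[0].strand == "+"
        assert hits[0].score == pytest.approx(pssm.scores.max(axis=1).sum(), abs=1e-9)

    def test_reverse_strand_hit_reported_on_forward_coordinates(self, pssms):
        pssm = pssms[1]
        background = hotspot_free_sequence(400, seed=22)
        seq, _ = plant_motif(background, pssm, 150, "-")
        hits = [h for h in scan_sequence(seq, [pssm]) if h.start == 150]
        assert hits and hits[0].strand == "-"
        assert hits[0].score == pytest.approx(pssm.max_score, abs=1e-9)

    def test_all_n_sequence_yields_nothing(self, pssms):
        assert scan_sequence("N" * 100, pssms) == []

    def test_hits_fit_inside_sequence(self, pssms):
        seq = hotspot_free_sequence(500, seed=23)
        for hit in scan_sequence(seq, pssms):
            assert hit.start + hit.width <= len(seq)
            assert hit.score > 0

    def test_strand_symmetry(self, pssms):
        """Scanning the reverse complement flips strands but keeps scores.

        Checked per motif: with one matrix, the best of (+, -) at a start
        index maps exactly onto the mirrored index of the mirrored scan.
        """
        seq = hotspot_free_sequence(600, seed=24)
        for pssm in pssms:
            fwd = scan_sequence(seq, [pssm])
            rev = scan_sequence(reverse_complement(seq), [pssm])
            assert sorted(round(h.score, 9) for h in fwd) == sorted(
                round(h.score, 9) for h in rev
            )
            flipped = {(len(seq) - h.end, "+-"[h.strand == "+"]) for h in fwd}
            assert flipped == {(h.start, h.strand) for h in rev}

    def test_consensus_is_the_maximal_scoring_word(self, pssms):
        for pssm in pssms:
            word = consensus(pssm)
            score = sum(
                pssm.scores[i]["ACGT".index(b)] for i, b in enumerate(word)
            )
            assert score == pytest.approx(pssm.max_score)

    def test_mean_background_score_is_nonpositive(self, pssms):
        # Kullback-Leibler: E[log-odds] under background <= 0; empirical
        # check at 1e5 positions within three standard errors.
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=100_008))
        code = _encode(seq)
        for pssm in pssms[:2]:
            window = _window_scores(code, pssm.scores)
            mean = window.mean()
            sem = window.std() / math.sqrt(window.size)
            assert mean <= 3 * sem
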