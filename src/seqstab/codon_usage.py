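"""Embedded host codon-usage tables for the supported organisms.

Values are approximate genomic codon-usage fractions (the share of each
codon within its synonymous family) of the kind tabulated in the standard
codon-usage databases; they are renormalised per family at load time so
every family sums to 1 exactly.  Codon optimization needs the relative
preferences and their ranking, not database-precision decimals.

Organism names are matched loosely: ``"E. coli"``, ``"e_coli"`` and
``"Escherichia coli"`` all resolve to the same table.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CodonUsageTable", "build_codon_table", "SUPPORTED_ORGANISMS", "STANDARD_CODE"]

# standard genetic code, DNA alphabet, '*' = stop
STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_E_COLI = {
    "TTT": 0.58, "TTC": 0.42,
    "TTA": 0.14, "TTG": 0.13, "CTT": 0.12, "CTC": 0.10, "CTA": 0.04, "CTG": 0.47,
    "ATT": 0.49, "ATC": 0.39, "ATA": 0.11, "ATG": 1.0,
    "GTT": 0.28, "GTC": 0.20, "GTA": 0.17, "GTG": 0.35,
    "TCT": 0.17, "TCC": 0.15, "TCA": 0.14, "TCG": 0.14, "AGT": 0.16, "AGC": 0.25,
    "CCT": 0.18, "CCC": 0.13, "CCA": 0.20, "CCG": 0.49,
    "ACT": 0.19, "ACC": 0.40, "ACA": 0.17, "ACG": 0.25,
    "GCT": 0.18, "GCC": 0.26, "GCA": 0.23, "GCG": 0.33,
    "TAT": 0.59, "TAC": 0.41, "CAT": 0.57, "CAC": 0.43,
    "CAA": 0.34, "CAG": 0.66, "AAT": 0.49, "AAC": 0.51,
    "AAA": 0.74, "AAG": 0.26, "GAT": 0.63, "GAC": 0.37,
    "GAA": 0.68, "GAG": 0.32, "TGT": 0.46, "TGC": 0.54, "TGG": 1.0,
    "CGT": 0.36, "CGC": 0.36, "CGA": 0.07, "CGG": 0.11, "AGA": 0.07, "AGG": 0.04,
    "GGT": 0.35, "GGC": 0.37, "GGA": 0.13, "GGG": 0.15,
    "TAA": 0.61, "TAG": 0.09, "TGA": 0.30,
}

_B_SUBTILIS = {
    "TTT": 0.68, "TTC": 0.32,
    "TTA": 0.21, "TTG": 0.16, "CTT": 0.23, "CTC": 0.11, "CTA": 0.05, "CTG": 0.24,
    "ATT": 0.49, "ATC": 0.37, "ATA": 0.13, "ATG": 1.0,
    "GTT": 0.28, "GTC": 0.26, "GTA": 0.20, "GTG": 0.26,
    "TCT": 0.22, "TCC": 0.13, "TCA": 0.23, "TCG": 0.10, "AGT": 0.11, "AGC": 0.23,
    "CCT": 0.28, "CCC": 0.09, "CCA": 0.19, "CCG": 0.44,
    "ACT": 0.16, "ACC": 0.17, "ACA": 0.40, "ACG": 0.27,
    "GCT": 0.25, "GCC": 0.21, "GCA": 0.28, "GCG": 0.26,
    "TAT": 0.65, "TAC": 0.35, "CAT": 0.68, "CAC": 0.32,
    "CAA": 0.52, "CAG": 0.48, "AAT": 0.56, "AAC": 0.44,
    "AAA": 0.70, "AAG": 0.30, "GAT": 0.64, "GAC": 0.36,
    "GAA": 0.68, "GAG": 0.32, "TGT": 0.54, "TGC": 0.46, "TGG": 1.0,
    "CGT": 0.18, "CGC": 0.20, "CGA": 0.10, "CGG": 0.17, "AGA": 0.26, "AGG": 0.10,
    "GGT": 0.19, "GGC": 0.34, "GGA": 0.31, "GGG": 0.16,
    "TAA": 0.61, "TAG": 0.15, "TGA": 0.24,
}

_C_ELEGANS = {
    "TTT": 0.49, "TTC": 0.51,
    "TTA": 0.11, "TTG": 0.23, "CTT": 0.25, "CTC": 0.17, "CTA": 0.09, "CTG": 0.14,
    "ATT": 0.53, "ATC": 0.31, "ATA": 0.16, "ATG": 1.0,
    "GTT": 0.39, "GTC": 0.22, "GTA": 0.16, "GTG": 0.23,
    "TCT": 0.21, "TCC": 0.13, "TCA": 0.25, "TCG": 0.15, "AGT": 0.15, "AGC": 0.10,
    "CCT": 0.18, "CCC": 0.09, "CCA": 0.53, "CCG": 0.20,
    "ACT": 0.33, "ACC": 0.18, "ACA": 0.34, "ACG": 0.15,
    "GCT": 0.36, "GCC": 0.20, "GCA": 0.31, "GCG": 0.13,
    "TAT": 0.56, "TAC": 0.44, "CAT": 0.61, "CAC": 0.39,
    "CAA": 0.66, "CAG": 0.34, "AAT": 0.62, "AAC": 0.38,
    "AAA": 0.59, "AAG": 0.41, "GAT": 0.68, "GAC": 0.32,
    "GAA": 0.62, "GAG": 0.38, "TGT": 0.55, "TGC": 0.45, "TGG": 1.0,
    "CGT": 0.21, "CGC": 0.10, "CGA": 0.23, "CGG": 0.09, "AGA": 0.29, "AGG": 0.08,
    "GGT": 0.20, "GGC": 0.12, "GGA": 0.59, "GGG": 0.08,
    "TAA": 0.44, "TAG": 0.23, "TGA": 0.33,
}

_D_MELANOGASTER = {
    "TTT": 0.37, "TTC": 0.63,
    "TTA": 0.05, "TTG": 0.18, "CTT": 0.10, "CTC": 0.15, "CTA": 0.09, "CTG": 0.43,
    "ATT": 0.34, "ATC": 0.47, "ATA": 0.19, "ATG": 1.0,
    "GTT": 0.18, "GTC": 0.24, "GTA": 0.11, "GTG": 0.47,
    "TCT": 0.09, "TCC": 0.24, "TCA": 0.09, "TCG": 0.20, "AGT": 0.14, "AGC": 0.25,
    "CCT": 0.13, "CCC": 0.33, "CCA": 0.25, "CCG": 0.29,
    "ACT": 0.17, "ACC": 0.38, "ACA": 0.20, "ACG": 0.26,
    "GCT": 0.19, "GCC": 0.45, "GCA": 0.17, "GCG": 0.19,
    "TAT": 0.37, "TAC": 0.63, "CAT": 0.40, "CAC": 0.60,
    "CAA": 0.30, "CAG": 0.70, "AAT": 0.44, "AAC": 0.56,
    "AAA": 0.30, "AAG": 0.70, "GAT": 0.53, "GAC": 0.47,
    "GAA": 0.33, "GAG": 0.67, "TGT": 0.29, "TGC": 0.71, "TGG": 1.0,
    "CGT": 0.16, "CGC": 0.33, "CGA": 0.15, "CGG": 0.15, "AGA": 0.09, "AGG": 0.11,
    "GGT": 0.21, "GGC": 0.43, "GGA": 0.29, "GGG": 0.07,
    "TAA": 0.41, "TAG": 0.33, "TGA": 0.26,
}

_G_GALLUS = {
    "TTT": 0.42, "TTC": 0.58,
    "TTA": 0.07, "TTG": 0.12, "CTT": 0.12, "CTC": 0.19, "CTA": 0.07, "CTG": 0.43,
    "ATT": 0.33, "ATC": 0.51, "ATA": 0.16, "ATG": 1.0,
    "GTT": 0.17, "GTC": 0.24, "GTA": 0.11, "GTG": 0.48,
    "TCT": 0.18, "TCC": 0.23, "TCA": 0.14, "TCG": 0.06, "AGT": 0.14, "AGC": 0.25,
    "CCT": 0.29, "CCC": 0.32, "CCA": 0.26, "CCG": 0.13,
    "ACT": 0.24, "ACC": 0.37, "ACA": 0.27, "ACG": 0.12,
    "GCT": 0.28, "GCC": 0.40, "GCA": 0.22, "GCG": 0.10,
    "TAT": 0.41, "TAC": 0.59, "CAT": 0.40, "CAC": 0.60,
    "CAA": 0.25, "CAG": 0.75, "AAT": 0.44, "AAC": 0.56,
    "AAA": 0.40, "AAG": 0.60, "GAT": 0.44, "GAC": 0.56,
    "GAA": 0.40, "GAG": 0.60, "TGT": 0.43, "TGC": 0.57, "TGG": 1.0,
    "CGT": 0.09, "CGC": 0.20, "CGA": 0.11, "CGG": 0.20, "AGA": 0.20, "AGG": 0.20,
    "GGT": 0.17, "GGC": 0.35, "GGA": 0.25, "GGG": 0.23,
    "TAA": 0.28, "TAG": 0.22, "TGA": 0.50,
}

_H_SAPIENS = {
    "TTT": 0.46, "TTC": 0.54,
    "TTA": 0.08, "TTG": 0.13, "CTT": 0.13, "CTC": 0.20, "CTA": 0.07, "CTG": 0.40,
    "ATT": 0.36, "ATC": 0.47, "ATA": 0.17, "ATG": 1.0,
    "GTT": 0.18, "GTC": 0.24, "GTA": 0.12, "GTG": 0.46,
    "TCT": 0.19, "TCC": 0.22, "TCA": 0.15, "TCG": 0.05, "AGT": 0.15, "AGC": 0.24,
    "CCT": 0.29, "CCC": 0.32, "CCA": 0.28, "CCG": 0.11,
    "ACT": 0.25, "ACC": 0.36, "ACA": 0.28, "ACG": 0.11,
    "GCT": 0.27, "GCC": 0.40, "GCA": 0.23, "GCG": 0.11,
    "TAT": 0.44, "TAC": 0.56, "CAT": 0.42, "CAC": 0.58,
    "CAA": 0.27, "CAG": 0.73, "AAT": 0.47, "AAC": 0.53,
    "AAA": 0.43, "AAG": 0.57, "GAT": 0.46, "GAC": 0.54,
    "GAA": 0.42, "GAG": 0.58, "TGT": 0.46, "TGC": 0.54, "TGG": 1.0,
    "CGT": 0.08, "CGC": 0.18, "CGA": 0.11, "CGG": 0.20, "AGA": 0.21, "AGG": 0.21,
    "GGT": 0.16, "GGC": 0.34, "GGA": 0.25, "GGG": 0.25,
    "TAA": 0.30, "TAG": 0.24, "TGA": 0.47,
}

_M_MUSCULUS = {
    "TTT": 0.43, "TTC": 0.57,
    "TTA": 0.06, "TTG": 0.13, "CTT": 0.13, "CTC": 0.20, "CTA": 0.08, "CTG": 0.40,
    "ATT": 0.34, "ATC": 0.50, "ATA": 0.16, "ATG": 1.0,
    "GTT": 0.17, "GTC": 0.25, "GTA": 0.12, "GTG": 0.46,
    "TCT": 0.20, "TCC": 0.22, "TCA": 0.14, "TCG": 0.05, "AGT": 0.15, "AGC": 0.24,
    "CCT": 0.31, "CCC": 0.31, "CCA": 0.28, "CCG": 0.10,
    "ACT": 0.25, "ACC": 0.35, "ACA": 0.29, "ACG": 0.11,
    "GCT": 0.29, "GCC": 0.38, "GCA": 0.23, "GCG": 0.10,
    "TAT": 0.43, "TAC": 0.57, "CAT": 0.40, "CAC": 0.60,
    "CAA": 0.25, "CAG": 0.75, "AAT": 0.43, "AAC": 0.57,
    "AAA": 0.39, "AAG": 0.61, "GAT": 0.44, "GAC": 0.56,
    "GAA": 0.40, "GAG": 0.60, "TGT": 0.48, "TGC": 0.52, "TGG": 1.0,
    "CGT": 0.09, "CGC": 0.18, "CGA": 0.12, "CGG": 0.19, "AGA": 0.21, "AGG": 0.21,
    "GGT": 0.18, "GGC": 0.33, "GGA": 0.26, "GGG": 0.23,
    "TAA": 0.26, "TAG": 0.23, "TGA": 0.51,
}

_S_CEREVISIAE = {
    "TTT": 0.59, "TTC": 0.41,
    "TTA": 0.28, "TTG": 0.29, "CTT": 0.13, "CTC": 0.06, "CTA": 0.14, "CTG": 0.11,
    "ATT": 0.46, "ATC": 0.26, "ATA": 0.27, "ATG": 1.0,
    "GTT": 0.39, "GTC": 0.21, "GTA": 0.21, "GTG": 0.19,
    "TCT": 0.26, "TCC": 0.16, "TCA": 0.21, "TCG": 0.10, "AGT": 0.16, "AGC": 0.11,
    "CCT": 0.31, "CCC": 0.15, "CCA": 0.42, "CCG": 0.12,
    "ACT": 0.35, "ACC": 0.22, "ACA": 0.30, "ACG": 0.14,
    "GCT": 0.38, "GCC": 0.22, "GCA": 0.29, "GCG": 0.11,
    "TAT": 0.56, "TAC": 0.44, "CAT": 0.64, "CAC": 0.36,
    "CAA": 0.69, "CAG": 0.31, "AAT": 0.59, "AAC": 0.41,
    "AAA": 0.58, "AAG": 0.42, "GAT": 0.65, "GAC": 0.35,
    "GAA": 0.70, "GAG": 0.30, "TGT": 0.63, "TGC": 0.37, "TGG": 1.0,
    "CGT": 0.14, "CGC": 0.06, "CGA": 0.07, "CGG": 0.04, "AGA": 0.48, "AGG": 0.21,
    "GGT": 0.47, "GGC": 0.19, "GGA": 0.22, "GGG": 0.12,
    "TAA": 0.47, "TAG": 0.23, "TGA": 0.30,
}

_TABLES = {
    "b_subtilis": _B_SUBTILIS,
    "c_elegans": _C_ELEGANS,
    "d_melanogaster": _D_MELANOGASTER,
    "e_coli": _E_COLI,
    "g_gallus": _G_GALLUS,
    "h_sapiens": _H_SAPIENS,
    "m_musculus": _M_MUSCULUS,
    "m_musculus_domesticus": _M_MUSCULUS,
    "s_cerevisiae": _S_CEREVISIAE,
}

_ALIASES = {
    "bacillus_subtilis": "b_subtilis",
    "caenorhabditis_elegans": "c_elegans",
    "drosophila_melanogaster": "d_melanogaster",
    "escherichia_coli": "e_coli",
    "gallus_gallus": "g_gallus",
    "homo_sapiens": "h_sapiens",
    "mus_musculus": "m_musculus",
    "mus_musculus_domesticus": "m_musculus_domesticus",
    "saccharomyces_cerevisiae": "s_cerevisiae",
}

SUPPORTED_ORGANISMS = tuple(sorted(_TABLES))


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative synonymous-codon frequencies of one host organism."""

    organism: str
    frequency: dict  # codon -> fraction within its synonymous family
    families: dict  # amino acid (or '*') -> codons, most frequent first

    def best_codon(self, amino_acid: str) -> str:
        return self.families[amino_acid][0]

    def rank(self, codon: str) -> int:
        """0-based frequency rank of a codon inside its family."""
        return self.families[STANDARD_CODE[codon]].index(codon)


def _normalise_name(organism: str) -> str:
    key = organism.strip().lower().replace(".", "").replace("-", " ")
    key = "_".join(key.split())
    return _ALIASES.get(key, key)


def build_codon_table(organism: str) -> CodonUsageTable:
    """Load the embedded usage table for ``organism``.

    Raises ``ValueError`` listing the supported names when the organism is
    unknown.
    """
    key = _normalise_name(organism)
    if key not in _TABLES:
        supported = ", ".join(SUPPORTED_ORGANISMS)
        raise ValueError(f"unknown organism {organism!r}; supported: {supported}")
    raw = _TABLES[key]
    families: dict[str, list[str]] = {}
    for codon, aa in STANDARD_CODE.items():
        families.setdefault(aa, []).append(codon)
    frequency: dict[str, float] = {}
    for aa, codons in families.items():
        total = sum(raw[c] for c in codons)
        for codon in codons:
            frequency[codon] = raw[codon] / total
        # most frequent first; alphabetical tie-break keeps ranks deterministic
        codons.sort(key=lambda c: (-frequency[c], c))
    return CodonUsageTable(organism=key, frequency=frequency, families=families)
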