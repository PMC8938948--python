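"""PSSM-based motif scanning for methylation and custom hotspots.

Motifs arrive as position probability matrices (PPMs) in MEME minimal
format — the exchange format used by methylation-motif databases and by
MEME itself.  Each PPM is normalised by the nucleotide background
frequencies and log2-transformed into a position-specific scoring matrix
(PSSM); a candidate site's score is the summed log-odds of its bases, so a
positive score means the site is more probable under the motif model than
under background.  With a uniform prior over candidate sites, ranking by
PSSM score ranks sites by their posterior probability of being a true
motif occurrence, which is all the optimizer needs; no estimate of
methylation strength is attempted.

Both strands are scanned; a reverse-strand hit is reported at its
forward-strand coordinate with strand ``-``.  When several motifs cover
the same start index only the best-scoring (motif, strand) is kept there.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "MotifMatrix",
    "PSSM",
    "MotifHit",
    "parse_meme_minimal",
    "ppm_to_pssm",
    "scan_sequence",
    "load_default_motifs",
    "consensus",
    "reverse_complement",
]

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_UNIFORM = np.full(4, 0.25)

#: name of the packaged motif file — a small synthetic stand-in, in MEME
#: minimal format, for the external methylation-motif databases users would
#: normally point the scanner at.
DEFAULT_MOTIF_RESOURCE = "methylation_motifs_synthetic.meme"


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifMatrix:
    """A position probability matrix plus MEME-minimal metadata.

    ``ppm`` is a ``width x 4`` array, columns ordered A, C, G, T; every row
    is a probability distribution over the four bases at that motif index.
    ``background`` carries the file-level background distribution (uniform
    when the file has no background line).
    """

    name: str
    width: int
    nsites: int
    evalue: float
    ppm: np.ndarray
    alphabet_length: int = 4
    background: np.ndarray = field(default_factory=lambda: _UNIFORM.copy())

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        if ppm.shape != (self.width, 4):
            raise ValueError(
                f"motif {self.name!r}: matrix shape {ppm.shape} does not match "
                f"declared width {self.width}"
            )
        if (ppm < 0).any() or (ppm > 1).any():
            raise ValueError(f"motif {self.name!r}: probabilities must lie in [0, 1]")
        bad = np.flatnonzero(np.abs(ppm.sum(axis=1) - 1.0) > 1e-3)
        if bad.size:
            raise ValueError(
                f"motif {self.name!r}: row {bad[0] + 1} sums to "
                f"{ppm[bad[0]].sum():.4f}, not 1 (tolerance 1e-3)"
            )


@dataclass(frozen=True)
class PSSM:
    """Log2-odds scoring matrix of a motif against background frequencies."""

    name: str
    width: int
    scores: np.ndarray  # width x 4
    background: np.ndarray  # length 4

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """One above-background motif occurrence, forward-strand coordinates."""

    motif: str
    start: int
    width: int
    strand: str  # "+" or "-"
    score: float

    @property
    def end(self) -> int:
        return self.start + self.width

    @property
    def rate_or_score(self) -> float:
        return self.score

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class MemeParseError(ValueError):
    pass


_HEADER_RE = re.compile(
    r"letter-probability\s+matrix:\s*alength=\s*(\d+)\s+w=\s*(\d+)"
    r"(?:\s+nsites=\s*(\S+))?(?:\s+E=\s*(\S+))?",
    re.IGNORECASE,
)


def parse_meme_minimal(text: str) -> list[MotifMatrix]:
    """Parse MEME minimal format into one :class:`MotifMatrix` per block.

    Honours a file-level ``Background letter frequencies`` line when
    present, otherwise assumes a uniform background.  Malformed blocks
    (alphabet size other than 4, fewer probability rows than the declared
    width, a row not summing to 1 within 1e-3) raise
    :class:`MemeParseError` naming the motif and the offending line.
    """
    lines = text.splitlines()
    background = _UNIFORM.copy()
    motifs: list[MotifMatrix] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            freq_tokens: list[str] = []
            while i < n_lines and lines[i].strip() and not lines[i].strip().upper().startswith("MOTIF"):
                freq_tokens.extend(lines[i].split())
                i += 1
            pairs = dict(zip(freq_tokens[::2], (float(v) for v in freq_tokens[1::2])))
            try:
                background = np.array([pairs[b] for b in _ALPHABET])
            except KeyError as exc:
                raise MemeParseError(f"background line missing frequency for {exc}") from exc
            if abs(background.sum() - 1.0) > 1e-3:
                raise MemeParseError("background frequencies do not sum to 1")
            continue
        if line.upper().startswith("MOTIF"):
            tokens = line.split()
            if len(tokens) < 2:
                raise MemeParseError(f"line {i + 1}: MOTIF line without a name")
            name = tokens[1]
            i += 1
            while i < n_lines and not _HEADER_RE.search(lines[i]):
                if lines[i].strip().upper().startswith("MOTIF"):
                    raise MemeParseError(
                        f"motif {name!r}: no letter-probability matrix header before line {i + 1}"
                    )
                i += 1
            if i == n_lines:
                raise MemeParseError(f"motif {name!r}: missing letter-probability matrix header")
            header = _HEADER_RE.search(lines[i])
            alength, width = int(header.group(1)), int(header.group(2))
            nsites = int(float(header.group(3))) if header.group(3) else 20
            evalue = float(header.group(4)) if header.group(4) else 0.0
            if alength != 4:
                raise MemeParseError(
                    f"motif {name!r} (line {i + 1}): alphabet length {alength} unsupported, need 4"
                )
            i += 1
            rows: list[list[float]] = []
            while len(rows) < width and i < n_lines:
                stripped = lines[i].strip()
                if not stripped:
                    i += 1
                    continue
                if stripped.upper().startswith(("MOTIF", "URL")):
                    break
                values = stripped.split()
                if len(values) != 4:
                    raise MemeParseError(
                        f"motif {name!r} (line {i + 1}): expected 4 probabilities, got {len(values)}"
                    )
                rows.append([float(v) for v in values])
                i += 1
            if len(rows) != width:
                raise MemeParseError(
                    f"motif {name!r}: declared width {width} but found {len(rows)} probability rows"
                )
            motifs.append(
                MotifMatrix(
                    name=name,
                    width=width,
                    nsites=nsites,
                    evalue=evalue,
                    ppm=np.array(rows),
                    background=background.copy(),
                )
            )
            continue
        i += 1
    return motifs


def ppm_to_pssm(
    motif: MotifMatrix,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-6,
) -> PSSM:
    """Convert a PPM to log2-odds scores against ``background``.

    ``score[i][b] = log2((ppm[i][b] + eps) / (background[b] + eps))``.  The
    pseudocount guards against the exact zeros common in curated PPMs
    without materially shifting score ranks.
    """
    bg = np.asarray(background if background is not None else motif.background, dtype=float)
    if bg.shape != (4,):
        raise ValueError("background must be a 4-vector over A,C,G,T")
    if abs(bg.sum() - 1.0) > 1e-3:
        raise ValueError("background frequencies must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and ((bg == 0).any() or (motif.ppm == 0).any()):
        raise ValueError("zero probabilities require a positive pseudocount")
    scores = np.log2((motif.ppm + pseudocount) / (bg + pseudocount))
    return PSSM(name=motif.name, width=motif.width, scores=scores, background=bg)


def consensus(motif: MotifMatrix | PSSM) -> str:
    """Highest-probability (or highest-scoring) base at each motif index."""
    matrix = motif.ppm if isinstance(motif, MotifMatrix) else motif.scores
    return "".join(_ALPHABET[b] for b in np.argmax(matrix, axis=1))


def _encode(sequence: str) -> np.ndarray:
    table = np.full(128, -1, dtype=np.int8)
    for idx, base in enumerate(_ALPHABET):
        table[ord(base)] = idx
    return table[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]


def _window_scores(code: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Summed per-window log-odds; N bases (code -1) contribute 0."""
    width = scores.shape[0]
    n_windows = code.size - width + 1
    if n_windows <= 0:
        return np.empty(0)
    total = np.zeros(n_windows)
    for i in range(width):
        col = code[i : i + n_windows]
        total += np.where(col >= 0, scores[i][col], 0.0)
    return total


def scan_sequence(sequence: str, pssms: list[PSSM]) -> list[MotifHit]:
    """Best above-background (motif, strand) per start index, both strands.

    Reverse-strand windows are scored by reverse-complementing the PSSM
    rather than the sequence, so a hit's ``start`` is always the leftmost
    forward-strand coordinate of the occupied span.
    """
    if not pssms:
        return []
    code = _encode(sequence)
    n = code.size
    best_score = np.full(n, -np.inf)
    best_key = np.full(n, -1, dtype=int)
    variants: list[tuple[PSSM, str]] = []
    for pssm in pssms:
        variants.append((pssm, "+"))
        variants.append((pssm, "-"))
    for key, (pssm, strand) in enumerate(variants):
        matrix = pssm.scores if strand == "+" else pssm.scores[::-1, ::-1]
        window = _window_scores(code, matrix)
        if window.size == 0:
            continue
        better = window > best_score[: window.size]
        best_score[: window.size][better] = window[better]
        best_key[: window.size][better] = key
    hits: list[MotifHit] = []
    for start in np.flatnonzero((best_score > 0) & (best_key >= 0)):
        pssm, strand = variants[best_key[start]]
        hits.append(
            MotifHit(
                motif=pssm.name,
                start=int(start),
                width=pssm.width,
                strand=strand,
                score=float(best_score[start]),
            )
        )
    return hits


def load_motif_file(path: str | Path, pseudocount: float = 1e-6) -> list[PSSM]:
    """Parse a MEME-minimal file and convert every motif to a PSSM."""
    motifs = parse_meme_minimal(Path(path).read_text())
    return [ppm_to_pssm(m, pseudocount=pseudocount) for m in motifs]


def load_default_motifs(pseudocount: float = 1e-6) -> list[PSSM]:
    """PSSMs of the packaged methylation-style motif set.

    The packaged file is a small synthetic stand-in with the CG-rich
    character of curated methylation motifs; real analyses should point
    the scanner at a full database in the same format.
    """
    text = resources.files("seqstab.data").joinpath(DEFAULT_MOTIF_RESOURCE).read_text()
    return [ppm_to_pssm(m, pseudocount=pseudocount) for m in parse_meme_minimal(text)]
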