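"""Brute-force hotspot enumerators.

Exhaustive reference implementations, deliberately independent of the
scanning detectors in :mod:`seqstab.hotspot_detection`: the SSR oracle
tests every ``(start, unit length)`` pair directly, and the RMD oracle
examines every pairwise alignment offset of the sequence against itself.
They exist to certify hotspot-free fixture sequences and to serve as
ground truth in equivalence tests; at a few kilobases they are fast
enough, but they are not meant for production scanning.
"""

from __future__ import annotations

import numpy as np

__all__ = ["brute_force_ssr_sites", "brute_force_rmd_sites", "has_repeated_kmer"]


def _primitive(unit: str) -> bool:
    length = len(unit)
    return not any(
        length % p == 0 and unit == unit[:p] * (length // p) for p in range(1, length)
    )


def brute_force_ssr_sites(sequence: str) -> set[tuple[int, int, str, int]]:
    """All maximal qualifying tandem runs as ``(start, end, unit, n_copies)``.

    For every start and every unit length 1..15, counts exact consecutive
    unit copies; keeps the run only if it qualifies ((N>=3, L>=2) or
    (N>=4, L=1)), the unit is primitive and N-free, and the period cannot
    be extended one base to the left (leftmost phase).
    """
    seq = sequence.upper()
    n = len(seq)
    found: set[tuple[int, int, str, int]] = set()
    for unit_len in range(1, 16):
        for start in range(n - unit_len):
            unit = seq[start : start + unit_len]
            if "N" in unit or not _primitive(unit):
                continue
            copies = 1
            while seq[start + copies * unit_len : start + (copies + 1) * unit_len] == unit:
                copies += 1
            if unit_len == 1:
                if copies < 4:
                    continue
            elif copies < 3:
                continue
            if start > 0:
                prev = seq[start - 1]
                if prev != "N" and prev == seq[start - 1 + unit_len]:
                    continue  # not the leftmost phase of this run
            found.add((start, start + copies * unit_len, unit, copies))
    return found


def brute_force_rmd_sites(sequence: str, min_len: int = 16) -> set[tuple[int, int, int]]:
    """All maximal same-strand direct-repeat pairs as ``(first, second, length)``.

    Scans every self-alignment offset d: positions where the sequence
    matches itself shifted by d form runs; every maximal run of length
    >= ``min_len`` that does not make the two copies overlap (run length
    <= d) is a repeat pair.
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    valid = arr != ord("N")
    found: set[tuple[int, int, int]] = set()
    for offset in range(1, n - min_len + 1):
        match = (arr[:-offset] == arr[offset:]) & valid[:-offset] & valid[offset:]
        if not match.any():
            continue
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        for lo, hi in zip(starts, ends):
            length = hi - lo
            if length >= min_len and length <= offset:
                found.add((int(lo), int(lo + offset), int(length)))
    return found


def has_repeated_kmer(sequence: str, k: int = 16) -> bool:
    """True if any N-free k-mer occurs more than once (fast exact check)."""
    seq = sequence.upper()
    seen: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        if kmer in seen:
            return True
        seen.add(kmer)
    return False
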