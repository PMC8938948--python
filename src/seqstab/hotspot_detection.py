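"""Detection and ranking of mutational hotspots in DNA sequences.

Two hotspot classes are enumerated:

* **SSR** — simple sequence repeats: maximal tandem runs of a short unit
  (unit length ``1 <= L <= 15``), prone to polymerase slippage.  A run
  qualifies with ``N >= 3`` copies for ``L >= 2`` (e.g. ``ATATAT``) or
  ``N >= 4`` copies for ``L = 1`` (e.g. ``AAAA``).
* **RMD** — repeat-mediated deletions: pairs of identical direct repeats of
  length ``>= 16`` nt on the same strand, which mediate deletion of the
  intervening spacer by recombination or misreplication.

Coordinates are 0-based half-open throughout this module.  ``N`` bases are
treated as matching nothing, including other ``N`` s: they break both
tandem runs and direct repeats.  Reverse-complement (inverted) repeats are
deliberately not considered — only direct repeats recombine by the
modelled mechanism.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence, Union

from .mutation_rates import RateModel, rmd_rate_from_params, ssr_rate_from_params

__all__ = ["SSRSite", "RMDSite", "find_ssr_sites", "find_rmd_sites", "rank_sites"]

_RMD_MIN_LEN = 16


@dataclass(frozen=True)
class SSRSite:
    """A maximal qualifying tandem run: ``sequence[start:end] == unit * n_copies``."""

    start: int
    end: int
    unit: str
    n_copies: int
    rate: float

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def rate_or_score(self) -> float:
        return self.rate

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RMDSite:
    """One ordered pair of identical direct-repeat copies.

    ``spacer`` is the gap between the end of the first copy and the start of
    the second (``second_start - first_start - repeat_len``, >= 0; copies
    never overlap).
    """

    first_start: int
    second_start: int
    repeat_len: int
    rate: float

    @property
    def spacer(self) -> int:
        return self.second_start - self.first_start - self.repeat_len

    @property
    def start(self) -> int:
        return self.first_start

    @property
    def end(self) -> int:
        return self.second_start + self.repeat_len

    @property
    def rate_or_score(self) -> float:
        return self.rate

    @property
    def span(self) -> tuple[int, int]:
        """Span of the first copy (the copy the optimizer rewrites)."""
        return (self.first_start, self.first_start + self.repeat_len)


HotspotSite = Union[SSRSite, RMDSite]


def _is_primitive(unit: str) -> bool:
    """True if the unit's smallest period equals its length."""
    length = len(unit)
    for period in range(1, length):
        if length % period == 0 and unit == unit[:period] * (length // period):
            return False
    return True


def find_ssr_sites(sequence: str, model: RateModel | None = None) -> list[SSRSite]:
    """Enumerate all maximal qualifying tandem runs, sorted by start.

    For every unit length ``L`` the sequence is scanned for maximal runs of
    period-``L`` self-matches (``seq[i] == seq[i+L]``); a run of ``m``
    matches spans ``m + L`` nt and holds ``N = (m + L) // L`` full copies.
    A run is reported once, at its leftmost start, with its smallest
    primitive unit — ``AAAAAA`` is one L=1 N=6 site, never also L=2 N=3.
    """
    model = model or RateModel()
    seq = sequence.upper()
    n = len(seq)
    sites: list[SSRSite] = []
    for unit_len in range(1, 16):
        i = 0
        limit = n - unit_len
        while i < limit:
            if seq[i] != "N" and seq[i] == seq[i + unit_len]:
                j = i
                while j < limit and seq[j] != "N" and seq[j] == seq[j + unit_len]:
                    j += 1
                n_copies = (j - i + unit_len) // unit_len
                min_copies = 4 if unit_len == 1 else 3
                unit = seq[i : i + unit_len]
                if n_copies >= min_copies and _is_primitive(unit):
                    sites.append(
                        SSRSite(
                            start=i,
                            end=i + unit_len * n_copies,
                            unit=unit,
                            n_copies=n_copies,
                            rate=ssr_rate_from_params(unit_len, n_copies, model),
                        )
                    )
                i = j + 1
            else:
                i += 1
    sites.sort(key=lambda s: (s.start, s.unit_length))
    return sites


def find_rmd_sites(sequence: str, model: RateModel | None = None) -> list[RMDSite]:
    """Enumerate maximal direct-repeat pairs of length >= 16 nt.

    All 16-mers are hash-indexed; each pair of occurrences of a shared
    16-mer seeds a maximal extension at its offset, so consecutive shared
    16-mers merge into one repeat (a planted 17-mer is reported as one
    17 nt repeat, not two 16 nt ones).  Repeats with more than two copies
    yield one site per ordered copy pair.  Pairs whose maximal extension
    would make the copies overlap are not reported.
    """
    model = model or RateModel()
    seq = sequence.upper()
    n = len(seq)
    k = _RMD_MIN_LEN
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)

    candidates: dict[int, set[int]] = defaultdict(set)  # offset -> seed starts
    for positions in index.values():
        if len(positions) > 1:
            for a, b in combinations(positions, 2):
                candidates[b - a].add(a)

    sites: list[RMDSite] = []
    for offset, seeds in candidates.items():
        seen_runs: set[int] = set()
        for i in sorted(seeds):
            lo = i
            while lo > 0 and seq[lo - 1] != "N" and seq[lo - 1] == seq[lo - 1 + offset]:
                lo -= 1
            if lo in seen_runs:
                continue
            seen_runs.add(lo)
            hi = i + k
            while hi + offset < n and seq[hi] != "N" and seq[hi] == seq[hi + offset]:
                hi += 1
            repeat_len = hi - lo
            if repeat_len >= k and repeat_len <= offset:
                sites.append(
                    RMDSite(
                        first_start=lo,
                        second_start=lo + offset,
                        repeat_len=repeat_len,
                        rate=rmd_rate_from_params(repeat_len, offset - repeat_len, model),
                    )
                )
    sites.sort(key=lambda s: (s.first_start, s.second_start))
    return sites


def rank_sites(sites: Sequence, budget: int = 10) -> list:
    """Top-``budget`` sites by descending rate/score; ties by ascending start.

    The default budget of 10 sites per type bounds the optimizer's workload
    while covering the most mutation-prone loci.
    """
    if budget < 0:
        raise ValueError("budget must be non-negative")
    ordered = sorted(sites, key=lambda s: (-s.rate_or_score, s.start))
    return list(ordered[:budget])
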