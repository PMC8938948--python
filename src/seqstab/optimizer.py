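"""Two-pass constrained removal of hotspots with codon and GC objectives.

The optimization runs in two passes.  Pass 1 brings the sequence to a
codon-usage optimum under the hard constraints — amino-acid translation
preserved in every ORF, locked regions byte-identical, GC fraction within
bounds in every non-overlapping window (50 nt by default).  Hotspots are
then detected on this semi-optimized sequence, and pass 2 repairs the
top-ranked sites under the same hard constraints: the first copy of each
direct-repeat pair is rewritten so that no 15-mer of it survives (hence no
16-mer identity can remain), motif hits are edited until they no longer
score above background, and alternating unit copies of each tandem run
are substituted to break slippage-prone identity.  Splitting the work this
way means hotspot repair starts from a near-optimal sequence, so few new
problematic sites appear and the codon objective is largely retained.

Constraint resolution is a deterministic, localized satisficer over
synonymous codon choices inside ORFs and free base substitutions outside
them, with a bounded cleanup sweep that re-detects and repairs any
mutational hotspot the edits themselves introduced.  Edits are never made
where no constraint demands them.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np

from .codon_usage import STANDARD_CODE, CodonUsageTable, build_codon_table
from .hotspot_detection import RMDSite, SSRSite, find_rmd_sites, find_ssr_sites
from .motif_scanning import PSSM, MotifHit

__all__ = [
    "OptimizationSpec",
    "PatternConstraint",
    "Change",
    "OptimizationResult",
    "ChangeSummary",
    "UnsatisfiableConstraintError",
    "AuditError",
    "codon_objective_score",
    "first_pass",
    "derive_avoid_constraints",
    "second_pass",
    "verify_result",
]

logger = logging.getLogger(__name__)

_METHODS = ("use_best_codon", "match_codon_usage", "harmonize_rca")
_BASES = "ACGT"
_GC = frozenset("GC")


class UnsatisfiableConstraintError(ValueError):
    """A hard constraint cannot be met (e.g. a locked window forces GC out)."""


class AuditError(AssertionError):
    """An optimization result violates an invariant it promised to keep."""


@dataclass(frozen=True)
class OptimizationSpec:
    """Everything the optimizer needs to know besides the sequence itself.

    Spans are 0-based half-open.  ORF spans must be divisible by 3 and
    disjoint; locked regions are left byte-identical.  ``gc_window`` is the
    width of the non-overlapping windows (anchored at 0) on which the GC
    bounds are enforced.
    """

    organism: str | None = None
    method: str = "use_best_codon"
    gc_min: float = 0.0
    gc_max: float = 1.0
    gc_window: int = 50
    orf_regions: tuple = ()
    locked_regions: tuple = ()
    site_budget: int = 10
    seed: int = 0
    source_organism: str | None = None  # harmonize_rca reference; default E. coli

    def validate(self, seq_length: int) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.gc_window < 1:
            raise ValueError("gc_window must be positive")
        spans = sorted(self.orf_regions)
        for start, end in spans:
            if not (0 <= start < end <= seq_length):
                raise ValueError(f"ORF span ({start}, {end}) outside sequence")
            if (end - start) % 3:
                raise ValueError(f"ORF span ({start}, {end}) length not divisible by 3")
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("ORF spans must not overlap")
        for start, end in self.locked_regions:
            if not (0 <= start < end <= seq_length):
                raise ValueError(f"locked span ({start}, {end}) outside sequence")

    def tables(self) -> tuple[CodonUsageTable | None, CodonUsageTable | None]:
        host = build_codon_table(self.organism) if self.organism else None
        source = build_codon_table(self.source_organism or "e_coli") if host else None
        return host, source


@dataclass(frozen=True)
class PatternConstraint:
    """One forbidden-pattern requirement derived from a ranked hotspot site.

    ``kind`` is ``recombination_15mer`` (every 15-mer of the first repeat
    copy must change), ``motif_span`` (the hit must stop scoring above
    background) or ``ssr_units`` (alternating unit copies substituted).
    """

    kind: str
    span: tuple[int, int]
    detail: dict


@dataclass(frozen=True)
class Change:
    position: int
    old: str
    new: str
    reason: str


@dataclass
class OptimizationResult:
    sequence: str
    changes: list[Change]
    targeted: dict  # type -> number of sites given to pass 2
    removed: dict  # type -> constraints satisfied
    remaining: dict  # type -> constraints not satisfied
    constraint_report: list[str]
    unsatisfied: list[str]
    objective_before: float | None
    objective_after: float | None
    seed: int


@dataclass(frozen=True)
class ChangeSummary:
    n_changes: int
    by_reason: dict


# ---------------------------------------------------------------------------
# editing machinery


class _Editor:
    """Mutable view of a sequence with lock/ORF awareness and a change log."""

    def __init__(self, sequence: str, spec: OptimizationSpec, table: CodonUsageTable | None):
        self.seq = list(sequence.upper())
        self.input = sequence.upper()
        self.n = len(self.seq)
        self.spec = spec
        self.table = table
        self.locked = np.zeros(self.n, dtype=bool)
        for start, end in spec.locked_regions:
            self.locked[start:end] = True
        self.orf_start = np.full(self.n, -1, dtype=np.int64)
        for start, end in spec.orf_regions:
            self.orf_start[start:end] = start
        self.reasons: dict[int, str] = {}

    # -- queries ------------------------------------------------------

    def text(self) -> str:
        return "".join(self.seq)

    def codon_at(self, pos: int) -> tuple[int, str] | None:
        """(codon start, codon string) for an ORF position, else None."""
        orf = int(self.orf_start[pos])
        if orf < 0:
            return None
        cstart = orf + 3 * ((pos - orf) // 3)
        return cstart, "".join(self.seq[cstart : cstart + 3])

    def window_gc(self, lo: int, hi: int) -> float:
        return sum(1 for b in self.seq[lo:hi] if b in _GC) / (hi - lo)

    # -- mutations ----------------------------------------------------

    def set_base(self, pos: int, base: str, reason: str) -> None:
        if self.locked[pos]:
            raise UnsatisfiableConstraintError(f"position {pos} is locked")
        if self.seq[pos] != base:
            self.seq[pos] = base
            self.reasons[pos] = reason

    def set_codon(self, cstart: int, codon: str, reason: str) -> None:
        for offset, base in enumerate(codon):
            if self.seq[cstart + offset] != base:
                self.set_base(cstart + offset, base, reason)

    def synonymous_candidates(self, cstart: int) -> list[str]:
        """Codons preserving translation whose every changed base is unlocked."""
        current = "".join(self.seq[cstart : cstart + 3])
        aa = STANDARD_CODE.get(current)
        if aa is None:
            return []
        out = []
        for codon in _FAMILIES[aa]:
            if codon == current:
                continue
            if all(
                codon[k] == current[k] or not self.locked[cstart + k] for k in range(3)
            ):
                out.append(codon)
        return out

    def change_position(
        self,
        pos: int,
        reason: str,
        avoid: frozenset[str] = frozenset(),
        require_clean: bool = False,
    ) -> bool:
        """Make seq[pos] differ from its current value (and from ``avoid``).

        Inside an ORF only synonymous codon swaps are considered; outside,
        the base is replaced directly, preferring a base that also differs
        from its neighbours (to avoid seeding new runs) and, when a codon
        table is available, the highest-frequency codon.
        """
        if self.locked[pos]:
            return False
        current = self.seq[pos]
        codon = self.codon_at(pos)
        if codon is None:
            neighbours = {current} | set(avoid)
            if pos > 0:
                neighbours.add(self.seq[pos - 1])
            if pos + 1 < self.n:
                neighbours.add(self.seq[pos + 1])
            choices = [b for b in _BASES if b not in neighbours] or [
                b for b in _BASES if b != current and b not in avoid
            ]
            if not choices:
                return False
            best = self._least_disruptive(choices, pos, 1, require_clean)
            if best is None:
                return False
            self.set_base(pos, best, reason)
            return True
        cstart, _ = codon
        offset = pos - cstart
        candidates = [
            c
            for c in self.synonymous_candidates(cstart)
            if c[offset] != current and c[offset] not in avoid
        ]
        if not candidates:
            return False
        if self.table is not None:
            candidates.sort(key=lambda c: (-self.table.frequency[c], c))
        best = self._least_disruptive(candidates, cstart, 3, require_clean)
        if best is None:
            return False
        self.set_codon(cstart, best, reason)
        return True

    def _least_disruptive(
        self, candidates: list[str], where: int, width: int, require_clean: bool = False
    ) -> str | None:
        """First candidate (in preference order) seeding no new tandem run.

        Each candidate is applied to a scratch copy of the local
        neighbourhood and checked for qualifying SSR runs that the current
        sequence does not have.  If every candidate seeds one, the most
        preferred is returned anyway — unless ``require_clean``, in which
        case None signals the caller to try another position.
        """
        lo = max(0, where - 18)
        hi = min(self.n, where + width + 18)
        local = self.seq[lo:hi]
        current_keys = {
            (s.start, s.end, s.unit) for s in find_ssr_sites("".join(local))
        }
        for cand in candidates:
            trial = local[:]
            trial[where - lo : where - lo + width] = cand
            keys = {(s.start, s.end, s.unit) for s in find_ssr_sites("".join(trial))}
            if keys <= current_keys:
                return cand
        return None if require_clean else candidates[0]


_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in STANDARD_CODE.items():
    _FAMILIES.setdefault(_aa, []).append(_codon)
for _fam in _FAMILIES.values():
    _fam.sort()


# ---------------------------------------------------------------------------
# codon objective


def _codons_of(sequence: str, span: tuple[int, int]) -> list[str]:
    start, end = span
    if (end - start) % 3:
        raise ValueError("ORF span length must be divisible by 3")
    codons = [sequence[i : i + 3] for i in range(start, end, 3)]
    for idx, codon in enumerate(codons[:-1]):
        if STANDARD_CODE.get(codon) == "*":
            raise ValueError(f"internal stop codon {codon} at ORF codon {idx + 1}")
    return codons


def codon_objective_score(
    sequence: str,
    orf_span: tuple[int, int],
    table: CodonUsageTable,
    method: str,
    source_table: CodonUsageTable | None = None,
    original_sequence: str | None = None,
) -> float:
    """Score one ORF under the chosen codon-usage objective.

    * ``use_best_codon`` — fraction of codons that are their family's
      most frequent codon (1.0 is optimal).
    * ``match_codon_usage`` — negative L1 distance between the ORF's
      within-family codon frequencies and the host table, weighted by each
      family's share of the ORF (0.0 is optimal).
    * ``harmonize_rca`` — fraction of codons whose within-family frequency
      rank in the host table equals the original codon's rank in the
      source table (1.0 is optimal); the source defaults to *E. coli*.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    codons = _codons_of(sequence.upper(), orf_span)
    if not codons:
        return 0.0
    if method == "use_best_codon":
        hits = sum(1 for c in codons if c == table.best_codon(STANDARD_CODE[c]))
        return hits / len(codons)
    if method == "match_codon_usage":
        counts: dict[str, dict[str, int]] = {}
        for c in codons:
            counts.setdefault(STANDARD_CODE[c], {}).setdefault(c, 0)
            counts[STANDARD_CODE[c]][c] += 1
        distance = 0.0
        for aa, fam_counts in counts.items():
            total = sum(fam_counts.values())
            weight = total / len(codons)
            l1 = sum(
                abs(fam_counts.get(c, 0) / total - table.frequency[c])
                for c in table.families[aa]
            )
            distance += weight * l1
        return -distance
    # harmonize_rca
    source_table = source_table or build_codon_table("e_coli")
    original = (original_sequence or sequence).upper()
    orig_codons = _codons_of(original, orf_span)
    hits = sum(
        1
        for cur, orig in zip(codons, orig_codons)
        if table.rank(cur) == source_table.rank(orig)
    )
    return hits / len(codons)


def _overall_objective(
    sequence: str, spec: OptimizationSpec, original_sequence: str | None = None
) -> float | None:
    host, source = spec.tables()
    if host is None or not spec.orf_regions:
        return None
    scores = [
        codon_objective_score(sequence, span, host, spec.method, source, original_sequence)
        for span in spec.orf_regions
    ]
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# pass 1


def _gc_windows(n: int, width: int) -> list[tuple[int, int]]:
    return [(lo, min(lo + width, n)) for lo in range(0, n, width)]


def _window_ok(editor: _Editor, lo: int, hi: int) -> bool:
    gc = editor.window_gc(lo, hi)
    return editor.spec.gc_min - 1e-12 <= gc <= editor.spec.gc_max + 1e-12


def _repair_window(editor: _Editor, lo: int, hi: int, guard=None, reason: str = "gc_content") -> bool:
    """Drive one window's GC inside bounds; True on success.

    Candidate moves are free-base flips outside ORFs and synonymous codon
    swaps for codons overlapping the window, ordered by GC gain in the
    needed direction and then by host-codon frequency; ``guard`` (if
    given) can veto a move after the fact, in which case it is reverted.
    """
    spec = editor.spec
    for _ in range(2 * (hi - lo)):
        gc = editor.window_gc(lo, hi)
        if spec.gc_min - 1e-12 <= gc <= spec.gc_max + 1e-12:
            return True
        want_gc = gc < spec.gc_min
        moves: list[tuple[float, float, int, str]] = []  # (-delta, -freq, cstart/pos, codon/base)
        pos = lo
        while pos < hi:
            if editor.locked[pos]:
                pos += 1
                continue
            codon = editor.codon_at(pos)
            if codon is None:
                base = editor.seq[pos]
                if want_gc and base in "AT":
                    new = "G" if (pos > 0 and editor.seq[pos - 1] != "G") else "C"
                    moves.append((-1.0, 0.0, pos, new))
                elif not want_gc and base in "GC":
                    new = "A" if (pos > 0 and editor.seq[pos - 1] != "A") else "T"
                    moves.append((-1.0, 0.0, pos, new))
                pos += 1
                continue
            cstart, current = codon
            for cand in editor.synonymous_candidates(cstart):
                delta = sum(
                    (cand[k] in _GC) - (current[k] in _GC)
                    for k in range(3)
                    if lo <= cstart + k < hi
                )
                if (want_gc and delta > 0) or (not want_gc and delta < 0):
                    freq = editor.table.frequency[cand] if editor.table else 0.0
                    moves.append((-abs(delta), -freq, cstart, cand))
            pos = cstart + 3
        moves.sort()
        applied = False
        for require_clean in (True, False):
            for _, _, where, what in moves:
                width = len(what)
                if require_clean and editor._least_disruptive([what], where, width, True) is None:
                    continue
                before = editor.seq[:]
                reasons_before = dict(editor.reasons)
                if width == 3:
                    editor.set_codon(where, what, reason)
                else:
                    editor.set_base(where, what, reason)
                if guard is not None and not guard(editor):
                    editor.seq = before
                    editor.reasons = reasons_before
                    continue
                applied = True
                break
            if applied:
                break
        if not applied:
            return False
    return _window_ok(editor, lo, hi)


def _assign_codons(editor: _Editor, source_table: CodonUsageTable | None) -> None:
    """Pass-1 codon assignment for every ORF, per the configured method.

    Codons with any locked base are kept as-is.  ``match_codon_usage``
    keeps current codons wherever the target allocation allows, so an
    already-matching ORF is a fixed point.
    """
    table = editor.table
    spec = editor.spec
    if table is None:
        return
    for start, end in spec.orf_regions:
        codon_starts = list(range(start, end, 3))
        currents = ["".join(editor.seq[c : c + 3]) for c in codon_starts]
        editable = [
            not editor.locked[c : c + 3].any() and currents[i] in STANDARD_CODE
            for i, c in enumerate(codon_starts)
        ]
        if spec.method == "use_best_codon":
            for i, cstart in enumerate(codon_starts):
                if editable[i]:
                    best = table.best_codon(STANDARD_CODE[currents[i]])
                    editor.set_codon(cstart, best, "codon_optimization")
        elif spec.method == "harmonize_rca":
            src = source_table or build_codon_table("e_coli")
            for i, cstart in enumerate(codon_starts):
                if editable[i]:
                    aa = STANDARD_CODE[currents[i]]
                    rank = src.rank(currents[i])
                    editor.set_codon(cstart, table.families[aa][rank], "codon_optimization")
        else:  # match_codon_usage
            by_family: dict[str, list[int]] = {}
            for i, c in enumerate(currents):
                if editable[i]:
                    by_family.setdefault(STANDARD_CODE[c], []).append(i)
            for aa, indices in by_family.items():
                allocation = _largest_remainder(table, aa, len(indices))
                # keep current codons while quota lasts
                for i in indices:
                    if allocation.get(currents[i], 0) > 0:
                        allocation[currents[i]] -= 1
                    else:
                        currents[i] = ""
                pool = [c for c, k in allocation.items() for _ in range(k)]
                pool_iter = iter(sorted(pool, key=lambda c: (-table.frequency[c], c)))
                for i in indices:
                    if currents[i] == "":
                        editor.set_codon(codon_starts[i], next(pool_iter), "codon_optimization")


def _largest_remainder(table: CodonUsageTable, aa: str, total: int) -> dict[str, int]:
    codons = table.families[aa]
    ideal = {c: table.frequency[c] * total for c in codons}
    counts = {c: int(ideal[c]) for c in codons}
    short = total - sum(counts.values())
    for c in sorted(codons, key=lambda c: (ideal[c] - counts[c], table.frequency[c]), reverse=True)[:short]:
        counts[c] += 1
    return counts


def first_pass(
    sequence: str, spec: OptimizationSpec, report: list[str] | None = None
) -> str:
    """Codon-optimize and regulate GC under the hard constraints.

    With no organism configured only the constraints are resolved.  Any GC
    window that cannot be brought within bounds (for instance because it is
    fully locked) is named in ``report`` (when given) or raises
    :class:`UnsatisfiableConstraintError`.
    """
    sequence = sequence.upper()
    spec.validate(len(sequence))
    host, source = spec.tables()
    editor = _Editor(sequence, spec, host)
    _assign_codons(editor, source)
    unsatisfiable: list[str] = []
    for _ in range(10):
        bad = [w for w in _gc_windows(editor.n, spec.gc_window) if not _window_ok(editor, *w)]
        if not bad:
            break
        progressed = False
        unsatisfiable = []
        for lo, hi in bad:
            if _repair_window(editor, lo, hi):
                progressed = True
            else:
                unsatisfiable.append(f"GC window [{lo}, {hi}) cannot reach bounds")
        if not progressed:
            break
    still_bad = [
        f"GC window [{lo}, {hi}) cannot reach bounds"
        for lo, hi in _gc_windows(editor.n, spec.gc_window)
        if not _window_ok(editor, lo, hi)
    ]
    for message in still_bad:
        if report is not None:
            report.append(message)
            logger.warning(message)
        else:
            raise UnsatisfiableConstraintError(message)
    return editor.text()


# ---------------------------------------------------------------------------
# pass 2


def derive_avoid_constraints(
    ranked_sites: list,
    locked_regions: tuple = (),
    pssms_by_name: dict[str, PSSM] | None = None,
) -> tuple[list[PatternConstraint], list[str]]:
    """Translate ranked hotspot sites into pattern constraints.

    Returns ``(constraints, skipped)``: a site whose target span intersects
    a locked region yields no constraint and is listed in ``skipped``
    (skipped sites do not free up ranking budget).
    """
    constraints: list[PatternConstraint] = []
    skipped: list[str] = []

    def _locked(span: tuple[int, int]) -> bool:
        return any(span[0] < end and start < span[1] for start, end in locked_regions)

    for site in ranked_sites:
        if isinstance(site, SSRSite):
            span = (site.start, site.end)
            if _locked(span):
                skipped.append(f"ssr at [{span[0]}, {span[1]}) skipped (locked)")
                continue
            constraints.append(
                PatternConstraint(
                    "ssr_units",
                    span,
                    {"unit": site.unit, "n_copies": site.n_copies},
                )
            )
        elif isinstance(site, RMDSite):
            span = site.span  # first copy
            if _locked(span):
                skipped.append(f"rmd at [{span[0]}, {span[1]}) skipped (locked)")
                continue
            constraints.append(
                PatternConstraint(
                    "recombination_15mer",
                    span,
                    {"repeat_len": site.repeat_len, "second_start": site.second_start},
                )
            )
        elif isinstance(site, MotifHit):
            span = site.span
            if _locked(span):
                skipped.append(f"motif {site.motif} at [{span[0]}, {span[1]}) skipped (locked)")
                continue
            pssm = (pssms_by_name or {}).get(site.motif)
            constraints.append(
                PatternConstraint(
                    "motif_span",
                    span,
                    {"motif": site.motif, "strand": site.strand, "pssm": pssm},
                )
            )
        else:
            raise TypeError(f"unknown site type {type(site).__name__}")
    for message in skipped:
        logger.warning(message)
    return constraints, skipped


def _motif_score_at(editor: _Editor, constraint: PatternConstraint) -> float:
    pssm: PSSM = constraint.detail["pssm"]
    start, end = constraint.span
    matrix = pssm.scores if constraint.detail["strand"] == "+" else pssm.scores[::-1, ::-1]
    score = 0.0
    for i in range(pssm.width):
        base = editor.seq[start + i]
        idx = _BASES.find(base)
        if idx >= 0:
            score += matrix[i][idx]
    return score


def _break_motif(editor: _Editor, constraint: PatternConstraint) -> bool:
    pssm: PSSM = constraint.detail["pssm"]
    if pssm is None:
        return False
    start, end = constraint.span
    matrix = pssm.scores if constraint.detail["strand"] == "+" else pssm.scores[::-1, ::-1]
    for _ in range(3 * pssm.width):
        if _motif_score_at(editor, constraint) <= 0:
            return True
        moves: list[tuple[float, int, str]] = []  # (delta, where, codon/base)
        pos = start
        while pos < end:
            if editor.locked[pos]:
                pos += 1
                continue
            codon = editor.codon_at(pos)
            if codon is None:
                cur = editor.seq[pos]
                cur_idx = _BASES.find(cur)
                for base in _BASES:
                    if base == cur:
                        continue
                    delta = matrix[pos - start][_BASES.find(base)] - matrix[pos - start][cur_idx]
                    moves.append((float(delta), pos, base))
                pos += 1
                continue
            cstart, current = codon
            for cand in editor.synonymous_candidates(cstart):
                delta = 0.0
                for k in range(3):
                    p = cstart + k
                    if start <= p < end and cand[k] != current[k]:
                        delta += (
                            matrix[p - start][_BASES.find(cand[k])]
                            - matrix[p - start][_BASES.find(current[k])]
                        )
                if any(
                    cand[k] != current[k] and not (start <= cstart + k < end)
                    for k in range(3)
                ):
                    delta += 0.0  # off-span changes are allowed but give no credit
                moves.append((float(delta), cstart, cand))
            pos = cstart + 3
        moves = [m for m in moves if m[0] < 0]
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        delta, where, what = moves[0]
        if len(what) == 3:
            editor.set_codon(where, what, "motif_break")
        else:
            editor.set_base(where, what, "motif_break")
    if _motif_score_at(editor, constraint) <= 0:
        return True
    # Greedy single moves can plateau when every individual substitution
    # raises the score (degenerate columns); sample joint assignments of
    # the editable choice points in the span instead.
    rng = random.Random(f"motif_fix:{editor.spec.seed}:{start}:{end}")
    choice_points: list[tuple[int, list[str]]] = []
    pos = start
    while pos < end:
        if editor.locked[pos]:
            pos += 1
            continue
        codon = editor.codon_at(pos)
        if codon is None:
            choice_points.append((pos, list(_BASES)))
            pos += 1
        else:
            cstart, current = codon
            options = [current] + editor.synonymous_candidates(cstart)
            if len(options) > 1:
                choice_points.append((cstart, options))
            pos = cstart + 3
    if not choice_points:
        return False
    saved = editor.seq[:]
    for _ in range(200):
        editor.seq = saved[:]
        for where, options in choice_points:
            pick = rng.choice(options)
            editor.seq[where : where + len(pick)] = pick
        if _motif_score_at(editor, constraint) <= 0:
            final = editor.seq
            editor.seq = saved
            for where, options in choice_points:
                picked = "".join(final[where : where + len(options[0])])
                if len(options[0]) == 3:
                    editor.set_codon(where, picked, "motif_break")
                elif editor.seq[where] != picked:
                    editor.set_base(where, picked, "motif_break")
            return True
    editor.seq = saved
    return False


def _break_rmd(editor: _Editor, constraint: PatternConstraint) -> bool:
    """Change at least one base in every 15-mer of the first repeat copy."""
    start, end = constraint.span
    changed = [p for p in range(start, end) if editor.seq[p] != editor.input[p]]
    last = start - 1
    ok = True
    window = start
    while window + 15 <= end:
        hit = [c for c in changed if window <= c < window + 15]
        if hit:
            last = max(hit)
        else:
            success = False
            for require_clean in (True, False):
                for p in range(min(window + 14, end - 1), window - 1, -1):
                    if editor.seq[p] == editor.input[p] and editor.change_position(
                        p, "rmd_break", require_clean=require_clean
                    ):
                        changed.append(p)
                        last = p
                        success = True
                        break
                if success:
                    break
            if not success:
                ok = False
                last = window + 14
        window = last + 1
    return ok


def _ssr_overlapping(sequence: str, span: tuple[int, int]) -> list[SSRSite]:
    lo = max(0, span[0] - 20)
    hi = min(len(sequence), span[1] + 20)
    local = find_ssr_sites(sequence[lo:hi])
    out = []
    for site in local:
        s, e = site.start + lo, site.end + lo
        if s < span[1] and span[0] < e:
            out.append(SSRSite(s, e, site.unit, site.n_copies, site.rate))
    return out


def _break_ssr(editor: _Editor, constraint: PatternConstraint) -> bool:
    start, end = constraint.span
    unit = constraint.detail["unit"]
    length = len(unit)
    n_copies = constraint.detail["n_copies"]
    # primary strategy: substitute alternating copies (2nd, 4th, ...)
    for copy_index in range(1, n_copies, 2):
        lo = start + copy_index * length
        hi = lo + length
        if "".join(editor.seq[lo:hi]) != unit:
            continue  # already differs
        for p in range(lo + length // 2, hi):
            if editor.change_position(p, "ssr_break"):
                break
        else:
            for p in range(lo, lo + length // 2):
                if editor.change_position(p, "ssr_break"):
                    break
    if not _ssr_overlapping(editor.text(), (start, end)):
        return True
    # Alternating substitution can itself leave a periodic pattern (e.g.
    # AAA/AAG choices over a lysine stretch).  Fall back to a seeded local
    # search over every editable choice point in the neighbourhood: codons
    # keep synonymous options, free bases range over ACGT, locks stay fixed.
    rng = random.Random(f"ssr_fix:{editor.spec.seed}:{start}:{end}")
    window_lo, window_hi = max(0, start - length), min(editor.n, end + length)
    choice_points: list[tuple[int, list[str]]] = []  # (pos or cstart, options)
    pos = window_lo
    while pos < window_hi:
        if editor.locked[pos]:
            pos += 1
            continue
        codon = editor.codon_at(pos)
        if codon is None:
            choice_points.append((pos, list(_BASES)))
            pos += 1
        else:
            cstart, current = codon
            options = [current] + editor.synonymous_candidates(cstart)
            if len(options) > 1:
                choice_points.append((cstart, options))
            pos = cstart + 3
    if not choice_points:
        return False
    for _ in range(200):
        trial = editor.seq[:]
        for where, options in choice_points:
            pick = rng.choice(options)
            trial[where : where + len(pick)] = pick
        text = "".join(trial)
        if not _ssr_overlapping(text, (start, end)):
            for where, options in choice_points:
                picked = "".join(trial[where : where + len(options[0])])
                if len(options[0]) == 3:
                    editor.set_codon(where, picked, "ssr_break")
                elif editor.seq[where] != picked:
                    editor.set_base(where, picked, "ssr_break")
            return True
    return False


def _constraint_satisfied(editor: _Editor, constraint: PatternConstraint) -> bool:
    if constraint.kind == "ssr_units":
        return not _ssr_overlapping(editor.text(), constraint.span)
    if constraint.kind == "recombination_15mer":
        start, end = constraint.span
        window = start
        while window + 15 <= end:
            if all(editor.seq[p] == editor.input[p] for p in range(window, window + 15)):
                return False
            window += 1
        return True
    if constraint.kind == "motif_span":
        if constraint.detail.get("pssm") is None:
            return True
        return _motif_score_at(editor, constraint) <= 0
    raise ValueError(f"unknown constraint kind {constraint.kind!r}")


_KIND_TO_TYPE = {"ssr_units": "ssr", "recombination_15mer": "rmd", "motif_span": "motif"}


def second_pass(
    sequence: str,
    spec: OptimizationSpec,
    constraints: list[PatternConstraint],
    skipped: list[str] | None = None,
) -> OptimizationResult:
    """Repair the ranked hotspots on a pass-1 sequence.

    All pattern constraints are resolved where possible by synonymous
    substitution inside ORFs and free substitution outside them, never in
    locked regions; pass-1 hard constraints (translation, locks, windowed
    GC) are maintained.  A bounded cleanup sweep then re-detects and
    repairs any *new* SSR/RMD hotspot the edits introduced.  Constraints
    that cannot be satisfied are reported, never silently dropped.
    """
    sequence = sequence.upper()
    spec.validate(len(sequence))
    host, _ = spec.tables()
    editor = _Editor(sequence, spec, host)
    objective_before = _overall_objective(sequence, spec, original_sequence=sequence)

    targeted: dict[str, int] = {"ssr": 0, "rmd": 0, "motif": 0}
    removed: dict[str, int] = {"ssr": 0, "rmd": 0, "motif": 0}
    remaining: dict[str, int] = {"ssr": 0, "rmd": 0, "motif": 0}
    report: list[str] = list(skipped or [])
    unsatisfied: list[str] = []

    breakers = {
        "ssr_units": _break_ssr,
        "recombination_15mer": _break_rmd,
        "motif_span": _break_motif,
    }
    order = sorted(constraints, key=lambda c: c.span)
    for constraint in order:
        targeted[_KIND_TO_TYPE[constraint.kind]] += 1
    baseline = _hotspot_keys(sequence)

    def _cleanup_fresh() -> bool:
        """Repair SSR/RMD hotspots the edits introduced; True if any edit made."""
        any_edit = False
        for _ in range(5):
            text = editor.text()
            fresh = [
                s
                for s in find_ssr_sites(text) + find_rmd_sites(text)
                if _site_key(s) not in baseline
                and not _span_locked(s, spec.locked_regions)
            ]
            if not fresh:
                return any_edit
            swept = False
            for site in fresh:
                if isinstance(site, SSRSite):
                    swept |= _break_ssr(
                        editor,
                        PatternConstraint(
                            "ssr_units",
                            (site.start, site.end),
                            {"unit": site.unit, "n_copies": site.n_copies},
                        ),
                    )
                else:
                    swept |= _break_identity(editor, site)
            any_edit |= swept
            if not swept:
                return any_edit
        return any_edit

    # Constraint resolution, fresh-hotspot cleanup and GC restoration can
    # disturb one another, so they run to a joint fixed point (bounded).
    for _ in range(4):
        for constraint in order:
            if not _constraint_satisfied(editor, constraint):
                breakers[constraint.kind](editor, constraint)
        _cleanup_fresh()
        protected = [c for c in order if _constraint_satisfied(editor, c)]

        def guard(ed: _Editor) -> bool:
            return all(_constraint_satisfied(ed, c) for c in protected)

        for lo, hi in _gc_windows(editor.n, spec.gc_window):
            if not _window_ok(editor, lo, hi):
                _repair_window(editor, lo, hi, guard=guard)
        text = editor.text()
        fresh_left = any(
            _site_key(s) not in baseline and not _span_locked(s, spec.locked_regions)
            for s in find_ssr_sites(text) + find_rmd_sites(text)
        )
        gc_ok = all(_window_ok(editor, *w) for w in _gc_windows(editor.n, spec.gc_window))
        if gc_ok and not fresh_left and all(
            _constraint_satisfied(editor, c) for c in order
        ):
            break

    for constraint in order:
        site_type = _KIND_TO_TYPE[constraint.kind]
        span_text = f"[{constraint.span[0]}, {constraint.span[1]})"
        if _constraint_satisfied(editor, constraint):
            removed[site_type] += 1
            report.append(f"{site_type} at {span_text}: removed")
        else:
            remaining[site_type] += 1
            message = (
                f"{site_type} at {span_text}: could not be fully removed "
                "(editable positions exhausted)"
            )
            report.append(message)
            unsatisfied.append(message)
    text = editor.text()
    leftover = [
        s
        for s in find_ssr_sites(text) + find_rmd_sites(text)
        if _site_key(s) not in baseline and not _span_locked(s, spec.locked_regions)
    ]
    if leftover:
        message = f"{len(leftover)} new hotspot(s) introduced by edits could not be repaired"
        report.append(message)
        unsatisfied.append(message)
    for lo, hi in _gc_windows(editor.n, spec.gc_window):
        if not _window_ok(editor, lo, hi):
            message = f"GC window [{lo}, {hi}) cannot reach bounds after hotspot removal"
            report.append(message)
            unsatisfied.append(message)

    final = editor.text()
    changes = [
        Change(pos, sequence[pos], final[pos], editor.reasons.get(pos, "unknown"))
        for pos in sorted(editor.reasons)
        if sequence[pos] != final[pos]
    ]
    return OptimizationResult(
        sequence=final,
        changes=changes,
        targeted=targeted,
        removed=removed,
        remaining=remaining,
        constraint_report=report,
        unsatisfied=unsatisfied,
        objective_before=objective_before,
        objective_after=_overall_objective(final, spec, original_sequence=sequence),
        seed=spec.seed,
    )


def _break_identity(editor: _Editor, site: RMDSite) -> bool:
    """Directly break a freshly created repeat pair (cleanup-sweep path).

    Unlike :func:`_break_rmd`, which enforces the every-15-mer-changed
    contract against the pass input, this only needs to make the two copies
    differ; one substitution in the first copy (never mirrored into the
    second) suffices.
    """
    first = list(range(site.first_start, site.first_start + site.repeat_len))
    mid = len(first) // 2
    ordering = first[mid:] + first[:mid][::-1]
    for p in ordering:
        twin = site.second_start + (p - site.first_start)
        if editor.seq[p] != editor.seq[twin]:
            return True  # identity already broken
    for require_clean in (True, False):
        for p in ordering:
            if editor.change_position(p, "hotspot_cleanup", require_clean=require_clean):
                return True
    return False


def _site_key(site) -> tuple:
    if isinstance(site, SSRSite):
        return ("ssr", site.start, site.end, site.unit)
    return ("rmd", site.first_start, site.second_start, site.repeat_len)


def _hotspot_keys(sequence: str) -> set:
    return {_site_key(s) for s in find_ssr_sites(sequence) + find_rmd_sites(sequence)}


def _span_locked(site, locked_regions) -> bool:
    lo, hi = site.span
    return any(lo < end and start < hi for start, end in locked_regions)


# ---------------------------------------------------------------------------
# audit


def verify_result(
    original: str,
    result: OptimizationResult,
    spec: OptimizationSpec,
    constraints: list[PatternConstraint] | None = None,
) -> ChangeSummary:
    """Independently re-check every invariant of an optimization result.

    Uses Biopython's translator (not the optimizer's own code paths) for
    the translation check.  Any violation raises :class:`AuditError`.
    """
    from Bio.Seq import Seq

    original = original.upper()
    final = result.sequence
    if len(final) != len(original):
        raise AuditError("sequence length changed")
    for start, end in spec.orf_regions:
        before = str(Seq(original[start:end]).translate())
        after = str(Seq(final[start:end]).translate())
        if before != after:
            raise AuditError(f"translation changed in ORF ({start}, {end})")
    for start, end in spec.locked_regions:
        if original[start:end] != final[start:end]:
            raise AuditError(f"locked region ({start}, {end}) was edited")
    reported = set(result.unsatisfied)
    for lo, hi in _gc_windows(len(final), spec.gc_window):
        gc = sum(1 for b in final[lo:hi] if b in _GC) / (hi - lo)
        if not (spec.gc_min - 1e-12 <= gc <= spec.gc_max + 1e-12):
            if not any(f"[{lo}, {hi})" in message for message in reported):
                raise AuditError(f"GC window [{lo}, {hi}) out of bounds and unreported")
    if constraints:
        editor = _Editor(final, spec, None)
        editor.input = original
        for constraint in constraints:
            message_frag = f"[{constraint.span[0]}, {constraint.span[1]})"
            if any(message_frag in m for m in reported):
                continue
            if not _constraint_satisfied(editor, constraint):
                raise AuditError(f"targeted site at {message_frag} survived optimization")
    hamming = sum(1 for a, b in zip(original, final) if a != b)
    if hamming != len(result.changes):
        raise AuditError(
            f"change log has {len(result.changes)} entries but Hamming distance is {hamming}"
        )
    by_reason: dict[str, int] = {}
    for change in result.changes:
        by_reason[change.reason] = by_reason.get(change.reason, 0) + 1
    return ChangeSummary(n_changes=hamming, by_reason=by_reason)
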