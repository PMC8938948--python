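"""Per-generation mutation-rate models for sequence-instability scoring.

Three mutational channels are modelled, all calibrated on *E. coli*
mutation-accumulation data:

* **BPS** (base-pair substitution) — a uniform spontaneous point-mutation
  baseline of ``mu_bps`` per base per generation.
* **SSR** (simple-sequence-repeat slippage) — tandem runs of a short unit
  (unit length ``L``, copy number ``N``) mutate by polymerase slippage at a
  rate that grows exponentially with copy number; we use a log-linear fit
  ``log10(mu) = intercept + slope * N`` with separate coefficient sets for
  homopolymers (L = 1) and multimeric units (L >= 2), whose qualification
  thresholds and empirical behaviour differ.
* **RMD** (repeat-mediated deletion) — recombination between two identical
  direct repeats of length ``L`` separated by a spacer of ``L_s`` nt.  The
  rate rises sigmoidally with repeat length (midpoint ``alpha`` = 29.0 nt,
  width ``A`` = 5.8 nt) and decays exponentially with spacer length (scale
  ``B`` = 1465.6 nt).

The headline summary statistic is the **RIP score** (Relative Instability
Prediction): the ratio of the total predicted mutation rate (BPS + all SSR
+ all RMD site rates) to the BPS-only rate.  It answers "how much more
likely is this sequence to mutate than an equally long hotspot-free one?"
and attains its minimum of exactly 1 when no hotspot is present.

Absolute rates are *E. coli* per-generation units; for other organisms the
ranking of hypermutable sites is approximately preserved even though the
absolute values are not.  Every constant can be overridden through a plain
``key = value`` config file (see :func:`RateModel.from_config`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover
    from .hotspot_detection import RMDSite, SSRSite

__all__ = ["RateModel", "bps_rate", "ssr_rate", "rmd_rate", "rip_score"]

#: caveat echoed into every report that prints absolute rates
RATE_CAVEAT = (
    "Rates are per-generation estimates calibrated on E. coli; for other "
    "organisms only the ranking of hypermutable sites is approximately "
    "maintained, not the absolute values."
)


def _default_ssr_coefficients() -> dict[str, tuple[float, float]]:
    # (intercept, slope) of log10(rate) vs copy number N, one set per
    # unit-length class.  Homopolymer runs gain ~5x per added base; multimeric
    # units gain ~2.4x per added copy, from a higher floor at the N=3
    # qualification threshold.
    return {
        "homopolymer": (-12.91, 0.729),  # L == 1, qualifies at N >= 4
        "multimer": (-10.18, 0.387),  # L >= 2, qualifies at N >= 3
    }


@dataclass(frozen=True)
class RateModel:
    """Constants of the instability rate model (defaults: *E. coli*)."""

    mu_bps: float = 2.2e-10
    rmd_A: float = 5.8
    rmd_B: float = 1465.6
    rmd_alpha: float = 29.0
    #: maximal per-generation recombination rate for long, adjacent repeats
    rmd_scale: float = 1.0e-4
    ssr_coefficients: dict[str, tuple[float, float]] = field(
        default_factory=_default_ssr_coefficients
    )

    def __post_init__(self) -> None:
        for name in ("mu_bps", "rmd_A", "rmd_B", "rmd_alpha", "rmd_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for lclass, (_, slope) in self.ssr_coefficients.items():
            if slope <= 0:
                raise ValueError(f"ssr slope for {lclass!r} must be positive")

    @classmethod
    def from_config(cls, path: str | Path) -> "RateModel":
        """Load overrides from a ``key = value`` text file.

        Recognised keys: ``mu_bps``, ``rmd_A``, ``rmd_B``, ``rmd_alpha``,
        ``rmd_scale``, ``ssr_homopolymer_intercept/slope``,
        ``ssr_multimer_intercept/slope``.  Unknown keys raise.
        """
        kwargs: dict[str, float] = {}
        coeffs = dict(_default_ssr_coefficients())
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in {"mu_bps", "rmd_A", "rmd_B", "rmd_alpha", "rmd_scale"}:
                kwargs[key] = float(value)
            elif key.startswith("ssr_") and key.endswith(("_intercept", "_slope")):
                lclass = key[len("ssr_") :].rsplit("_", 1)[0]
                which = key.rsplit("_", 1)[1]
                if lclass not in coeffs:
                    raise ValueError(f"{path}:{lineno}: unknown SSR class {lclass!r}")
                intercept, slope = coeffs[lclass]
                coeffs[lclass] = (
                    (float(value), slope) if which == "intercept" else (intercept, float(value))
                )
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(ssr_coefficients=coeffs, **kwargs)

    def ssr_class(self, unit_length: int) -> str:
        return "homopolymer" if unit_length == 1 else "multimer"


def bps_rate(seq_length: int, model: RateModel | None = None) -> float:
    """Whole-sequence baseline: ``seq_length * mu_bps`` per generation."""
    if seq_length < 0:
        raise ValueError("sequence length must be non-negative")
    model = model or RateModel()
    return seq_length * model.mu_bps


def ssr_rate_from_params(unit_length: int, n_copies: int, model: RateModel | None = None) -> float:
    """Slippage rate of a tandem run with unit length ``L`` and ``N`` copies."""
    model = model or RateModel()
    if unit_length < 1 or unit_length > 15:
        raise ValueError("SSR unit length must be in 1..15")
    qualifies = (n_copies >= 3 and unit_length >= 2) or (n_copies >= 4 and unit_length == 1)
    if not qualifies:
        raise ValueError(
            f"site (L={unit_length}, N={n_copies}) does not meet the SSR "
            "qualification thresholds (N>=3, L>=2) or (N>=4, L=1)"
        )
    intercept, slope = model.ssr_coefficients[model.ssr_class(unit_length)]
    return 10.0 ** (intercept + slope * n_copies)


def ssr_rate(site: "SSRSite", model: RateModel | None = None) -> float:
    return ssr_rate_from_params(site.unit_length, site.n_copies, model)


def rmd_rate_from_params(repeat_len: int, spacer: int, model: RateModel | None = None) -> float:
    """Recombination rate of a direct-repeat pair (length ``L``, spacer ``L_s``).

    ``rate = scale * exp(-L_s / B) / (1 + exp((alpha - L) / A))`` — a logistic
    in repeat length whose midpoint ``alpha`` and width ``A``, and the spacer
    decay scale ``B``, are the empirically fitted constants.
    """
    model = model or RateModel()
    if repeat_len < 16:
        raise ValueError("RMD repeats must be at least 16 nt long")
    if spacer < 0:
        raise ValueError("spacer must be non-negative (overlapping copies are not scored)")
    logistic = 1.0 / (1.0 + math.exp((model.rmd_alpha - repeat_len) / model.rmd_A))
    return model.rmd_scale * math.exp(-spacer / model.rmd_B) * logistic


def rmd_rate(site: "RMDSite", model: RateModel | None = None) -> float:
    return rmd_rate_from_params(site.repeat_len, site.spacer, model)


def rip_score(
    seq_length: int,
    ssr_sites: Iterable["SSRSite"] = (),
    rmd_sites: Iterable["RMDSite"] = (),
    model: RateModel | None = None,
) -> float:
    """Relative Instability Prediction: (BPS + sum SSR + sum RMD) / BPS.

    Equals exactly 1.0 when both site lists are empty; strictly above 1
    otherwise.  ``seq_length`` must be positive (the ratio is undefined for
    an empty sequence).
    """
    if seq_length <= 0:
        raise ValueError("RIP score is undefined for an empty sequence")
    model = model or RateModel()
    baseline = bps_rate(seq_length, model)
    total = baseline
    total += sum(ssr_rate(site, model) for site in ssr_sites)
    total += sum(rmd_rate(site, model) for site in rmd_sites)
    return total / baseline
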