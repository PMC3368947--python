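"""Correction factors and the rdnsv estimator.

The genetic code enriches synonymous opportunities for transitions, and
transitions mutate faster than transversions.  With a per-opportunity
transition/transversion rate ratio ``w`` (default 4, i.e. a per-basepair
ratio of 2 given 1 transition vs 2 transversion opportunities per basepair),
the observed per-class rates are inflated/deflated relative to a random
genetic code by

    f_class = (w * q + (1 - q)) / (w/3 + 2/3)

where q is the transition fraction of that class's sites (1/3 under a random
code).  The multiplicative corrector applied to Rn/Rs is f = f_s / f_ns;
equivalently Rs is divided by f_s and Rn by f_ns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .code_sites import SiteCounts

#: Constants observed genome-wide in the reference coding sequence:
#: transition fraction of synonymous sites ~0.5 and of nonsynonymous
#: sites ~4/14, giving f_s = 1.25 and f_ns = 0.925.
FIXED_F_S = 1.25
FIXED_F_NS = 0.925
#: Typical sSite/nsSite ratio of large gene sets.
TYPICAL_SITE_RATIO = 0.3


class UndefinedEstimateError(ZeroDivisionError):
    """rdnsv is undefined (no synonymous SNVs to anchor the neutral rate)."""


def per_opportunity_ratio(per_basepair_ratio: float = 2.0) -> float:
    """Per-opportunity ts/tv rate ratio from the per-basepair ratio.

    Each basepair offers 1 transition and 2 transversion opportunities, so a
    per-basepair rate ratio kappa corresponds to a per-opportunity ratio of
    2 * kappa (default: kappa = 2 -> w = 4).
    """
    if per_basepair_ratio <= 0:
        raise ValueError("rate ratio must be positive")
    return 2.0 * per_basepair_ratio


@dataclass(frozen=True)
class CorrectionFactors:
    """Genetic-code correction factors under transition weight ``w``."""

    w: float
    f_s: float
    f_ns: float
    f_prime: float

    @property
    def f(self) -> float:
        return self.f_s / self.f_ns

    def __post_init__(self) -> None:
        if self.w <= 0 or self.f_s <= 0 or self.f_ns <= 0:
            raise ValueError("w, f_s and f_ns must be positive")


def _class_factor(q_ts: float, w: float) -> float:
    return (w * q_ts + (1.0 - q_ts)) / (w / 3.0 + 2.0 / 3.0)


def correction_factors(sites: SiteCounts, w: float = 4.0) -> CorrectionFactors:
    """Correction factors computed from a gene set's own site counts."""
    if sites.s_site <= 0 or sites.ns_site <= 0:
        raise ValueError("site counts must be positive to derive correction factors")
    q_s = float(sites.s_site_ts / sites.s_site)
    q_n = float(sites.ns_site_ts / sites.ns_site)
    f_s = _class_factor(q_s, w)
    f_ns = _class_factor(q_n, w)
    f_prime = float(sites.s_site / sites.ns_site) * (f_s / f_ns)
    return CorrectionFactors(w=w, f_s=f_s, f_ns=f_ns, f_prime=f_prime)


def fixed_factors(
    w: float = 4.0,
    f_s: float = FIXED_F_S,
    f_ns: float = FIXED_F_NS,
    site_ratio: float = TYPICAL_SITE_RATIO,
) -> CorrectionFactors:
    """The published genome-wide constants (f_s = 1.25, f_ns = 0.925)."""
    return CorrectionFactors(w=w, f_s=f_s, f_ns=f_ns, f_prime=site_ratio * f_s / f_ns)


@dataclass(frozen=True)
class RdnsvEstimate:
    """Relative density of nonsynonymous variants for one set of genes."""

    ns_snv: int
    s_snv: int
    sites: SiteCounts
    factors: CorrectionFactors
    n_chromosomes: Optional[int] = None

    @property
    def rn(self) -> float:
        return self.ns_snv / float(self.sites.ns_site)

    @property
    def rs(self) -> float:
        return self.s_snv / float(self.sites.s_site)

    @property
    def rdnsv(self) -> float:
        return self.factors.f * self.rn / self.rs


def rdnsv_estimate(
    ns_snv: int,
    s_snv: int,
    sites: SiteCounts,
    factors: CorrectionFactors,
    n_chromosomes: Optional[int] = None,
) -> RdnsvEstimate:
    """rdnsv = f * Rn / Rs = f * (nsSNV/sSNV) * (sSite/nsSite)."""
    if sites.s_site <= 0 or sites.ns_site <= 0:
        raise ValueError("site counts must be positive")
    if s_snv == 0:
        raise UndefinedEstimateError(
            "no synonymous SNVs: rdnsv is undefined (neither 0 nor infinite)"
        )
    return RdnsvEstimate(
        ns_snv=ns_snv, s_snv=s_snv, sites=sites, factors=factors,
        n_chromosomes=n_chromosomes,
    )


def rdnsv_rule_of_thumb(ns_snv: int, s_snv: int, f_prime: float = 0.4) -> float:
    """Shortcut estimate: f' * nsSNV/sSNV (f' = 0.4 for typical gene sets)."""
    if s_snv == 0:
        raise UndefinedEstimateError("no synonymous SNVs")
    return f_prime * ns_snv / s_snv
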