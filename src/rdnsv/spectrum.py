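"""rdnsv across derived-allele-frequency bins and the spectrum regression.

SNVs are grouped into disjoint frequency bins, rdnsv is estimated per bin,
and an unweighted ordinary-least-squares line is fitted to the per-bin
values over x = ln(p_rep / p0) with anchor p0 = 0.01.  The intercept is
rdnsv_0 (relative density near frequency 0, i.e. the tolerated-site
proportion) and the prediction at p = 1, rdnsv_1 = a + b*ln(1/p0), is the
proportion of sites where variants are not prevented from fixation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .annotation import AnnotatedSnv
from .code_sites import SiteCounts
from .core import CorrectionFactors, RdnsvEstimate, rdnsv_estimate

logger = logging.getLogger(__name__)

DEFAULT_EDGES: Tuple[float, ...] = (0.02, 0.05, 0.10, 0.20, 0.40, 0.80, 0.95)
DEFAULT_P0 = 0.01


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (presentation convention for summary tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FrequencyBin:
    """Half-open derived-frequency bin [lower, upper) with log coordinate."""

    lower: float
    upper: float
    p_rep: float
    x: float

    def contains(self, p: float) -> bool:
        return self.lower <= p < self.upper


def make_bins(
    edges: Sequence[float] = DEFAULT_EDGES,
    n_chromosomes: int = 400,
    p0: float = DEFAULT_P0,
) -> List[FrequencyBin]:
    """Disjoint bins from upper edges; p_rep is the geometric mean of bounds.

    The first bin's zero lower bound is replaced by 1/n_chromosomes (the
    smallest observable frequency) for the representative-frequency and
    log-coordinate computation only; assignment still uses lower bound 0.
    """
    edges = tuple(edges)
    if any(not (0.0 < e < 1.0) for e in edges) or any(
        b <= a for a, b in zip(edges, edges[1:])
    ):
        raise ValueError(f"bin edges must be strictly increasing within (0,1): {edges}")
    if n_chromosomes < 2:
        raise ValueError("n_chromosomes must be >= 2")
    bins: List[FrequencyBin] = []
    lower = 0.0
    for upper in edges:
        rep_lower = lower if lower > 0 else 1.0 / n_chromosomes
        p_rep = math.sqrt(rep_lower * upper)
        bins.append(FrequencyBin(lower=lower, upper=upper, p_rep=p_rep, x=math.log(p_rep / p0)))
        lower = upper
    return bins


def assign_bin(p: float, bins: Sequence[FrequencyBin]) -> Optional[int]:
    """Index of the bin containing p, or None when p is above the last edge."""
    for i, b in enumerate(bins):
        if b.contains(p):
            return i
    return None


def rdnsv_by_bin(
    annotated: Iterable[AnnotatedSnv],
    sites: SiteCounts,
    factors: CorrectionFactors,
    bins: Sequence[FrequencyBin],
    cumulative: bool = False,
    n_chromosomes: Optional[int] = None,
) -> List[Optional[RdnsvEstimate]]:
    """Per-bin rdnsv estimates sharing the pooled sites and factors.

    SNVs with derived frequency at or above the last edge (default 95%) are
    excluded.  In the default disjoint mode each SNV contributes to exactly
    one bin; in cumulative mode a bin holds every SNV below its upper edge.
    Bins without synonymous SNVs yield None (dropped from the regression).
    """
    ns = np.zeros(len(bins), dtype=int)
    s = np.zeros(len(bins), dtype=int)
    for record in annotated:
        idx = assign_bin(record.p, bins)
        if idx is None:
            continue
        if record.is_nonsynonymous:
            ns[idx] += 1
        else:
            s[idx] += 1
    if cumulative:
        ns = np.cumsum(ns)
        s = np.cumsum(s)
    estimates: List[Optional[RdnsvEstimate]] = []
    for i, b in enumerate(bins):
        if s[i] == 0:
            logger.warning(
                "bin [%.3f, %.3f) has no synonymous SNVs; dropped", b.lower, b.upper
            )
            estimates.append(None)
        else:
            estimates.append(
                rdnsv_estimate(int(ns[i]), int(s[i]), sites, factors, n_chromosomes)
            )
    return estimates


@dataclass(frozen=True)
class SpectrumFit:
    """OLS fit of per-bin rdnsv on x = ln(p_rep/p0)."""

    intercept: float
    slope: float
    p0: float
    r_squared: float
    p_slope: float
    p_intercept: float
    x: Tuple[float, ...]
    y: Tuple[float, ...]
    residuals: Tuple[float, ...]
    lowest_bin_residual: float
    n_bins: int

    @property
    def rdnsv_0(self) -> float:
        return self.intercept

    @property
    def rdnsv_1(self) -> float:
        return self.intercept + self.slope * math.log(1.0 / self.p0)


def evaluate_model(intercept: float, slope: float, p: float, p0: float = DEFAULT_P0) -> float:
    """Evaluate a fitted line a + b*ln(p/p0) at frequency p."""
    if p <= 0:
        raise ValueError("frequency must be positive")
    return intercept + slope * math.log(p / p0)


def predict_rdnsv(fit: SpectrumFit, p: float) -> float:
    return evaluate_model(fit.intercept, fit.slope, p, fit.p0)


def fit_spectrum(
    estimates: Sequence[Optional[RdnsvEstimate]],
    bins: Sequence[FrequencyBin],
    p0: float = DEFAULT_P0,
) -> SpectrumFit:
    """Unweighted OLS of per-bin rdnsv over the log-frequency coordinate.

    Both coefficient tests (slope vs 0, intercept vs 1) are two-sided t-tests
    sharing the residual variance of the fit.  The residual of the lowest
    usable frequency bin is reported separately.
    """
    if len(estimates) != len(bins):
        raise ValueError("estimates and bins must align")
    usable = [(b, e) for b, e in zip(bins, estimates) if e is not None]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable bins to fit, got {len(usable)}")
    x = np.array([math.log(b.p_rep / p0) for b, _ in usable])
    y = np.array([e.rdnsv for _, e in usable])
    if np.ptp(x) == 0:
        raise ValueError("singular design: all bins share one x coordinate")
    result = stats.linregress(x, y)
    fitted = result.intercept + result.slope * x
    residuals = y - fitted
    df = len(x) - 2
    if result.intercept_stderr > 0:
        t_int = (result.intercept - 1.0) / result.intercept_stderr
        p_intercept = 2.0 * stats.t.sf(abs(t_int), df)
    else:
        p_intercept = 0.0 if result.intercept != 1.0 else 1.0
    r_squared = result.rvalue**2
    p_slope = result.pvalue if np.isfinite(result.pvalue) else 1.0
    return SpectrumFit(
        intercept=float(result.intercept),
        slope=float(result.slope),
        p0=p0,
        r_squared=float(r_squared),
        p_slope=float(p_slope),
        p_intercept=float(p_intercept),
        x=tuple(float(v) for v in x),
        y=tuple(float(v) for v in y),
        residuals=tuple(float(v) for v in residuals),
        lowest_bin_residual=float(residuals[0]),
        n_bins=len(x),
    )


def plot_spectrum(fit: SpectrumFit, path: str) -> None:
    """Scatter of per-bin rdnsv with the fitted line (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(fit.x, fit.y, color="k", zorder=3)
    grid = np.linspace(min(fit.x), max(fit.x), 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, color="grey")
    ax.set_xlabel(f"ln(p / {fit.p0:g})")
    ax.set_ylabel("rdnsv")
    ax.set_title(
        f"rdnsv = {fit.intercept:.2f} {fit.slope:+.3f} x  (R^2 = {fit.r_squared:.2f})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
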