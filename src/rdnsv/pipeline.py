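"""Convenience plumbing: run the estimator chain on in-memory datasets."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

from .annotation import AnnotatedSnv, Annotator
from .code_sites import SiteCounts, aggregate, site_counts
from .core import CorrectionFactors, RdnsvEstimate, correction_factors, rdnsv_estimate
from .simulate import SimulatedDataset
from .spectrum import DEFAULT_EDGES, SpectrumFit, fit_spectrum, make_bins, rdnsv_by_bin


def annotate_dataset(dataset: SimulatedDataset) -> List[AnnotatedSnv]:
    """Re-annotate a simulated dataset through the estimator-side classifier."""
    return Annotator(dataset.models, dataset.genome).annotate_all(dataset.snvs)


def pooled_estimate(
    dataset: SimulatedDataset,
    annotated: Optional[Sequence[AnnotatedSnv]] = None,
    w: float = 4.0,
) -> RdnsvEstimate:
    """Pooled rdnsv with factors derived from the dataset's own sequences."""
    if annotated is None:
        annotated = annotate_dataset(dataset)
    sites = aggregate(site_counts(c) for c in dataset.cds)
    factors = correction_factors(sites, w=w)
    ns = sum(1 for a in annotated if a.is_nonsynonymous)
    s = len(annotated) - ns
    return rdnsv_estimate(ns, s, sites, factors,
                          n_chromosomes=dataset.truth["n_chromosomes"])


def spectrum_fit(
    dataset: SimulatedDataset,
    annotated: Optional[Sequence[AnnotatedSnv]] = None,
    edges: Sequence[float] = DEFAULT_EDGES,
    p0: float = 0.01,
    w: float = 4.0,
) -> SpectrumFit:
    """Frequency-bin regression on a simulated dataset."""
    if annotated is None:
        annotated = annotate_dataset(dataset)
    sites = aggregate(site_counts(c) for c in dataset.cds)
    factors = correction_factors(sites, w=w)
    n = int(dataset.truth["n_chromosomes"])
    bins = make_bins(edges, n_chromosomes=n, p0=p0)
    per_bin = rdnsv_by_bin(annotated, sites, factors, bins, n_chromosomes=n)
    return fit_spectrum(per_bin, bins, p0=p0)
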