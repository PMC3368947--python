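"""Gene-set comparisons: permutation tests, background envelopes, selection.

Statistics (Rn, Rs, Rn/Rs, rdnsv) are recomputed from pooled SNV and site
counts of each (permuted) gene set — they are set-level rates, not averages
of per-gene values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import AnnotatedSnv
from .code_sites import SiteCounts
from .core import correction_factors, rdnsv_estimate

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = (
    "ns_snv", "s_snv", "s_site_ts", "s_site_tv", "ns_site_ts", "ns_site_tv",
)
STATISTICS = ("Rn", "Rs", "Rn/Rs", "rdnsv")

_MAX_EXHAUSTIVE = 500_000


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PermutationResult:
    statistic: str
    observed_diff: float
    n_perm: int
    p_value: float
    seed: Optional[int]
    exhaustive: bool


@dataclass(frozen=True)
class BackgroundEnvelope:
    statistic: str
    n_draws: int
    set_size: int
    q_low: float
    q_high: float
    seed: Optional[int]


def build_gene_table(
    sites_by_gene: Mapping[str, SiteCounts],
    annotated: Iterable[AnnotatedSnv],
) -> pd.DataFrame:
    """Per-gene counts table used by all set-level statistics."""
    rows: Dict[str, List[float]] = {
        gene: [0, 0, float(sc.s_site_ts), float(sc.s_site_tv),
               float(sc.ns_site_ts), float(sc.ns_site_tv)]
        for gene, sc in sites_by_gene.items()
    }
    for record in annotated:
        if record.gene_id not in rows:
            logger.warning("SNV gene %s not in site-count universe; skipped", record.gene_id)
            continue
        rows[record.gene_id][0 if record.is_nonsynonymous else 1] += 1
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(GENE_TABLE_COLUMNS))
    table.index.name = "gene_id"
    return table.sort_index()


def _pooled_statistic(pooled: np.ndarray, statistic: str, w: float) -> float:
    """Statistic on a pooled count vector (GENE_TABLE_COLUMNS order)."""
    ns_snv, s_snv, s_ts, s_tv, ns_ts, ns_tv = pooled
    s_site = s_ts + s_tv
    ns_site = ns_ts + ns_tv
    if statistic == "Rn":
        return ns_snv / ns_site
    if statistic == "Rs":
        return s_snv / s_site
    if s_snv == 0:
        return np.nan
    rn_rs = (ns_snv / ns_site) / (s_snv / s_site)
    if statistic == "Rn/Rs":
        return rn_rs
    if statistic == "rdnsv":
        q_s = s_ts / s_site
        q_n = ns_ts / ns_site
        f = (w * q_s + (1 - q_s)) / (w * q_n + (1 - q_n))
        return f * rn_rs
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def _set_matrix(table: pd.DataFrame, genes: Sequence[str]) -> np.ndarray:
    missing = [g for g in genes if g not in table.index]
    if missing:
        raise KeyError(f"genes missing from table: {missing[:5]}...")
    return table.loc[list(genes), list(GENE_TABLE_COLUMNS)].to_numpy(dtype=float)


def set_statistic(
    table: pd.DataFrame, genes: Sequence[str], statistic: str = "rdnsv", w: float = 4.0
) -> float:
    """Pooled-count statistic for one gene set."""
    return _pooled_statistic(_set_matrix(table, genes).sum(axis=0), statistic, w)


def permutation_test(
    table: pd.DataFrame,
    set_a: GeneSet,
    set_b: GeneSet,
    statistic: str = "rdnsv",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    exhaustive: bool = False,
    w: float = 4.0,
) -> PermutationResult:
    """Two-sided label-permutation test of a set-level statistic difference.

    Monte-Carlo p-values carry the add-one correction
    p = (1 + #{|diff*| >= |diff|}) / (n_perm + 1) so they are never 0;
    exhaustive mode enumerates every partition exactly.
    """
    if set(set_a.members) & set(set_b.members):
        raise ValueError("gene sets must be disjoint for the permutation test")
    data = np.vstack([_set_matrix(table, set_a.members), _set_matrix(table, set_b.members)])
    n_a = len(set_a)
    n = data.shape[0]
    observed = _pooled_statistic(data[:n_a].sum(axis=0), statistic, w) - _pooled_statistic(
        data[n_a:].sum(axis=0), statistic, w
    )
    obs_abs = abs(observed) - 1e-12  # tolerate float ties
    total = data.sum(axis=0)

    if exhaustive:
        n_partitions = comb(n, n_a)
        if n_partitions > _MAX_EXHAUSTIVE:
            raise ValueError(
                f"{n_partitions} partitions exceed the exhaustive limit; use Monte Carlo"
            )
        hits = 0
        for idx in combinations(range(n), n_a):
            part_a = data[list(idx)].sum(axis=0)
            diff = _pooled_statistic(part_a, statistic, w) - _pooled_statistic(
                total - part_a, statistic, w
            )
            if abs(diff) >= obs_abs:
                hits += 1
        return PermutationResult(
            statistic=statistic, observed_diff=float(observed),
            n_perm=n_partitions, p_value=hits / n_partitions,
            seed=None, exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        part_a = data[perm[:n_a]].sum(axis=0)
        diff = _pooled_statistic(part_a, statistic, w) - _pooled_statistic(
            total - part_a, statistic, w
        )
        if abs(diff) >= obs_abs:
            hits += 1
    return PermutationResult(
        statistic=statistic, observed_diff=float(observed),
        n_perm=n_perm, p_value=(1 + hits) / (n_perm + 1),
        seed=seed, exhaustive=False,
    )


def background_quantiles(
    table: pd.DataFrame,
    set_size: int = 1500,
    n_draws: int = 10_000,
    statistic: str = "rdnsv",
    seed: Optional[int] = None,
    w: float = 4.0,
    quantiles: Tuple[float, float] = (0.025, 0.975),
) -> BackgroundEnvelope:
    """Envelope of a statistic over random gene sets drawn without replacement."""
    universe = table.index.to_numpy()
    if set_size > len(universe):
        raise ValueError(f"set_size {set_size} exceeds universe size {len(universe)}")
    data = table.loc[:, list(GENE_TABLE_COLUMNS)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    values = np.empty(n_draws)
    for i in range(n_draws):
        idx = rng.choice(len(universe), size=set_size, replace=False)
        values[i] = _pooled_statistic(data[idx].sum(axis=0), statistic, w)
    q_low, q_high = np.quantile(values, quantiles)  # linear interpolation
    return BackgroundEnvelope(
        statistic=statistic, n_draws=n_draws, set_size=set_size,
        q_low=float(q_low), q_high=float(q_high), seed=seed,
    )


def tissue_specificity(
    expression: pd.DataFrame, z_threshold: float = 1.0
) -> pd.DataFrame:
    """Boolean genes x tissues specificity matrix from raw expression values.

    Values are log2 transformed and Z-scored per gene across tissues; a gene
    is specifically expressed in a tissue iff Z > z_threshold.  Zero-variance
    genes are specific in no tissue.
    """
    if expression.shape[1] < 2:
        raise ValueError("expression matrix needs >= 2 tissues")
    if (expression <= 0).to_numpy().any():
        raise ValueError("raw expression values must be positive (log2 applied internally)")
    log_expr = np.log2(expression.astype(float))
    mean = log_expr.mean(axis=1)
    std = log_expr.std(axis=1, ddof=1)
    flat = std == 0
    if flat.any():
        logger.info("%d zero-variance gene(s): specific in no tissue", int(flat.sum()))
    z = log_expr.sub(mean, axis=0).div(std.where(~flat, np.inf), axis=0)
    return z > z_threshold


def select_tissue_specific(
    expression: pd.DataFrame,
    target_tissues: Sequence[str],
    k: int = 1500,
    z_threshold: float = 1.0,
    name: str = "selected",
) -> GeneSet:
    """Top-k genes specifically expressed in the most target tissues.

    Ties are broken by total specificity count across all tissues, then by
    gene id.  Genes specific in no target tissue are never selected.
    """
    missing = [t for t in target_tissues if t not in expression.columns]
    if missing:
        raise KeyError(f"target tissues absent from matrix: {missing}")
    specific = tissue_specificity(expression, z_threshold=z_threshold)
    target_count = specific.loc[:, list(target_tissues)].sum(axis=1)
    total_count = specific.sum(axis=1)
    ranked = pd.DataFrame({"target": target_count, "total": total_count}).query("target > 0")
    order = np.lexsort(
        (ranked.index.to_numpy(), -ranked["total"].to_numpy(), -ranked["target"].to_numpy())
    )
    ranked = ranked.iloc[order]
    if len(ranked) < k:
        logger.warning("only %d genes specific in target tissues (k=%d)", len(ranked), k)
    return GeneSet(name=name, members=tuple(ranked.index[:k]))


def remove_shared(a: GeneSet, b: GeneSet) -> Tuple[GeneSet, GeneSet, Tuple[str, ...]]:
    """Drop genes belonging to both sets from each (returned third)."""
    shared = tuple(sorted(set(a.members) & set(b.members)))
    if shared:
        logger.info("removing %d gene(s) shared by %s and %s", len(shared), a.name, b.name)
    keep_a = tuple(g for g in a.members if g not in shared)
    keep_b = tuple(g for g in b.members if g not in shared)
    return GeneSet(a.name, keep_a), GeneSet(b.name, keep_b), shared
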