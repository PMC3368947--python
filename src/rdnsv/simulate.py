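"""Synthetic exome-variation datasets with known selection structure.

Generates in-frame stop-free coding sequences placed on both strands of
synthetic chromosomes, then sprinkles SNVs over mutational opportunities
with probability proportional to the opportunity weight (transitions x w).
Nonsynonymous opportunities are intolerant with probability pi_intolerant
and never emit; tolerated nonsynonymous variants draw derived counts from a
1/k spectrum optionally down-weighted by exp(-gamma*k/N) to mimic purifying
selection, while synonymous variants are neutral (1/k).  Ground truth
(expected rdnsv_0 = 1 - pi_intolerant) is recorded for parameter-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .annotation import Snv, TranscriptModel, reverse_complement
from .code_sites import (
    BASES,
    CodingSequence,
    EFFECT_SYNONYMOUS,
    GeneticCode,
    STANDARD_CODE,
    classify_substitution,
)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    codon_min: int = 250
    codon_max: int = 350
    n_chromosomes: int = 400
    w: float = 4.0
    s_snv_density: float = 0.05
    pi_intolerant: float = 0.0
    gamma: float = 0.0
    neutral_fraction: float = 0.0
    codon_weights: Optional[Mapping[str, float]] = None
    n_exons_max: int = 3
    flank: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.codon_min < 1 or self.codon_max < self.codon_min:
            raise ValueError("invalid gene/codon-count configuration")
        if self.n_chromosomes < 2 or self.n_chromosomes % 2:
            raise ValueError("n_chromosomes must be an even integer >= 2")
        if not 0.0 <= self.pi_intolerant <= 1.0:
            raise ValueError("pi_intolerant must be in [0, 1]")
        if not 0.0 <= self.neutral_fraction <= 1.0:
            raise ValueError("neutral_fraction must be in [0, 1]")
        if self.gamma < 0 or self.w <= 0 or self.s_snv_density <= 0:
            raise ValueError("gamma >= 0, w > 0 and s_snv_density > 0 required")


@dataclass
class SimulatedDataset:
    cds: List[CodingSequence]
    models: List[TranscriptModel]
    genome: Dict[str, str]
    snvs: List[Snv]
    truth: Dict[str, float]


class _OpportunityTables:
    """Per-sense-codon lookup arrays over the 9 substitution slots.

    Slot s of a codon encodes offset = s // 3 and the (s % 3)-th alternate
    base in sorted order.
    """

    def __init__(self, code: GeneticCode = STANDARD_CODE):
        self.code = code
        self.sense_codons = code.sense_codons
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}
        n = len(self.sense_codons)
        self.effect = np.zeros((n, 9), dtype=np.int8)  # 0 syn, 1 mis, 2 non
        self.is_ts = np.zeros((n, 9), dtype=bool)
        self.alt = np.zeros((n, 9), dtype=np.int8)
        for ci, codon in enumerate(self.sense_codons):
            for offset in range(3):
                alts = [b for b in BASES if b != codon[offset]]
                for rank, alt in enumerate(alts):
                    s = 3 * offset + rank
                    eff, channel = classify_substitution(codon, offset, alt, code)
                    self.effect[ci, s] = (
                        0 if eff == EFFECT_SYNONYMOUS else (2 if eff == "nonsense" else 1)
                    )
                    self.is_ts[ci, s] = channel == "transition"
                    self.alt[ci, s] = _BASE_INDEX[alt]


_TABLES: Dict[int, _OpportunityTables] = {}


def _tables(code: GeneticCode = STANDARD_CODE) -> _OpportunityTables:
    key = id(code)
    if key not in _TABLES:
        _TABLES[key] = _OpportunityTables(code)
    return _TABLES[key]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(BASES)[rng.integers(0, 4, size=n)])


def simulate_cds(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    code: GeneticCode = STANDARD_CODE,
) -> Tuple[List[CodingSequence], List[TranscriptModel], Dict[str, str]]:
    """Random stop-free CDS set with transcript models and a genome.

    Each gene sits on its own synthetic chromosome, split into 1..n_exons_max
    CDS intervals; strands alternate so both orientations are exercised.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    tables = _tables(code)
    weights = None
    if config.codon_weights is not None:
        weights = np.array(
            [config.codon_weights.get(c, 0.0) for c in tables.sense_codons], dtype=float
        )
        if weights.sum() <= 0:
            raise ValueError("codon_weights assign no mass to sense codons")
        weights = weights / weights.sum()

    cds_list: List[CodingSequence] = []
    models: List[TranscriptModel] = []
    genome: Dict[str, str] = {}
    for i in range(config.n_genes):
        n_codons = int(rng.integers(config.codon_min, config.codon_max + 1))
        codon_idx = rng.choice(len(tables.sense_codons), size=n_codons, p=weights)
        cds_seq = "".join(tables.sense_codons[ci] for ci in codon_idx)
        gene_id, transcript_id = f"g{i:04d}", f"t{i:04d}"
        chrom = f"chr{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        genomic_seq = cds_seq if strand == "+" else reverse_complement(cds_seq)

        n_exons = int(rng.integers(1, config.n_exons_max + 1))
        length = len(genomic_seq)
        n_exons = min(n_exons, length)
        cuts = sorted(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        pieces = np.split(np.arange(length), cuts)

        parts: List[str] = [_random_bases(rng, config.flank)]
        pos = config.flank
        intervals: List[Tuple[int, int]] = []
        for j, piece in enumerate(pieces):
            seg = genomic_seq[piece[0] : piece[-1] + 1]
            parts.append(seg)
            intervals.append((pos, pos + len(seg)))
            pos += len(seg)
            if j < len(pieces) - 1:
                intron = _random_bases(rng, int(rng.integers(30, 121)))
                parts.append(intron)
                pos += len(intron)
        parts.append(_random_bases(rng, config.flank))

        genome[chrom] = "".join(parts)
        cds_list.append(CodingSequence(gene_id, transcript_id, cds_seq))
        models.append(
            TranscriptModel(
                gene_id=gene_id, transcript_id=transcript_id, chrom=chrom,
                strand=strand, cds_intervals=tuple(intervals),
            )
        )
    return cds_list, models, genome


def _sfs_pmf(n_chromosomes: int, gamma: float) -> np.ndarray:
    """Discretized spectrum on derived counts 1..N-1, mass ~ exp(-g*k/N)/k."""
    k = np.arange(1, n_chromosomes, dtype=float)
    mass = np.exp(-gamma * k / n_chromosomes) / k
    return mass / mass.sum()


def _position_map(model: TranscriptModel) -> np.ndarray:
    """Coding-strand CDS index -> genomic position."""
    plus = np.concatenate([np.arange(s, e) for s, e in model.cds_intervals])
    return plus[::-1] if model.strand == "-" else plus


def simulate_snvs(
    cds_list: Sequence[CodingSequence],
    models: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    code: GeneticCode = STANDARD_CODE,
) -> SimulatedDataset:
    """Place SNVs over mutational opportunities of the simulated CDS set.

    Every opportunity emits independently with probability c * weight where
    weight is w for transitions and 1 for transversions, and c is calibrated
    so the expected synonymous SNV count equals s_snv_density * sSite.  At
    most one SNV is kept per basepair.  The reference/ancestral allele is the
    genome base; the derived allele is always the alternate.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    tables = _tables(code)
    n = config.n_chromosomes

    codon_arrays = []
    for cds in cds_list:
        idx = np.array([tables.codon_index[c] for c in cds.codons()], dtype=np.int64)
        codon_arrays.append(idx)

    # global calibration of the per-opportunity base rate
    n_syn_ts = n_syn_tv = 0
    for idx in codon_arrays:
        eff = tables.effect[idx].ravel()
        ts = tables.is_ts[idx].ravel()
        syn = eff == 0
        n_syn_ts += int(np.count_nonzero(syn & ts))
        n_syn_tv += int(np.count_nonzero(syn & ~ts))
    if n_syn_ts + n_syn_tv == 0:
        raise ValueError("no synonymous opportunities in the CDS set")
    s_site_total = (n_syn_ts + n_syn_tv) / 3.0
    c = config.s_snv_density * s_site_total / (config.w * n_syn_ts + n_syn_tv)
    if c * max(config.w, 1.0) > 1.0:
        raise ValueError(
            "target sSNV density implies emission probability > 1 per opportunity"
        )

    neutral_pmf = _sfs_pmf(n, 0.0)
    deleterious_pmf = _sfs_pmf(n, config.gamma)
    counts = np.arange(1, n)

    snvs: List[Snv] = []
    n_ns_emitted = n_s_emitted = 0
    for cds, model, idx in zip(cds_list, models, codon_arrays):
        eff = tables.effect[idx].ravel()
        ts = tables.is_ts[idx].ravel()
        alt_idx = tables.alt[idx].ravel()
        size = eff.size
        prob = c * np.where(ts, config.w, 1.0)
        u = rng.random(size)
        tolerated = rng.random(size) >= config.pi_intolerant
        emit = (u < prob) & ((eff == 0) | tolerated)
        op = np.flatnonzero(emit)
        if op.size == 0:
            continue
        bp = (op // 9) * 3 + (op % 9) // 3  # coding-strand CDS position
        _, first = np.unique(bp, return_index=True)
        op = op[np.sort(first)]
        bp = (op // 9) * 3 + (op % 9) // 3

        is_ns = eff[op] != 0
        deleterious = is_ns & (rng.random(op.size) >= config.neutral_fraction)
        ks = np.where(
            deleterious,
            rng.choice(counts, size=op.size, p=deleterious_pmf),
            rng.choice(counts, size=op.size, p=neutral_pmf),
        )

        pos_map = _position_map(model)
        seq = cds.sequence
        flip = model.strand == "-"
        order = np.argsort(pos_map[bp])
        for j in order:
            coding_ref = seq[bp[j]]
            coding_alt = BASES[alt_idx[op[j]]]
            if flip:
                ref = reverse_complement(coding_ref)
                alt = reverse_complement(coding_alt)
            else:
                ref, alt = coding_ref, coding_alt
            snvs.append(
                Snv(
                    chrom=model.chrom, pos=int(pos_map[bp[j]]), ref=ref, alt=alt,
                    alt_count=int(ks[j]), allele_number=n, ancestral=ref,
                )
            )
            if is_ns[j]:
                n_ns_emitted += 1
            else:
                n_s_emitted += 1

    truth = {
        "pi_intolerant": config.pi_intolerant,
        "gamma": config.gamma,
        "neutral_fraction": config.neutral_fraction,
        "expected_rdnsv_0": 1.0 - config.pi_intolerant,
        "n_chromosomes": n,
        "seed": config.seed,
        "n_ns_snv": n_ns_emitted,
        "n_s_snv": n_s_emitted,
    }
    return SimulatedDataset(
        cds=list(cds_list), models=list(models), genome=dict(genome),
        snvs=snvs, truth=truth,
    )


def simulate_dataset(
    config: SimulationConfig, code: GeneticCode = STANDARD_CODE
) -> SimulatedDataset:
    """Full simulation: CDS + models + genome + SNVs under one seeded stream."""
    rng = np.random.default_rng(config.seed)
    cds_list, models, genome = simulate_cds(config, rng=rng, code=code)
    return simulate_snvs(cds_list, models, genome, config, rng=rng, code=code)


def expected_truth(config: SimulationConfig, top_exclusion: float = 0.95) -> Dict[str, float]:
    """Analytic expectations of the generative model.

    ``expected_rdnsv_0`` is the tolerated fraction 1 - pi_intolerant; the
    pooled expectation over all SNVs equals the same value because emission
    is frequency-independent, while the binned pooled value integrates the
    two spectrum shapes over the retained frequency range (p < top_exclusion).
    """
    n = config.n_chromosomes
    k = np.arange(1, n)
    retain = k / n < top_exclusion
    neutral = _sfs_pmf(n, 0.0)
    deleterious = _sfs_pmf(n, config.gamma)
    a = neutral[retain].sum()
    b = deleterious[retain].sum()
    nf = config.neutral_fraction
    tolerated = 1.0 - config.pi_intolerant
    return {
        "expected_rdnsv_0": tolerated,
        "expected_pooled_rdnsv": tolerated,
        "expected_pooled_rdnsv_binned": tolerated * (nf * a + (1.0 - nf) * b) / a,
    }
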