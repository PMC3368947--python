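"""SNV annotation against transcript models.

Maps genomic SNVs into codon space, classifies coding effects, and polarizes
alleles into ancestral/derived states to obtain derived allele frequencies.
Missense and nonsense changes are pooled downstream as nonsynonymous SNVs.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .code_sites import (
    BASES,
    EFFECT_SYNONYMOUS,
    GeneticCode,
    STANDARD_CODE,
    classify_substitution,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

POLARIZATION_OUTGROUP = "outgroup"
POLARIZATION_MINOR_ALLELE = "minor-allele-fallback"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RefMismatchError(ValueError):
    """VCF reference allele disagrees with the genome sequence."""


class MonomorphicSnvError(ValueError):
    """Record carries no segregating derived allele (p == 0)."""


@dataclass(frozen=True)
class Snv:
    """A biallelic single-nucleotide variant with allele counts.

    ``pos`` is 0-based; conversion from VCF's 1-based coordinates happens at
    the I/O boundary.  ``ancestral`` is the outgroup/ancestral base when known.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    allele_number: int
    ancestral: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"non-ACGT alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")
        if not (0 <= self.alt_count <= self.allele_number):
            raise ValueError(
                f"alt count {self.alt_count} outside [0, {self.allele_number}] "
                f"at {self.chrom}:{self.pos}"
            )
        if self.allele_number < 2:
            raise ValueError(f"allele number must be >= 2 at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class TranscriptModel:
    """CDS intervals (0-based, half-open, genomic) for one transcript."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        prev_end = -1
        for start, end in self.cds_intervals:
            if start >= end:
                raise ValueError(f"{self.transcript_id}: empty interval {start}-{end}")
            if start < prev_end:
                raise ValueError(f"{self.transcript_id}: intervals overlap or unsorted")
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    @property
    def span(self) -> Tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]


@dataclass(frozen=True)
class CodonContext:
    """Coding-strand codon context of an SNV."""

    codon: str
    offset: int
    ref: str
    alt: str
    cds_index: int


@dataclass(frozen=True)
class Polarization:
    derived: str
    p: float
    source: str


@dataclass(frozen=True)
class AnnotatedSnv:
    snv: Snv
    gene_id: str
    transcript_id: str
    codon: str
    offset: int
    effect: str
    channel: str
    derived: str
    p: float
    source: str

    @property
    def is_nonsynonymous(self) -> bool:
        return self.effect != EFFECT_SYNONYMOUS


def extract_cds(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Coding-strand CDS sequence of a transcript from a genome mapping."""
    chrom_seq = genome[model.chrom]
    plus = "".join(chrom_seq[s:e] for s, e in model.cds_intervals).upper()
    return reverse_complement(plus) if model.strand == "-" else plus


def _plus_index(model: TranscriptModel, pos: int) -> Optional[int]:
    """Index of ``pos`` within the plus-strand concatenated CDS, or None."""
    offset = 0
    for start, end in model.cds_intervals:
        if start <= pos < end:
            return offset + (pos - start)
        offset += end - start
    return None


def locate_in_cds(
    model: TranscriptModel,
    snv: Snv,
    genome: Mapping[str, str],
    cds: Optional[str] = None,
) -> Optional[CodonContext]:
    """Codon context of an SNV, or None when the position is not coding.

    Alleles and codon are reported on the coding strand; minus-strand models
    reverse-complement the genomic alleles (transition/transversion status is
    preserved by complementation).
    """
    if snv.chrom != model.chrom:
        return None
    plus_idx = _plus_index(model, snv.pos)
    if plus_idx is None:
        return None
    genome_ref = genome[model.chrom][snv.pos].upper()
    if genome_ref != snv.ref:
        raise RefMismatchError(
            f"{snv.chrom}:{snv.pos}: VCF ref {snv.ref} != genome {genome_ref}"
        )
    if cds is None:
        cds = extract_cds(model, genome)
    if model.strand == "-":
        idx = len(cds) - 1 - plus_idx
        ref = snv.ref.translate(_COMPLEMENT)
        alt = snv.alt.translate(_COMPLEMENT)
    else:
        idx = plus_idx
        ref, alt = snv.ref, snv.alt
    offset = idx % 3
    codon = cds[idx - offset : idx - offset + 3]
    if codon[offset] != ref:
        raise RefMismatchError(
            f"{snv.chrom}:{snv.pos}: CDS base {codon[offset]} != coding-strand ref {ref}"
        )
    return CodonContext(codon=codon, offset=offset, ref=ref, alt=alt, cds_index=idx)


def polarize(snv: Snv) -> Polarization:
    """Ancestral/derived polarization of a biallelic SNV.

    Uses the outgroup/ancestral base when it matches one of the two alleles;
    otherwise falls back to taking the minor allele as the most likely derived
    allele.  Monomorphic records raise :class:`MonomorphicSnvError`.
    """
    an = snv.allele_number
    ancestral = snv.ancestral.upper() if snv.ancestral else None
    if ancestral == snv.ref:
        derived, count, source = snv.alt, snv.alt_count, POLARIZATION_OUTGROUP
    elif ancestral == snv.alt:
        derived, count, source = snv.ref, an - snv.alt_count, POLARIZATION_OUTGROUP
    else:
        if snv.alt_count <= an - snv.alt_count:
            derived, count = snv.alt, snv.alt_count
        else:
            derived, count = snv.ref, an - snv.alt_count
        source = POLARIZATION_MINOR_ALLELE
    if count == 0:
        raise MonomorphicSnvError(
            f"{snv.chrom}:{snv.pos}: derived allele count is 0 (monomorphic)"
        )
    return Polarization(derived=derived, p=count / an, source=source)


def classify_snv(
    model: TranscriptModel,
    snv: Snv,
    genome: Mapping[str, str],
    code: GeneticCode = STANDARD_CODE,
    cds: Optional[str] = None,
) -> Optional[AnnotatedSnv]:
    """Annotate one SNV against one transcript model.

    Returns None for non-coding positions; monomorphic records are skipped
    with a warning.
    """
    context = locate_in_cds(model, snv, genome, cds=cds)
    if context is None:
        return None
    effect, channel = classify_substitution(context.codon, context.offset, context.alt, code)
    try:
        polarization = polarize(snv)
    except MonomorphicSnvError as exc:
        logger.warning("skipping monomorphic record: %s", exc)
        return None
    return AnnotatedSnv(
        snv=snv,
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        codon=context.codon,
        offset=context.offset,
        effect=effect,
        channel=channel,
        derived=polarization.derived,
        p=polarization.p,
        source=polarization.source,
    )


def count_by_class(
    annotated: Iterable[AnnotatedSnv], genes: Optional[Iterable[str]] = None
) -> Tuple[int, int]:
    """(nsSNV, sSNV) counts, optionally restricted to a gene-set filter."""
    gene_filter = set(genes) if genes is not None else None
    ns = s = 0
    for record in annotated:
        if gene_filter is not None and record.gene_id not in gene_filter:
            continue
        if record.is_nonsynonymous:
            ns += 1
        else:
            s += 1
    return ns, s


class Annotator:
    """Annotates SNV streams against a set of transcript models.

    One designated (canonical) transcript per gene is expected; an SNV hit by
    the canonical transcripts of two different genes is annotated against
    both (and logged).
    """

    def __init__(
        self,
        models: Sequence[TranscriptModel],
        genome: Mapping[str, str],
        code: GeneticCode = STANDARD_CODE,
    ):
        self.models = list(models)
        self.genome = genome
        self.code = code
        self._cds_cache: Dict[str, str] = {
            m.transcript_id: extract_cds(m, genome) for m in self.models
        }
        self._by_chrom: Dict[str, List[Tuple[int, int, TranscriptModel]]] = {}
        for m in self.models:
            start, end = m.span
            self._by_chrom.setdefault(m.chrom, []).append((start, end, m))
        for entries in self._by_chrom.values():
            entries.sort(key=lambda t: (t[0], t[1]))
        self._starts = {c: [t[0] for t in v] for c, v in self._by_chrom.items()}
        self.n_fallback = 0
        self.n_polarized = 0

    def _candidates(self, snv: Snv) -> List[TranscriptModel]:
        entries = self._by_chrom.get(snv.chrom, [])
        if not entries:
            return []
        hi = bisect.bisect_right(self._starts[snv.chrom], snv.pos)
        return [m for start, end, m in entries[:hi] if start <= snv.pos < end]

    def annotate(self, snv: Snv) -> List[AnnotatedSnv]:
        hits: List[AnnotatedSnv] = []
        for model in self._candidates(snv):
            record = classify_snv(
                model, snv, self.genome, code=self.code,
                cds=self._cds_cache[model.transcript_id],
            )
            if record is not None:
                hits.append(record)
        if len(hits) > 1:
            logger.info(
                "%s:%d annotated against %d genes: %s",
                snv.chrom, snv.pos, len(hits), ",".join(h.gene_id for h in hits),
            )
        for record in hits[:1]:
            self.n_polarized += 1
            if record.source == POLARIZATION_MINOR_ALLELE:
                self.n_fallback += 1
        return hits

    def annotate_all(self, snvs: Iterable[Snv]) -> List[AnnotatedSnv]:
        out: List[AnnotatedSnv] = []
        for snv in snvs:
            out.extend(self.annotate(snv))
        return out

    @property
    def fallback_fraction(self) -> float:
        """Fraction of annotated SNVs polarized by the minor-allele fallback."""
        return self.n_fallback / self.n_polarized if self.n_polarized else 0.0
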