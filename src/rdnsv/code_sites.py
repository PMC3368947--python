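"""Counting of synonymous and nonsynonymous mutational opportunities.

Every basepair of an in-frame coding sequence allows three single-base
substitutions.  Each substitution is one "opportunity" weighted 1/3 site and
classified by its coding effect (synonymous / missense / nonsense) and its
mutational channel (transition / transversion).  Counts are accumulated in
exact rational arithmetic so that conservation identities (total sites = L,
transition sites = L/3) hold exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import product
from typing import Iterable, Mapping, Tuple

from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

BASES: Tuple[str, ...] = ("A", "C", "G", "T")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
THIRD = Fraction(1, 3)

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_MISSENSE = "missense"
EFFECT_NONSENSE = "nonsense"
CHANNEL_TRANSITION = "transition"
CHANNEL_TRANSVERSION = "transversion"


class InternalStopError(ValueError):
    """Raised when a coding sequence contains a stop codon."""

    def __init__(self, codon: str, codon_index: int):
        self.codon = codon
        self.codon_index = codon_index
        super().__init__(
            f"internal stop codon {codon!r} at codon index {codon_index}"
        )


class FrameError(ValueError):
    """Raised when a coding sequence length is not divisible by 3."""


def is_transition(ref: str, alt: str) -> bool:
    """True iff ref->alt is a purine<->purine or pyrimidine<->pyrimidine change."""
    pair = {ref, alt}
    return pair <= _PURINES or pair <= _PYRIMIDINES


@dataclass(frozen=True, eq=False)
class GeneticCode:
    """Total codon -> amino-acid lookup over {A,C,G,T}^3; ``*`` marks stops."""

    table: Mapping[str, str]

    def __post_init__(self) -> None:
        expected = {"".join(c) for c in product(BASES, repeat=3)}
        if set(self.table) != expected:
            missing = expected - set(self.table)
            raise ValueError(f"genetic code table is not total; missing {sorted(missing)[:3]}...")

    def translate(self, codon: str) -> str:
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == "*"

    @property
    def sense_codons(self) -> Tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.table.items()) if aa != "*")

    @property
    def stop_codons(self) -> Tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.table.items()) if aa == "*")

    @classmethod
    def standard(cls) -> "GeneticCode":
        ncbi = unambiguous_dna_by_id[1]
        table = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            table[stop] = "*"
        code = cls(table=table)
        assert len(code.sense_codons) == 61 and len(code.stop_codons) == 3
        return code


STANDARD_CODE = GeneticCode.standard()


def classify_substitution(
    codon: str, offset: int, alt: str, code: GeneticCode = STANDARD_CODE
) -> Tuple[str, str]:
    """Classify a single-base change in a sense codon.

    Returns ``(effect, channel)`` where effect is one of synonymous /
    missense / nonsense and channel is transition / transversion.
    """
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon!r} is not a valid substitution context")
    if offset not in (0, 1, 2):
        raise ValueError(f"offset must be 0..2, got {offset}")
    if alt not in BASES:
        raise ValueError(f"invalid alternate base {alt!r}")
    ref = codon[offset]
    if alt == ref:
        raise ValueError(f"alternate base equals reference base {ref!r}")

    mutated = codon[:offset] + alt + codon[offset + 1 :]
    if code.is_stop(mutated):
        effect = EFFECT_NONSENSE
    elif code.translate(mutated) == code.translate(codon):
        effect = EFFECT_SYNONYMOUS
    else:
        effect = EFFECT_MISSENSE
    channel = CHANNEL_TRANSITION if is_transition(ref, alt) else CHANNEL_TRANSVERSION
    return effect, channel


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous/nonsynonymous opportunity counts by channel."""

    s_site_ts: Fraction = Fraction(0)
    s_site_tv: Fraction = Fraction(0)
    ns_site_ts: Fraction = Fraction(0)
    ns_site_tv: Fraction = Fraction(0)

    @property
    def s_site(self) -> Fraction:
        return self.s_site_ts + self.s_site_tv

    @property
    def ns_site(self) -> Fraction:
        return self.ns_site_ts + self.ns_site_tv

    @property
    def total(self) -> Fraction:
        return self.s_site + self.ns_site

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(
            self.s_site_ts + other.s_site_ts,
            self.s_site_tv + other.s_site_tv,
            self.ns_site_ts + other.ns_site_ts,
            self.ns_site_tv + other.ns_site_tv,
        )

    def validate(self, n_basepairs: int) -> None:
        """Assert the conservation identities for ``n_basepairs`` counted bp."""
        if self.total != n_basepairs:
            raise AssertionError(
                f"site total {self.total} != counted basepairs {n_basepairs}"
            )
        if self.s_site_ts + self.ns_site_ts != Fraction(n_basepairs, 3):
            raise AssertionError("transition sites != L/3")
        if self.s_site_tv + self.ns_site_tv != Fraction(2 * n_basepairs, 3):
            raise AssertionError("transversion sites != 2L/3")


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding-strand sequence for one transcript."""

    gene_id: str
    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) % 3 != 0:
            raise FrameError(
                f"{self.gene_id}/{self.transcript_id}: length {len(self.sequence)} "
                "not divisible by 3"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    def codons(self) -> Iterable[str]:
        seq = self.sequence
        for i in range(0, len(seq), 3):
            yield seq[i : i + 3]


def strip_terminal_stop(sequence: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Remove a trailing stop codon if present."""
    sequence = sequence.upper()
    if len(sequence) >= 3 and len(sequence) % 3 == 0:
        last = sequence[-3:]
        if all(b in BASES for b in last) and code.is_stop(last):
            return sequence[:-3]
    return sequence


@lru_cache(maxsize=None)
def _codon_site_counts(codon: str, code: GeneticCode) -> SiteCounts:
    cells = {
        (EFFECT_SYNONYMOUS, CHANNEL_TRANSITION): Fraction(0),
        (EFFECT_SYNONYMOUS, CHANNEL_TRANSVERSION): Fraction(0),
        (EFFECT_MISSENSE, CHANNEL_TRANSITION): Fraction(0),
        (EFFECT_MISSENSE, CHANNEL_TRANSVERSION): Fraction(0),
        (EFFECT_NONSENSE, CHANNEL_TRANSITION): Fraction(0),
        (EFFECT_NONSENSE, CHANNEL_TRANSVERSION): Fraction(0),
    }
    for offset in range(3):
        for alt in BASES:
            if alt == codon[offset]:
                continue
            effect, channel = classify_substitution(codon, offset, alt, code)
            cells[(effect, channel)] += THIRD
    # nonsense opportunities are nonsynonymous opportunities
    return SiteCounts(
        s_site_ts=cells[(EFFECT_SYNONYMOUS, CHANNEL_TRANSITION)],
        s_site_tv=cells[(EFFECT_SYNONYMOUS, CHANNEL_TRANSVERSION)],
        ns_site_ts=cells[(EFFECT_MISSENSE, CHANNEL_TRANSITION)]
        + cells[(EFFECT_NONSENSE, CHANNEL_TRANSITION)],
        ns_site_tv=cells[(EFFECT_MISSENSE, CHANNEL_TRANSVERSION)]
        + cells[(EFFECT_NONSENSE, CHANNEL_TRANSVERSION)],
    )


def site_counts(
    cds: "CodingSequence | str", code: GeneticCode = STANDARD_CODE
) -> SiteCounts:
    """Count mutational opportunities in an in-frame, stop-free CDS.

    Codons containing ambiguity codes (N etc.) are skipped entirely and
    logged; internal stop codons raise :class:`InternalStopError`.
    """
    if isinstance(cds, CodingSequence):
        sequence = cds.sequence
        label = f"{cds.gene_id}/{cds.transcript_id}"
    else:
        sequence = cds.upper()
        label = "<sequence>"
    if len(sequence) % 3 != 0:
        raise FrameError(f"{label}: length {len(sequence)} not divisible by 3")

    total = SiteCounts()
    n_skipped = 0
    for index in range(0, len(sequence), 3):
        codon = sequence[index : index + 3]
        if any(b not in BASES for b in codon):
            n_skipped += 1
            continue
        if code.is_stop(codon):
            raise InternalStopError(codon, index // 3)
        total = total + _codon_site_counts(codon, code)
    if n_skipped:
        logger.warning("%s: skipped %d codon(s) with ambiguity codes", label, n_skipped)
    return total


def aggregate(counts: Iterable[SiteCounts]) -> SiteCounts:
    """Field-wise sum of site counts."""
    total = SiteCounts()
    for c in counts:
        total = total + c
    return total
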