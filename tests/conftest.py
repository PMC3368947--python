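"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

from fractions import Fraction

import pytest
from Bio.Data.CodonTable import unambiguous_dna_by_id

from rdnsv import Annotator
from rdnsv.simulate import SimulationConfig, simulate_dataset

BASES = ("A", "C", "G", "T")

# independent genetic-code oracle built straight from the NCBI table,
# bypassing the package's GeneticCode wrapper
_NCBI = unambiguous_dna_by_id[1]
ORACLE_TABLE = dict(_NCBI.forward_table)
for _stop in _NCBI.stop_codons:
    ORACLE_TABLE[_stop] = "*"


def oracle_site_counts(sequence: str):
    """Brute-force enumeration of all 3L substitutions with 1/3 weights.

    Returns dict with keys (effect, channel) -> Fraction plus class totals.
    Deliberately independent of rdnsv.code_sites.
    """
    cells = {}
    purines, pyrimidines = {"A", "G"}, {"C", "T"}
    for i in range(0, len(sequence), 3):
        codon = sequence[i : i + 3]
        aa = ORACLE_TABLE[codon]
        assert aa != "*", "oracle expects stop-free input"
        for offset in range(3):
            for alt in BASES:
                if alt == codon[offset]:
                    continue
                mutated = codon[:offset] + alt + codon[offset + 1 :]
                new_aa = ORACLE_TABLE[mutated]
                if new_aa == "*":
                    effect = "nonsense"
                elif new_aa == aa:
                    effect = "synonymous"
                else:
                    effect = "missense"
                pair = {codon[offset], alt}
                channel = (
                    "transition" if pair <= purines or pair <= pyrimidines
                    else "transversion"
                )
                cells[(effect, channel)] = cells.get((effect, channel), Fraction(0)) + Fraction(1, 3)
    out = dict(cells)
    out["s_site"] = cells.get(("synonymous", "transition"), Fraction(0)) + cells.get(
        ("synonymous", "transversion"), Fraction(0)
    )
    out["ns_site"] = sum(
        cells.get((e, c), Fraction(0))
        for e in ("missense", "nonsense")
        for c in ("transition", "transversion")
    )
    return out


@pytest.fixture(scope="session")
def neutral_dataset():
    """Small neutral simulation shared by annotation/estimator tests."""
    config = SimulationConfig(
        n_genes=40, codon_min=150, codon_max=250, seed=11,
        s_snv_density=0.06, pi_intolerant=0.0, gamma=0.0,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def neutral_annotated(neutral_dataset):
    annotator = Annotator(neutral_dataset.models, neutral_dataset.genome)
    return annotator.annotate_all(neutral_dataset.snvs)
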