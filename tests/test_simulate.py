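import numpy as np
import pytest

from rdnsv.annotation import Annotator
from rdnsv.code_sites import STANDARD_CODE, aggregate, site_counts
from rdnsv.core import correction_factors, rdnsv_estimate
from rdnsv.simulate import (
    SimulationConfig,
    expected_truth,
    simulate_cds,
    simulate_dataset,
    simulate_snvs,
)

SMALL = dict(n_genes=15, codon_min=80, codon_max=120, seed=3)


class TestSimulateCds:
    def test_zero_genes(self):
        cds, models, genome = simulate_cds(SimulationConfig(n_genes=0))
        assert cds == [] and models == [] and genome == {}

    def test_in_frame_and_stop_free(self):
        cds, models, _ = simulate_cds(SimulationConfig(**SMALL))
        for rec in cds:
            assert len(rec.sequence) % 3 == 0
            for codon in rec.codons():
                assert not STANDARD_CODE.is_stop(codon)

    def test_both_strands_present(self):
        _, models, _ = simulate_cds(SimulationConfig(**SMALL))
        assert {m.strand for m in models} == {"+", "-"}

    def test_cds_lengths_match_models(self):
        cds, models, genome = simulate_cds(SimulationConfig(**SMALL))
        from rdnsv.annotation import extract_cds

        for rec, model in zip(cds, models):
            assert extract_cds(model, genome) == rec.sequence

    def test_seed_determinism(self):
        a = simulate_cds(SimulationConfig(**SMALL))
        b = simulate_cds(SimulationConfig(**SMALL))
        assert [c.sequence for c in a[0]] == [c.sequence for c in b[0]]
        assert a[2] == b[2]

    def test_codon_usage_skew_raises_synonymous_share(self):
        uniform = SimulationConfig(**SMALL)
        fourfold = {c: 1.0 for c in STANDARD_CODE.sense_codons if c.startswith(("GG", "GC", "CC", "GT"))}
        skewed = SimulationConfig(**{**SMALL, "codon_weights": fourfold})
        s_uniform = aggregate(site_counts(c) for c in simulate_cds(uniform)[0])
        s_skewed = aggregate(site_counts(c) for c in simulate_cds(skewed)[0])
        assert (s_skewed.s_site / s_skewed.total) > (s_uniform.s_site / s_uniform.total)


class TestSimulateSnvs:
    def test_all_positions_inside_cds(self):
        ds = simulate_dataset(SimulationConfig(**SMALL))
        from rdnsv.annotation import locate_in_cds

        by_chrom = {m.chrom: m for m in ds.models}
        for snv in ds.snvs:
            ctx = locate_in_cds(by_chrom[snv.chrom], snv, ds.genome)
            assert ctx is not None

    def test_one_snv_per_position(self):
        ds = simulate_dataset(SimulationConfig(**SMALL))
        keys = [(s.chrom, s.pos) for s in ds.snvs]
        assert len(keys) == len(set(keys))

    def test_ancestral_equals_reference(self):
        ds = simulate_dataset(SimulationConfig(**SMALL))
        assert all(s.ancestral == s.ref for s in ds.snvs)

    def test_fully_intolerant_emits_no_ns_snvs(self):
        ds = simulate_dataset(SimulationConfig(**SMALL, pi_intolerant=1.0))
        assert ds.truth["n_ns_snv"] == 0
        assert ds.truth["n_s_snv"] > 0

    def test_excessive_density_rejected(self):
        with pytest.raises(ValueError, match="> 1 per opportunity"):
            simulate_dataset(SimulationConfig(**SMALL, s_snv_density=2.5))

    def test_transition_enrichment_matches_weight(self):
        # transitions are placed w times more often per opportunity
        ds = simulate_dataset(
            SimulationConfig(n_genes=60, codon_min=200, codon_max=260, seed=5,
                             s_snv_density=0.08)
        )
        annotated = Annotator(ds.models, ds.genome).annotate_all(ds.snvs)
        sites = aggregate(site_counts(c) for c in ds.cds)
        syn = [a for a in annotated if not a.is_nonsynonymous]
        n_ts = sum(1 for a in syn if a.channel == "transition")
        n_tv = len(syn) - n_ts
        rate_ratio = (n_ts / float(sites.s_site_ts)) / (n_tv / float(sites.s_site_tv))
        assert rate_ratio == pytest.approx(4.0, rel=0.25)

    def test_deleterious_skew_shifts_ns_to_rare(self):
        ds = simulate_dataset(
            SimulationConfig(n_genes=60, codon_min=200, codon_max=260, seed=5,
                             gamma=8.0, pi_intolerant=0.0)
        )
        ns_p = np.array([s.alt_count / s.allele_number
                         for s, is_ns in self._polarized(ds) if is_ns])
        s_p = np.array([s.alt_count / s.allele_number
                        for s, is_ns in self._polarized(ds) if not is_ns])
        assert ns_p.mean() < s_p.mean()

    @staticmethod
    def _polarized(ds):
        annotated = Annotator(ds.models, ds.genome).annotate_all(ds.snvs)
        return [(a.snv, a.is_nonsynonymous) for a in annotated]


class TestDeterminism:
    def test_identical_config_gives_identical_vcf_bytes(self, tmp_path):
        from rdnsv.io import write_vcf

        paths = []
        for name in ("a.vcf", "b.vcf"):
            ds = simulate_dataset(SimulationConfig(**SMALL, pi_intolerant=0.3))
            contigs = {c: len(s) for c, s in ds.genome.items()}
            out = tmp_path / name
            write_vcf(ds.snvs, contigs, str(out))
            paths.append(out.read_bytes())
        assert paths[0] == paths[1]


class TestExpectedTruth:
    def test_no_intolerance_gives_one(self):
        truth = expected_truth(SimulationConfig(pi_intolerant=0.0))
        assert truth["expected_rdnsv_0"] == 1.0
        assert truth["expected_pooled_rdnsv"] == 1.0

    def test_complement_identity(self):
        truth = expected_truth(SimulationConfig(pi_intolerant=0.55))
        assert truth["expected_rdnsv_0"] == pytest.approx(0.45)

    def test_selection_raises_binned_retention(self):
        # deleterious variants concentrate below the 95% exclusion threshold,
        # so the binned pooled expectation exceeds the all-SNV value slightly
        weak = expected_truth(SimulationConfig(gamma=0.0))
        strong = expected_truth(SimulationConfig(gamma=200.0))
        assert weak["expected_pooled_rdnsv_binned"] == pytest.approx(1.0)
        assert strong["expected_pooled_rdnsv_binned"] > 1.0
        # independent check: ratio of retained spectrum masses
        import numpy as np

        n = 400
        k = np.arange(1, n)
        neutral = (1 / k) / (1 / k).sum()
        dele = (np.exp(-200.0 * k / n) / k) / (np.exp(-200.0 * k / n) / k).sum()
        keep = k / n < 0.95
        expected = dele[keep].sum() / neutral[keep].sum()
        assert strong["expected_pooled_rdnsv_binned"] == pytest.approx(expected)

    def test_neutral_fraction_interpolates(self):
        full = expected_truth(SimulationConfig(gamma=50.0, neutral_fraction=1.0))
        none = expected_truth(SimulationConfig(gamma=50.0, neutral_fraction=0.0))
        half = expected_truth(SimulationConfig(gamma=50.0, neutral_fraction=0.5))
        assert full["expected_pooled_rdnsv_binned"] == pytest.approx(1.0)
        assert 1.0 < half["expected_pooled_rdnsv_binned"] < none["expected_pooled_rdnsv_binned"]


class TestNeutralCalibration:
    def test_mean_rdnsv_near_one(self):
        values = []
        for seed in range(8):
            config = SimulationConfig(n_genes=60, codon_min=150, codon_max=250,
                                      seed=seed, s_snv_density=0.06)
            ds = simulate_dataset(config)
            annotated = Annotator(ds.models, ds.genome).annotate_all(ds.snvs)
            sites = aggregate(site_counts(c) for c in ds.cds)
            factors = correction_factors(sites)
            ns = sum(1 for a in annotated if a.is_nonsynonymous)
            values.append(rdnsv_estimate(ns, len(annotated) - ns, sites, factors).rdnsv)
        mean = np.mean(values)
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(mean - 1.0) < 3 * se + 0.02
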