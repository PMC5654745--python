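"""Statistical and structural properties of the synthetic-data generator."""
import numpy as np
import pytest

import cracflow as cf
from cracflow import CracflowError, SimConfig


@pytest.fixture(scope="module")
def small_dataset():
    return cf.simulate_dataset(SimConfig(seed=9, n_genes=60, n_chroms=2))


class TestAnnotation:
    def test_seeded_determinism_bit_identical(self):
        cfg = SimConfig(seed=3, n_genes=10, n_chroms=1)
        a = cf.simulate_annotation(cfg)
        b = cf.simulate_annotation(cfg)
        assert a[0] == b[0]
        assert a[1].sites == b[1].sites
        assert a[2].equals(b[2])

    def test_features_do_not_overlap(self, small_dataset):
        by_chrom = {}
        for f in small_dataset.features:
            by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 <= s2

    def test_intron_probability_one_gives_every_mrna_an_intron(self):
        cfg = SimConfig(seed=1, n_genes=40, n_chroms=1, intron_probability=1.0)
        features, _, _ = cf.simulate_annotation(cfg)
        mrnas = [f for f in features if f.feature_class == "mRNA"]
        assert mrnas and all(len(f.introns) >= 1 for f in mrnas)

    def test_single_pa_site_equals_true_wpas(self, small_dataset):
        pa, truth = small_dataset.pa_table, small_dataset.truth
        singles = [g for g, sites in pa.sites.items() if len(sites) == 1]
        assert singles  # the site-count distribution covers k=1
        for g in singles:
            assert truth.at[g, "true_wpas"] == pa.sites[g][0][0]

    def test_pa_sites_in_final_tenth_on_the_strand(self, small_dataset):
        feats = {f.gene_id: f for f in small_dataset.features}
        for g, sites in small_dataset.pa_table.sites.items():
            f = feats[g]
            for pos, _ in sites:
                local = f.genomic_to_local(pos)
                assert f.length - f.length // 10 - 1 <= local < f.length

    def test_too_small_genome_raises(self):
        cfg = SimConfig(seed=0, n_genes=50, n_chroms=1, chrom_length=5000)
        with pytest.raises(CracflowError, match="too small"):
            cf.simulate_annotation(cfg)

    def test_post_txn_truth_multipliers(self, small_dataset):
        t = small_dataset.truth
        assert (t.loc[t.is_post_txn, "post_txn_multiplier"] > 1).all()
        assert (t.loc[~t.is_post_txn, "post_txn_multiplier"] == 1).all()


class TestRnapiiModel:
    def test_decline_zero_gives_flat_body(self):
        cfg = SimConfig(pol_3prime_decline_fraction=0.0)
        shape = cf.pol_local_shape(1000, cfg)
        assert np.allclose(shape[cfg.pol_entry_ramp_nt:], 1.0)

    def test_zero_expression_gives_zero_expectation(self):
        cfg = SimConfig(seed=2, n_genes=10, n_chroms=1)
        features, _, truth = cf.simulate_annotation(cfg)
        truth = truth.copy()
        truth["expression"] = 0.0
        exp = cf.expected_rnapii(features, truth, cfg)
        assert all(np.all(v == 0) for v in exp.values())

    def test_poisson_mean_matches_expectation_at_body_position(self):
        """Mean of 100 seeded replicates at a mid-gene position is within 3
        standard errors of the constructed expectation."""
        cfg = SimConfig(seed=4, n_genes=8, n_chroms=1)
        features, _, truth = cf.simulate_annotation(cfg)
        f = max(features, key=lambda x: x.length)
        exp = cf.expected_rnapii(features, truth, cfg)
        pos = f.start + f.length // 2
        mu = exp[(f.chrom, f.strand)][pos]
        vals = [
            cf.simulate_rnapii_track(
                features, truth, cfg.replace(seed=s, sample_recovery_log_sd=0.0)
            ).vector(f.chrom, f.strand)[pos]
            for s in range(100)
        ]
        se = np.sqrt(mu / len(vals))
        assert abs(np.mean(vals) - mu) < 3 * se


class TestSet1Model:
    def make(self, seed=6, **kw):
        cfg = SimConfig(seed=seed, n_genes=30, n_chroms=1, **kw)
        features, pa, truth = cf.simulate_annotation(cfg)
        pol = cf.expected_rnapii(features, truth, cfg)
        return cfg, features, pa, truth, pol

    def test_yfaa_factor_one_makes_genotypes_identical(self):
        cfg, features, _, truth, pol = self.make(yfaa_5prime_factor=1.0)
        wt = cf.expected_set1_cl(features, pol, truth, cfg, "WT")
        yf = cf.expected_set1_cl(features, pol, truth, cfg, "YF_AA")
        for k in wt:
            np.testing.assert_array_equal(wt[k], yf[k])

    def test_reduces_to_proportionality_without_extra_terms(self):
        """With no 3' peak, no post-transcriptional class, no lag and no
        release, the CL expectation is proportional to RNAPII per gene."""
        cfg, features, _, truth, pol = self.make(
            peak3_amplitude=0.0, post_txn_fraction=0.0, set1_lag_nt=0,
            set1_release_decay_nt=None)
        cl = cf.expected_set1_cl(features, pol, truth, cfg, "WT")
        for f in features:
            eff = truth.at[f.gene_id, "crosslink_efficiency"]
            p = pol[(f.chrom, f.strand)][f.start:f.end]
            c = cl[(f.chrom, f.strand)][f.start:f.end]
            np.testing.assert_allclose(c, eff * p, rtol=1e-12)

    def test_lag_expectation_argmax_in_paper_window(self):
        """With lag 150 the per-gene CL/RNAPII expectation ratio peaks within
        100-250 nt of the TSS."""
        cfg, features, _, truth, pol = self.make(
            seed=8, peak3_amplitude=0.0, post_txn_fraction=0.0)
        for f in (x for x in features if x.length >= 1000):
            pv = pol[(f.chrom, f.strand)][f.start:f.end]
            cv = cf.expected_set1_cl(features, pol, truth, cfg, "WT")[
                (f.chrom, f.strand)][f.start:f.end]
            if f.strand == "-":
                pv, cv = pv[::-1], cv[::-1]
            ratio = cv[:500] / np.maximum(pv[:500], 1e-12)
            assert 100 <= int(np.argmax(ratio)) <= 250
            break  # one long gene suffices; the construction is deterministic

    def test_3prime_window_genotype_ratio_is_exactly_one(self):
        """In the wPAS-proximal window the WT and YF/AA expectations agree
        when the co-transcriptional term is removed, and the bump term itself
        is genotype-independent by construction."""
        cfg, features, _, truth, pol = self.make(yfaa_5prime_factor=0.3)
        wt = cf.expected_set1_cl(features, pol, truth, cfg, "WT")
        yf = cf.expected_set1_cl(features, pol, truth, cfg, "YF_AA")
        # difference of the two expectations equals (1 - factor) * co term,
        # so the bump+post share cancels exactly:
        cfg_nopeak = cfg.replace(peak3_amplitude=0.0, yfaa_5prime_factor=1.0)
        truth_co = truth.copy()
        truth_co["is_post_txn"] = False  # isolate the co-transcriptional term
        co = cf.expected_set1_cl(features, pol, truth_co, cfg_nopeak, "WT")
        for k in wt:
            diff = wt[k] - yf[k]
            np.testing.assert_allclose(diff, 0.7 * co[k], rtol=1e-9, atol=1e-9)

    def test_unknown_genotype_rejected(self):
        cfg, features, _, truth, pol = self.make()
        with pytest.raises(CracflowError, match="genotype"):
            cf.expected_set1_cl(features, pol, truth, cfg, "petite")


class TestSpikeAndConservation:
    def test_zero_fraction_gives_zero_spike(self):
        cfg = SimConfig(seed=1, spike_read_fraction=0.0)
        assert cf.simulate_spike_counts(cfg, "s1") == 0

    def test_spike_counts_deterministic(self):
        cfg = SimConfig(seed=12)
        a = cf.simulate_spike_counts(cfg, "sampleX", depth=10**6)
        b = cf.simulate_spike_counts(cfg, "sampleX", depth=10**6)
        assert a == b

    def test_binomial_mean_without_jitter(self):
        """fraction 0.005 at depth 1e6 with no recovery jitter: counts within
        3 binomial standard deviations of 5000."""
        sd = np.sqrt(1e6 * 0.005 * 0.995)
        counts = [
            cf.simulate_spike_counts(
                SimConfig(seed=s, sample_recovery_log_sd=0.0), "s")
            for s in range(50)
        ]
        assert abs(np.mean(counts) - 5000) < 3 * sd / np.sqrt(len(counts))

    def test_reads_are_allocated_not_resampled(self, small_dataset):
        for track in small_dataset.tracks.values():
            assert track.total_signal() == track.total_mapped - track.spike_reads

    def test_dataset_determinism_bit_identical(self, tmp_path):
        cfg = SimConfig(seed=21, n_genes=15, n_chroms=1)
        for sub in ("a", "b"):
            cf.write_dataset(cf.simulate_dataset(cfg), tmp_path / sub)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes(), fa.name
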