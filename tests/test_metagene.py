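"""Anchored metagene profiles, ratios, size matching and 3'-peak comparison."""
import itertools

import numpy as np
import pytest

import cracflow as cf
from cracflow import CracflowError, Feature

from conftest import make_track


def flat_track(sizes, plus=4.0, minus=4.0):
    return make_track(sizes, {
        (c, s): np.full(n, plus if s == "+" else minus)
        for c, n in sizes.items() for s in "+-"
    })


class TestProfiles:
    def test_mean_of_window_normalization_gives_flat_one(self):
        sizes = {"chrI": 3000}
        track = make_track(sizes, {
            ("chrI", "+"): np.concatenate([np.zeros(100), np.full(1000, 4.0),
                                           np.zeros(1900)]),
            ("chrI", "-"): np.zeros(3000),
        })
        track.data[("chrI", "-")][1500:2500] = 8.0
        feats = [Feature("a", "chrI", 100, 1100, "+", "mRNA"),
                 Feature("b", "chrI", 1500, 2500, "-", "mRNA")]
        prof = cf.metagene_profile(track, feats, anchor="TSS", window=(0, 1000),
                                   bin_size=10, per_gene_norm="mean_of_window")
        np.testing.assert_allclose(prof.values, 1.0)
        assert (prof.n_genes_per_bin == 2).all()

    def test_strand_symmetry_of_five_prime_signal(self):
        """A minus-strand gene with signal in its first (5') 100 nt produces
        the same profile as the equivalent plus-strand gene."""
        sizes = {"chrI": 2000}
        plus_t = make_track(sizes, {("chrI", "+"): np.zeros(2000)})
        plus_t.data[("chrI", "+")][500:600] = 3.0  # 5' end of plus gene
        minus_t = make_track(sizes, {("chrI", "-"): np.zeros(2000)})
        minus_t.data[("chrI", "-")][1400:1500] = 3.0  # 5' end of minus gene
        fplus = Feature("p", "chrI", 500, 1500, "+", "mRNA")
        fminus = Feature("m", "chrI", 500, 1500, "-", "mRNA")
        pp = cf.metagene_profile(plus_t, [fplus], anchor="TSS", window=(0, 1000),
                                 bin_size=10, per_gene_norm="none")
        pm = cf.metagene_profile(minus_t, [fminus], anchor="TSS", window=(0, 1000),
                                 bin_size=10, per_gene_norm="none")
        np.testing.assert_allclose(pp.values, pm.values)
        assert pp.values[:10] == pytest.approx([3.0] * 10)
        assert np.nansum(pp.values[10:]) == 0

    def test_cohort_of_one_equals_the_gene_profile(self):
        sizes = {"chrI": 1200}
        rng = np.random.default_rng(1)
        v = rng.integers(0, 30, 1200).astype(float)
        track = make_track(sizes, {("chrI", "+"): v})
        f = Feature("g", "chrI", 100, 1100, "+", "mRNA")
        prof = cf.metagene_profile(track, [f], anchor="TSS", window=(0, 1000),
                                   bin_size=10, per_gene_norm="none")
        expected = v[100:1100].reshape(100, 10).mean(axis=1)
        np.testing.assert_allclose(prof.values, expected)

    def test_clip_to_gene_marks_outside_bins_missing(self):
        sizes = {"chrI": 2000}
        track = flat_track(sizes)
        f = Feature("g", "chrI", 500, 800, "+", "mRNA")  # 300 nt gene
        prof = cf.metagene_profile(track, [f], anchor="TSS", window=(0, 1000),
                                   bin_size=100, per_gene_norm="none",
                                   clip_to_gene=True)
        assert np.isfinite(prof.values[:3]).all()
        assert np.isnan(prof.values[3:]).all()
        assert prof.n_genes_per_bin.tolist() == [1, 1, 1] + [0] * 7

    def test_single_gene_scaling_invariance_under_mean_norm(self):
        sizes = {"chrI": 4000}
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 5, 4000)
        feats = [Feature("a", "chrI", 0, 1500, "+", "mRNA"),
                 Feature("b", "chrI", 2000, 3500, "+", "mRNA")]
        t1 = make_track(sizes, {("chrI", "+"): base.copy()})
        scaled = base.copy()
        scaled[2000:3500] *= 7.0  # scale one gene's coverage only
        t2 = make_track(sizes, {("chrI", "+"): scaled})
        p1 = cf.metagene_profile(t1, feats, window=(0, 1000), per_gene_norm="mean_of_window")
        p2 = cf.metagene_profile(t2, feats, window=(0, 1000), per_gene_norm="mean_of_window")
        np.testing.assert_allclose(p1.values, p2.values, rtol=1e-12)

    def test_wpas_anchor_and_missing_wpas_skips_gene(self, caplog):
        sizes = {"chrI": 3000}
        track = flat_track(sizes)
        feats = [Feature("a", "chrI", 100, 1100, "+", "mRNA"),
                 Feature("b", "chrI", 1500, 2500, "+", "mRNA")]
        wp = cf.compute_wpas(cf.PolyASiteTable(sites={"a": [(1050, 1.0)]}))
        with caplog.at_level("WARNING"):
            prof = cf.metagene_profile(track, feats, anchor="wPAS",
                                       window=(500, 300), per_gene_norm="none",
                                       wpas=wp)
        assert prof.gene_ids == ["a"]
        assert any("skipped" in r.message for r in caplog.records)

    def test_empty_cohort_is_error(self):
        track = flat_track({"chrI": 100})
        with pytest.raises(CracflowError, match="cohort"):
            cf.metagene_profile(track, [], window=(0, 100))


class TestProfileRatio:
    def prof(self, values):
        return cf.MetageneProfile(anchor="TSS", upstream=0, downstream=len(values) * 10,
                                  bin_size=10, values=np.asarray(values, float),
                                  n_genes_per_bin=np.ones(len(values), int),
                                  per_gene_norm="none")

    def test_identical_profiles_give_unity(self):
        r = cf.profile_ratio(self.prof([1, 2, 3]), self.prof([1, 2, 3]))
        np.testing.assert_allclose(r, 1.0)

    def test_zero_denominator_bin_is_missing(self):
        r = cf.profile_ratio(self.prof([1, 1]), self.prof([2, 0]))
        assert r[0] == 0.5 and np.isnan(r[1])

    def test_doubling_everywhere(self):
        r = cf.profile_ratio(self.prof([2, 4, 8]), self.prof([1, 2, 4]))
        np.testing.assert_allclose(r, 2.0)

    def test_structure_mismatch_is_error(self):
        with pytest.raises(CracflowError, match="structure"):
            cf.profile_ratio(self.prof([1, 2]), self.prof([1, 2, 3]))


def mkfeat(i, length, cls="mRNA"):
    return Feature(f"f{i}", "chrI", 10**6 + i * 10**5, 10**6 + i * 10**5 + length,
                   "+", cls)


class TestSizeMatch:
    def test_identical_length_multisets_match_perfectly(self):
        a = [mkfeat(i, L) for i, L in enumerate([100, 200, 300])]
        b = [mkfeat(i + 10, L) for i, L in enumerate([300, 100, 200])]
        res = cf.size_match(a, b, tolerance_fraction=0.0)
        assert res.matched_fraction == 1.0
        assert all(fa.length == fb.length for fa, fb in res.pairs)

    def test_disjoint_ranges_give_error(self):
        a = [mkfeat(i, 100) for i in range(3)]
        b = [mkfeat(i + 10, 10_000) for i in range(3)]
        with pytest.raises(CracflowError, match="tolerance"):
            cf.size_match(a, b, tolerance_fraction=0.2)

    def test_matching_is_injective_and_near_optimal(self):
        """Greedy matching is a bijection onto a subset of B, and on average
        (randomized cohorts, n <= 8) its mean length gap stays within 2x of
        the brute-force optimal assignment. The bound is aggregate: greedy
        nearest-length matching can exceed 2x optimal on individual
        adversarial instances."""
        rng = np.random.default_rng(11)
        greedy_costs, optimal_costs = [], []
        for trial in range(30):
            na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 9))
            a = [mkfeat(i, int(rng.integers(100, 2000))) for i in range(na)]
            b = [mkfeat(50 + i, int(rng.integers(100, 2000))) for i in range(nb)]
            res = cf.size_match(a, b, tolerance_fraction=10.0)
            used = [fb.gene_id for _, fb in res.pairs]
            assert len(used) == len(set(used))
            assert len(res.pairs) == min(na, nb)
            greedy_costs.append(
                np.mean([abs(x.length - y.length) for x, y in res.pairs]))
            # brute-force optimal assignment over all B-subset orderings
            best = np.inf
            for perm in itertools.permutations(range(nb), min(na, nb)):
                cost = np.mean([abs(a[i].length - b[j].length)
                                for i, j in enumerate(perm)])
                best = min(best, cost)
            optimal_costs.append(best)
        assert np.mean(greedy_costs) <= 2 * np.mean(optimal_costs)


class TestPeak3Equivalence:
    def wpas_profiles(self, scale_mut=1.0):
        sizes = {"chrI": 3000}
        v = np.zeros(3000)
        v[900:1000] = 6.0  # signal just upstream of the anchor
        wt = make_track(sizes, {("chrI", "+"): v})
        mut = make_track(sizes, {("chrI", "+"): v * scale_mut})
        f = Feature("g", "chrI", 100, 1100, "+", "mRNA")
        wp = cf.compute_wpas(cf.PolyASiteTable(sites={"g": [(1000, 1.0)]}))
        kw = dict(anchor="wPAS", window=(500, 300), per_gene_norm="none",
                  wpas=wp, clip_to_gene=False)
        return (cf.metagene_profile(wt, [f], **kw),
                cf.metagene_profile(mut, [f], **kw))

    def test_identical_inputs_give_ratio_one(self):
        pw, pm = self.wpas_profiles(1.0)
        eq = cf.peak3_equivalence(pw, pm, wpas_window=100, n_boot=50)
        assert eq.ratio == pytest.approx(1.0)

    def test_halved_mutant_gives_ratio_half(self):
        pw, pm = self.wpas_profiles(0.5)
        eq = cf.peak3_equivalence(pw, pm, wpas_window=100, n_boot=50)
        assert eq.ratio == pytest.approx(0.5)

    def test_requires_wpas_anchor(self):
        track = flat_track({"chrI": 2000})
        f = Feature("g", "chrI", 100, 1500, "+", "mRNA")
        p = cf.metagene_profile(track, [f], anchor="TSS", window=(0, 1000),
                                per_gene_norm="none")
        with pytest.raises(CracflowError, match="wPAS"):
            cf.peak3_equivalence(p, p)


class TestOnSyntheticData:
    def test_rnapii_metagene_declines_over_final_region(self):
        """The noise-averaged RNAPII wPAS-anchored profile is monotone
        non-increasing through the 3' decline region (200-gene cohort)."""
        cfg = cf.SimConfig(seed=13, n_genes=200, n_chroms=2)
        ds = cf.simulate_dataset(cfg)
        wp = cf.compute_wpas(ds.pa_table)
        prof = cf.metagene_profile(
            ds.tracks["rnapii_wt"], ds.features, anchor="wPAS",
            window=(100, 0), bin_size=20, per_gene_norm="mean_of_window",
            min_length=1000, clip_to_gene=True, wpas=wp)
        smooth = prof.values
        # allow small noise wiggles: each step down by at least -2%
        assert all(b <= a * 1.02 for a, b in zip(smooth, smooth[1:]))

    def test_set1_lag_recovered_from_profile_ratio(self):
        """On synthetic WT data with lag 150 nt the Set1/RNAPII metagene
        ratio peaks 100-250 nt downstream of the TSS (co-transcriptional
        cohort: no post-transcriptional genes)."""
        cfg = cf.SimConfig(seed=17, n_genes=200, n_chroms=2,
                           post_txn_fraction=0.0)
        ds = cf.simulate_dataset(cfg)
        profs = {}
        for sid in ("set1_wt_cl", "rnapii_wt"):
            profs[sid] = cf.metagene_profile(
                ds.tracks[sid], ds.features, anchor="TSS", window=(200, 1500),
                bin_size=10, per_gene_norm="none", min_length=1000)
        ratio = cf.profile_ratio(profs["set1_wt_cl"], profs["rnapii_wt"])
        centers = profs["rnapii_wt"].bin_centers
        sel = (centers >= 0) & (centers < 500)
        peak = centers[sel][np.nanargmax(ratio[sel])]
        assert cfg.set1_lag_nt - 10 <= peak <= cfg.set1_lag_nt + 150
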