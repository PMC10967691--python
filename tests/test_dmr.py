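import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelome import dmr
from allelome.io import GeneModel

from conftest import make_track


def bins_frame(n=1, chrom="c1"):
    return pd.DataFrame(
        {"chrom": chrom, "start": np.arange(n) * 200, "end": (np.arange(n) + 1) * 200}
    )


class TestBinCounts:
    def test_replicate_pooling_and_cytosine_filter(self):
        bins = bins_frame(2)
        t1 = make_track(
            [("c1", p, "+", "CG", 8, 2) for p in (0, 10, 20, 30, 40)]
            + [("c1", 210, "+", "CG", 1, 1)]  # second bin: only 1 site
        )
        t2 = make_track(
            [("c1", p, "+", "CG", 3, 7) for p in (0, 10, 20, 30, 40)]
            + [("c1", 210, "+", "CG", 1, 1)]
        )
        kept, mc, cov = dmr.bin_counts([t1, t2], bins, "CG")
        assert len(kept) == 1  # bin with 1 cytosine dropped (needs >= 5 in all)
        assert mc[0].tolist() == [40, 15]
        assert cov[0].tolist() == [50, 50]

    def test_site_pooling_within_replicate(self):
        bins = bins_frame(1)
        t = make_track([("c1", 0, "+", "CG", 8, 2)] * 1 + [("c1", 5, "+", "CG", 3, 7)]
                       + [("c1", p, "+", "CG", 0, 1) for p in (10, 20, 30)])
        kept, mc, cov = dmr.bin_counts([t], bins, "CG")
        assert mc[0, 0] == 11 and cov[0, 0] == 23


class TestBinomialLRT:
    def test_identical_groups_not_significant(self):
        g, p = dmr.binomial_lrt(
            np.array([50.0]), np.array([100.0]), np.array([50.0]), np.array([100.0])
        )
        assert g[0] == pytest.approx(0.0)
        assert p[0] == pytest.approx(1.0)

    def test_strong_difference(self):
        g, p = dmr.binomial_lrt(
            np.array([90.0]), np.array([100.0]), np.array([10.0]), np.array([100.0])
        )
        assert p[0] < 1e-10

    def test_matches_fisher_within_order_of_magnitude(self, rng):
        # quick version of the exact-test oracle comparison: tables drawn
        # from a shared binomial proportion (the calibration-relevant case)
        for _ in range(60):
            c1, c2 = rng.integers(10, 101, size=2)
            pr = rng.uniform(0.05, 0.95)
            m1 = rng.binomial(c1, pr)
            m2 = rng.binomial(c2, pr)
            _, p = dmr.binomial_lrt(
                np.array([float(m1)]), np.array([float(c1)]),
                np.array([float(m2)]), np.array([float(c2)]),
            )
            fisher = stats.fisher_exact([[m1, c1 - m1], [m2, c2 - m2]])[1]
            if fisher < 0.999:
                assert abs(np.log10(max(p[0], 1e-300)) - np.log10(fisher)) <= 1.0

    def test_agrees_with_logistic_regression_lrt(self):
        # independent oracle: statsmodels binomial GLM with replicate rows
        import statsmodels.api as sm

        reps = [(30, 50), (25, 50), (35, 50)], [(10, 50), (15, 50), (12, 50)]
        y = np.array([m / c for grp in reps for m, c in grp])
        w = np.array([c for grp in reps for _, c in grp])
        X_full = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        full = sm.GLM(y, X_full, family=sm.families.Binomial(), freq_weights=w).fit()
        red = sm.GLM(y, np.ones((6, 1)), family=sm.families.Binomial(), freq_weights=w).fit()
        lrt_sm = 2 * (full.llf - red.llf)
        m1 = np.array([sum(m for m, _ in reps[0])], dtype=float)
        c1 = np.array([sum(c for _, c in reps[0])], dtype=float)
        m2 = np.array([sum(m for m, _ in reps[1])], dtype=float)
        c2 = np.array([sum(c for _, c in reps[1])], dtype=float)
        g, _ = dmr.binomial_lrt(m1, c1, m2, c2)
        assert g[0] == pytest.approx(lrt_sm, rel=1e-6)


class TestTestDmr:
    def run(self, m1, c1, m2, c2, context):
        n = len(m1)
        bins = bins_frame(n)
        g1 = (np.asarray(m1, dtype=float)[:, None], np.asarray(c1, dtype=float)[:, None])
        g2 = (np.asarray(m2, dtype=float)[:, None], np.asarray(c2, dtype=float)[:, None])
        return dmr.test_dmr(g1, g2, bins, context)

    def test_threshold_table_context_dependence(self):
        # difference 0.2 with overwhelming counts: DMR in CHH, not in CG
        m1, c1 = [4000], [10000]
        m2, c2 = [6000], [10000]
        chh = self.run(m1, c1, m2, c2, "CHH")
        cg = self.run(m1, c1, m2, c2, "CG")
        assert chh["difference"].iloc[0] == pytest.approx(0.2)
        assert chh["q"].iloc[0] < 0.05
        assert bool(chh["is_dmr"].iloc[0])
        assert not bool(cg["is_dmr"].iloc[0])

    def test_direction_and_transition_flags(self):
        out = self.run([9000], [10000], [500], [10000], "CG")
        assert out["direction"].iloc[0] == "hypo"
        assert bool(out["to_low"].iloc[0])
        out2 = self.run([500], [10000], [9000], [10000], "CG")
        assert out2["direction"].iloc[0] == "hyper"
        assert bool(out2["to_high"].iloc[0])

    def test_group_swap_negates_difference_keeps_p(self):
        a = self.run([90, 10], [100, 100], [30, 70], [100, 100], "CG")
        b = self.run([30, 70], [100, 100], [90, 10], [100, 100], "CG")
        assert np.allclose(a["difference"], -b["difference"])
        assert np.allclose(a["p"], b["p"])

    def test_zero_coverage_group_skipped(self):
        out = self.run([5, 0], [10, 0], [5, 5], [10, 10], "CG")
        assert len(out) == 1


class TestAnnotateDmg:
    def setup_method(self):
        self.genes = [
            GeneModel("gA", "c1", 10000, 12000, "+", [(10000, 12000)]),
            GeneModel("gB", "c1", 7000, 8500, "-", [(7000, 8500)]),
        ]

    def annotate(self, start, end):
        frame = pd.DataFrame({"chrom": ["c1"], "start": [start], "end": [end]})
        return dmr.annotate_dmg(frame, self.genes)

    def test_inside_gene_is_gene_body(self):
        ann, dmgs = self.annotate(10500, 10700)
        assert ann["primary_feature"].iloc[0] == "gene_body"
        assert set(dmgs["gene_id"]) == {"gA"}

    def test_minus_strand_promoter_is_strand_aware(self):
        # 500 bp upstream of gB's TSS (TSS at 8500, promoter is [8500, 10500))
        ann, dmgs = self.annotate(8900, 9100)
        assert ann["primary_feature"].iloc[0] == "promoter"
        assert "gB" in set(dmgs["gene_id"])

    def test_promoter_precedence_and_both_genes_become_dmgs(self):
        # overlaps gA's promoter ([8000,10000)) and gB's body
        ann, dmgs = self.annotate(8300, 10100)
        assert ann["primary_feature"].iloc[0] == "promoter"
        assert set(dmgs["gene_id"]) == {"gA", "gB"}

    def test_far_intergenic(self):
        ann, dmgs = self.annotate(100, 300)
        assert ann["primary_feature"].iloc[0] == "intergenic"
        assert len(dmgs) == 0


class TestStemCluster:
    def test_decreasing_series_gets_decreasing_profile(self):
        series = np.array([[0.9, 0.6, 0.3]] * 10)
        assign, prof = dmr.stem_cluster(series, seed=1)
        traj = prof.set_index("profile_id").loc[assign["profile_id"].iloc[0], "trajectory"]
        steps = [int(x) for x in traj.split(";")]
        assert steps[0] == 0 and steps == sorted(steps, reverse=True) and steps[-1] < 0

    def test_constant_series_assigned_to_flat_profile(self):
        series = np.array([[0.5, 0.5, 0.5]])
        assign, prof = dmr.stem_cluster(series, seed=1)
        traj = prof.set_index("profile_id").loc[assign["profile_id"].iloc[0], "trajectory"]
        assert all(int(x) == 0 for x in traj.split(";"))

    def test_permutation_p_reproducible(self, rng):
        series = rng.random((30, 4))
        _, p1 = dmr.stem_cluster(series, seed=9)
        _, p2 = dmr.stem_cluster(series, seed=9)
        pd.testing.assert_frame_equal(p1, p2)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            dmr.stem_cluster(np.zeros((5, 2)))


class TestEnrich:
    def test_exact_hypergeometric_value(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = {"s": universe[:10]}
        selected = universe[:5] + universe[50:55]  # overlap 5 of 10
        out = dmr.enrich(selected, universe, gene_set)
        # brute-force tail: sum_{k>=5} C(10,k) C(90,10-k) / C(100,10)
        from math import comb

        expected = sum(
            comb(10, k) * comb(90, 10 - k) for k in range(5, 11)
        ) / comb(100, 10)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(6.4e-4, rel=0.05)

    def test_no_overlap_near_one(self):
        universe = [f"g{i}" for i in range(100)]
        out = dmr.enrich(universe[:5], universe, {"s": universe[95:]})
        assert out["p"].iloc[0] > 0.5

    def test_selected_equals_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = dmr.enrich(universe, universe, {"s": universe[:7]})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            dmr.enrich([], [], {"s": ["g1"]})
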