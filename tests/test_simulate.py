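import numpy as np
import pandas as pd
import pytest

from allelome import io
from allelome.simulate import (
    SimConfig,
    place_motifs,
    promoter_sequences,
    simulate_expression,
    simulate_genomes,
    simulate_methylomes,
    toy_motif_library,
    true_lfc_table,
)


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(snp_rate=1.5)

    def test_positive_coverage_and_dispersion(self):
        with pytest.raises(ValueError):
            SimConfig(coverage_mean=0)
        with pytest.raises(ValueError):
            SimConfig(nb_dispersion=-1)

    def test_promoter_length_fixed(self):
        with pytest.raises(ValueError):
            SimConfig(promoter_length=1000)


class TestGenomes:
    def test_same_seed_identical_sequences(self):
        a, _ = simulate_genomes(SimConfig(seed=71, n_gene_pairs=10))
        b, _ = simulate_genomes(SimConfig(seed=71, n_gene_pairs=10))
        assert a.sequences == b.sequences

    def test_different_seed_differs(self):
        a, _ = simulate_genomes(SimConfig(seed=71, n_gene_pairs=10))
        b, _ = simulate_genomes(SimConfig(seed=72, n_gene_pairs=10))
        assert a.sequences != b.sequences

    def test_zero_divergence_gene_sequences_identical(self):
        bundle, truth = simulate_genomes(
            SimConfig(seed=73, n_gene_pairs=8, snp_rate=0.0, relocation_fraction=0.0)
        )
        from allelome.pipeline import _gene_cds

        cds_m = _gene_cds(bundle, "alb")
        cds_p = _gene_cds(bundle, "gla")
        for _, row in truth.iterrows():
            assert cds_m[row["maternal_id"]] == cds_p[row["paternal_id"]]

    def test_relocation_count_by_construction(self):
        _, truth = simulate_genomes(
            SimConfig(seed=79, n_gene_pairs=100, relocation_fraction=0.1)
        )
        assert truth["relocated"].sum() == 10

    def test_bundle_passes_validation(self, tiny_bundle):
        bundle, _ = tiny_bundle
        bundle.validate()

    def test_truth_ids_exist_in_annotation(self, tiny_bundle):
        bundle, truth = tiny_bundle
        gm = set(g.gene_id for g in bundle.genes["alb"])
        gp = set(g.gene_id for g in bundle.genes["gla"])
        assert set(truth["maternal_id"]) <= gm
        assert set(truth["paternal_id"]) <= gp


class TestMethylomes:
    def test_unknown_phase_rejected(self, tiny_bundle, tiny_config):
        bundle, truth = tiny_bundle
        with pytest.raises(ValueError, match="phase"):
            simulate_methylomes(bundle, tiny_config, truth, phases=["LEX"])

    def test_nonconversion_pathological_control(self):
        # with epsilon = 0.5 and true p = 0 the observed level converges to 0.5
        cfg = SimConfig.null(
            seed=83, n_gene_pairs=6, non_conversion=0.5,
            context_meth_fraction={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            asmg_fraction=0.0, silent_fraction=0.0,
        )
        bundle, truth = simulate_genomes(cfg)
        tracks, _, _ = simulate_methylomes(bundle, cfg, truth, phases=["LE"])
        t = tracks[("LE", 1)]
        level = t["mc"].sum() / (t["mc"] + t["uc"]).sum()
        # baseline sites still draw a low Beta level (~2%), inflating slightly
        assert abs(level - 0.5) < 0.03

    def test_observed_mean_matches_closed_form(self):
        # non-conversion adjustment: E[level] = E[p] + (1 - E[p]) * eps.
        # With the methylated class off, E[p] is the low-Beta mean.
        eps = 0.25
        cfg = SimConfig.null(
            seed=89, n_gene_pairs=6, non_conversion=eps,
            context_meth_fraction={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            asmg_fraction=0.0, silent_fraction=0.0,
        )
        bundle, truth = simulate_genomes(cfg)
        tracks, _, _ = simulate_methylomes(bundle, cfg, truth, phases=["LE"])
        t = tracks[("LE", 1)]
        level = t["mc"].sum() / (t["mc"] + t["uc"]).sum()
        lo_a, lo_b = cfg.beta_low
        p_mean = lo_a / (lo_a + lo_b)
        assert level == pytest.approx(p_mean + (1 - p_mean) * eps, abs=0.005)

    def test_no_offsets_empty_dmr_truth(self, tiny_bundle):
        bundle, truth = tiny_bundle
        cfg = SimConfig.null(seed=97, n_gene_pairs=16)
        _, dmr_truth, _ = simulate_methylomes(bundle, cfg, truth, phases=["LE"])
        assert len(dmr_truth) == 0

    def test_same_seed_identical_counts(self, tiny_bundle, tiny_config):
        bundle, truth = tiny_bundle
        t1, _, _ = simulate_methylomes(bundle, tiny_config, truth, phases=["LE"])
        t2, _, _ = simulate_methylomes(bundle, tiny_config, truth, phases=["LE"])
        pd.testing.assert_frame_equal(t1[("LE", 1)], t2[("LE", 1)])

    def test_emitted_reports_round_trip(self, tiny_methylomes, tmp_path):
        tracks, _, _ = tiny_methylomes
        sample = tracks[("LE", 1)].head(500)
        path = tmp_path / "le.cov"
        io.write_cytosine_report(sample, path)
        back = io.read_cytosine_report(path)
        assert len(back) == len(sample)
        assert (back["pos0"].to_numpy() == sample["pos0"].to_numpy()).all()
        assert (back["mc"].to_numpy() == sample["mc"].to_numpy()).all()


class TestExpression:
    def test_zero_aseg_fraction_all_lfc_zero(self):
        cfg = SimConfig.null(seed=101, n_gene_pairs=50, silent_fraction=0.0)
        _, _, _, truth = simulate_expression(cfg)
        assert (truth["true_lfc"] == 0).all()

    def test_designated_pair_expected_allele_means(self):
        truth = pd.DataFrame(
            {"pair_id": ["p0"], "maternal_id": ["m0"], "paternal_id": ["f0"],
             "length": [1500], "is_silent": [False], "is_aseg": [True],
             "lfc_base": [2.0], "is_phase_dependent": [False], "pd_kind": ["none"]}
        )
        cfg = SimConfig(
            seed=103, n_gene_pairs=1, expr_log_mean=np.log(100), expr_log_sd=0.0,
            nb_dispersion=0.01, depth_factor_range=(1.0, 1.0), phase_effect_sd=0.0,
            n_expr_replicates=3,
        )
        reps = []
        for s in range(40):
            cfg2 = SimConfig(**{**cfg.__dict__, "seed": s})
            m, p, _, _ = simulate_expression(cfg2, truth, phases=["LE"])
            reps.append((m.iloc[0].mean(), p.iloc[0].mean()))
        means = np.mean(reps, axis=0)
        assert means[0] == pytest.approx(200, rel=0.05)
        assert means[1] == pytest.approx(50, rel=0.05)

    def test_phase_dependent_truth_table(self):
        truth = pd.DataFrame(
            {"pair_id": ["a", "b"], "maternal_id": ["m", "n"], "paternal_id": ["x", "y"],
             "length": [1500, 1500], "is_silent": [False, False],
             "is_aseg": [True, True], "lfc_base": [2.0, 2.0],
             "is_phase_dependent": [True, True], "pd_kind": ["appear", "flip"]}
        )
        lt = true_lfc_table(truth, phases=["LE", "DP1"])
        lt = lt.set_index(["pair_id", "phase"])["true_lfc"]
        assert lt[("a", "LE")] == 0.0 and lt[("a", "DP1")] == 2.0
        assert lt[("b", "LE")] == 2.0 and lt[("b", "DP1")] == -2.0

    def test_same_seed_identical_tables(self):
        cfg = SimConfig(seed=107, n_gene_pairs=20)
        m1, p1, _, _ = simulate_expression(cfg)
        m2, p2, _, _ = simulate_expression(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, nb_dispersion=0.0)


class TestMotifs:
    def test_toy_library_size_and_stochastic_rows(self):
        lib = toy_motif_library(24, seed=5)
        assert len(lib) == 24
        for m in lib:
            assert np.allclose(m.matrix.sum(axis=1), 1.0)

    def test_flip_probability_zero_identical_vectors(self):
        cfg = SimConfig(seed=109, n_gene_pairs=8, motif_flip_prob=0.0,
                        motif_flip_prob_aseg=0.0)
        bundle, truth = simulate_genomes(cfg)
        lib = toy_motif_library(cfg.n_motifs, seed=cfg.seed)
        _, vectors = place_motifs(bundle, truth, cfg, lib)
        vec = vectors.set_index("allele_id")
        for _, row in truth.iterrows():
            assert (vec.loc[row["maternal_id"]] == vec.loc[row["paternal_id"]]).all()

    def test_placements_deterministic(self):
        cfg = SimConfig(seed=113, n_gene_pairs=6)
        b1, t1 = simulate_genomes(cfg)
        p1, _ = place_motifs(b1, t1, cfg)
        b2, t2 = simulate_genomes(cfg)
        p2, _ = place_motifs(b2, t2, cfg)
        pd.testing.assert_frame_equal(p1, p2)

    def test_motif_wider_than_promoter_rejected(self, tiny_bundle, tiny_config):
        bundle, truth = tiny_bundle
        wide = io.Motif("wide", np.full((2100, 4), 0.25))
        with pytest.raises(ValueError):
            place_motifs(bundle, truth, tiny_config, [wide])

    def test_embedded_words_present_in_promoters(self):
        cfg = SimConfig(seed=127, n_gene_pairs=6, motif_presence_prob=1.0,
                        motif_flip_prob=0.0, motif_flip_prob_aseg=0.0)
        bundle, truth = simulate_genomes(cfg)
        lib = toy_motif_library(4, seed=cfg.seed)
        placements, _ = place_motifs(bundle, truth, cfg, lib)
        proms = promoter_sequences(bundle, "alb")
        consensus = {m.motif_id: "".join("ACGT"[i] for i in np.argmax(m.matrix, axis=1))
                     for m in lib}
        sub = placements[placements["allele_id"].isin(proms)]
        for _, row in sub.head(20).iterrows():
            seq = proms[row["allele_id"]]
            off = row["promoter_offset"]
            word = consensus[row["motif_id"]]
            assert seq[off : off + len(word)] == word
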