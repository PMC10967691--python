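import itertools

import numpy as np
import pandas as pd
import pytest

from allelome import tfbs
from allelome.io import Motif
from allelome.simulate import toy_motif_library


def informative_motif(width=4, motif_id="M"):
    rng = np.random.default_rng(width)
    mat = np.full((width, 4), 0.05)
    mat[np.arange(width), rng.integers(0, 4, width)] = 0.85
    return Motif(motif_id, mat)


def brute_force_tail(pwm: tfbs.PreparedPWM) -> dict[int, float]:
    """Exact null tail mass by enumerating all 4^w words."""
    w = pwm.width
    probs = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(pwm.iscores[j, b] for j, b in enumerate(word)))
        p = float(np.prod([pwm.background[b] for b in word]))
        probs[s] = probs.get(s, 0.0) + p
    scores = sorted(probs, reverse=True)
    tail = {}
    acc = 0.0
    for s in scores:
        acc += probs[s]
        tail[s] = acc
    return tail


class TestScanPValues:
    @pytest.mark.parametrize("width", [3, 4, 5, 6])
    def test_dp_tail_matches_enumeration_exactly(self, width):
        pwm = tfbs.prepare_pwm(informative_motif(width))
        tail = brute_force_tail(pwm)
        for s, p_exact in tail.items():
            assert pwm.pvalue(s) == pytest.approx(p_exact, abs=1e-12)

    def test_nonuniform_background(self):
        pwm = tfbs.prepare_pwm(informative_motif(4), background=np.array([0.4, 0.1, 0.1, 0.4]))
        tail = brute_force_tail(pwm)
        for s, p_exact in tail.items():
            assert pwm.pvalue(s) == pytest.approx(p_exact, abs=1e-12)


class TestScanning:
    def test_embedded_consensus_found_at_position(self, rng):
        motif = informative_motif(8, "M8")
        consensus = "".join("ACGT"[i] for i in np.argmax(motif.matrix, axis=1))
        seq = "".join(rng.choice(list("ACGT"), 300))
        seq = seq[:100] + consensus + seq[108:]
        pwm = tfbs.prepare_pwm(motif)
        hits = tfbs.scan_pwm(seq, pwm)
        fwd = hits[(hits["strand"] == "+") & (hits["position"] == 100)]
        assert len(fwd) == 1
        assert fwd["p"].iloc[0] <= 4.0 ** -6  # far into the null tail

    def test_reverse_complement_symmetry(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seq = "".join(rng.choice(list("ACGT"), 400))
        rc = "".join(comp[b] for b in reversed(seq))
        pwm = tfbs.prepare_pwm(informative_motif(6, "M6"), p_threshold=1e-2)
        h1 = tfbs.scan_pwm(seq, pwm)
        h2 = tfbs.scan_pwm(rc, pwm)
        # hit scores are the same multiset, strands exchanged
        assert sorted(h1["score"]) == sorted(h2["score"])
        assert (h1["strand"] == "+").sum() == (h2["strand"] == "-").sum()

    def test_sequence_shorter_than_motif_no_hits(self):
        pwm = tfbs.prepare_pwm(informative_motif(8))
        assert len(tfbs.scan_pwm("ACG", pwm)) == 0

    def test_ambiguous_bases_score_as_background(self):
        pwm = tfbs.prepare_pwm(informative_motif(4))
        codes = tfbs.encode("ANNT")
        scores = tfbs._window_scores(codes, pwm.iscores)
        assert len(scores) == 1  # runs without error; N contributes 0


class TestVectorsAndCosine:
    def test_presence_not_count(self):
        lib = [informative_motif(4, "A"), informative_motif(5, "B")]
        hits = pd.DataFrame(
            {"allele_id": ["x", "x", "x"], "motif_id": ["A", "A", "A"],
             "position": [1, 5, 9], "strand": "+", "score": 1.0, "p": 1e-5}
        )
        v = tfbs.promoter_vector(hits, "x", lib)
        assert v.tolist() == [1, 0]
        assert tfbs.promoter_vector(hits, "absent", lib).tolist() == [0, 0]

    @pytest.mark.parametrize(
        "v1,v2,expected",
        [([1, 1, 0], [1, 1, 0], 1.0), ([1, 1, 0], [1, 0, 1], 0.5), ([1, 0], [0, 1], 0.0)],
    )
    def test_cosine_values(self, v1, v2, expected):
        cs, flag = tfbs.cosine_similarity(np.array(v1), np.array(v2))
        assert cs == pytest.approx(expected)
        assert not flag

    def test_both_zero_flagged_as_identical_absence(self):
        cs, flag = tfbs.cosine_similarity(np.zeros(3), np.zeros(3))
        assert cs == 1.0 and flag

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tfbs.cosine_similarity(np.ones(2), np.ones(3))

    @pytest.mark.parametrize(
        "cs,label",
        [(0.0, "I"), (0.19, "I"), (0.2, "II"), (0.59, "III"), (0.79, "IV"), (0.8, "V"), (1.0, "V")],
    )
    def test_cs_class_bands(self, cs, label):
        assert tfbs.cs_class(cs) == label


class TestGroupCorrelation:
    def test_fisher_z_closed_form(self):
        z, p = tfbs.fisher_r_to_z(0.9, 500, 0.5, 200)
        se = np.sqrt(1 / 497 + 1 / 197)
        assert z == pytest.approx((np.arctanh(0.9) - np.arctanh(0.5)) / se)
        assert p < 0.001

    def test_equal_correlations_z_zero(self):
        z, p = tfbs.fisher_r_to_z(0.6, 100, 0.6, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_identical_allele_expression_r_one(self, rng):
        pairs = pd.DataFrame(
            {"pair_id": [f"p{i}" for i in range(30)],
             "maternal_id": [f"m{i}" for i in range(30)],
             "paternal_id": [f"f{i}" for i in range(30)],
             "cs": 0.9, "cs_class": "V"}
        )
        expr = pd.Series(rng.normal(5, 2, 30), index=[f"m{i}" for i in range(30)])
        expr_p = pd.Series(expr.to_numpy(), index=[f"f{i}" for i in range(30)])
        out = tfbs.class_expression_correlation(pairs, expr, expr_p, set())
        row = out.set_index("cs_class").loc["V"]
        assert row["r_all"] == pytest.approx(1.0)


class TestSimulatorCoupling:
    def test_cs_monotone_in_flip_probability(self):
        from allelome.simulate import SimConfig, place_motifs, simulate_genomes
        from allelome.tfbs import pair_cosine_table, scan_promoters
        from allelome.simulate import promoter_sequences

        means = []
        for flip in (0.0, 0.3, 0.8):
            cfg = SimConfig(
                seed=61, n_gene_pairs=12, motif_flip_prob=flip,
                motif_flip_prob_aseg=flip, phase_dependent_fraction=0.0,
            )
            bundle, truth = simulate_genomes(cfg)
            lib = toy_motif_library(cfg.n_motifs, seed=cfg.seed)
            place_motifs(bundle, truth, cfg, lib)
            promoters = {}
            promoters.update(promoter_sequences(bundle, "alb"))
            promoters.update(promoter_sequences(bundle, "gla"))
            hits = scan_promoters(promoters, lib)
            cs = pair_cosine_table(hits, truth, lib)
            means.append(cs["cs"].mean())
        assert means[0] > means[1] > means[2]

    def test_zero_flip_probability_gives_cs_one(self):
        from allelome.simulate import SimConfig, place_motifs, promoter_sequences, simulate_genomes
        from allelome.tfbs import pair_cosine_table, scan_promoters

        cfg = SimConfig(seed=67, n_gene_pairs=10, motif_flip_prob=0.0,
                        motif_flip_prob_aseg=0.0, snp_rate=0.0)
        bundle, truth = simulate_genomes(cfg)
        lib = toy_motif_library(cfg.n_motifs, seed=cfg.seed)
        place_motifs(bundle, truth, cfg, lib)
        promoters = {}
        promoters.update(promoter_sequences(bundle, "alb"))
        promoters.update(promoter_sequences(bundle, "gla"))
        hits = scan_promoters(promoters, lib)
        cs = pair_cosine_table(hits, truth, lib)
        assert np.allclose(cs["cs"], 1.0)


class TestTfbsMethylation:
    def test_pooling_matches_region_level(self):
        from allelome.methylome import weighted_region_level

        track = pd.DataFrame(
            {"chrom": ["c1"] * 4, "pos0": [100, 103, 106, 200], "strand": "+",
             "context": "CG", "mc": [8, 2, 5, 9], "uc": [2, 8, 5, 1]}
        )
        lib = [informative_motif(8, "M")]
        hits = pd.DataFrame(
            {"allele_id": ["x"], "motif_id": ["M"], "position": [0], "strand": "+",
             "score": [1.0], "p": [1e-5]}
        )
        out = tfbs.tfbs_methylation(hits, {"x": ("c1", 100)}, track, "CG", lib)
        ref = weighted_region_level(track, "c1", 100, 108, "CG")
        assert out["level"].iloc[0] == pytest.approx(ref.weighted_level)

    def test_hit_without_cytosines_excluded(self):
        track = pd.DataFrame(
            {"chrom": ["c1"], "pos0": [900], "strand": "+", "context": "CG",
             "mc": [1], "uc": [1]}
        )
        lib = [informative_motif(8, "M")]
        hits = pd.DataFrame(
            {"allele_id": ["x"], "motif_id": ["M"], "position": [0], "strand": "+",
             "score": [1.0], "p": [1e-5]}
        )
        out = tfbs.tfbs_methylation(hits, {"x": ("c1", 100)}, track, "CG", lib)
        assert len(out) == 0
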