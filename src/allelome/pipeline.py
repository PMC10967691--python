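"""End-to-end run on a synthetic dataset: simulate, analyse, write tables.

Produces, under a run directory, the full set of figure-level result tables:
methylome summaries and metagene profiles, DMRs/DMGs with time-course
profile clusters, TPM/DEG/expression-class and methylation-expression
correlation tables, allele pairs, ASE and phase-dependent ASE, ASMRs/ASMGs
with the bias-shift statistic, and promoter TFBS cosine-similarity tables.
Runs are deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allele_pairs import pair_alleles
from .ase import (
    AlleleCounts,
    allele_pca,
    classify_consistency,
    test_ase_per_phase,
    test_phase_dependent_ase,
)
from .asmr import asmr_count_comparison, bias_shift_fraction, call_asmgs, test_asmr
from .dmr import annotate_dmg, call_dmrs, enrich, stem_cluster
from .expression import (
    bin_expression_correlation,
    class_methylation_comparison,
    correlation_sign_summary,
    test_deg,
    tpm,
    tpm_classes,
)
from .io import CONTEXTS, METHYLOME_PHASES, write_bed, write_counts, write_fasta, write_gff3
from .methylome import (
    TrackIndex,
    feature_bin_levels,
    global_summary,
    interval_counts,
    metagene_profile,
)
from .simulate import (
    SimConfig,
    place_motifs,
    promoter_sequences,
    promoter_windows,
    simulate_expression,
    simulate_genomes,
    simulate_methylomes,
    toy_motif_library,
)
from .tfbs import (
    class_expression_correlation,
    pair_cosine_table,
    scan_promoters,
    tfbs_methylation,
)

#: phase contrasts analysed for differential methylation (direct + indirect)
DMR_CONTRASTS = [("LE", "DP1"), ("DP1", "DP2"), ("LE", "IP1"), ("IP1", "IP2"), ("IP2", "IP3")]
DEG_CONTRASTS = [("LE", "DP1"), ("LE", "IP1")]

_FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _gene_cds(bundle, subgenome: str) -> dict[str, str]:
    seqs = bundle.sequences[subgenome]
    out = {}
    for g in bundle.genes[subgenome]:
        out[g.gene_id] = "".join(seqs[g.chrom][s:e] for s, e in g.exons)
    return out


def _gene_order(bundle, subgenome: str) -> dict[str, tuple[str, int]]:
    order: dict[str, tuple[str, int]] = {}
    rank: dict[str, int] = {}
    for g in sorted(bundle.genes[subgenome], key=lambda g: (g.chrom, g.start)):
        r = rank.get(g.chrom, 0)
        order[g.gene_id] = (g.chrom, r)
        rank[g.chrom] = r + 1
    return order


def run_pipeline(config: SimConfig, outdir: str | Path) -> dict:
    """Simulate the default dataset and run every analysis stage.

    Returns the run report (also written as ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed}

    # --- simulation ------------------------------------------------------
    bundle, truth = simulate_genomes(config)
    library = toy_motif_library(config.n_motifs, seed=config.seed)
    placements, vector_truth = place_motifs(bundle, truth, config, library)
    bundle.validate()
    tracks, dmr_truth, asmr_truth = simulate_methylomes(bundle, config, truth)
    mat_counts, pat_counts, samples, lfc_truth = simulate_expression(config, truth)
    _write(truth, outdir / "truth_pairs.tsv")
    _write(dmr_truth, outdir / "truth_dmrs.tsv")
    _write(lfc_truth, outdir / "truth_ase.tsv")

    # --- methylome summaries (need the raw site frames) -------------------
    summaries = []
    for ph in METHYLOME_PHASES:
        s = global_summary(tracks[(ph, 1)], non_conversion=config.non_conversion)
        s.insert(0, "phase", ph)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)
    _write(summary, outdir / "methylome_summary.tsv")

    indexes = {key: TrackIndex(t) for key, t in tracks.items()}
    phase_pooled = {}
    for ph in METHYLOME_PHASES:
        # replicates share the site list and order, so pooling is a column sum
        reps = [t for (p, _), t in tracks.items() if p == ph]
        pooled = reps[0].copy()
        for rep in reps[1:]:
            pooled["mc"] = pooled["mc"] + rep["mc"]
            pooled["uc"] = pooled["uc"] + rep["uc"]
        phase_pooled[ph] = TrackIndex(pooled)
        del pooled
    del tracks

    chrom_sizes = {}
    for sg in bundle.sequences:
        chrom_sizes.update(bundle.chrom_sizes(sg))
    all_genes = bundle.genes["alb"] + bundle.genes["gla"]
    gene_lengths = pd.Series(
        {g.gene_id: g.length for g in all_genes}, name="length"
    )

    # --- metagene profiles ------------------------------------------------
    te_feats = []
    for sg in bundle.tes:
        for _, row in bundle.tes[sg].iterrows():
            te_feats.append((row["chrom"], int(row["start"]), int(row["end"]), "+"))
    prof_rows = []
    for ph in METHYLOME_PHASES:
        for ctx in CONTEXTS:
            gp = metagene_profile(all_genes, phase_pooled[ph], ctx)
            for b, v in enumerate(gp):
                prof_rows.append({"phase": ph, "context": ctx, "feature": "gene", "bin": b, "level": v})
            if te_feats:
                tp = metagene_profile(te_feats, phase_pooled[ph], ctx)
                for b, v in enumerate(tp):
                    prof_rows.append({"phase": ph, "context": ctx, "feature": "TE", "bin": b, "level": v})
    _write(pd.DataFrame(prof_rows), outdir / "metagene_profiles.tsv")

    # --- DMR calling ------------------------------------------------------
    dmr_frames = []
    for g1, g2 in DMR_CONTRASTS:
        t1 = [indexes[(g1, r)] for r in range(1, config.n_meth_replicates + 1)]
        t2 = [indexes[(g2, r)] for r in range(1, config.n_meth_replicates + 1)]
        for ctx in CONTEXTS:
            res = call_dmrs(t1, t2, chrom_sizes, ctx)
            res.insert(0, "contrast", f"{g1}_vs_{g2}")
            dmr_frames.append(res)
    dmr_all = pd.concat(dmr_frames, ignore_index=True)
    dmr_sig = dmr_all[dmr_all["is_dmr"]].reset_index(drop=True)
    _write(dmr_sig, outdir / "dmrs.tsv")
    report["n_dmrs"] = {
        f"{c}/{x}": int(((dmr_sig["contrast"] == c) & (dmr_sig["context"] == x)).sum())
        for c in dmr_sig["contrast"].unique()
        for x in CONTEXTS
    }

    ann, dmgs = annotate_dmg(dmr_sig, all_genes)
    _write(ann, outdir / "dmr_features.tsv")
    _write(dmgs, outdir / "dmgs.tsv")
    report["n_dmgs"] = int(len(dmgs))
    if len(ann):
        report["dmr_feature_fractions"] = (
            ann["primary_feature"].value_counts(normalize=True).round(4).to_dict()
        )

    # DMR time-course clustering over the direct-induction series
    direct_phases = ["LE", "DP1", "DP2"]
    stem_frames = []
    for ctx in CONTEXTS:
        sub = dmr_sig[dmr_sig["context"] == ctx].drop_duplicates(["chrom", "start", "end"])
        if len(sub) < 5:
            continue
        intervals = sub[["chrom", "start", "end"]].reset_index(drop=True)
        series = np.column_stack(
            [
                interval_counts(phase_pooled[ph], intervals, ctx)["level"].to_numpy()
                for ph in direct_phases
            ]
        )
        series = np.nan_to_num(series, nan=0.0)
        assign, prof = stem_cluster(series, seed=config.seed)
        prof.insert(0, "context", ctx)
        stem_frames.append(prof)
    if stem_frames:
        _write(pd.concat(stem_frames, ignore_index=True), outdir / "dmr_profiles.tsv")

    # enrichment of DMGs against chromosome-membership sets (demo gene sets)
    universe = [g.gene_id for g in all_genes]
    gene_sets = {}
    for g in all_genes:
        gene_sets.setdefault(f"chrom_{g.chrom}", []).append(g.gene_id)
    if len(dmgs):
        enr = enrich(set(dmgs["gene_id"]), universe, gene_sets)
        _write(enr, outdir / "dmg_enrichment.tsv")

    # --- expression -------------------------------------------------------
    total_counts = mat_counts.add(pat_counts)
    total_counts.index = truth["pair_id"]
    stacked = pd.concat(
        [mat_counts.set_axis(truth["maternal_id"]), pat_counts.set_axis(truth["paternal_id"])]
    )
    tpm_mat = tpm(stacked, gene_lengths)
    _write(tpm_mat.reset_index().rename(columns={"index": "gene_id"}), outdir / "tpm.tsv")

    condition = samples.set_index("sample_id")["phase"]
    deg_frames = []
    for base, other in DEG_CONTRASTS:
        res = test_deg(total_counts, condition.loc[total_counts.columns].to_numpy(), (base, other))
        res.insert(0, "contrast", f"{other}_vs_{base}")
        deg_frames.append(res.reset_index())
    degs = pd.concat(deg_frames, ignore_index=True)
    _write(degs, outdir / "degs.tsv")
    report["n_degs"] = int(degs["flag"].sum())

    le_cols = samples.loc[samples["phase"] == "LE", "sample_id"]
    le_tpm = tpm_mat[le_cols].mean(axis=1)
    classes = tpm_classes(le_tpm)
    _write(classes.reset_index().rename(columns={"index": "gene_id"}), outdir / "tpm_classes.tsv")
    report["tpm_class_sizes"] = classes.value_counts().sort_index().to_dict()

    # per-gene body methylation in the explant, CG context, vs class
    body_levels, body_ids = feature_bin_levels(all_genes, phase_pooled["LE"], "CG")
    body_mean = pd.Series(
        np.nanmean(body_levels[:, 20:60], axis=1), index=body_ids
    )
    try:
        cls_cmp, letters = class_methylation_comparison(classes, body_mean)
        cls_cmp["letters_a"] = cls_cmp["class_a"].map(letters)
        cls_cmp["letters_b"] = cls_cmp["class_b"].map(letters)
        _write(cls_cmp, outdir / "class_methylation.tsv")
    except ValueError:
        pass

    # bin-level methylation-expression correlation over the WGBS phases
    phase_tpm = pd.DataFrame(
        {
            ph: tpm_mat[samples.loc[samples["phase"] == ph, "sample_id"]].mean(axis=1)
            for ph in METHYLOME_PHASES
        }
    )
    corr_frames = []
    for ctx in CONTEXTS:
        per_phase = [feature_bin_levels(all_genes, phase_pooled[ph], ctx) for ph in METHYLOME_PHASES]
        ids = per_phase[0][1]
        cube = np.stack([lv for lv, _ in per_phase], axis=2)
        recs = bin_expression_correlation(cube, ids, phase_tpm, ctx)
        corr_frames.append(recs)
    corr = pd.concat(corr_frames, ignore_index=True)
    _write(corr[corr["significant"]], outdir / "methylation_expression_correlation.tsv")
    sign_summary = correlation_sign_summary(corr)
    _write(sign_summary, outdir / "correlation_sign_summary.tsv")
    report["correlation_sign"] = sign_summary.set_index("context")["frac_negative"].round(4).to_dict()

    # --- allele pairing ---------------------------------------------------
    pairs_pred = pair_alleles(
        _gene_cds(bundle, "alb"),
        _gene_cds(bundle, "gla"),
        _gene_order(bundle, "alb"),
        _gene_order(bundle, "gla"),
    )
    _write(pairs_pred, outdir / "allele_pairs.tsv")
    true_set = set(zip(truth["maternal_id"], truth["paternal_id"]))
    pred_set = set(zip(pairs_pred["maternal_id"], pairs_pred["paternal_id"]))
    report["allele_pairing"] = {
        "n_pairs": len(pred_set),
        "recall": round(len(true_set & pred_set) / max(len(true_set), 1), 4),
        "false_pairs": len(pred_set - true_set),
    }

    # --- allele-specific expression --------------------------------------
    counts = AlleleCounts(mat_counts.set_axis(truth["pair_id"]),
                          pat_counts.set_axis(truth["pair_id"]), samples)
    ase_frames = [test_ase_per_phase(counts, ph) for ph in dict.fromkeys(samples["phase"])]
    ase_all = pd.concat(ase_frames, ignore_index=True)
    _write(ase_all, outdir / "ase.tsv")
    asegs = set(ase_all.loc[ase_all["bias"] != "none", "pair_id"])
    report["n_asegs"] = len(asegs)
    consistency = classify_consistency(ase_all)
    _write(consistency, outdir / "ase_consistency.tsv")
    report["ase_consistency"] = consistency["consistency"].value_counts().to_dict()

    phase_dep = test_phase_dependent_ase(counts)
    _write(phase_dep, outdir / "phase_dependent_ase.tsv")
    pd_pairs = set(phase_dep.loc[phase_dep["phase_dependent"], "pair_id"])
    report["n_phase_dependent_asegs"] = len(pd_pairs)

    log_tpm = np.log2(tpm_mat + 1.0)
    parent_of = {g: "maternal" for g in truth["maternal_id"]}
    parent_of.update({g: "paternal" for g in truth["paternal_id"]})
    pca_scores = allele_pca(log_tpm, parent_of)
    pca_scores.reset_index(names="allele_id").to_csv(
        outdir / "allele_pca.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    # --- allele-specific methylation -------------------------------------
    gm = bundle.gene_index("alb")
    gp = bundle.gene_index("gla")
    asmr_frames = []
    for ph in METHYLOME_PHASES:
        phase_tracks = [indexes[(ph, r)] for r in range(1, config.n_meth_replicates + 1)]
        for ctx in CONTEXTS:
            res = test_asmr(truth, gm, gp, phase_tracks, ctx, ph)
            asmr_frames.append(res)
    asmr_all = pd.concat(asmr_frames, ignore_index=True)
    _write(asmr_all[asmr_all["is_asmr"]], outdir / "asmrs.tsv")
    asmgs = call_asmgs(asmr_all)
    _write(asmgs, outdir / "asmgs.tsv")
    report["n_asmgs"] = {
        ctx: int((asmgs["context"] == ctx).sum()) for ctx in CONTEXTS
    }
    shift = bias_shift_fraction(asmr_all)
    _write(shift, outdir / "asmr_shift.tsv")
    report["asmr_shift_fraction"] = {
        r["context"]: (None if pd.isna(r["shift_fraction"]) else round(r["shift_fraction"], 6))
        for _, r in shift.iterrows()
    }
    if len(asmgs) and pd_pairs:
        try:
            cmp_tab = asmr_count_comparison(asmgs, pd_pairs)
            _write(cmp_tab, outdir / "asmr_count_comparison.tsv")
        except ValueError:
            pass

    # --- promoter TFBS analysis ------------------------------------------
    promoters = {}
    promoters.update(promoter_sequences(bundle, "alb"))
    promoters.update(promoter_sequences(bundle, "gla"))
    hits = scan_promoters(promoters, library)
    _write(hits, outdir / "tfbs_hits.tsv")
    cs_table = pair_cosine_table(hits, truth, library)
    _write(cs_table, outdir / "cs_classes.tsv")
    report["cs_class_sizes"] = cs_table["cs_class"].value_counts().sort_index().to_dict()
    expr_mean = np.log2(tpm_mat + 1.0).mean(axis=1)
    cls_corr = class_expression_correlation(cs_table, expr_mean, expr_mean, pd_pairs)
    _write(cls_corr, outdir / "cs_expression_correlation.tsv")
    coords = {}
    coords.update(promoter_windows(bundle, "alb"))
    coords.update(promoter_windows(bundle, "gla"))
    tfbs_meth = tfbs_methylation(hits, coords, indexes[("LE", 1)], "CG", library)
    _write(tfbs_meth, outdir / "tfbs_methylation.tsv")
    if len(tfbs_meth):
        report["tfbs_low_methylation_fraction"] = round(
            float((tfbs_meth["level"] <= 0.1).mean()), 4
        )

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def write_dataset(config: SimConfig, outdir: str | Path) -> None:
    """Simulate and write the raw dataset (genomes, annotations, reports, counts)."""
    from .io import write_cytosine_report, write_meme_motifs

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle, truth = simulate_genomes(config)
    library = toy_motif_library(config.n_motifs, seed=config.seed)
    place_motifs(bundle, truth, config, library)
    for sg in bundle.sequences:
        write_fasta(bundle.sequences[sg], outdir / f"{sg}.fasta")
        write_gff3(bundle.genes[sg], outdir / f"{sg}.gff3")
        write_bed(bundle.tes[sg], outdir / f"{sg}_tes.bed")
    write_meme_motifs(library, outdir / "motifs.meme")
    _write(truth, outdir / "truth_pairs.tsv")
    tracks, dmr_truth, asmr_truth = simulate_methylomes(bundle, config, truth)
    _write(dmr_truth, outdir / "truth_dmrs.tsv")
    _write(asmr_truth, outdir / "truth_asmrs.tsv")
    meth_dir = outdir / "methylomes"
    meth_dir.mkdir(exist_ok=True)
    for (ph, rep), track in tracks.items():
        write_cytosine_report(track, meth_dir / f"{ph}_{rep}.cov.tsv")
    mat, pat, samples, lfc_truth = simulate_expression(config, truth)
    write_counts(mat.set_axis(truth["maternal_id"]), outdir / "counts_maternal.tsv")
    write_counts(pat.set_axis(truth["paternal_id"]), outdir / "counts_paternal.tsv")
    _write(samples, outdir / "samples.tsv")
    _write(lfc_truth, outdir / "truth_ase.tsv")
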