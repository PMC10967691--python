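"""TPM quantification, differential expression and methylation-expression links.

Differential expression uses the package's own NB GLM (median-of-ratios size
factors, per-gene method-of-moments dispersion with a floor, Wald test on the
condition coefficient, BH FDR); see :mod:`allelome.glm`.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import LN2, bh_adjust, fit_nb_glm, mom_dispersion, size_factors

DEG_LFC_THRESHOLD = 1.0
DEG_FDR_THRESHOLD = 0.05
CORR_R_THRESHOLD = 0.6
CORR_P_THRESHOLD = 0.05

TPM_CLASS_BOUNDS = (0.0, 1.0, 10.0, 100.0)
TPM_CLASS_LABELS = ("I", "II", "III", "IV", "V")


def tpm(counts: pd.DataFrame, lengths: pd.Series | Mapping[str, int]) -> pd.DataFrame:
    """Transcripts per million from raw counts and exon-union gene lengths."""
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = denom.index[denom == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    return rate.div(denom, axis=1) * 1e6


def tpm_classes(tpm_sample: pd.Series) -> pd.Series:
    """Expression classes I-V: TPM = 0; (0,1]; (1,10]; (10,100]; > 100."""
    vals = tpm_sample.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative TPM")
    labels = np.empty(len(vals), dtype=object)
    labels[vals == 0] = "I"
    labels[(vals > 0) & (vals <= 1)] = "II"
    labels[(vals > 1) & (vals <= 10)] = "III"
    labels[(vals > 10) & (vals <= 100)] = "IV"
    labels[vals > 100] = "V"
    return pd.Series(labels, index=tpm_sample.index, name="tpm_class")


def test_deg(
    counts: pd.DataFrame,
    condition: Sequence[str],
    contrast: tuple[str, str],
    lfc_threshold: float = DEG_LFC_THRESHOLD,
    fdr_threshold: float = DEG_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of ``contrast[1]`` vs ``contrast[0]``.

    Genes with all-zero counts are excluded and reported with NaN results.
    """
    condition = np.asarray(condition)
    keep = np.isin(condition, contrast)
    sub = counts.loc[:, keep]
    cond = condition[keep]
    sf = size_factors(sub)
    offset = np.log(sf)
    x_cond = (cond == contrast[1]).astype(float)
    X = np.column_stack([np.ones(len(cond)), x_cond])
    rows = []
    for gene, y in sub.iterrows():
        y = y.to_numpy(dtype=float)
        if not np.any(y > 0):
            rows.append({"gene_id": gene, "log2FC": np.nan, "p": np.nan, "excluded": True})
            continue
        alpha = mom_dispersion(y, sf, cond)
        fit = fit_nb_glm(y, X, alpha, offset=offset)
        lfc = float(fit.beta[1]) / LN2
        _, p = fit.wald(1)
        rows.append({"gene_id": gene, "log2FC": lfc, "p": p, "excluded": False})
    out = pd.DataFrame(rows).set_index("gene_id")
    out["FDR"] = bh_adjust(out["p"].to_numpy())
    out["flag"] = (out["log2FC"].abs() > lfc_threshold) & (out["FDR"] < fdr_threshold)
    out["flag"] = out["flag"].fillna(False)
    return out


# ---------------------------------------------------------------------------
# Expression-class methylation comparison
# ---------------------------------------------------------------------------

def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration over midranks (tie-safe)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    total = 0
    extreme = 0
    mean = ranks.sum() * n1 / len(pooled)
    dev = abs(obs - mean)
    for combo in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= dev - 1e-9:
            extreme += 1
    return extreme / total


def _asymptotic_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8) -> float:
    """Wilcoxon-Mann-Whitney two-sided p; exact enumeration for small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return _exact_rank_sum_p(x, y)
    return _asymptotic_rank_sum_p(x, y)


def compact_letter_display(
    labels: Sequence[str], pmat: Mapping[tuple[str, str], float], alpha: float = 0.05
) -> dict[str, str]:
    """Insert-absorb compact letter display from pairwise p-values."""
    groups: list[set[str]] = [set(labels)]
    for a, b in itertools.combinations(labels, 2):
        p = pmat.get((a, b), pmat.get((b, a), 1.0))
        if p >= alpha:
            continue
        new_groups = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {a})
                new_groups.append(g - {b})
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if not any(g < h or g == h for h in groups):
                groups.append(g)
    letters = {}
    for i, g in enumerate(sorted(groups, key=lambda s: sorted(s))):
        for lab in g:
            letters.setdefault(lab, "")
            letters[lab] += chr(ord("a") + i)
    return {k: "".join(sorted(v)) for k, v in letters.items()}


def class_methylation_comparison(
    classes: pd.Series, region_levels: pd.Series, min_class_size: int = 2
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise rank-sum tests of per-gene methylation between expression classes.

    ``classes`` maps gene -> class label; ``region_levels`` maps gene ->
    methylation level for one region/context. Classes smaller than
    ``min_class_size`` are excluded. Returns (pairwise table, letter groups).
    """
    joined = pd.DataFrame({"cls": classes, "level": region_levels}).dropna()
    sizes = joined.groupby("cls").size()
    keep = sizes[sizes >= min_class_size].index
    joined = joined[joined["cls"].isin(keep)]
    present = sorted(joined["cls"].unique())
    if len(present) < 2:
        raise ValueError("need at least two nonempty classes")
    rows = []
    pmat = {}
    for a, b in itertools.combinations(present, 2):
        xa = joined.loc[joined["cls"] == a, "level"].to_numpy()
        xb = joined.loc[joined["cls"] == b, "level"].to_numpy()
        p = rank_sum_test(xa, xb)
        pmat[(a, b)] = p
        rows.append({"class_a": a, "class_b": b, "n_a": len(xa), "n_b": len(xb), "p": p})
    letters = compact_letter_display(present, pmat)
    return pd.DataFrame(rows), letters


# ---------------------------------------------------------------------------
# Bin-level methylation-expression correlation
# ---------------------------------------------------------------------------

def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of x[i] vs y[i] with two-sided t-test p (vectorised)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", xc, yc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    p[~np.isfinite(r)] = np.nan
    return r, p


def bin_expression_correlation(
    bin_levels: np.ndarray,
    gene_ids: Sequence[str],
    tpm_by_phase: pd.DataFrame,
    context: str,
    r_threshold: float = CORR_R_THRESHOLD,
    p_threshold: float = CORR_P_THRESHOLD,
) -> pd.DataFrame:
    """Pearson correlation of each gene's 80 bin levels with TPM across phases.

    ``bin_levels`` has shape (n_genes, 80, n_phases); ``tpm_by_phase`` is a
    gene x phase frame of replicate-mean TPM in the same phase order. Records
    with fewer than 3 phases of defined bin levels, or a constant series, are
    skipped. Significance needs both |r| > 0.6 and p < 0.05.
    """
    bin_levels = np.asarray(bin_levels, dtype=float)
    n_genes, n_bins, n_phases = bin_levels.shape
    if n_phases < 3:
        raise ValueError("need at least 3 phases")
    expr = tpm_by_phase.reindex(gene_ids).to_numpy(dtype=float)
    rows = []
    for gi in range(n_genes):
        lv = bin_levels[gi]
        defined = ~np.isnan(lv).any(axis=1)
        if not defined.any():
            continue
        x = lv[defined]
        y = np.broadcast_to(expr[gi], x.shape)
        # near-zero variance counts as constant (float representation noise)
        const = (x.std(axis=1) <= 1e-9) | (np.std(expr[gi]) <= 1e-9)
        r, p = pearson_with_p(x, y)
        bins_idx = np.flatnonzero(defined)
        for bi, rr, pp, cc in zip(bins_idx, r, p, const):
            if cc or not np.isfinite(rr):
                continue
            rows.append(
                {
                    "gene_id": gene_ids[gi],
                    "bin": int(bi),
                    "context": context,
                    "r": float(rr),
                    "p": float(pp),
                }
            )
    out = pd.DataFrame(rows, columns=["gene_id", "bin", "context", "r", "p"])
    if len(out):
        out["significant"] = (out["r"].abs() > r_threshold) & (out["p"] < p_threshold)
        out["sign"] = np.where(out["r"] > 0, "positive", "negative")
    else:
        out["significant"] = pd.Series(dtype=bool)
        out["sign"] = pd.Series(dtype=object)
    return out


def correlation_sign_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-context gene counts and sign split among significant correlations.

    A gene is counted by the sign of its strongest significant bin (largest
    |r|).
    """
    sig = records[records["significant"]]
    rows = []
    for ctx, sub in sig.groupby("context"):
        # per gene, the row with the largest |r|
        best = sub.assign(absr=sub["r"].abs()).sort_values("absr").groupby("gene_id").tail(1)
        neg = int((best["r"] < 0).sum())
        pos = int((best["r"] > 0).sum())
        rows.append(
            {
                "context": ctx,
                "n_significant_bins": len(sub),
                "n_genes": best["gene_id"].nunique(),
                "n_negative": neg,
                "n_positive": pos,
                "frac_negative": neg / max(neg + pos, 1),
            }
        )
    return pd.DataFrame(rows, columns=["context", "n_significant_bins", "n_genes", "n_negative", "n_positive", "frac_negative"])
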