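"""Differential methylation between sample groups on 200-bp sliding bins.

The per-bin test is a binomial logistic regression of the methylated
proportion on group membership, with each replicate entering as a separate
binomial observation, compared with the intercept-only model by a
likelihood-ratio test. Because the group model has one free proportion per
group, its MLE is the group-pooled proportion, so the LRT statistic reduces
to the binomial G statistic on pooled group counts and can be computed in
closed form for every bin at once. Q-values are Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import bh_adjust
from .io import GeneModel
from .methylome import interval_counts, make_sliding_bins

#: per-context absolute methylation-difference thresholds for calling a DMR
DIFF_THRESHOLDS = {"CG": 0.25, "CHG": 0.25, "CHH": 0.15}
Q_THRESHOLD = 0.05
MIN_CYTOSINES = 5


def bin_counts(
    tracks: Sequence[pd.DataFrame],
    bins: pd.DataFrame,
    context: str,
    min_cytosines: int = MIN_CYTOSINES,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-bin, per-replicate pooled counts for one context.

    Returns (bins kept, mc matrix, cov matrix) where matrices are
    bins x replicates. Only bins with >= ``min_cytosines`` cytosines of the
    context in *all* samples are retained.
    """
    mc_cols, cov_cols, n_cols = [], [], []
    for track in tracks:
        cnt = interval_counts(track, bins, context)
        mc_cols.append(cnt["mc"].to_numpy())
        cov_cols.append(cnt["cov"].to_numpy())
        n_cols.append(cnt["n_cytosines"].to_numpy())
    mc = np.column_stack(mc_cols)
    cov = np.column_stack(cov_cols)
    n = np.column_stack(n_cols)
    keep = (n >= min_cytosines).all(axis=1)
    return bins.loc[keep].reset_index(drop=True), mc[keep], cov[keep]


def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def binomial_lrt(
    m1: np.ndarray, c1: np.ndarray, m2: np.ndarray, c2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised G statistic and chi2 p for group-pooled binomial counts.

    Equal to the LRT of the replicate-level binomial logistic regression
    (group model vs intercept-only), whose MLEs are the pooled proportions.
    """
    u1, u2 = c1 - m1, c2 - m2
    m, u, c = m1 + m2, u1 + u2, c1 + c2
    ll_full = _xlogx(m1) + _xlogx(u1) - _xlogx(c1) + _xlogx(m2) + _xlogx(u2) - _xlogx(c2)
    ll_null = _xlogx(m) + _xlogx(u) - _xlogx(c)
    g = 2.0 * (ll_full - ll_null)
    g = np.maximum(g, 0.0)
    p = stats.chi2.sf(g, 1)
    return g, p


def estimate_inflation(mc: np.ndarray, cov: np.ndarray) -> float:
    """Beta-binomial variance-inflation factor from replicate heterogeneity.

    Method of moments on the replicate proportions within each bin: the mean
    chi-square of replicates around the pooled bin proportion estimates the
    factor by which binomial variance is exceeded. Returns max(1, estimate).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = mc.sum(axis=1, keepdims=True) / np.maximum(cov.sum(axis=1, keepdims=True), 1)
        p = np.clip(pooled, 1e-9, 1 - 1e-9)
        chi = (mc - cov * p) ** 2 / (cov * p * (1 - p))
    valid = cov > 0
    nrep = valid.sum(axis=1)
    ok = nrep > 1
    if not ok.any():
        return 1.0
    per_bin = np.nansum(np.where(valid, chi, np.nan), axis=1)[ok] / (nrep[ok] - 1)
    return float(max(np.mean(per_bin), 1.0))


def test_dmr(
    group1: tuple[np.ndarray, np.ndarray],
    group2: tuple[np.ndarray, np.ndarray],
    bins: pd.DataFrame,
    context: str,
    overdispersion: bool = False,
    diff_thresholds: Mapping[str, float] = DIFF_THRESHOLDS,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """DMR candidates between two replicate groups on shared bins.

    ``group*`` are (mc, cov) matrices as produced by :func:`bin_counts`.
    Difference = pooled level(group2) - pooled level(group1). A bin is a DMR
    when |difference| > per-context threshold and q < ``q_threshold``.
    Bins with zero total coverage in either group are skipped.
    """
    m1 = group1[0].sum(axis=1).astype(float)
    c1 = group1[1].sum(axis=1).astype(float)
    m2 = group2[0].sum(axis=1).astype(float)
    c2 = group2[1].sum(axis=1).astype(float)
    ok = (c1 > 0) & (c2 > 0)
    out = bins.loc[ok].reset_index(drop=True).copy()
    m1, c1, m2, c2 = m1[ok], c1[ok], m2[ok], c2[ok]
    g, p = binomial_lrt(m1, c1, m2, c2)
    if overdispersion:
        infl = max(
            estimate_inflation(np.concatenate([group1[0], group2[0]], axis=1)[ok],
                               np.concatenate([group1[1], group2[1]], axis=1)[ok]),
            1.0,
        )
        p = stats.chi2.sf(g / infl, 1)
    level1 = m1 / c1
    level2 = m2 / c2
    out["context"] = context
    out["level1"] = level1
    out["level2"] = level2
    out["difference"] = level2 - level1
    out["p"] = p
    out["q"] = bh_adjust(p)
    thr = diff_thresholds[context]
    out["is_dmr"] = (np.abs(out["difference"]) > thr) & (out["q"] < q_threshold)
    out["direction"] = np.where(out["difference"] > 0, "hyper", "hypo")
    out["to_high"] = out["is_dmr"] & (out["level2"] > 0.8)
    out["to_low"] = out["is_dmr"] & (out["level2"] < 0.2)
    return out


def call_dmrs(
    group1_tracks: Sequence[pd.DataFrame],
    group2_tracks: Sequence[pd.DataFrame],
    chrom_sizes: dict[str, int],
    context: str,
    length: int = 200,
    step: int = 100,
    **kwargs,
) -> pd.DataFrame:
    """Convenience wrapper: sliding bins -> filtered counts -> DMR test."""
    from .methylome import TrackIndex

    bins = make_sliding_bins(chrom_sizes, length, step)
    tracks = [
        t if isinstance(t, TrackIndex) else TrackIndex(t)
        for t in list(group1_tracks) + list(group2_tracks)
    ]
    kept, mc, cov = bin_counts(tracks, bins, context)
    n1 = len(group1_tracks)
    return test_dmr((mc[:, :n1], cov[:, :n1]), (mc[:, n1:], cov[:, n1:]), kept, context, **kwargs)


# ---------------------------------------------------------------------------
# DMG annotation
# ---------------------------------------------------------------------------

FEATURE_PRECEDENCE = ("promoter", "gene_body", "downstream", "intergenic")


def annotate_dmg(
    dmrs: pd.DataFrame, genes: Sequence[GeneModel], flank: int = 2000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign DMRs to genes and genic features; derive the DMG table.

    A DMR overlapping (by >= 1 bp) a gene body, its strand-aware 2-kb
    promoter, or its 2-kb downstream region makes that gene a DMG. Each DMR
    gets one primary feature by the precedence promoter > gene_body >
    downstream > intergenic. Returns (per-DMR annotation, DMG table).
    """
    regions = []  # (chrom, start, end, feature, gene_id)
    for g in genes:
        if g.strand == "+":
            prom = (g.start - flank, g.start)
            down = (g.end, g.end + flank)
        else:
            prom = (g.end, g.end + flank)
            down = (g.start - flank, g.start)
        regions.append((g.chrom, max(prom[0], 0), prom[1], "promoter", g.gene_id))
        regions.append((g.chrom, g.start, g.end, "gene_body", g.gene_id))
        regions.append((g.chrom, max(down[0], 0), down[1], "downstream", g.gene_id))
    reg = pd.DataFrame(regions, columns=["chrom", "start", "end", "feature", "gene_id"])
    dmr_rows = dmrs[dmrs.get("is_dmr", True)].reset_index(drop=True) if "is_dmr" in dmrs else dmrs.reset_index(drop=True)
    prec = {f: i for i, f in enumerate(FEATURE_PRECEDENCE)}
    primary = []
    hits_all = []
    for chrom, sub in dmr_rows.groupby("chrom", sort=False):
        rsub = reg[reg["chrom"] == chrom]
        rs = rsub["start"].to_numpy()
        re_ = rsub["end"].to_numpy()
        for i, row in sub.iterrows():
            mask = (rs < row["end"]) & (re_ > row["start"])
            feats = rsub.loc[mask]
            if feats.empty:
                primary.append((i, "intergenic"))
            else:
                best = min(feats["feature"], key=prec.__getitem__)
                primary.append((i, best))
                for _, f in feats.iterrows():
                    hits_all.append((i, f["gene_id"], f["feature"]))
    ann = dmr_rows.copy()
    ann["primary_feature"] = "intergenic"
    for i, feat in primary:
        ann.loc[i, "primary_feature"] = feat
    hits = pd.DataFrame(hits_all, columns=["dmr_index", "gene_id", "feature"])
    if hits.empty:
        dmgs = pd.DataFrame(columns=["gene_id", "n_dmrs", "features"])
    else:
        dmgs = (
            hits.groupby("gene_id")
            .agg(n_dmrs=("dmr_index", "nunique"), features=("feature", lambda s: ",".join(sorted(set(s)))))
            .reset_index()
        )
    return ann, dmgs


# ---------------------------------------------------------------------------
# Time-course profile clustering (STEM-style, simplified)
# ---------------------------------------------------------------------------

def _candidate_profiles(n_timepoints: int, c: int, n_profiles: int, rng: np.random.Generator) -> np.ndarray:
    steps = range(-c, c + 1)
    trajs = []
    for combo in itertools.product(steps, repeat=n_timepoints - 1):
        traj = np.concatenate([[0], np.cumsum(combo)])
        trajs.append(traj)
    trajs = np.unique(np.asarray(trajs, dtype=float), axis=0)
    if len(trajs) <= n_profiles:
        return trajs
    # greedy max-min-distance reduction, seeded at the flat profile
    flat = int(np.argmin(np.abs(trajs).sum(axis=1)))
    chosen = [flat]
    d = np.linalg.norm(trajs - trajs[flat], axis=1)
    for _ in range(n_profiles - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(trajs - trajs[nxt], axis=1))
    return trajs[sorted(chosen)]


def _assign(series: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Assign each standardised series to its highest-correlation profile.

    Constant series (undefined correlation) go to the flat profile.
    """
    s = series - series[:, :1]
    flat_idx = int(np.argmin(np.abs(profiles).sum(axis=1)))
    sc = s - s.mean(axis=1, keepdims=True)
    pc = profiles - profiles.mean(axis=1, keepdims=True)
    snorm = np.linalg.norm(sc, axis=1)
    pnorm = np.linalg.norm(pc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (sc @ pc.T) / np.outer(snorm, pnorm)
    corr[:, pnorm == 0] = -np.inf
    assigned = np.argmax(np.where(np.isnan(corr), -np.inf, corr), axis=1)
    assigned[snorm == 0] = flat_idx
    return assigned


def stem_cluster(
    series: np.ndarray,
    c: int = 2,
    n_candidate_profiles: int = 50,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster short methylation time series into model profiles.

    ``series`` is an (n_series, T) array, T in {3, 4}. Candidate profiles are
    integer-step trajectories starting at 0 (steps in [-c, c]), greedily
    thinned to ``n_candidate_profiles`` by max-min distance. Each series is
    assigned to its most-correlated profile; profile significance compares
    the assigned count with the distribution obtained by permuting each
    series' time order (all T! permutations enumerated when feasible).

    Returns (per-series assignment frame, per-profile frame with counts and
    permutation p-values).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 3:
        raise ValueError("need series over at least 3 timepoints")
    t = series.shape[1]
    rng = np.random.default_rng(seed)
    profiles = _candidate_profiles(t, c, n_candidate_profiles, rng)
    assigned = _assign(series, profiles)
    n_series = series.shape[0]
    counts = np.bincount(assigned, minlength=len(profiles))

    perms = list(itertools.permutations(range(t)))
    if len(perms) > n_permutations:
        idx = rng.choice(len(perms), size=n_permutations, replace=False)
        perms = [perms[i] for i in idx]
    null_prob = np.zeros(len(profiles))
    for perm in perms:
        a = _assign(series[:, list(perm)], profiles)
        null_prob += np.bincount(a, minlength=len(profiles))
    null_prob /= len(perms) * n_series
    # one-sided binomial tail: observed count vs expected under permutation
    pvals = stats.binom.sf(counts - 1, n_series, np.clip(null_prob, 1e-12, 1.0))
    prof_frame = pd.DataFrame(
        {
            "profile_id": np.arange(len(profiles)),
            "trajectory": [";".join(str(int(v)) for v in p) for p in profiles],
            "n_assigned": counts,
            "expected": null_prob * n_series,
            "p": pvals,
        }
    )
    assign_frame = pd.DataFrame({"series_index": np.arange(n_series), "profile_id": assigned})
    return assign_frame, prof_frame


# ---------------------------------------------------------------------------
# Generic gene-set enrichment
# ---------------------------------------------------------------------------

def enrich(
    selected: set[str] | Sequence[str],
    universe: set[str] | Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set, BH across sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    rows = []
    for name, members in gene_sets.items():
        m = set(members) & universe
        k = len(selected & m)
        p = stats.hypergeom.sf(k - 1, len(universe), len(m), len(selected))
        rows.append({"set": name, "set_size": len(m), "overlap": k, "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
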