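"""Allele-specific methylation: per-gene 80-bin tests between allele pairs.

The test is the same replicate-aware binomial LRT used for phase-contrast
DMRs (:func:`allelome.dmr.binomial_lrt`), with the two alleles as the two
groups. Bins correspond across alleles by ordinal index in the shared
20/40/20 scheme, since allele bodies differ in length. Significance
thresholds are inherited from the DMR caller per context.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import DIFF_THRESHOLDS, MIN_CYTOSINES, Q_THRESHOLD, binomial_lrt
from .glm import bh_adjust
from .io import GeneModel
from .methylome import gene_bin_scheme, interval_counts


def _bins_frame(genes: Sequence[GeneModel], flank: int) -> pd.DataFrame | None:
    """Stacked 80-bin intervals for a gene list (rows: gene-major, bin-minor)."""
    import warnings

    chroms, starts, ends = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in genes:
            bins = gene_bin_scheme(g, flank=flank)
            assert bins is not None
            chroms.extend([g.chrom] * len(bins))
            starts.extend(max(b[0], 0) for b in bins)
            ends.extend(max(b[1], 0) for b in bins)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def test_asmr(
    pairs: pd.DataFrame,
    maternal_genes: Mapping[str, GeneModel],
    paternal_genes: Mapping[str, GeneModel],
    tracks: Sequence,
    context: str,
    phase: str,
    min_cytosines: int = MIN_CYTOSINES,
    diff_thresholds: Mapping[str, float] = DIFF_THRESHOLDS,
    q_threshold: float = Q_THRESHOLD,
    flank: int = 2000,
) -> pd.DataFrame:
    """ASMRs between allele pairs for one phase and context.

    ``tracks`` are the phase's replicate methylation tracks (or prebuilt
    :class:`allelome.methylome.TrackIndex` objects) covering both
    subgenomes. Bin i of the maternal gene is compared with bin i of the
    paternal gene; bins need >= ``min_cytosines`` cytosines of the context
    in every replicate on both alleles. Direction is the sign of
    maternal - paternal. Unpaired or too-short genes are skipped.
    """
    n_bins = 80
    kept_rows = []
    for _, row in pairs.iterrows():
        m = maternal_genes.get(row["maternal_id"])
        p = paternal_genes.get(row["paternal_id"])
        if m is None or p is None:
            continue
        if m.end - m.start < 40 or p.end - p.start < 40:
            continue
        kept_rows.append((row, m, p))
    empty_cols = ["pair_id", "maternal_id", "paternal_id", "bin", "context", "phase",
                  "level_maternal", "level_paternal", "difference", "p"]
    if not kept_rows:
        return pd.DataFrame(columns=empty_cols + ["q", "is_asmr", "direction"])
    m_frame = _bins_frame([m for _, m, _ in kept_rows], flank)
    p_frame = _bins_frame([p for _, _, p in kept_rows], flank)
    m_mc, m_cov, m_n = [], [], []
    p_mc, p_cov, p_n = [], [], []
    for track in tracks:
        cm = interval_counts(track, m_frame, context)
        cp = interval_counts(track, p_frame, context)
        m_mc.append(cm["mc"].to_numpy())
        m_cov.append(cm["cov"].to_numpy())
        m_n.append(cm["n_cytosines"].to_numpy())
        p_mc.append(cp["mc"].to_numpy())
        p_cov.append(cp["cov"].to_numpy())
        p_n.append(cp["n_cytosines"].to_numpy())
    m_mc, m_cov, m_n = (np.column_stack(a) for a in (m_mc, m_cov, m_n))
    p_mc, p_cov, p_n = (np.column_stack(a) for a in (p_mc, p_cov, p_n))
    ok = (m_n >= min_cytosines).all(axis=1) & (p_n >= min_cytosines).all(axis=1)
    ok &= (m_cov.sum(axis=1) > 0) & (p_cov.sum(axis=1) > 0)
    idx = np.flatnonzero(ok)
    mm = m_mc[idx].sum(axis=1).astype(float)
    mC = m_cov[idx].sum(axis=1).astype(float)
    pm = p_mc[idx].sum(axis=1).astype(float)
    pC = p_cov[idx].sum(axis=1).astype(float)
    _, pv = binomial_lrt(mm, mC, pm, pC)
    pair_ids = np.array([
        r.get("pair_id", f"{r['maternal_id']}|{r['paternal_id']}") for r, _, _ in kept_rows
    ])
    mat_ids = np.array([r["maternal_id"] for r, _, _ in kept_rows])
    pat_ids = np.array([r["paternal_id"] for r, _, _ in kept_rows])
    gene_idx = idx // n_bins
    out = pd.DataFrame(
        {
            "pair_id": pair_ids[gene_idx],
            "maternal_id": mat_ids[gene_idx],
            "paternal_id": pat_ids[gene_idx],
            "bin": (idx % n_bins).astype(int),
            "context": context,
            "phase": phase,
            "level_maternal": mm / mC,
            "level_paternal": pm / pC,
            "difference": mm / mC - pm / pC,
            "p": pv,
        },
        columns=empty_cols,
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    thr = diff_thresholds[context]
    out["is_asmr"] = (out["difference"].abs() > thr) & (out["q"] < q_threshold)
    out["direction"] = np.where(out["difference"] > 0, "maternal_hyper", "paternal_hyper")
    return out


def call_asmgs(asmrs: pd.DataFrame) -> pd.DataFrame:
    """Genes (allele pairs) carrying >= 1 ASMR, per context."""
    sig = asmrs[asmrs["is_asmr"]]
    if sig.empty:
        return pd.DataFrame(columns=["pair_id", "context", "n_asmrs", "phases"])
    out = (
        sig.groupby(["pair_id", "context"])
        .agg(
            n_asmrs=("bin", lambda s: len(set(s))),
            phases=("phase", lambda s: ",".join(sorted(set(s)))),
        )
        .reset_index()
    )
    return out


def bias_shift_fraction(asmrs: pd.DataFrame) -> pd.DataFrame:
    """Per-context fraction of matched ASMRs whose direction flips across phases.

    A region (pair, bin) is *matched* when significant in >= 2 phases;
    *shifted* when those significant calls disagree in direction. Regions
    significant in a single phase only are stable by default and excluded
    from both numerator and denominator.
    """
    sig = asmrs[asmrs["is_asmr"]]
    rows = []
    for ctx in sorted(asmrs["context"].unique()):
        sub = sig[sig["context"] == ctx]
        grouped = sub.groupby(["pair_id", "bin"])
        matched = 0
        shifted = 0
        for _, g in grouped:
            if g["phase"].nunique() < 2:
                continue
            matched += 1
            if g["direction"].nunique() > 1:
                shifted += 1
        rows.append(
            {
                "context": ctx,
                "n_matched": matched,
                "n_shifted": shifted,
                "shift_fraction": shifted / matched if matched else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["context", "n_matched", "n_shifted", "shift_fraction"])


def asmr_count_comparison(
    asmgs: pd.DataFrame,
    phase_dependent_pairs: set[str] | Sequence[str],
) -> pd.DataFrame:
    """Compare ASMR-count distributions of phase-dependent ASEGs vs other ASMGs.

    Per context, ASMG counts are banded into {1, 2, >=3}; the >=3 band is
    compared between the two groups by a chi-square test with continuity
    correction, replaced by Fisher's exact test when any expected cell is
    < 5. Raises when either group is empty in every context.
    """
    phase_dependent_pairs = set(phase_dependent_pairs)
    rows = []
    any_groups = False
    for ctx in sorted(asmgs["context"].unique()):
        sub = asmgs[asmgs["context"] == ctx]
        in_pd = sub["pair_id"].isin(phase_dependent_pairs)
        g1 = sub[in_pd]  # phase-dependent ASEGs
        g2 = sub[~in_pd]  # remaining ASMGs
        if g1.empty or g2.empty:
            continue
        any_groups = True
        row = {"context": ctx, "n_phase_dep": len(g1), "n_other": len(g2)}
        for label, g in (("phase_dep", g1), ("other", g2)):
            counts = g["n_asmrs"]
            row[f"{label}_1"] = int((counts == 1).sum())
            row[f"{label}_2"] = int((counts == 2).sum())
            row[f"{label}_3plus"] = int((counts >= 3).sum())
        a, b = row["phase_dep_3plus"], row["n_phase_dep"] - row["phase_dep_3plus"]
        c, d = row["other_3plus"], row["n_other"] - row["other_3plus"]
        table = np.array([[a, b], [c, d]])
        if (a + c) == 0 or (b + d) == 0:
            row["test"] = "skipped"
            row["p"] = np.nan
        else:
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            if (expected < 5).any():
                row["test"] = "fisher"
                row["p"] = float(stats.fisher_exact(table)[1])
            else:
                row["test"] = "chi2_cc"
                row["p"] = float(stats.chi2_contingency(table, correction=True)[1])
        rows.append(row)
    if not any_groups:
        raise ValueError("empty group: no context has both phase-dependent and other ASMGs")
    return pd.DataFrame(rows)
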