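"""Methylation levels, genome summaries, sliding bins and metagene profiles.

A "methylation track" is the per-site frame produced by
:func:`allelome.io.read_cytosine_report`: one row per cytosine with
``chrom, pos0, strand, context, mc, uc``. Levels are the classic weighted
methylation level: methylated read count over total read count.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTEXTS, GeneModel

DEFAULT_MIN_COV = 5
LEVEL_BANDS = ((0.0, 0.2), (0.2, 0.8), (0.8, 1.0))  # low, mid, high


def site_levels(records: pd.DataFrame, min_cov: int = DEFAULT_MIN_COV) -> pd.DataFrame:
    """Per-site methylation level mc/(mc+uc), keeping sites with coverage >= min_cov."""
    cov = records["mc"] + records["uc"]
    out = records.loc[cov >= min_cov].copy()
    out["level"] = out["mc"] / (out["mc"] + out["uc"])
    return out


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def call_methylated(
    records: pd.DataFrame,
    non_conversion: float = 0.005,
    alpha: float = 0.01,
    min_cov: int = DEFAULT_MIN_COV,
) -> pd.DataFrame:
    """Binomial test of each site's methylated count against the non-conversion rate.

    A site is called methylated when its one-sided binomial p-value (against
    the null that every methylated read is a conversion failure) survives BH
    correction within its context at ``alpha``.
    """
    df = site_levels(records, min_cov=min_cov).copy()
    cov = (df["mc"] + df["uc"]).to_numpy()
    p = stats.binom.sf(df["mc"].to_numpy() - 1, cov, non_conversion)
    df["p_methylated"] = p
    q = np.ones(len(df))
    for ctx in CONTEXTS:
        mask = (df["context"] == ctx).to_numpy()
        q[mask] = _bh(p[mask])
    df["q_methylated"] = q
    df["is_methylated"] = q < alpha
    return df


def global_summary(
    records: pd.DataFrame,
    min_cov: int = DEFAULT_MIN_COV,
    non_conversion: float = 0.005,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-context mean level, methylated-site fraction and level-band histogram.

    Bands follow the conventional low/mid/high split: [0, 0.2), [0.2, 0.8],
    (0.8, 1.0]. Band fractions are taken over methylation-called sites.
    """
    called = call_methylated(records, non_conversion, alpha, min_cov)
    rows = []
    for ctx in CONTEXTS:
        sub = called[called["context"] == ctx]
        n = len(sub)
        meth = sub[sub["is_methylated"]]
        lv = meth["level"].to_numpy()
        rows.append(
            {
                "context": ctx,
                "n_sites": n,
                "mean_level": float(sub["level"].mean()) if n else np.nan,
                "frac_methylated": len(meth) / n if n else np.nan,
                "band_low": float(np.mean(lv < 0.2)) if lv.size else np.nan,
                "band_mid": float(np.mean((lv >= 0.2) & (lv <= 0.8)))
                if lv.size
                else np.nan,
                "band_high": float(np.mean(lv > 0.8)) if lv.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RegionLevel:
    chrom: str
    start: int
    end: int
    context: str
    weighted_level: float  # nan when undefined
    n_cytosines: int
    total_coverage: int

    @property
    def defined(self) -> bool:
        return self.n_cytosines > 0


def weighted_region_level(
    records: pd.DataFrame, chrom: str, start: int, end: int, context: str
) -> RegionLevel:
    """Coverage-weighted level over the cytosines of one interval."""
    sub = records[
        (records["chrom"] == chrom)
        & (records["pos0"] >= start)
        & (records["pos0"] < end)
        & (records["context"] == context)
    ]
    mc = int(sub["mc"].sum())
    uc = int(sub["uc"].sum())
    n = len(sub)
    level = mc / (mc + uc) if (n > 0 and mc + uc > 0) else np.nan
    return RegionLevel(chrom, start, end, context, level, n, mc + uc)


def make_sliding_bins(
    chrom_sizes: dict[str, int], length: int = 200, step: int = 100
) -> pd.DataFrame:
    """Half-open sliding bins tiling each chromosome.

    The last partial bin is kept when it is at least ``step`` long, so
    chromosome ends are not silently dropped.
    """
    if step > length:
        raise ValueError("step must not exceed bin length")
    frames = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size")
        starts = np.arange(0, size, step)
        ends = np.minimum(starts + length, size)
        keep = (ends - starts) >= min(step, size)
        starts, ends = starts[keep], ends[keep]
        # drop trailing bins fully contained in their predecessor
        while len(starts) > 1 and ends[-1] == ends[-2] and starts[-1] >= starts[-2]:
            starts, ends = starts[:-1], ends[:-1]
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


def gene_bin_scheme(
    feature: GeneModel | tuple[str, int, int, str],
    flank: int = 2000,
    n_flank_bins: int = 20,
    n_body_bins: int = 40,
) -> list[tuple[int, int]] | None:
    """80 ordered genomic bins for one gene or TE: 20 upstream, 40 body, 20 downstream.

    Bin order follows transcription: bin 0 is the 5'-most flank bin. Flank
    bins are fixed-width (flank / n_flank_bins); body bins split the feature
    proportionally. Features shorter than ``n_body_bins`` bp are excluded
    (returns None with a warning).
    """
    if isinstance(feature, GeneModel):
        chrom, start, end, strand = feature.chrom, feature.start, feature.end, feature.strand
    else:
        chrom, start, end, strand = feature
    if end - start < n_body_bins:
        warnings.warn(f"feature on {chrom} shorter than {n_body_bins} bp; excluded")
        return None
    fw = flank // n_flank_bins
    body_edges = np.round(np.linspace(start, end, n_body_bins + 1)).astype(int)
    body = list(zip(body_edges[:-1], body_edges[1:]))
    up = [(start - flank + i * fw, start - flank + (i + 1) * fw) for i in range(n_flank_bins)]
    down = [(end + i * fw, end + (i + 1) * fw) for i in range(n_flank_bins)]
    if strand == "+":
        bins = up + body + down
    else:
        # transcription runs right to left: 5'-most bin is the far-right one
        up_rev = [(end + flank - (i + 1) * fw, end + flank - i * fw) for i in range(n_flank_bins)]
        down_rev = [(start - (i + 1) * fw, start - i * fw) for i in range(n_flank_bins)]
        bins = up_rev + body[::-1] + down_rev
    return bins


class TrackIndex:
    """Prefix-sum index over one sample's methylation track.

    Build once, query many intervals cheaply; used by the DMR/ASMR callers
    and the metagene profiler.
    """

    def __init__(self, track: pd.DataFrame) -> None:
        self._by_context: dict[str, dict[str, tuple]] = {}
        for ctx, sub in track.groupby("context", observed=True, sort=False):
            per_chrom = {}
            for chrom, grp in sub.groupby("chrom", observed=True, sort=False):
                g = grp.sort_values("pos0")
                pos = g["pos0"].to_numpy()
                mc = np.concatenate([[0], np.cumsum(g["mc"].to_numpy(dtype=np.int64))])
                cov = np.concatenate(
                    [[0], np.cumsum((g["mc"] + g["uc"]).to_numpy(dtype=np.int64))]
                )
                per_chrom[str(chrom)] = (pos, mc, cov)
            self._by_context[str(ctx)] = per_chrom

    def arrays(self, context: str) -> dict[str, tuple]:
        return self._by_context.get(context, {})


def interval_counts(
    track: "pd.DataFrame | TrackIndex", bins: pd.DataFrame, context: str
) -> pd.DataFrame:
    """Pooled (mc, cov, n_cytosines) per interval; vectorised via prefix sums."""
    index = track if isinstance(track, TrackIndex) else TrackIndex(track)
    idx = index.arrays(context)
    mc = np.zeros(len(bins), dtype=np.int64)
    cov = np.zeros(len(bins), dtype=np.int64)
    n = np.zeros(len(bins), dtype=np.int64)
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    for chrom in pd.unique(chroms):
        if chrom not in idx:
            continue
        pos, cmc, ccov = idx[chrom]
        mask = chroms == chrom
        lo = np.searchsorted(pos, starts[mask], side="left")
        hi = np.searchsorted(pos, ends[mask], side="left")
        mc[mask] = cmc[hi] - cmc[lo]
        cov[mask] = ccov[hi] - ccov[lo]
        n[mask] = hi - lo
    out = bins.copy()
    out["mc"] = mc
    out["cov"] = cov
    out["n_cytosines"] = n
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(cov > 0, mc / np.maximum(cov, 1), np.nan)
    return out


def feature_bin_levels(
    features: Sequence[GeneModel | tuple[str, int, int, str]],
    track: pd.DataFrame,
    context: str,
    flank: int = 2000,
    n_flank_bins: int = 20,
    n_body_bins: int = 40,
) -> tuple[np.ndarray, list[str]]:
    """Per-feature 80-bin weighted levels; rows are features, columns bins.

    Returns (levels matrix with NaN where a bin has no covered cytosines,
    feature ids in row order). Features failing the length filter are skipped.
    """
    n_bins = 2 * n_flank_bins + n_body_bins
    chroms, starts, ends, ids = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for feat in features:
            bins = gene_bin_scheme(feat, flank, n_flank_bins, n_body_bins)
            if bins is None:
                continue
            if isinstance(feat, GeneModel):
                chrom, fid = feat.chrom, feat.gene_id
            else:
                chrom, fid = feat[0], f"{feat[0]}:{feat[1]}-{feat[2]}"
            chroms.extend([chrom] * n_bins)
            starts.extend(max(b[0], 0) for b in bins)
            ends.extend(max(b[1], 0) for b in bins)
            ids.append(fid)
    if not ids:
        return np.empty((0, n_bins)), []
    frame = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    cnt = interval_counts(track, frame, context)
    return cnt["level"].to_numpy().reshape(len(ids), n_bins), ids


def metagene_profile(
    features: Sequence[GeneModel | tuple[str, int, int, str]],
    track: pd.DataFrame,
    context: str,
    flank: int = 2000,
    n_flank_bins: int = 20,
    n_body_bins: int = 40,
) -> np.ndarray:
    """80-bin profile averaged over features (NaN-aware per bin)."""
    levels, _ = feature_bin_levels(features, track, context, flank, n_flank_bins, n_body_bins)
    if levels.shape[0] == 0:
        raise ValueError("no qualifying features")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(levels, axis=0)
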