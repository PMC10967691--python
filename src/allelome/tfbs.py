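"""Promoter motif scanning and allele cosine-similarity analysis.

The scanner scores 2-kb promoters against position weight matrices with
log-odds scores over a 0-order background, on both strands. Hit p-values
are exact: the null score distribution is obtained by dynamic-programming
convolution of the integerised per-column score distributions, so the tail
mass at a score equals the probability that a random background word scores
at least as high.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Motif

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_P_THRESHOLD = 1e-4
SCORE_SCALE = 100  # log-odds units are integerised at 0.01 resolution

CS_CLASS_BOUNDS = (0.2, 0.4, 0.6, 0.8)
CS_CLASS_LABELS = ("I", "II", "III", "IV", "V")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclasses.dataclass
class PreparedPWM:
    """Integerised log-odds matrix with its exact null score distribution."""

    motif_id: str
    iscores: np.ndarray  # (width, 4) integers
    background: np.ndarray  # length 4
    offset: int  # min achievable integer score
    tail: np.ndarray  # tail[s - offset] = P(score >= s) under background
    min_hit_score: int  # smallest integer score with p < threshold
    p_threshold: float

    @property
    def width(self) -> int:
        return self.iscores.shape[0]

    def pvalue(self, iscore: int) -> float:
        idx = int(iscore) - self.offset
        if idx < 0:
            return 1.0
        if idx >= len(self.tail):
            return 0.0
        return float(self.tail[idx])


def prepare_pwm(
    motif: Motif,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> PreparedPWM:
    """Integerised log-odds matrix + exact DP null distribution for one PWM."""
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    mat = motif.matrix + pseudocount
    mat = mat / mat.sum(axis=1, keepdims=True)
    lodds = np.log2(mat / background)
    iscores = np.round(lodds * SCORE_SCALE).astype(np.int64)
    lo = int(iscores.min(axis=1).sum())
    hi = int(iscores.max(axis=1).sum())
    # DP convolution of per-column integer score distributions
    dist = np.zeros(hi - lo + 1)
    dist[0] = 1.0
    cur_lo = 0
    for col in range(iscores.shape[0]):
        nxt = np.zeros_like(dist)
        col_min = int(iscores[col].min())
        for b in range(4):
            shift = int(iscores[col, b]) - col_min
            nxt[shift:] += background[b] * dist[: len(dist) - shift if shift else None]
        dist = nxt
        cur_lo += col_min
    assert cur_lo == lo
    tail = np.cumsum(dist[::-1])[::-1]
    below = np.flatnonzero(tail < p_threshold)
    min_hit = int(below[0]) + lo if below.size else hi + 1
    return PreparedPWM(
        motif_id=motif.motif_id,
        iscores=iscores,
        background=background,
        offset=lo,
        tail=tail,
        min_hit_score=min_hit,
        p_threshold=p_threshold,
    )


def encode(seq: str) -> np.ndarray:
    """Sequence to integer codes; ambiguous bases map to 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(codes: np.ndarray, iscores: np.ndarray) -> np.ndarray:
    """Integer score of every window; ambiguous bases contribute 0."""
    w = iscores.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    # column 4 (ambiguous) scores 0 = background log-odds of itself
    padded = np.hstack([iscores, np.zeros((w, 1), dtype=np.int64)])
    total = np.zeros(n, dtype=np.int64)
    for j in range(w):
        total += padded[j, codes[j : j + n]]
    return total


def _revcomp_matrix(iscores: np.ndarray) -> np.ndarray:
    return iscores[::-1, ::-1]


def scan_pwm(seq: str, pwm: PreparedPWM) -> pd.DataFrame:
    """Scan both strands of one sequence; report hits with p < threshold.

    Positions are 0-based offsets of the hit window start on the forward
    sequence, for both strands.
    """
    codes = encode(seq)
    rows = []
    for strand, mat in (("+", pwm.iscores), ("-", _revcomp_matrix(pwm.iscores))):
        scores = _window_scores(codes, mat)
        hit_pos = np.flatnonzero(scores >= pwm.min_hit_score)
        for pos in hit_pos:
            s = int(scores[pos])
            rows.append(
                {
                    "motif_id": pwm.motif_id,
                    "position": int(pos),
                    "strand": strand,
                    "score": s / SCORE_SCALE,
                    "p": pwm.pvalue(s),
                }
            )
    return pd.DataFrame(rows, columns=["motif_id", "position", "strand", "score", "p"])


def scan_promoters(
    promoters: Mapping[str, str],
    motifs: Sequence[Motif],
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Scan every promoter with every motif; returns the pooled hit table.

    The background is the 0-order nucleotide composition of the scanned
    promoter set unless given explicitly.
    """
    if background is None:
        counts = np.zeros(4)
        for seq in promoters.values():
            codes = encode(seq)
            counts += np.bincount(codes[codes < 4], minlength=4)
        background = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    prepared = [prepare_pwm(m, background, pseudocount, p_threshold) for m in motifs]
    mats = [(pwm, pwm.iscores, _revcomp_matrix(pwm.iscores)) for pwm in prepared]
    rows: list[tuple] = []
    for allele_id, seq in promoters.items():
        codes = encode(seq)
        for pwm, fwd, rev in mats:
            for strand, mat in (("+", fwd), ("-", rev)):
                scores = _window_scores(codes, mat)
                for pos in np.flatnonzero(scores >= pwm.min_hit_score):
                    s = int(scores[pos])
                    rows.append(
                        (allele_id, pwm.motif_id, int(pos), strand,
                         s / SCORE_SCALE, pwm.pvalue(s))
                    )
    return pd.DataFrame(
        rows, columns=["allele_id", "motif_id", "position", "strand", "score", "p"]
    )


def promoter_vector(hits: pd.DataFrame, allele_id: str, library: Sequence[Motif]) -> np.ndarray:
    """Binary presence vector over the motif library for one allele."""
    present = set(hits.loc[hits["allele_id"] == allele_id, "motif_id"])
    return np.array([1 if m.motif_id in present else 0 for m in library], dtype=int)


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> tuple[float, bool]:
    """Cosine similarity of two presence vectors.

    Returns (CS, both_zero_flag). Two all-zero vectors denote identical
    absence and score 1 with the flag set.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("vector length mismatch")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 and n2 == 0:
        return 1.0, True
    if n1 == 0 or n2 == 0:
        return 0.0, False
    return float(np.dot(v1, v2) / (n1 * n2)), False


def cs_class(cs: float) -> str:
    """CS classes I-V on 0.2-wide bands (V includes 1.0)."""
    for label, bound in zip(CS_CLASS_LABELS, CS_CLASS_BOUNDS):
        if cs < bound:
            return label
    return "V"


def pair_cosine_table(
    hits: pd.DataFrame,
    pairs: pd.DataFrame,
    library: Sequence[Motif],
) -> pd.DataFrame:
    """Cosine similarity and CS class per allele pair from the pooled hit table."""
    motif_ids = [m.motif_id for m in library]
    presence: dict[str, set] = {}
    for aid, sub in hits.groupby("allele_id"):
        presence[aid] = set(sub["motif_id"])
    rows = []
    for _, row in pairs.iterrows():
        vm = np.array([1 if mid in presence.get(row["maternal_id"], set()) else 0 for mid in motif_ids])
        vp = np.array([1 if mid in presence.get(row["paternal_id"], set()) else 0 for mid in motif_ids])
        cs, flag = cosine_similarity(vm, vp)
        rows.append(
            {
                "pair_id": row.get("pair_id", f"{row['maternal_id']}|{row['paternal_id']}"),
                "maternal_id": row["maternal_id"],
                "paternal_id": row["paternal_id"],
                "cs": cs,
                "cs_class": cs_class(cs),
                "both_absent": flag,
            }
        )
    return pd.DataFrame(rows)


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample Fisher r-to-z comparison of independent correlations."""
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


def class_expression_correlation(
    cs_records: pd.DataFrame,
    expression_maternal: pd.Series,
    expression_paternal: pd.Series,
    group_pairs: set[str] | Sequence[str],
    min_class_n: int = 3,
) -> pd.DataFrame:
    """Per-CS-class Pearson r of maternal vs paternal expression, two groups.

    Group "all" uses every pair; group "selected" the given subset
    (typically phase-dependent ASEGs). Per class the group difference is a
    Fisher r-to-z two-sample test. Classes with < ``min_class_n`` pairs in a
    group are skipped for that comparison.
    """
    group_pairs = set(group_pairs)
    rows = []
    for cls in CS_CLASS_LABELS:
        sub = cs_records[cs_records["cs_class"] == cls]
        res = {}
        for label, frame in (("all", sub), ("selected", sub[sub["pair_id"].isin(group_pairs)])):
            xs = expression_maternal.reindex(frame["maternal_id"]).to_numpy(dtype=float)
            ys = expression_paternal.reindex(frame["paternal_id"]).to_numpy(dtype=float)
            ok = np.isfinite(xs) & np.isfinite(ys)
            xs, ys = xs[ok], ys[ok]
            if len(xs) < min_class_n or np.std(xs) == 0 or np.std(ys) == 0:
                res[label] = (np.nan, len(xs))
            else:
                res[label] = (float(stats.pearsonr(xs, ys)[0]), len(xs))
        r_all, n_all = res["all"]
        r_sel, n_sel = res["selected"]
        if np.isfinite(r_all) and np.isfinite(r_sel) and min(n_all, n_sel) > 3:
            z, p = fisher_r_to_z(r_all, n_all, r_sel, n_sel)
        else:
            z, p = np.nan, np.nan
        rows.append(
            {"cs_class": cls, "r_all": r_all, "n_all": n_all,
             "r_selected": r_sel, "n_selected": n_sel, "z": z, "p": p}
        )
    return pd.DataFrame(rows)


def tfbs_methylation(
    hits: pd.DataFrame,
    promoter_coords: Mapping[str, tuple[str, int]],
    track: pd.DataFrame,
    context: str,
    library: Sequence[Motif],
) -> pd.DataFrame:
    """Weighted methylation level over each hit footprint, per context.

    ``promoter_coords`` maps allele id -> (chromosome, genomic start of the
    promoter window on the forward strand); hit positions are offsets into
    that window. Hits with no covered cytosines are excluded. Pooling uses
    the same interval-count machinery as region methylation levels.
    """
    from .methylome import interval_counts

    if hits.empty:
        return pd.DataFrame(columns=["allele_id", "motif_id", "chrom", "start", "end",
                                     "context", "level", "n_cytosines"])
    widths = {m.motif_id: m.width for m in library}
    rows = []
    for _, h in hits.iterrows():
        if h["allele_id"] not in promoter_coords:
            continue
        chrom, pstart = promoter_coords[h["allele_id"]]
        start = pstart + int(h["position"])
        end = start + widths[h["motif_id"]]
        rows.append((h["allele_id"], h["motif_id"], chrom, start, end))
    frame = pd.DataFrame(rows, columns=["allele_id", "motif_id", "chrom", "start", "end"])
    cnt = interval_counts(track, frame[["chrom", "start", "end"]], context)
    frame["context"] = context
    frame["level"] = cnt["level"].to_numpy()
    frame["n_cytosines"] = cnt["n_cytosines"].to_numpy()
    return frame[frame["n_cytosines"] > 0].reset_index(drop=True)
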