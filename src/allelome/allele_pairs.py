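"""Maternal-paternal allele pairing between two subgenomes.

Three evidence tiers, applied in order on shrinking residual gene sets:

1. synteny  - collinearity chains over c-score-filtered homology anchors;
   anchors unique within a block become pairs;
2. bbh      - bidirectional best hits among the remaining genes;
3. single_copy - reciprocal best hits restricted to remaining genes with
   exactly one hit each (single-copy ortholog fallback).

Homology scoring at desk scale is k-mer-seeded global alignment (shared
8-mers nominate candidate pairs; the similarity score is max sequence length
minus the edit distance). Twelve-column tabular alignment files from an
external aligner are accepted as an alternative input.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEED_K = 8
MIN_SHARED_KMERS = 3


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def score_homology(
    cds_a: Mapping[str, str],
    cds_b: Mapping[str, str],
    k: int = SEED_K,
    min_shared: int = MIN_SHARED_KMERS,
) -> pd.DataFrame:
    """All-vs-all similarity scores between two CDS sets.

    Candidate pairs must share >= ``min_shared`` distinct k-mers; for each
    candidate the similarity score is len(A) + len(B) - 2 * edit distance,
    i.e. 2 * matches - gap count of the optimal global alignment, which is
    positive only for genuinely similar sequences. Returns a frame with
    columns query, subject, score (one row per ordered A->B pair; scores are
    symmetric by construction).
    """
    index: dict[str, list[str]] = {}
    for name, seq in cds_b.items():
        for km in _kmers(seq, k):
            index.setdefault(km, []).append(name)
    rows = []
    for qname, qseq in cds_a.items():
        shared: Counter[str] = Counter()
        for km in _kmers(qseq, k):
            for sname in index.get(km, ()):
                shared[sname] += 1
        for sname, cnt in shared.items():
            if cnt < min_shared:
                continue
            sseq = cds_b[sname]
            d = edlib.align(qseq, sseq, mode="NW", task="distance")["editDistance"]
            score = len(qseq) + len(sseq) - 2 * d
            if score > 0:
                rows.append((qname, sname, float(score)))
    return pd.DataFrame(rows, columns=["query", "subject", "score"])


def read_tabular_hits(path: str | Path) -> pd.DataFrame:
    """Read 12-column tabular alignment output (query, subject, ..., bitscore)."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected 12 columns")
    out = df.iloc[:, [0, 1, 11]].copy()
    out.columns = ["query", "subject", "score"]
    # keep the best-scoring hit per ordered pair
    out = out.sort_values("score").drop_duplicates(["query", "subject"], keep="last")
    return out.reset_index(drop=True)


def cscore_filter(hits: pd.DataFrame, c: float = 0.99) -> pd.DataFrame:
    """Keep hit (A,B) iff score >= c * max(best score of A, best score of B)."""
    if hits.empty:
        return hits.copy()
    best_q = hits.groupby("query")["score"].max()
    best_s = hits.groupby("subject")["score"].max()
    thr = np.maximum(
        best_q.reindex(hits["query"]).to_numpy(),
        best_s.reindex(hits["subject"]).to_numpy(),
    )
    return hits[hits["score"].to_numpy() >= c * thr].reset_index(drop=True)


@dataclasses.dataclass
class SyntenyBlock:
    block_id: int
    chrom_a: str
    chrom_b: str
    orientation: str  # "+" (collinear) or "-" (inverted)
    anchors: list[tuple[str, str]]  # (gene_a, gene_b) in chain order


def _longest_chain(order_a: np.ndarray, order_b: np.ndarray, max_gap: int) -> list[int]:
    """Longest chain of anchors strictly increasing in both orders, gaps <= max_gap.

    Anchors are pre-sorted by order_a. O(n^2) dynamic programme; n is the
    anchor count of one chromosome pair, small at desk scale.
    """
    n = len(order_a)
    best_len = np.ones(n, dtype=int)
    prev = np.full(n, -1)
    for i in range(n):
        for j in range(i):
            if (
                order_a[i] > order_a[j]
                and order_b[i] > order_b[j]
                and order_a[i] - order_a[j] <= max_gap
                and order_b[i] - order_b[j] <= max_gap
                and best_len[j] + 1 > best_len[i]
            ):
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = int(np.argmax(best_len))
    chain = []
    while end != -1:
        chain.append(end)
        end = int(prev[end])
    return chain[::-1]


def chain_synteny(
    anchors: pd.DataFrame, min_block: int = 4, max_gap: int = 20
) -> tuple[list[SyntenyBlock], pd.DataFrame]:
    """Chain anchors into collinear blocks; derive unique within-block pairs.

    ``anchors`` needs columns query, subject, chrom_a, chrom_b, order_a,
    order_b (gene ranks along each chromosome). Both orientations are
    chained; chains are extracted greedily (longest first) per chromosome
    pair until shorter than ``min_block``. Genes appearing more than once
    within a block are dropped from that block's pairs.
    """
    blocks: list[SyntenyBlock] = []
    pair_rows = []
    bid = 0
    for (ca, cb), sub in anchors.groupby(["chrom_a", "chrom_b"], sort=True):
        sub = sub.sort_values(["order_a", "order_b"]).reset_index(drop=True)
        remaining = sub
        while len(remaining) >= min_block:
            oa = remaining["order_a"].to_numpy()
            ob = remaining["order_b"].to_numpy()
            fwd = _longest_chain(oa, ob, max_gap)
            rev = _longest_chain(oa, -ob, max_gap)
            chain, orient = (fwd, "+") if len(fwd) >= len(rev) else (rev, "-")
            if len(chain) < min_block:
                break
            rows = remaining.iloc[chain]
            anchor_list = list(zip(rows["query"], rows["subject"]))
            blocks.append(SyntenyBlock(bid, str(ca), str(cb), orient, anchor_list))
            qc = Counter(q for q, _ in anchor_list)
            sc = Counter(s for _, s in anchor_list)
            for q, s in anchor_list:
                if qc[q] == 1 and sc[s] == 1:
                    pair_rows.append({"maternal_id": q, "paternal_id": s, "block": bid})
            bid += 1
            remaining = remaining.drop(remaining.index[chain]).reset_index(drop=True)
    pairs = pd.DataFrame(pair_rows, columns=["maternal_id", "paternal_id", "block"])
    # a gene may sit in two blocks; keep it only if uniquely paired overall
    pairs = pairs[~pairs["maternal_id"].duplicated(keep=False)]
    pairs = pairs[~pairs["paternal_id"].duplicated(keep=False)]
    return blocks, pairs.reset_index(drop=True)


def bbh(hits: pd.DataFrame) -> pd.DataFrame:
    """Bidirectional best hits; score ties broken by lexicographic subject id."""
    if hits.empty:
        return pd.DataFrame(columns=["maternal_id", "paternal_id"])
    h = hits.sort_values(["score", "subject"], ascending=[False, True], kind="mergesort")
    ties_q = h.groupby("query")["score"].transform("max") == h["score"]
    n_tied = int(h[ties_q].groupby("query").size().gt(1).sum())
    if n_tied:
        logger.warning("bbh: %d queries with tied best scores; lexicographic tie-break", n_tied)
    best_ab = h.drop_duplicates("query").set_index("query")["subject"]
    h2 = hits.sort_values(["score", "query"], ascending=[False, True], kind="mergesort")
    best_ba = h2.drop_duplicates("subject").set_index("subject")["query"]
    rows = [
        {"maternal_id": q, "paternal_id": s}
        for q, s in best_ab.items()
        if best_ba.get(s) == q
    ]
    return pd.DataFrame(rows, columns=["maternal_id", "paternal_id"])


def single_copy_pairs(hits: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal pairs among genes with exactly one hit each."""
    if hits.empty:
        return pd.DataFrame(columns=["maternal_id", "paternal_id"])
    q_counts = hits.groupby("query").size()
    s_counts = hits.groupby("subject").size()
    single = hits[
        hits["query"].map(q_counts).eq(1) & hits["subject"].map(s_counts).eq(1)
    ]
    return single.rename(columns={"query": "maternal_id", "subject": "paternal_id"})[
        ["maternal_id", "paternal_id"]
    ].reset_index(drop=True)


def merge_allele_pairs(
    synteny_pairs: pd.DataFrame,
    bbh_pairs: pd.DataFrame,
    sco_pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Combine evidence tiers with precedence synteny > bbh > single_copy.

    Inputs are expected to come from residual gene sets (each tier computed
    after removing genes paired by earlier tiers); a conflicting assignment
    therefore indicates an internal error and raises.
    """
    out = []
    used_m: set[str] = set()
    used_p: set[str] = set()
    for evidence, frame in (
        ("synteny", synteny_pairs),
        ("bbh", bbh_pairs),
        ("single_copy", sco_pairs),
    ):
        for _, row in frame.iterrows():
            m, p = row["maternal_id"], row["paternal_id"]
            if m in used_m or p in used_p:
                raise RuntimeError(
                    f"conflicting assignment for ({m}, {p}); tiers must use residual sets"
                )
            used_m.add(m)
            used_p.add(p)
            out.append(
                {
                    "maternal_id": m,
                    "paternal_id": p,
                    "evidence": evidence,
                    "block": row.get("block", -1) if evidence == "synteny" else -1,
                }
            )
    return pd.DataFrame(out, columns=["maternal_id", "paternal_id", "evidence", "block"])


def pair_alleles(
    cds_maternal: Mapping[str, str],
    cds_paternal: Mapping[str, str],
    gene_order_maternal: Mapping[str, tuple[str, int]],
    gene_order_paternal: Mapping[str, tuple[str, int]],
    c: float = 0.99,
    min_block: int = 4,
    max_gap: int = 20,
) -> pd.DataFrame:
    """Full pairing pipeline: score -> c-score anchors -> synteny -> BBH -> SCO.

    ``gene_order_*`` map gene id -> (chromosome, rank along chromosome).
    """
    hits = score_homology(cds_maternal, cds_paternal)
    anchors = cscore_filter(hits, c=c)
    if not anchors.empty:
        anchors = anchors.assign(
            chrom_a=[gene_order_maternal[g][0] for g in anchors["query"]],
            order_a=[gene_order_maternal[g][1] for g in anchors["query"]],
            chrom_b=[gene_order_paternal[g][0] for g in anchors["subject"]],
            order_b=[gene_order_paternal[g][1] for g in anchors["subject"]],
        )
        _, syn_pairs = chain_synteny(anchors, min_block=min_block, max_gap=max_gap)
    else:
        syn_pairs = pd.DataFrame(columns=["maternal_id", "paternal_id", "block"])
    paired_m = set(syn_pairs["maternal_id"])
    paired_p = set(syn_pairs["paternal_id"])
    residual = hits[~hits["query"].isin(paired_m) & ~hits["subject"].isin(paired_p)]
    bbh_pairs = bbh(residual)
    paired_m |= set(bbh_pairs["maternal_id"])
    paired_p |= set(bbh_pairs["paternal_id"])
    residual2 = hits[~hits["query"].isin(paired_m) & ~hits["subject"].isin(paired_p)]
    sco = single_copy_pairs(residual2)
    return merge_allele_pairs(syn_pairs, bbh_pairs, sco)
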