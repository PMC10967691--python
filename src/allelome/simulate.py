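"""Synthetic two-subgenome hybrid with ground truth for every pipeline stage.

The generator emulates the study system this pipeline targets: an
inter-species hybrid with a maternal and a paternal subgenome, diverged
allele pairs laid out collinearly (with a configurable relocated fraction),
TE-rich intergenic space, phase-structured methylomes sampled as replicate
bisulfite counts at ~30x coverage, negative-binomially distributed
allele-resolved expression counts with configurable phase-dependent bias,
and promoters whose motif content diverges more for designated
phase-dependent allele-biased genes.

All randomness flows from ``SimConfig.seed`` through per-stage child
streams, so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CONTEXTS,
    EXPRESSION_PHASES,
    METHYLOME_PHASES,
    GeneModel,
    GenomeBundle,
    Motif,
)

TE_CLASSES = ("LTR", "LINE", "SINE", "DNA")

# rng stream tags per stage
_STAGE_GENOME = 1
_STAGE_METHYLOME = 2
_STAGE_EXPRESSION = 3
_STAGE_MOTIF = 4
_STAGE_PAIR_PROFILE = 5
_STAGE_DMR_WINDOW = 6

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_phase_factors() -> dict[str, dict[str, float]]:
    # global hypomethylation at induction (stronger for direct induction),
    # with the CHH context dipping then recovering past baseline
    cg = {"LE": 1.0, "DP1": 0.8333, "DP2": 0.90, "IP1": 0.9086, "IP2": 0.93, "IP3": 0.95}
    chh = {"LE": 1.0, "DP1": 0.72, "DP2": 0.88, "IP1": 0.80, "IP2": 0.97, "IP3": 1.06}
    return {"CG": dict(cg), "CHG": dict(cg), "CHH": chh}


@dataclasses.dataclass
class SimConfig:
    """Generator configuration; defaults define the standard study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    n_gene_pairs: int = 500
    gene_length_log_mean: float = 7.2  # lognormal body length, ~1340 bp median
    gene_length_log_sd: float = 0.35
    gene_length_min: int = 400
    gene_length_max: int = 6000
    promoter_length: int = 2000
    intergenic_gap_min: int = 4200  # leaves room for both 2-kb flanks
    intergenic_gap_max: int = 5400
    snp_rate: float = 0.01
    relocation_fraction: float = 0.1
    te_density: float = 0.4  # fraction of placeable intergenic bp covered by TEs
    te_class_weights: tuple[float, ...] = (0.4, 0.25, 0.15, 0.2)  # LTR, LINE, SINE, DNA
    # methylation model
    context_meth_fraction: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"CG": 0.45, "CHG": 0.30, "CHH": 0.08}
    )
    beta_high: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {"CG": (8.0, 1.5), "CHG": (4.0, 2.5), "CHH": (1.5, 5.0)}
    )
    beta_low: tuple[float, float] = (0.3, 15.0)
    feature_scale: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {
            "CG": {"gene_body": 0.8, "promoter": 0.3, "intergenic": 1.0},
            "CHG": {"gene_body": 0.5, "promoter": 0.3, "intergenic": 1.0},
            "CHH": {"gene_body": 0.6, "promoter": 0.6, "intergenic": 1.0},
        }
    )
    silent_fraction: float = 0.08  # non-expressed genes, hypermethylated
    silent_meth_factor: float = 1.8
    te_elevation: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"LTR": 1.5, "LINE": 1.45, "SINE": 1.8, "DNA": 1.35}
    )
    phase_factors: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=_default_phase_factors
    )
    coverage_mean: float = 30.0
    non_conversion: float = 0.005
    replicate_concentration: float = 150.0  # beta-binomial replicate jitter
    n_meth_replicates: int = 3
    # DMR truth
    n_dmr_per_context: int = 100
    dmr_offset: float = 0.4
    dmr_hypo_fraction: float = 0.7
    genic_dmr_fraction: float = 0.5  # windows placed inside gene units (both alleles)
    # expression model
    expr_log_mean: float = 4.2
    expr_log_sd: float = 1.1
    nb_dispersion: float = 0.05
    n_expr_replicates: int = 3
    depth_factor_range: tuple[float, float] = (0.75, 1.3)
    phase_effect_sd: float = 0.25  # per-gene lognormal phase wobble
    aseg_fraction: float = 0.15
    aseg_lfc_min: float = 1.5
    aseg_lfc_max: float = 3.0
    phase_dependent_fraction: float = 0.05
    # allele-specific methylation truth
    asmg_fraction: float = 0.2
    asmr_offset: float = 0.4
    asmr_flip_count: int = 0
    # promoter motif model
    n_motifs: int = 24
    motif_presence_prob: float = 0.35
    motif_flip_prob: float = 0.05
    motif_flip_prob_aseg: float = 0.35

    def __post_init__(self) -> None:
        for name in (
            "snp_rate", "relocation_fraction", "te_density", "aseg_fraction",
            "phase_dependent_fraction", "asmg_fraction", "motif_presence_prob",
            "motif_flip_prob", "motif_flip_prob_aseg", "dmr_hypo_fraction",
            "silent_fraction", "genic_dmr_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.promoter_length != 2000:
            raise ValueError("promoter_length is fixed at 2000 bp")
        if self.n_meth_replicates < 2 or self.n_expr_replicates < 2:
            raise ValueError("need >= 2 replicates per phase")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])

    @classmethod
    def null(cls, **overrides) -> "SimConfig":
        """Configuration with every differential effect switched off."""
        flat = {ctx: {ph: 1.0 for ph in METHYLOME_PHASES} for ctx in CONTEXTS}
        defaults = dict(
            phase_factors=flat,
            n_dmr_per_context=0,
            aseg_fraction=0.0,
            phase_dependent_fraction=0.0,
            asmg_fraction=0.0,
            motif_flip_prob=0.0,
            motif_flip_prob_aseg=0.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# Genomes and allele-pair truth
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    if rate <= 0:
        return out
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size:
        # substitute with a different base: shift by 1..3 in base order
        lut = np.zeros(256, dtype=np.int64)
        lut[[65, 67, 71, 84]] = [0, 1, 2, 3]
        cur = lut[out[hits]]
        new = (cur + rng.integers(1, 4, size=hits.size)) % 4
        out[hits] = _BASES[new]
    return out


def simulate_genomes(config: SimConfig) -> tuple[GenomeBundle, pd.DataFrame]:
    """Build the two subgenomes and the per-pair ground-truth table.

    Gene pairs are placed collinearly on homologous chromosomes except a
    configurable relocated fraction; paternal gene sequences are maternal
    copies diverged at the SNP rate; TEs fill the placeable intergenic
    space. Returns (bundle, truth) where truth carries pairing plus all
    downstream designations (ASEG/phase-dependent/ASMG/motif groups).
    """
    rng = config.rng(_STAGE_GENOME)
    n = config.n_gene_pairs
    n_chrom = config.n_chromosomes

    lengths = np.exp(
        rng.normal(config.gene_length_log_mean, config.gene_length_log_sd, size=n)
    ).astype(int)
    lengths = np.clip(lengths, config.gene_length_min, config.gene_length_max)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    two_exon = rng.random(n) < 0.5
    # maternal layout: pairs round-robin across chromosomes, in order
    chrom_of = np.arange(n) % n_chrom
    order_m = [np.flatnonzero(chrom_of == c) for c in range(n_chrom)]
    # paternal layout: same, then relocate a fraction to random new slots
    n_reloc = int(round(config.relocation_fraction * n))
    reloc = rng.choice(n, size=n_reloc, replace=False) if n_reloc else np.array([], dtype=int)
    reloc_set = set(int(i) for i in reloc)
    order_p = [[int(i) for i in arr if int(i) not in reloc_set] for arr in order_m]
    for i in reloc:
        c = int(rng.integers(0, n_chrom))
        pos = int(rng.integers(0, len(order_p[c]) + 1))
        order_p[c].insert(pos, int(i))

    body_m = [ _random_seq(rng, int(L)) for L in lengths ]
    body_p = [ _mutate(rng, b, config.snp_rate) for b in body_m ]
    prom_m = [ _random_seq(rng, config.promoter_length) for _ in range(n) ]
    prom_p = [ _mutate(rng, p, config.snp_rate) for p in prom_m ]
    # the flank opposite the promoter is pair-shared too, so the whole
    # 80-bin footprint of a pair is homologous sequence
    dflank_m = [ _random_seq(rng, config.promoter_length) for _ in range(n) ]
    dflank_p = [ _mutate(rng, d, config.snp_rate) for d in dflank_m ]

    def build(subg: str, prefix: str, orders, bodies, proms, dflanks):
        sequences, genes, te_rows = {}, [], []
        gene_meta = {}
        for c, idxs in enumerate(orders):
            chrom = f"{prefix}{c + 1}"
            parts: list[np.ndarray] = []
            pos = 0
            for rank, i in enumerate(idxs):
                gap = int(rng.integers(config.intergenic_gap_min, config.intergenic_gap_max + 1))
                gap_seq = _random_seq(rng, gap)
                # TEs occupy the middle of the gap, clear of both 2-kb flanks
                lo, hi = 2100, gap - 2100
                cursor = lo
                while hi - cursor > 150 and rng.random() < config.te_density:
                    cls = TE_CLASSES[
                        rng.choice(len(TE_CLASSES), p=np.asarray(config.te_class_weights) /
                                   np.sum(config.te_class_weights))
                    ]
                    te_len = {
                        "LTR": rng.integers(1500, 5000),
                        "LINE": rng.integers(800, 3000),
                        "SINE": rng.integers(150, 400),
                        "DNA": rng.integers(300, 1500),
                    }[cls]
                    te_len = int(min(te_len, hi - cursor))
                    if te_len < 150:
                        break
                    te_rows.append((chrom, pos + cursor, pos + cursor + te_len, cls))
                    cursor += te_len + int(rng.integers(50, 200))
                parts.append(gap_seq)
                pos += gap
                body = bodies[i]
                start, end = pos, pos + len(body)
                strand = strands[i]
                gid = f"{subg}_{chrom}g{i:05d}"
                if two_exon[i]:
                    mid = (end - start) // 2
                    intron = max((end - start) // 10, 1)
                    half = max((mid - intron // 2), 1)
                    exons = [(start, start + half), (start + half + intron, end)]
                    if exons[1][0] >= exons[1][1]:
                        exons = [(start, end)]
                else:
                    exons = [(start, end)]
                genes.append(GeneModel(gid, chrom, start, end, strand, exons))
                gene_meta[i] = (gid, chrom, rank)
                parts.append(body)
                pos = end
            tail = int(rng.integers(config.intergenic_gap_min, config.intergenic_gap_max + 1))
            tail_seq = _random_seq(rng, tail)
            parts.append(tail_seq)
            pos += tail
            # write the pair-shared flank sequences around each gene:
            # promoter on the transcribed-upstream side, shared flank opposite
            seq = np.concatenate(parts)
            pl = config.promoter_length
            for g_i in idxs:
                gid, gchrom, _ = gene_meta[g_i]
                if gchrom != chrom:
                    continue
                gm = next(g for g in genes if g.gene_id == gid)
                if strands[g_i] == "+":
                    seq[gm.start - pl : gm.start] = proms[g_i]
                    seq[gm.end : gm.end + pl] = dflanks[g_i]
                else:
                    seq[gm.end : gm.end + pl] = proms[g_i]
                    seq[gm.start - pl : gm.start] = dflanks[g_i]
            sequences[chrom] = seq.tobytes().decode()
            for g in genes:
                if g.chrom == chrom and g.end > len(seq):
                    raise ValueError("infeasible packing: gene exceeds chromosome")
        tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "name"])
        tes["score"] = 0
        tes["strand"] = "+"
        return sequences, genes, tes, gene_meta

    seq_m, genes_m, tes_m, meta_m = build("alb", "A", order_m, body_m, prom_m, dflank_m)
    seq_p, genes_p, tes_p, meta_p = build("gla", "G", order_p, body_p, prom_p, dflank_p)

    bundle = GenomeBundle(
        sequences={"alb": seq_m, "gla": seq_p},
        genes={"alb": genes_m, "gla": genes_p},
        tes={"alb": tes_m, "gla": tes_p},
        parent_of={"alb": "maternal", "gla": "paternal"},
    )

    # truth designations
    gm_index = bundle.gene_index("alb")
    is_silent = rng.random(n) < config.silent_fraction
    is_aseg = (rng.random(n) < config.aseg_fraction) & ~is_silent
    is_pd = (rng.random(n) < config.phase_dependent_fraction) & ~is_silent
    is_aseg |= is_pd  # phase-dependent genes are allele-biased by definition
    lfc = rng.uniform(config.aseg_lfc_min, config.aseg_lfc_max, size=n)
    lfc *= np.where(rng.random(n) < 0.5, 1.0, -1.0)
    lfc[~is_aseg] = 0.0
    pd_kind = np.where(rng.random(n) < 0.5, "appear", "flip")
    pd_kind = np.where(is_pd, pd_kind, "none")
    is_asmg = rng.random(n) < config.asmg_fraction
    asmg_ctx = rng.choice(CONTEXTS, size=n)
    asmg_dir = np.where(rng.random(n) < 0.5, 1, -1)
    flip_idx = set()
    if config.asmr_flip_count:
        cands = np.flatnonzero(is_asmg)
        take = min(config.asmr_flip_count, cands.size)
        flip_idx = set(int(i) for i in rng.choice(cands, size=take, replace=False))

    rows = []
    for i in range(n):
        gid_m = meta_m[i][0]
        gid_p = meta_p[i][0]
        rows.append(
            {
                "pair_id": f"pair{i:05d}",
                "maternal_id": gid_m,
                "paternal_id": gid_p,
                "chrom_m": meta_m[i][1],
                "chrom_p": meta_p[i][1],
                "strand": strands[i],
                "length": gm_index[gid_m].length,
                "relocated": i in reloc_set,
                "is_silent": bool(is_silent[i]),
                "is_aseg": bool(is_aseg[i]),
                "lfc_base": float(lfc[i]),
                "is_phase_dependent": bool(is_pd[i]),
                "pd_kind": pd_kind[i],
                "is_asmg": bool(is_asmg[i]),
                "asmg_context": asmg_ctx[i] if is_asmg[i] else "",
                "asmg_direction": int(asmg_dir[i]) if is_asmg[i] else 0,
                "asmr_flips": i in flip_idx,
            }
        )
    truth = pd.DataFrame(rows)
    return bundle, truth


def promoter_windows(bundle: GenomeBundle, subgenome: str, length: int = 2000) -> dict[str, tuple[str, int]]:
    """Allele id -> (chrom, forward-strand genomic start) of the 2-kb promoter."""
    out = {}
    for g in bundle.genes[subgenome]:
        if g.strand == "+":
            out[g.gene_id] = (g.chrom, g.start - length)
        else:
            out[g.gene_id] = (g.chrom, g.end)
    return out


def promoter_sequences(bundle: GenomeBundle, subgenome: str, length: int = 2000) -> dict[str, str]:
    """Forward-strand promoter window sequences per allele."""
    seqs = bundle.sequences[subgenome]
    out = {}
    for gid, (chrom, start) in promoter_windows(bundle, subgenome, length).items():
        out[gid] = seqs[chrom][max(start, 0) : start + length]
    return out


# ---------------------------------------------------------------------------
# Methylomes
# ---------------------------------------------------------------------------

_FEAT_INTERGENIC = 0
_FEAT_PROMOTER = 1
_FEAT_GENE_BODY = 2
_FEAT_TE = {cls: 3 + i for i, cls in enumerate(TE_CLASSES)}


def _feature_codes(bundle: GenomeBundle, subgenome: str, chrom: str, promoter: int) -> np.ndarray:
    size = len(bundle.sequences[subgenome][chrom])
    codes = np.zeros(size, dtype=np.int8)
    tes = bundle.tes[subgenome]
    for _, row in tes[tes["chrom"] == chrom].iterrows():
        codes[int(row["start"]) : int(row["end"])] = _FEAT_TE[row["name"]]
    for g in bundle.genes[subgenome]:
        if g.chrom != chrom:
            continue
        if g.strand == "+":
            codes[max(g.start - promoter, 0) : g.start] = _FEAT_PROMOTER
        else:
            codes[g.end : g.end + promoter] = _FEAT_PROMOTER
        codes[g.start : g.end] = _FEAT_GENE_BODY
    return codes


def _cytosine_sites(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions, strands (+ = C, - = G) and context codes for one chromosome.

    Context codes: 0 = CG, 1 = CHG, 2 = CHH. Sites within 2 bp of either end
    are skipped so the trinucleotide is always defined.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    c = ord("C")
    g = ord("G")
    pos_c = np.flatnonzero(arr == c)
    pos_c = pos_c[(pos_c >= 2) & (pos_c < len(arr) - 2)]
    nxt1 = arr[pos_c + 1]
    nxt2 = arr[pos_c + 2]
    ctx_c = np.where(nxt1 == g, 0, np.where(nxt2 == g, 1, 2))
    pos_g = np.flatnonzero(arr == g)
    pos_g = pos_g[(pos_g >= 2) & (pos_g < len(arr) - 2)]
    prv1 = arr[pos_g - 1]
    prv2 = arr[pos_g - 2]
    ctx_g = np.where(prv1 == c, 0, np.where(prv2 == c, 1, 2))
    pos = np.concatenate([pos_c, pos_g])
    strand = np.concatenate([np.zeros(len(pos_c), dtype=np.int8), np.ones(len(pos_g), dtype=np.int8)])
    ctx = np.concatenate([ctx_c, ctx_g]).astype(np.int8)
    order = np.argsort(pos, kind="mergesort")
    return pos[order], strand[order], ctx[order]


def _pick_dmr_windows(
    bundle: GenomeBundle,
    config: SimConfig,
    rng: np.random.Generator,
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Designate true-DMR windows of two kinds.

    Intergenic windows are drawn per subgenome in TE/intergenic space, clear
    of gene units (so the allele-methylation truth stays orthogonal). Genic
    windows are drawn per allele pair at a shared offset within the pair's
    80-bin footprint and applied to both subgenomes at homologous positions,
    so they make promoter/gene-body DMRs without inducing allelic bias.
    """
    rows = []
    window_id = 0
    n_genic = int(round(config.n_dmr_per_context * config.genic_dmr_fraction))
    n_intergenic = config.n_dmr_per_context - n_genic
    # genic windows: pairs not carrying an allele-methylation designation
    if truth is not None and len(truth) and n_genic:
        gm = bundle.gene_index("alb")
        gp = bundle.gene_index("gla")
        eligible = truth[~truth["is_asmg"]].reset_index(drop=True)
        for ctx in CONTEXTS:
            used: dict[str, set] = {}
            placed = attempts = 0
            while placed < n_genic and attempts < n_genic * 100 and len(eligible):
                attempts += 1
                row = eligible.iloc[int(rng.integers(0, len(eligible)))]
                m = gm[row["maternal_id"]]
                p = gp[row["paternal_id"]]
                region_len = (m.end - m.start) + 2 * config.promoter_length
                if region_len < 400:
                    continue
                off = int(rng.integers(0, region_len - 200))
                key = row["pair_id"]
                taken = used.setdefault(key, set())
                if any(abs(off - o) < 200 for o in taken):
                    continue
                taken.add(off)
                direction = -1 if rng.random() < config.dmr_hypo_fraction else 1
                for subg, g in (("alb", m), ("gla", p)):
                    a0 = g.start - config.promoter_length + off
                    rows.append(
                        {"window_id": window_id, "subgenome": subg, "chrom": g.chrom,
                         "start": a0, "end": a0 + 200, "context": ctx,
                         "direction": direction, "kind": "genic",
                         "pair_id": row["pair_id"]}
                    )
                window_id += 1
                placed += 1
    for subg in bundle.sequences:
        sizes = bundle.chrom_sizes(subg)
        chroms = list(sizes)
        # keep truth windows clear of gene units so the DMR and allele-level
        # methylation truths stay orthogonal
        forbidden = {c: [] for c in chroms}
        for g in bundle.genes[subg]:
            forbidden[g.chrom].append((g.start - 2100, g.end + 2100))
        fb = {
            c: (np.array([iv[0] for iv in sorted(v)]), np.array([iv[1] for iv in sorted(v)]))
            for c, v in forbidden.items()
        }
        for ctx in CONTEXTS:
            used_pos: dict[str, set[int]] = {c: set() for c in chroms}
            placed = 0
            attempts = 0
            while placed < n_intergenic and attempts < max(n_intergenic, 1) * 200:
                attempts += 1
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                start = int(rng.integers(0, max(sizes[chrom] // 100 - 2, 1))) * 100
                if any(s in used_pos[chrom] for s in (start - 100, start, start + 100)):
                    continue
                fs, fe = fb[chrom]
                if fs.size:
                    j = np.searchsorted(fe, start, side="right")
                    if j < fs.size and fs[j] < start + 200:
                        continue
                used_pos[chrom].add(start)
                direction = -1 if rng.random() < config.dmr_hypo_fraction else 1
                rows.append(
                    {"window_id": window_id, "subgenome": subg, "chrom": chrom,
                     "start": start, "end": start + 200, "context": ctx,
                     "direction": direction, "kind": "intergenic", "pair_id": ""}
                )
                window_id += 1
                placed += 1
    return pd.DataFrame(
        rows,
        columns=["window_id", "subgenome", "chrom", "start", "end", "context",
                 "direction", "kind", "pair_id"],
    )


def _asmr_truth_regions(bundle: GenomeBundle, truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Maternal-allele regions (promoter + body) carrying the allele offset."""
    gm = bundle.gene_index("alb")
    rows = []
    for _, row in truth[truth["is_asmg"]].iterrows():
        g = gm[row["maternal_id"]]
        if g.strand == "+":
            start, end = g.start - config.promoter_length, g.end
        else:
            start, end = g.start, g.end + config.promoter_length
        rows.append(
            {
                "pair_id": row["pair_id"],
                "maternal_id": row["maternal_id"],
                "chrom": g.chrom,
                "start": max(start, 0),
                "end": end,
                "context": row["asmg_context"],
                "direction": int(row["asmg_direction"]),
                "flips": bool(row["asmr_flips"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "maternal_id", "chrom", "start", "end", "context",
                 "direction", "flips"],
    )


#: phases at which an engineered ASMR direction flip is active
_FLIP_PHASES = frozenset({"IP2", "IP3"})


def simulate_methylomes(
    bundle: GenomeBundle,
    config: SimConfig,
    truth: pd.DataFrame | None = None,
    phases: Sequence[str] = METHYLOME_PHASES,
) -> tuple[dict[tuple[str, int], pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Replicate cytosine tracks per phase, plus DMR and ASMR truth tables.

    Per-site true methylation = Beta-mixture baseline by context and feature
    x phase factor, plus additive offsets inside designated DMR windows
    (phases other than the explant baseline) and inside maternal alleles of
    designated ASMG pairs. Observed counts: coverage ~ Poisson(mean),
    methylated ~ Binomial(coverage, p'), with p' = p_rep + (1 - p_rep) * eps
    for non-conversion eps and beta-distributed replicate jitter p_rep.
    """
    for ph in phases:
        if ph not in METHYLOME_PHASES:
            raise ValueError(f"unknown methylome phase {ph!r}")
    rng = config.rng(_STAGE_METHYLOME)
    dmr_truth = _pick_dmr_windows(bundle, config, rng, truth)
    asmr_truth = (
        _asmr_truth_regions(bundle, truth, config)
        if truth is not None
        else pd.DataFrame(columns=["pair_id", "maternal_id", "chrom", "start", "end",
                                   "context", "direction", "flips"])
    )

    ctx_codes = {"CG": 0, "CHG": 1, "CHH": 2}
    tracks: dict[tuple[str, int], list[pd.DataFrame]] = {
        (ph, r): [] for ph in phases for r in range(1, config.n_meth_replicates + 1)
    }
    for subg in bundle.sequences:
        for chrom, seq in bundle.sequences[subg].items():
            pos, strand, ctx = _cytosine_sites(seq)
            feats = _feature_codes(bundle, subg, chrom, config.promoter_length)[pos]
            n_sites = len(pos)
            base_p = np.empty(n_sites, dtype=np.float64)
            for cname, ccode in ctx_codes.items():
                mask = ctx == ccode
                f = np.full(mask.sum(), config.context_meth_fraction[cname])
                sub_feats = feats[mask]
                for feat_name, code in (
                    ("promoter", _FEAT_PROMOTER), ("gene_body", _FEAT_GENE_BODY)
                ):
                    f[sub_feats == code] *= config.feature_scale[cname][feat_name]
                for te_cls, code in _FEAT_TE.items():
                    f[sub_feats == code] *= config.te_elevation[te_cls]
                f = np.clip(f, 0.0, 0.95)
                hi_a, hi_b = config.beta_high[cname]
                lo_a, lo_b = config.beta_low
                is_meth = rng.random(mask.sum()) < f
                p = np.where(
                    is_meth,
                    rng.beta(hi_a, hi_b, size=mask.sum()),
                    rng.beta(lo_a, lo_b, size=mask.sum()),
                )
                base_p[mask] = p

            # Pair-shared latent profiles over gene units: both alleles of a
            # pair read the same per-offset random field, so their true
            # methylomes agree over promoters and bodies except where an
            # allele offset is designated or a SNP changed the context.
            if truth is not None and len(truth):
                from scipy.stats import beta as beta_dist

                id_col = (
                    "maternal_id" if bundle.parent_of[subg] == "maternal" else "paternal_id"
                )
                pair_info = {
                    row[id_col]: (pi, bool(row.get("is_silent", False)))
                    for pi, row in truth.iterrows()
                }
                f0 = np.array([config.context_meth_fraction[c] for c in CONTEXTS])
                scale_prom = np.array([config.feature_scale[c]["promoter"] for c in CONTEXTS])
                scale_body = np.array([config.feature_scale[c]["gene_body"] for c in CONTEXTS])
                a_hi = np.array([config.beta_high[c][0] for c in CONTEXTS])
                b_hi = np.array([config.beta_high[c][1] for c in CONTEXTS])
                lo_a, lo_b = config.beta_low
                for g in bundle.genes[subg]:
                    if g.chrom != chrom or g.gene_id not in pair_info:
                        continue
                    pi, silent = pair_info[g.gene_id]
                    # cover the whole 80-bin footprint: both 2-kb flanks + body
                    a0 = g.start - config.promoter_length
                    b0 = g.end + config.promoter_length
                    lo_i = int(np.searchsorted(pos, a0))
                    hi_i = int(np.searchsorted(pos, b0))
                    if hi_i <= lo_i:
                        continue
                    offs = pos[lo_i:hi_i] - a0
                    cx = ctx[lo_i:hi_i]
                    ft = feats[lo_i:hi_i]
                    u = np.random.default_rng(
                        [int(config.seed), _STAGE_PAIR_PROFILE, int(pi)]
                    ).random((2, b0 - a0))
                    u_class = u[0][offs]
                    u_lvl = u[1][offs]
                    scale = np.where(
                        ft == _FEAT_PROMOTER, scale_prom[cx],
                        np.where(ft == _FEAT_GENE_BODY, scale_body[cx], 1.0),
                    )
                    f = f0[cx] * scale
                    if silent:
                        f = f * config.silent_meth_factor
                    f = np.clip(f, 0.0, 0.95)
                    p_hi = beta_dist.ppf(u_lvl, a_hi[cx], b_hi[cx])
                    p_lo = beta_dist.ppf(u_lvl, lo_a, lo_b)
                    base_p[lo_i:hi_i] = np.where(u_class < f, p_hi, p_lo)

            # site membership in DMR truth windows of this chrom/subgenome;
            # window baselines are redrawn inside a range compatible with the
            # additive offset, so the configured offset is realised unclipped
            dmr_delta = np.zeros(n_sites, dtype=np.float64)
            dsub = dmr_truth[(dmr_truth["subgenome"] == subg) & (dmr_truth["chrom"] == chrom)]
            for _, w in dsub.iterrows():
                mask = (pos >= w["start"]) & (pos < w["end"]) & (ctx == ctx_codes[w["context"]])
                dmr_delta[mask] = w["direction"] * config.dmr_offset
                if w["direction"] > 0:
                    lo_r, hi_r = 0.05, max(0.9 - config.dmr_offset, 0.06)
                else:
                    lo_r, hi_r = min(0.1 + config.dmr_offset, 0.94), 0.95
                if w.get("kind", "intergenic") == "genic":
                    # both alleles read the same per-offset uniforms so the
                    # window stays allele-balanced
                    u = np.random.default_rng(
                        [int(config.seed), _STAGE_DMR_WINDOW, int(w["window_id"])]
                    ).random(int(w["end"]) - int(w["start"]))
                    base_p[mask] = lo_r + (hi_r - lo_r) * u[pos[mask] - int(w["start"])]
                else:
                    base_p[mask] = rng.uniform(lo_r, hi_r, int(mask.sum()))
            asmr_delta = np.zeros(n_sites, dtype=np.float64)
            asmr_flip_mask = np.zeros(n_sites, dtype=bool)
            if subg == "alb" and len(asmr_truth):
                asub = asmr_truth[asmr_truth["chrom"] == chrom]
                for _, w in asub.iterrows():
                    mask = (pos >= w["start"]) & (pos < w["end"]) & (ctx == ctx_codes[w["context"]])
                    asmr_delta[mask] = w["direction"] * config.asmr_offset
                    if w["flips"]:
                        asmr_flip_mask |= mask

            for ph in phases:
                factor = np.empty(n_sites)
                for cname, ccode in ctx_codes.items():
                    factor[ctx == ccode] = config.phase_factors[cname][ph]
                p_phase = base_p * factor
                if ph != "LE":
                    p_phase = p_phase + dmr_delta
                flip_sign = np.where(asmr_flip_mask & (ph in _FLIP_PHASES), -1.0, 1.0)
                p_phase = p_phase + asmr_delta * flip_sign
                p_phase = np.clip(p_phase, 1e-4, 1 - 1e-4)
                kappa = config.replicate_concentration
                for r in range(1, config.n_meth_replicates + 1):
                    p_rep = rng.beta(p_phase * kappa, (1 - p_phase) * kappa)
                    cov = rng.poisson(config.coverage_mean, size=n_sites)
                    p_obs = p_rep + (1 - p_rep) * config.non_conversion
                    mc = rng.binomial(cov, p_obs)
                    frame = pd.DataFrame(
                        {
                            "chrom": pd.Categorical([chrom] * n_sites),
                            "pos0": pos.astype(np.int32),
                            "strand": pd.Categorical.from_codes(
                                strand, categories=["+", "-"]
                            ),
                            "context": pd.Categorical.from_codes(
                                ctx, categories=list(CONTEXTS)
                            ),
                            "mc": mc.astype(np.int32),
                            "uc": (cov - mc).astype(np.int32),
                        }
                    )
                    tracks[(ph, r)].append(frame)
    merged = {
        key: pd.concat(parts, ignore_index=True).astype({"chrom": "category"})
        for key, parts in tracks.items()
    }
    return merged, dmr_truth, asmr_truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def true_lfc_table(truth: pd.DataFrame, phases: Sequence[str] = EXPRESSION_PHASES) -> pd.DataFrame:
    """Per-pair, per-phase true allelic log2 fold change (maternal/paternal)."""
    rows = []
    for _, row in truth.iterrows():
        for ph in phases:
            lfc = row["lfc_base"]
            if row["is_phase_dependent"]:
                if row["pd_kind"] == "appear":
                    lfc = 0.0 if ph == "LE" else row["lfc_base"]
                else:  # flip: bias reverses after the explant phase
                    lfc = row["lfc_base"] if ph == "LE" else -row["lfc_base"]
            rows.append({"pair_id": row["pair_id"], "phase": ph, "true_lfc": float(lfc)})
    return pd.DataFrame(rows)


def simulate_expression(
    config: SimConfig,
    truth: pd.DataFrame | None = None,
    phases: Sequence[str] = EXPRESSION_PHASES,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Allele-resolved NB counts per phase/replicate plus ASEG truth.

    Without a genome-derived truth table, a free-standing pair set of size
    ``config.n_gene_pairs`` is designated from the configured fractions.
    Returns (maternal counts, paternal counts, sample sheet, per-phase truth).
    """
    rng = config.rng(_STAGE_EXPRESSION)
    n = config.n_gene_pairs if truth is None else len(truth)
    if truth is None:
        is_silent = rng.random(n) < config.silent_fraction
        is_aseg = (rng.random(n) < config.aseg_fraction) & ~is_silent
        is_pd = (rng.random(n) < config.phase_dependent_fraction) & ~is_silent
        is_aseg |= is_pd
        lfc = rng.uniform(config.aseg_lfc_min, config.aseg_lfc_max, size=n)
        lfc *= np.where(rng.random(n) < 0.5, 1.0, -1.0)
        lfc[~is_aseg] = 0.0
        pd_kind = np.where(rng.random(n) < 0.5, "appear", "flip")
        truth = pd.DataFrame(
            {
                "pair_id": [f"pair{i:05d}" for i in range(n)],
                "maternal_id": [f"alb_g{i:05d}" for i in range(n)],
                "paternal_id": [f"gla_g{i:05d}" for i in range(n)],
                "length": np.full(n, 1500),
                "is_silent": is_silent,
                "is_aseg": is_aseg,
                "lfc_base": lfc,
                "is_phase_dependent": is_pd,
                "pd_kind": np.where(is_pd, pd_kind, "none"),
            }
        )
    lfc_truth = true_lfc_table(truth, phases)
    lfc_map = lfc_truth.set_index(["pair_id", "phase"])["true_lfc"]

    mu = np.exp(rng.normal(config.expr_log_mean, config.expr_log_sd, size=n))
    if "is_silent" in truth.columns:
        mu = np.where(truth["is_silent"].to_numpy(), 0.05, mu)
    sample_rows = []
    mat_cols, pat_cols = {}, {}
    shape = 1.0 / config.nb_dispersion
    for ph in phases:
        phase_mult = np.exp(rng.normal(0.0, config.phase_effect_sd, size=n))
        lfc_ph = lfc_map.loc[list(zip(truth["pair_id"], [ph] * n))].to_numpy()
        mean_m = mu * phase_mult * np.power(2.0, lfc_ph / 2.0)
        mean_p = mu * phase_mult * np.power(2.0, -lfc_ph / 2.0)
        for r in range(1, config.n_expr_replicates + 1):
            depth = rng.uniform(*config.depth_factor_range)
            sid = f"{ph}_{r}"
            sample_rows.append({"sample_id": sid, "phase": ph, "replicate": r})
            lam_m = rng.gamma(shape, mean_m * depth * config.nb_dispersion)
            lam_p = rng.gamma(shape, mean_p * depth * config.nb_dispersion)
            mat_cols[sid] = rng.poisson(lam_m)
            pat_cols[sid] = rng.poisson(lam_p)
    samples = pd.DataFrame(sample_rows)
    maternal = pd.DataFrame(mat_cols, index=truth["pair_id"])
    paternal = pd.DataFrame(pat_cols, index=truth["pair_id"])
    return maternal, paternal, samples, lfc_truth


# ---------------------------------------------------------------------------
# Promoter motifs
# ---------------------------------------------------------------------------

def toy_motif_library(n_motifs: int = 24, seed: int = 7, width_range: tuple[int, int] = (8, 12)) -> list[Motif]:
    """Deterministic informative PWM library for the synthetic promoters."""
    rng = np.random.default_rng([seed, _STAGE_MOTIF])
    motifs = []
    for i in range(n_motifs):
        w = int(rng.integers(width_range[0], width_range[1] + 1))
        mat = np.full((w, 4), 0.05)
        dominant = rng.integers(0, 4, size=w)
        mat[np.arange(w), dominant] = 0.85
        motifs.append(Motif(motif_id=f"MOTIF{i:03d}", matrix=mat))
    return motifs


def place_motifs(
    bundle: GenomeBundle,
    truth: pd.DataFrame,
    config: SimConfig,
    library: Sequence[Motif] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Embed consensus motif words into promoters; emit placement + vector truth.

    Per pair, motif presence is Bernoulli(motif_presence_prob); the paternal
    allele's presence is toggled per motif with the flip probability, which
    is elevated for phase-dependent allele-biased pairs (coupling promoter
    divergence to expression divergence). Embedded words are the PWM
    consensus, written into reserved non-overlapping slots of the 2-kb
    forward-strand promoter window. Mutates bundle sequences in place.
    """
    if library is None:
        library = toy_motif_library(config.n_motifs, seed=config.seed)
    max_w = max(m.width for m in library)
    slot = max_w + 4
    if slot * len(library) > config.promoter_length:
        raise ValueError("motif library does not fit the promoter slot layout")
    for m in library:
        if m.width > config.promoter_length:
            raise ValueError(f"motif {m.motif_id} wider than promoter")
    rng = config.rng(_STAGE_MOTIF)
    windows = {
        "alb": promoter_windows(bundle, "alb", config.promoter_length),
        "gla": promoter_windows(bundle, "gla", config.promoter_length),
    }
    seqs = {sg: {c: bytearray(s.encode()) for c, s in bundle.sequences[sg].items()}
            for sg in bundle.sequences}
    consensus = {
        m.motif_id: "".join("ACGT"[i] for i in np.argmax(m.matrix, axis=1)) for m in library
    }
    placement_rows, vector_rows = [], []
    for _, row in truth.iterrows():
        flip_p = (
            config.motif_flip_prob_aseg
            if row.get("is_phase_dependent", False)
            else config.motif_flip_prob
        )
        present_m = rng.random(len(library)) < config.motif_presence_prob
        flips = rng.random(len(library)) < flip_p
        present_p = present_m ^ flips
        jitters = rng.integers(0, 5, size=len(library))
        for sg, gid, present in (
            ("alb", row["maternal_id"], present_m),
            ("gla", row["paternal_id"], present_p),
        ):
            chrom, pstart = windows[sg][gid]
            vec = present.astype(int)
            vector_rows.append({"allele_id": gid, **{
                m.motif_id: int(v) for m, v in zip(library, vec)
            }})
            for k, m in enumerate(library):
                if not present[k]:
                    continue
                word = consensus[m.motif_id]
                offset = k * slot + int(jitters[k])
                gstart = pstart + offset
                seqs[sg][chrom][gstart : gstart + m.width] = word.encode()
                placement_rows.append(
                    {"allele_id": gid, "motif_id": m.motif_id, "chrom": chrom,
                     "promoter_offset": offset, "genomic_start": gstart}
                )
    for sg in seqs:
        bundle.sequences[sg] = {c: bytes(b).decode() for c, b in seqs[sg].items()}
    placements = pd.DataFrame(
        placement_rows,
        columns=["allele_id", "motif_id", "chrom", "promoter_offset", "genomic_start"],
    )
    vectors = pd.DataFrame(vector_rows)
    return placements, vectors
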