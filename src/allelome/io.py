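"""Readers and writers for the on-disk formats the pipeline touches.

Internal convention: all coordinates are 0-based half-open. Conversion to the
1-based conventions of cytosine reports and GFF3 happens only here, at the
I/O boundary. BED is already 0-based half-open and passes through unchanged.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONTEXTS = ("CG", "CHG", "CHH")
#: phases with RNA-seq in the study design this pipeline emulates
EXPRESSION_PHASES = ("LE", "DP1", "DP2", "IP0.5", "IP1", "IP1.5", "IP2", "IP3")
#: phases with whole-genome bisulfite sequencing
METHYLOME_PHASES = ("LE", "DP1", "DP2", "IP1", "IP2", "IP3")

CYTOSINE_COLUMNS = ["chrom", "pos0", "strand", "mc", "uc", "context", "tri"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclasses.dataclass
class GeneModel:
    """A gene with its exon structure; 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]

    @property
    def length(self) -> int:
        """Exon-union length in bp."""
        return sum(e - s for s, e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site (higher coordinate on the minus strand)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclasses.dataclass
class GenomeBundle:
    """Two-subgenome genome: sequences, gene models and TE intervals."""

    sequences: dict[str, dict[str, str]]  # subgenome -> chrom -> sequence
    genes: dict[str, list[GeneModel]]  # subgenome -> gene models
    tes: dict[str, pd.DataFrame]  # subgenome -> BED-like frame
    parent_of: dict[str, str]  # subgenome -> {"maternal", "paternal"}

    def chrom_sizes(self, subgenome: str) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences[subgenome].items()}

    def gene_index(self, subgenome: str) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes[subgenome]}

    def validate(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("subgenome identifiers must be distinct")
        for sg, models in self.genes.items():
            sizes = self.chrom_sizes(sg)
            for g in models:
                if g.start < 0 or g.end > sizes[g.chrom]:
                    raise ValueError(f"gene {g.gene_id} outside {g.chrom} bounds")
                exons = sorted(g.exons)
                if exons != g.exons:
                    raise ValueError(f"gene {g.gene_id}: exons not sorted")
                for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                    if s2 < e1:
                        raise ValueError(f"gene {g.gene_id}: overlapping exons")


@dataclasses.dataclass
class SampleSheet:
    """Sample metadata: phase label, replicate index and file paths."""

    rows: pd.DataFrame  # columns: sample_id, phase, replicate, path

    PHASES = frozenset(EXPRESSION_PHASES)

    def __post_init__(self) -> None:
        bad = set(self.rows["phase"]) - self.PHASES
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    def samples(self, phase: str) -> pd.DataFrame:
        return self.rows[self.rows["phase"] == phase]


# ---------------------------------------------------------------------------
# Cytosine reports (Bismark cytosine-report layout)
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read a 7-column cytosine report into a per-site frame.

    Columns on disk: chrom, 1-based position, strand, methylated count,
    unmethylated count, context, trinucleotide. Positions come back 0-based.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CYTOSINE_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "tri": str,
            },
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CYTOSINE_COLUMNS)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed cytosine report: {exc}") from exc
    for col in ("pos0", "mc", "uc"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise FormatError(f"{path}: non-numeric {col!r} field at line {line}")
        df[col] = vals.astype(np.int64)
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FormatError(
            f"{path}: unknown context {df['context'].iloc[line - 1]!r} at line {line}"
        )
    bad = ~df["strand"].isin(("+", "-"))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise FormatError(f"{path}: bad strand at line {line}")
    if (df[["mc", "uc"]].to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    df["pos0"] = df["pos0"] - 1  # 1-based on disk -> 0-based internal
    if (df["pos0"] < 0).any():
        raise FormatError(f"{path}: position < 1")
    return df


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    out = df[CYTOSINE_COLUMNS].copy() if "tri" in df else df.copy()
    if "tri" not in out:
        out["tri"] = out["context"]
    out = out[CYTOSINE_COLUMNS]
    out["pos0"] = out["pos0"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon features) from GFF3.

    GFF3 is 1-based inclusive on disk; models come back 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            if exon.end < exon.start:
                raise FormatError(f"{path}: exon end < start in {gene.id}")
            if exon.start - 1 < gene.start - 1 or exon.end > gene.end:
                raise FormatError(f"{path}: exon outside gene span in {gene.id}")
            exons.append((exon.start - 1, exon.end))
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand,
                exons=sorted(exons),
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            base = f"{g.chrom}\tallelome\t"
            tail = f"\t.\t{g.strand}\t.\t"
            fh.write(f"{base}gene\t{g.start + 1}\t{g.end}{tail}ID={g.gene_id}\n")
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{base}mRNA\t{g.start + 1}\t{g.end}{tail}ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{base}exon\t{s + 1}\t{e}{tail}ID={mrna}.exon{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# BED (0-based half-open, as on disk)
# ---------------------------------------------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLUMNS)
    df.columns = BED6_COLUMNS[: df.shape[1]] + [
        f"extra{i}" for i in range(max(0, df.shape[1] - 6))
    ]
    df["chrom"] = df["chrom"].astype(str)
    if (df["end"] < df["start"]).any():
        raise FormatError(f"{path}: interval end < start")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in BED6_COLUMNS
    ]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """TSV with header 'gene_id' + sample ids; genes as rows."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id'")
    return df.set_index("gene_id")


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Motif:
    """A motif as a column-stochastic probability matrix over A,C,G,T."""

    motif_id: str
    matrix: np.ndarray  # shape (width, 4), rows sum to 1

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


def read_meme_motifs(path: str | Path, tol: float = 1e-3) -> list[Motif]:
    """Parse MEME minimal format, validating that each row sums to ~1."""
    motifs: list[Motif] = []
    name: str | None = None
    rows: list[list[float]] = []
    width: int | None = None

    def flush(lineno: int) -> None:
        nonlocal name, rows, width
        if name is None:
            return
        if width is not None and len(rows) != width:
            raise FormatError(
                f"{path}: motif {name} declared width {width}, got {len(rows)} rows"
            )
        mat = np.asarray(rows, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise FormatError(f"{path}: motif {name}: expected 4 columns per row")
        sums = mat.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise FormatError(
                f"{path}: motif {name}: row {bad} sums to {sums[bad]:.4f}, not 1"
            )
        motifs.append(Motif(motif_id=name, matrix=mat))
        name, rows, width = None, [], None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("MOTIF"):
                flush(lineno)
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}: line {lineno}: MOTIF without a name")
                name = parts[1]
            elif line.startswith("letter-probability matrix"):
                if "w=" in line:
                    width = int(line.split("w=")[1].split()[0])
            elif name is not None and line and (line[0].isdigit() or line[0] == "."):
                try:
                    rows.append([float(x) for x in line.split()])
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from exc
        flush(-1)
    return motifs


def write_meme_motifs(motifs: Iterable[Motif], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
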