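"""Readers and writers for the external formats the pipeline touches.

Conventions: all genomic intervals are 0-based half-open [start, end) (BED
convention) everywhere internally; FASTA and TSV adapters keep that convention.
Readers validate strictly and raise :class:`FormatError` naming the offending
line rather than coercing malformed rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .diffexpr import ExpressionDataset, GeneExpression


class FormatError(ValueError):
    """A malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Interval:
    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative coordinate in interval {self.name!r}")
        if self.end <= self.start:
            raise ValueError(f"interval {self.name!r} has start >= end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneAnnotation:
    """TSS/strand plus labelled gene regions (promoter, intron, downstream)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for label, ivs in self.regions.items():
            for s, e in ivs:
                if not s < e:
                    raise ValueError(f"gene {self.gene_id}: empty {label} interval")


@dataclass
class MotifMatrix:
    """Position probability matrix for a TF motif (columns sum to 1)."""

    motif_id: str
    tf_name: str
    probs: np.ndarray  # shape (4, width), rows A C G T

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError(f"motif {self.motif_id}: probs must be 4 x width")
        if self.width < 4:
            raise ValueError(f"motif {self.motif_id}: width must be >= 4")
        if (self.probs < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative probability")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.motif_id}: columns must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))


@dataclass
class PeakRecord:
    """A ChIP peak with its 45-bp probe-centred sequence and peak-level FDR."""

    peak_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    peak_fdr: float
    assigned_gene: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"peak {self.peak_id}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start}"
            )
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"peak {self.peak_id}: bases must be in ACGTN")
        if not 0 <= self.peak_fdr <= 1:
            raise ValueError(f"peak {self.peak_id}: peak_fdr outside [0,1]")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

_EXPR_COLUMNS = ["gene_id", "probe_id", "condition", "replicate", "value"]


def read_expression_table(path: str | Path) -> ExpressionDataset:
    """Read a probe-level two-condition expression TSV.

    Columns: gene_id, probe_id, condition (1 or 2), replicate, value (log2).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "probe_id": str})
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in _EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for col in ("condition", "replicate", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna())[0]) + 2  # 1-based + header
            raise FormatError(f"{path}: non-numeric {col} on line {line}")
        df[col] = coerced
    bad_cond = ~df["condition"].isin([1, 2])
    if bad_cond.any():
        line = int(np.flatnonzero(bad_cond)[0]) + 2
        raise FormatError(f"{path}: condition outside {{1,2}} on line {line}")
    if not np.isfinite(df["value"]).all():
        line = int(np.flatnonzero(~np.isfinite(df["value"]))[0]) + 2
        raise FormatError(f"{path}: non-finite value on line {line}")

    genes = []
    for gid, sub in df.groupby("gene_id", sort=True):
        probe_ids = sorted(sub["probe_id"].unique())
        mats = {}
        for cond in (1, 2):
            sc = sub[sub["condition"] == cond]
            if sc.empty:
                raise FormatError(f"{path}: gene {gid} has no condition-{cond} rows")
            reps = sorted(sc["replicate"].unique())
            mat = np.full((len(probe_ids), len(reps)), np.nan)
            for _, row in sc.iterrows():
                mat[probe_ids.index(row["probe_id"]), reps.index(row["replicate"])] = row["value"]
            if np.isnan(mat).any():
                raise FormatError(
                    f"{path}: gene {gid} condition {cond} has an incomplete probe x replicate grid"
                )
            mats[cond] = mat
        genes.append(GeneExpression(str(gid), mats[1], mats[2]))
    return ExpressionDataset(genes)


def write_expression_table(dataset: ExpressionDataset, path: str | Path) -> None:
    rows = []
    for g in dataset:
        for cond, mat in ((1, g.values1), (2, g.values2)):
            for j in range(mat.shape[0]):
                for k in range(mat.shape[1]):
                    rows.append((g.gene_id, f"p{j + 1}", cond, k + 1, mat[j, k]))
    pd.DataFrame(rows, columns=_EXPR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TRANSFAC matrices
# ---------------------------------------------------------------------------

def read_transfac_matrices(path: str | Path, pseudocount: float = 0.01) -> list[MotifMatrix]:
    """Parse TRANSFAC flat-file matrix blocks into probability matrices.

    Counts get ``pseudocount`` added per cell before column normalisation, so
    log-odds scores stay finite for bases unseen in the alignment.
    """
    path = Path(path)
    motifs: list[MotifMatrix] = []
    motif_id = tf_name = None
    rows: list[list[float]] = []
    in_matrix = False

    def flush(lineno: int) -> None:
        nonlocal motif_id, tf_name, rows, in_matrix
        if motif_id is None and not rows:
            return
        if motif_id is None or not rows:
            raise FormatError(f"{path}: truncated matrix block before line {lineno}")
        counts = np.array(rows, dtype=float).T  # (4, width)
        if (counts.sum(axis=0) == 0).any():
            raise FormatError(f"{path}: matrix {motif_id} has an all-zero column")
        counts = counts + pseudocount
        probs = counts / counts.sum(axis=0, keepdims=True)
        motifs.append(MotifMatrix(motif_id, tf_name or motif_id, probs))
        motif_id = tf_name = None
        rows = []
        in_matrix = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("//"):
                flush(lineno)
                continue
            if line.startswith(("ID", "AC")) and motif_id is None:
                motif_id = line.split(None, 1)[1].strip() if len(line.split(None, 1)) > 1 else ""
                if not motif_id:
                    raise FormatError(f"{path}: empty ID on line {lineno}")
            elif line.startswith("NA"):
                tf_name = line.split(None, 1)[1].strip() if len(line.split(None, 1)) > 1 else ""
            elif line.startswith("P0") or line.startswith("PO"):
                in_matrix = True
            elif in_matrix and line[:2].strip().isdigit():
                parts = line.split()
                try:
                    rows.append([float(x) for x in parts[1:5]])
                except (ValueError, IndexError) as exc:
                    raise FormatError(f"{path}: bad matrix row on line {lineno}") from exc
    if motif_id is not None or rows:
        if rows:
            flush(-1)
        else:
            raise FormatError(f"{path}: truncated matrix block at end of file")
    return motifs


# ---------------------------------------------------------------------------
# BED / FASTA
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> list[Interval]:
    """Read BED (>=3 columns, 0-based half-open) into Interval records."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}: fewer than 3 BED fields on line {lineno}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer coordinate on line {lineno}") from exc
            name = parts[3] if len(parts) > 3 else f"iv{lineno}"
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            try:
                out.append(Interval(parts[0], start, end, name, score, strand))
            except ValueError as exc:
                raise FormatError(f"{path}: {exc} (line {lineno})") from exc
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to an id -> sequence map; duplicate ids are an error."""
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Peaks and gene annotation
# ---------------------------------------------------------------------------

def read_peaks(bed_path: str | Path, fasta_path: str | Path) -> list[PeakRecord]:
    """Combine a peak BED (name, score column = peak FDR) with peak sequences.

    The optional 7th BED column carries the assigned gene id.
    """
    seqs = read_fasta(fasta_path)
    peaks = []
    with open(bed_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"{bed_path}: need >=5 fields (incl. FDR) on line {lineno}")
            name = parts[3]
            if name not in seqs:
                raise FormatError(f"{bed_path}: no sequence for peak {name!r} (line {lineno})")
            gene = parts[6] if len(parts) > 6 else ""
            try:
                peaks.append(
                    PeakRecord(name, parts[0], int(parts[1]), int(parts[2]),
                               seqs[name], float(parts[4]), gene)
                )
            except ValueError as exc:
                raise FormatError(f"{bed_path}: {exc} (line {lineno})") from exc
    return peaks


def read_gene_annotation(path: str | Path) -> dict[str, GeneAnnotation]:
    """BED6-style annotation: chrom, start, end, gene_id[:region], score, strand.

    A plain gene line defines the TSS (strand-aware end of the interval) and a
    promoter; lines named ``gene:region`` add labelled regions.
    """
    genes: dict[str, GeneAnnotation] = {}
    for iv in read_bed_intervals(path):
        if ":" in iv.name:
            gid, label = iv.name.split(":", 1)
            if gid not in genes:
                raise FormatError(f"{path}: region line for unknown gene {gid!r}")
            genes[gid].regions.setdefault(label, []).append((iv.start, iv.end))
        else:
            if iv.name in genes:
                raise FormatError(f"{path}: duplicate gene id {iv.name!r}")
            tss = iv.start if iv.strand == "+" else iv.end - 1
            genes[iv.name] = GeneAnnotation(iv.name, iv.chrom, tss, iv.strand, {})
    return genes


def assign_peaks_to_genes(
    peaks: Sequence[PeakRecord], annotation: dict[str, GeneAnnotation]
) -> list[PeakRecord]:
    """Assign unassigned peaks to the first gene whose labelled region overlaps.

    Peaks already carrying an assigned_gene are left untouched; a peak that
    overlaps no region stays unassigned.
    """
    out = []
    for p in peaks:
        if p.assigned_gene:
            out.append(p)
            continue
        hit = ""
        for g in annotation.values():
            if g.chrom != p.chrom:
                continue
            for ivs in g.regions.values():
                if any(p.start < e and s < p.end for s, e in ivs):
                    hit = g.gene_id
                    break
            if hit:
                break
        out.append(PeakRecord(p.peak_id, p.chrom, p.start, p.end, p.sequence, p.peak_fdr, hit))
    return out


# ---------------------------------------------------------------------------
# Network output
# ---------------------------------------------------------------------------

def write_network(net, path: str | Path, hubs_json: str | Path | None = None) -> None:
    """Write a network as a TSV edge list plus an optional JSON hub summary."""
    rows = [(e.tf, e.gene, e.mechanism, e.direction, e.site_fdr) for e in net.edges]
    pd.DataFrame(rows, columns=["tf", "gene", "mechanism", "direction", "fdr"]).to_csv(
        path, sep="\t", index=False
    )
    if hubs_json is not None:
        write_report(
            {"timepoint": net.timepoint,
             "hubs": [{"tf": h.tf, "target_count": h.target_count, "p_value": h.p_value}
                      for h in net.hubs]},
            hubs_json,
        )


def write_report(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
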