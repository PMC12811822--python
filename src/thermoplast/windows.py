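"""Strand-aware regulatory windows and peak–gene association.

Builds gene-proximal windows (gene body ± flank, slop semantics) and
promoter windows (upstream/downstream of the biological TSS, flank
semantics), classifies differential peak-associated genes (DPGs) by ≥1 bp
overlap, computes peak-coverage fractions of gene lists, and filters DEGs
by transcription-factor footprint fold change inside promoters.

All coordinates are 0-based half-open internally; GFF3 input (1-based
closed) is converted on read. Overlap queries use interval trees.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "read_bed6",
    "write_bed6",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_footprints",
    "gene_flank_windows",
    "promoter_windows",
    "classify_dpg",
    "peak_coverage_fraction",
    "footprint_promoter_filter",
]

BED6_COLS = ["chrom", "start", "end", "gene_id", "score", "strand"]
NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]
FOOTPRINT_COLS = ["motif_id", "chrom", "start", "end", "score_condA", "score_condB", "log2fc"]


# ---------------------------------------------------------------------------
# readers / writers (plain-text standard formats)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6 requires 6 columns, found {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = BED6_COLS
    _check_intervals(df, path)
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    df.loc[:, BED6_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into a BED6-like frame.

    GFF3 is 1-based closed; returned coordinates are 0-based half-open.
    The gene id is taken from the ID= attribute.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{path}:{ln}: GFF3 requires 9 columns, found {len(parts)}")
        chrom, _, ftype, start, end, score, strand, _, attrs = parts
        if ftype != "gene":
            continue
        gid = None
        for kv in attrs.split(";"):
            if kv.startswith("ID="):
                gid = kv[3:]
        if gid is None:
            raise ValueError(f"{path}:{ln}: gene feature lacks an ID attribute")
        rows.append((chrom, int(start) - 1, int(end), gid, 0, strand))
    df = pd.DataFrame(rows, columns=BED6_COLS)
    _check_intervals(df, path)
    return df


def write_gff3_genes(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in df.itertuples():
            fh.write(
                f"{r.chrom}\tsynth\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\tID={r.gene_id}\n"
            )


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 10:
        raise ValueError(f"{path}: narrowPeak requires 10 columns, found {df.shape[1]}")
    df.columns = NARROWPEAK_COLS
    _check_intervals(df, path)
    bad = ~((df["peak"] >= -1) & (df["peak"] < df["end"] - df["start"]))
    if bad.any():
        raise ValueError(f"{path}: summit offset out of range on row(s) {list(df.index[bad])}")
    return df


def write_narrowpeak(df: pd.DataFrame, path) -> None:
    df.loc[:, NARROWPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_footprints(path, fold_change_scale: str = "log2") -> pd.DataFrame:
    """Read a footprint-score table (TSV with header).

    ``fold_change_scale`` declares the scale of the fold-change column:
    "log2" (column log2fc) or "raw" (column fold_change, converted).
    """
    df = pd.read_csv(path, sep="\t")
    if fold_change_scale == "raw":
        if "fold_change" not in df.columns:
            raise ValueError("raw fold-change table requires a fold_change column")
        df = df.copy()
        df["log2fc"] = np.log2(df["fold_change"])
    missing = [c for c in FOOTPRINT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"footprint table missing column(s): {missing}")
    return df[FOOTPRINT_COLS]


def _check_intervals(df: pd.DataFrame, source) -> None:
    bad = df.index[~(df["start"] < df["end"])].tolist()
    if bad:
        raise ValueError(f"{source}: start >= end on row(s) {bad}")
    if (df["start"] < 0).any():
        raise ValueError(f"{source}: negative coordinates")


# ---------------------------------------------------------------------------
# window construction


def _check_chroms(genes: pd.DataFrame, chrom_sizes: dict[str, int]) -> None:
    unknown = sorted(set(genes["chrom"]) - set(chrom_sizes))
    if unknown:
        raise ValueError(f"gene(s) on unknown chromosome(s): {unknown}")
    for r in genes.itertuples():
        if r.end > chrom_sizes[r.chrom]:
            raise ValueError(f"gene {r.gene_id} extends past the end of {r.chrom}")


def gene_flank_windows(
    genes: pd.DataFrame, flank: int = 5000, chrom_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Gene body extended by ``flank`` bp on both sides (slop semantics).

    Strand-independent; windows are clipped to [0, chromosome length).
    Returns a frame with columns chrom, start, end, gene_id, strand.
    """
    if chrom_sizes is None:
        raise ValueError("chrom_sizes is required")
    _check_chroms(genes, chrom_sizes)
    out = genes.loc[:, ["chrom", "start", "end", "gene_id", "strand"]].copy()
    out["start"] = np.maximum(0, out["start"] - flank)
    out["end"] = [min(chrom_sizes[c], e + flank) for c, e in zip(out["chrom"], genes["end"])]
    return out.reset_index(drop=True)


def promoter_windows(
    genes: pd.DataFrame,
    up: int = 1000,
    down: int = 100,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Promoter windows around the biological TSS (flank semantics).

    Strand-aware: + strand → [start − up, start + down); − strand →
    [end − down, end + up). Clipped to the chromosome.
    """
    if chrom_sizes is None:
        raise ValueError("chrom_sizes is required")
    _check_chroms(genes, chrom_sizes)
    rows = []
    for r in genes.itertuples():
        if r.strand == "+":
            lo, hi = r.start - up, r.start + down
        else:
            lo, hi = r.end - down, r.end + up
        clen = chrom_sizes[r.chrom]
        rows.append((r.chrom, max(0, lo), min(clen, hi), r.gene_id, r.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])


# ---------------------------------------------------------------------------
# association


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in intervals.itertuples():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, getattr(r, "name", None))
    return trees


def classify_dpg(differential_peaks: pd.DataFrame, gene_windows: pd.DataFrame) -> set[str]:
    """Genes whose window overlaps ≥1 differential peak by ≥1 bp.

    Overlap follows half-open semantics: a.start < b.end and b.start < a.end,
    so a peak that exactly abuts a window does not count.
    """
    if len(differential_peaks) == 0:
        return set()
    trees = _trees(differential_peaks)
    hits = set()
    for w in gene_windows.itertuples():
        t = trees.get(w.chrom)
        if t is not None and t.overlap(w.start, w.end):
            hits.add(w.gene_id)
    return hits


def peak_coverage_fraction(
    gene_list, peaks: pd.DataFrame, gene_windows: pd.DataFrame
) -> float:
    """Fraction of listed genes with ≥1 peak overlapping their window."""
    gene_list = list(gene_list)
    known = set(gene_windows["gene_id"])
    unknown = sorted(set(gene_list) - known)
    if unknown:
        raise ValueError(f"unknown gene id(s): {unknown}")
    if not gene_list:
        return 0.0
    covered = classify_dpg(peaks, gene_windows[gene_windows["gene_id"].isin(gene_list)])
    return len(covered & set(gene_list)) / len(gene_list)


def footprint_promoter_filter(
    deg_ids,
    footprints: pd.DataFrame,
    promoters: pd.DataFrame,
    motif_ids=None,
    fc_threshold: float = 2.0,
) -> set[str]:
    """DEGs with a strong-fold-change footprint inside their promoter.

    Keeps DEGs having ≥1 footprint of any listed motif (union over the
    motif family) within their promoter window whose fold change satisfies
    |fold change| > fc_threshold on the raw-ratio scale, i.e.
    |log2fc| > log2(fc_threshold), strictly.
    """
    deg_ids = set(deg_ids)
    if not deg_ids:
        return set()
    if motif_ids is None:
        motif_ids = sorted(footprints["motif_id"].unique())
    present = set(footprints["motif_id"])
    use = []
    for mid in motif_ids:
        if mid not in present:
            import warnings

            warnings.warn(f"motif id {mid!r} absent from footprint table; skipped", UserWarning)
        else:
            use.append(mid)
    fp = footprints[footprints["motif_id"].isin(use)]
    fp = fp[np.abs(fp["log2fc"]) > np.log2(fc_threshold)]
    if fp.empty:
        return set()
    trees = _trees(fp)
    out = set()
    for w in promoters[promoters["gene_id"].isin(deg_ids)].itertuples():
        t = trees.get(w.chrom)
        if t is not None and t.overlap(w.start, w.end):
            out.add(w.gene_id)
    return out
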