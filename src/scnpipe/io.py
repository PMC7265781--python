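"""Readers and writers for the pipeline's on-disk formats.

TSV tables throughout (binning table, count/ratio/CN matrices with bins
as rows and cells as columns, seg-style long tables, QC), BED for
exclusion masks (0-based half-open), FASTA via pyfaidx for indexed
access, SAM/BAM via pysam, and Newick for the cell tree.  All writers
round-trip: writing then reading reproduces the original structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import BINNING_COLUMNS, GenomeBinning


def read_fasta(path):
    """Indexed FASTA access; returns a pyfaidx.Fasta."""
    import pyfaidx

    return pyfaidx.Fasta(str(path))


def write_fasta(path, sequences: dict, width: int = 70):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_sam_positions(path, mapq_min: int | None = None) -> pd.DataFrame:
    """Leftmost positions of mapped reads from SAM/BAM: chrom, pos, mapq."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if mapq_min is not None and read.mapping_quality < mapq_min:
                continue
            rows.append((read.reference_name, read.reference_start, read.mapping_quality))
    return pd.DataFrame(rows, columns=["chrom", "pos", "mapq"])


def read_bed(path) -> list:
    """BED intervals as (chrom, start, end), 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                out.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED coordinates") from exc
    return out


def write_bed(path, intervals):
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_binning(path, binning: GenomeBinning):
    with open(path, "w") as fh:
        fh.write(f"#read_length={binning.read_length}\tn_bins={binning.n_bins_requested}\n")
        binning.bins.to_csv(fh, sep="\t", index=False)


def read_binning(path) -> GenomeBinning:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#read_length="):
            raise ValueError(f"{path}:1: missing binning metadata header")
        fields = dict(item.split("=") for item in header.lstrip("#").split("\t"))
        df = pd.read_csv(fh, sep="\t")
    missing = [c for c in BINNING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return GenomeBinning(bins=df, read_length=int(fields["read_length"]),
                         n_bins_requested=int(fields["n_bins"]))


def write_matrix(path, matrix: np.ndarray, cells, index_name: str = "bin"):
    """Bins-as-rows, cells-as-columns TSV."""
    df = pd.DataFrame(matrix, columns=list(cells))
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.columns)


def write_seg_table(path, seg_rows: pd.DataFrame):
    """Long 'seg'-style table: cell, chrom, start_bin, end_bin, n_bins, seg_mean."""
    seg_rows.to_csv(path, sep="\t", index=False)


def read_seg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def linkage_to_newick(z: np.ndarray, labels) -> str:
    """Newick string from a scipy linkage matrix.

    Leaves sit at the height of the most negative merge; every edge
    length is the (non-negative, for monotone linkages) height difference
    between parent and child.
    """
    n = len(labels)
    heights = z[:, 2]
    leaf_h = float(min(heights.min(), 0.0))

    def node_height(idx):
        return leaf_h if idx < n else float(z[idx - n, 2])

    def render(idx):
        if idx < n:
            return str(labels[idx])
        a, b = int(z[idx - n, 0]), int(z[idx - n, 1])
        h = node_height(idx)
        la = max(h - node_height(a), 0.0)
        lb = max(h - node_height(b), 0.0)
        return f"({render(a)}:{la:.6g},{render(b)}:{lb:.6g})"

    return render(2 * n - 2) + ";"


def write_newick(path, z: np.ndarray, labels):
    with open(path, "w") as fh:
        fh.write(linkage_to_newick(z, labels) + "\n")
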