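"""Genome equipartition binning.

Sparse single-cell copy-number estimation rests on dividing the
reference genome into contiguous bins that each contain the same number
of uniquely mappable read-start positions, so a diploid cell is expected
to deposit the same number of uniquely mapping reads in every bin.  This
module builds the mappability mask (exact k-mer uniqueness over both
strands, suitable for toy genomes; externally computed masks can be
imported), performs the equipartition with optional exclusion intervals
(e.g. centromeres), and annotates bins with GC content.

Coordinates are 0-based half-open internally; TSV output adds no offset
but the CLI reports 1-based inclusive coordinates in log messages.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BINNING_COLUMNS = ["chrom", "start", "end", "mappable_starts", "gc", "excluded"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MappabilityMask:
    """Per-chromosome boolean vectors over read-start positions.

    ``masks[chrom][p]`` is True iff a read of ``read_length`` starting at
    0-based position ``p`` maps uniquely.  Vector length is
    ``len(chrom) - read_length + 1`` (chromosomes shorter than the read
    contribute an empty vector).
    """

    read_length: int
    masks: dict = field(default_factory=dict)
    chrom_lengths: dict = field(default_factory=dict)

    @property
    def chroms(self):
        return list(self.masks)

    def n_mappable(self) -> int:
        return int(sum(int(m.sum()) for m in self.masks.values()))


@dataclass
class GenomeBinning:
    """Result of the equipartition: an ordered bin table.

    ``bins`` has columns chrom, start, end (half-open), mappable_starts,
    gc, excluded.  Bins tile each chromosome; excluded bins (exclusion
    intervals, zero-mappability blocks, all-N spans) carry
    ``mappable_starts == 0`` and take no part in profiling.
    """

    bins: pd.DataFrame
    read_length: int
    n_bins_requested: int

    def __post_init__(self):
        self.bins = self.bins.reset_index(drop=True)

    @property
    def usable(self) -> pd.DataFrame:
        """The non-excluded bins, in genome order."""
        return self.bins[~self.bins["excluded"]].reset_index(drop=True)

    @property
    def n_usable(self) -> int:
        return int((~self.bins["excluded"]).sum())

    def usable_chrom_labels(self) -> np.ndarray:
        return self.usable["chrom"].to_numpy()

    def usable_gc(self) -> np.ndarray:
        return self.usable["gc"].to_numpy(dtype=float)


def _sequences(genome) -> dict:
    """Accept a dict of sequences or a pyfaidx.Fasta-like mapping."""
    if isinstance(genome, dict):
        return {c: str(s).upper() for c, s in genome.items()}
    return {name: str(genome[name][:]).upper() for name in genome.keys()}


def build_mappability(genome, read_length: int) -> MappabilityMask:
    """Mark every position whose k-mer occurs exactly once over both strands.

    A position is mappable iff its ``read_length``-mer contains no N and
    the k-mer together with its reverse complement occurs exactly once in
    the genome (one forward-scan hit in canonical form).  This exact-match
    uniqueness stands in for aligner-derived uniqueness and is intended
    for toy genomes; use an imported mask for real references.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    seqs = _sequences(genome)
    k = read_length
    counts: Counter = Counter()
    for seq in seqs.values():
        for p in range(len(seq) - k + 1):
            kmer = seq[p : p + k]
            if "N" in kmer:
                continue
            counts[min(kmer, reverse_complement(kmer))] += 1
    masks = {}
    for chrom, seq in seqs.items():
        n_pos = max(len(seq) - k + 1, 0)
        mask = np.zeros(n_pos, dtype=bool)
        for p in range(n_pos):
            kmer = seq[p : p + k]
            if "N" in kmer:
                continue
            mask[p] = counts[min(kmer, reverse_complement(kmer))] == 1
        masks[chrom] = mask
    if all(m.size == 0 for m in masks.values()):
        raise ValueError("no mappable positions: read_length exceeds every chromosome")
    return MappabilityMask(
        read_length=read_length,
        masks=masks,
        chrom_lengths={c: len(s) for c, s in seqs.items()},
    )


def largest_remainder(weights, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Floor of each proportional share, remaining units to the largest
    fractional parts; ties go to the earlier index (order-stable).
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be >= 0")
    if weights.sum() <= 0:
        return np.zeros(len(weights), dtype=int)
    shares = total * weights / weights.sum()
    base = np.floor(shares).astype(int)
    remainder = total - int(base.sum())
    if remainder > 0:
        frac = shares - base
        # stable sort descending by fraction; earlier index wins ties
        order = np.argsort(-frac, kind="stable")
        base[order[:remainder]] += 1
    return base


def _blocks_for_chrom(chrom_len: int, exclusions):
    """Split [0, chrom_len) into alternating keep/excluded blocks."""
    ivs = sorted((max(0, s), min(chrom_len, e)) for s, e in exclusions if e > 0 and s < chrom_len)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    blocks = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            blocks.append((cursor, s, False))
        blocks.append((s, e, True))
        cursor = e
    if cursor < chrom_len:
        blocks.append((cursor, chrom_len, False))
    return blocks


def equipartition(mask: MappabilityMask, n_bins: int, exclusions=None) -> GenomeBinning:
    """Partition the genome into ``n_bins`` bins of equal mappable-start count.

    ``exclusions`` is an iterable of (chrom, start, end) half-open
    intervals; excluded spans are emitted as their own bins with
    ``excluded=True`` and contribute no mappable starts.  Bin counts are
    apportioned to chromosomes (then to blocks between exclusions) by
    largest-remainder on their mappable totals; within a block, bins
    earlier in genome order receive the ceil counts.  A bin ends at the
    coordinate immediately after its last counted mappable start; the
    final bin of a block extends to the block end.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    excl_by_chrom: dict = {}
    for chrom, s, e in exclusions or []:
        excl_by_chrom.setdefault(chrom, []).append((int(s), int(e)))

    chroms = list(mask.masks)
    eff_masks = {}
    blocks_by_chrom = {}
    for chrom in chroms:
        chrom_len = mask.chrom_lengths[chrom]
        m = mask.masks[chrom].copy()
        blocks = _blocks_for_chrom(chrom_len, excl_by_chrom.get(chrom, []))
        for s, e, excl in blocks:
            if excl:
                lo, hi = min(s, m.size), min(e, m.size)
                m[lo:hi] = False
        eff_masks[chrom] = m
        blocks_by_chrom[chrom] = blocks
        if chrom in excl_by_chrom and not any(not b[2] for b in blocks):
            warnings.warn(f"exclusions cover all of {chrom}; no bins emitted for it")

    totals = np.array([int(eff_masks[c].sum()) for c in chroms])
    total_mappable = int(totals.sum())
    if n_bins > total_mappable:
        raise ValueError(
            f"n_bins={n_bins} exceeds {total_mappable} mappable positions outside exclusions"
        )
    global_base = total_mappable // n_bins
    chrom_quota = largest_remainder(totals, n_bins)

    rows = []
    for chrom, quota in zip(chroms, chrom_quota):
        chrom_len = mask.chrom_lengths[chrom]
        m = eff_masks[chrom]
        blocks = blocks_by_chrom[chrom]
        keep_blocks = [(s, e) for s, e, excl in blocks if not excl]
        block_tot = [int(m[s : min(e, m.size)].sum()) for s, e in keep_blocks]
        block_quota = largest_remainder(block_tot, int(quota))
        qi = 0
        for (s, e, excl) in blocks:
            if excl:
                rows.append((chrom, s, e, 0, np.nan, True))
                continue
            t_blk = int(m[s : min(e, m.size)].sum())
            q_blk = int(block_quota[qi])
            qi += 1
            if t_blk == 0 or q_blk == 0:
                # nothing usable here; keep the span as an excluded filler bin
                rows.append((chrom, s, e, 0, np.nan, True))
                continue
            rows.extend(_cut_block(chrom, s, e, m, t_blk, q_blk, global_base))
    # final bin of each chromosome extends to chromosome end by construction
    bins = pd.DataFrame(rows, columns=BINNING_COLUMNS)
    return GenomeBinning(bins=bins, read_length=mask.read_length, n_bins_requested=n_bins)


def _cut_block(chrom, start, end, m, t_blk, q_blk, global_base):
    """Cut one keep-block into q_blk bins of near-equal mappable counts."""
    extras = t_blk - q_blk * global_base
    if 0 <= extras <= q_blk:
        sizes = [global_base + 1] * extras + [global_base] * (q_blk - extras)
    else:  # degenerate block; fall back to local floor/ceil
        local = t_blk // q_blk
        extra = t_blk - q_blk * local
        sizes = [local + 1] * extra + [local] * (q_blk - extra)
    positions = np.flatnonzero(m[start : min(end, m.size)]) + start
    rows = []
    cursor = start
    offset = 0
    for j, size in enumerate(sizes):
        last = positions[offset + size - 1]
        bin_end = end if j == len(sizes) - 1 else int(last) + 1
        rows.append((chrom, cursor, bin_end, int(size), np.nan, False))
        cursor = bin_end
        offset += size
    return rows


def annotate_gc(genome, binning: GenomeBinning) -> GenomeBinning:
    """Fill the gc column: (G+C)/(A+C+G+T) over each bin span.

    All-N bins get gc = NaN and are flagged excluded.
    """
    seqs = _sequences(genome)
    gc = np.full(len(binning.bins), np.nan)
    excluded = binning.bins["excluded"].to_numpy().copy()
    for i, row in binning.bins.iterrows():
        seq = seqs[row["chrom"]][row["start"] : row["end"]]
        n_gc = seq.count("G") + seq.count("C")
        n_acgt = n_gc + seq.count("A") + seq.count("T")
        if n_acgt == 0:
            excluded[i] = True
        else:
            gc[i] = n_gc / n_acgt
    bins = binning.bins.assign(gc=gc, excluded=excluded)
    return GenomeBinning(bins=bins, read_length=binning.read_length,
                         n_bins_requested=binning.n_bins_requested)


def rescan_mappable(mask: MappabilityMask, binning: GenomeBinning) -> np.ndarray:
    """Independent recount of mappable starts per bin (consistency check)."""
    out = np.zeros(len(binning.bins), dtype=int)
    for i, row in binning.bins.iterrows():
        if row["excluded"]:
            continue
        m = mask.masks[row["chrom"]]
        lo, hi = row["start"], min(row["end"], m.size)
        out[i] = int(m[lo:hi].sum())
    return out
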