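"""Synthetic single-cell populations with known copy-number truth.

The generator emulates the cell-line admixture benchmark used to
demonstrate clone detection: a majority of flat diploid cells plus a
minority clone (default 10% of cells) carrying a fixed set of shared CNV
events, sequenced to a mean of 25 reads per bin (the recommended depth
for sparse single-cell CNV work is >= 20 reads/bin).  Counts are Poisson
around lambda * c_b/ploidy modulated by an injected exp-quadratic GC
bias, so the GC-correction, segmentation, quantization and clone-calling
stages can all be tested against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_N_CELLS = 200
DEFAULT_N_BINS = 5000
DEFAULT_LAMBDA = 25.0
DEFAULT_PLOIDY = 2
DEFAULT_CLONE_FRACTION = 0.10
DEFAULT_N_EVENTS = 30
DEFAULT_EVENT_CN = (1, 3, 4)
DEFAULT_EVENT_LEN = (20, 80)
DEFAULT_GC_BIAS = (1.5, -15.0)  # linear, quadratic coefficient in (g - mean g)
DEFAULT_GC_RANGE = (0.35, 0.55)


@dataclass
class CNVEvent:
    """A copy-number event over bins [start, end) at integer CN ``cn``."""
    start: int
    end: int
    cn: int


@dataclass
class CloneSpec:
    """A clonal subpopulation: fraction of cells and its shared events."""
    fraction: float
    events: list


@dataclass
class SimulationConfig:
    n_cells: int = DEFAULT_N_CELLS
    n_bins: int = DEFAULT_N_BINS
    clones: list | None = None  # None -> one default admixture clone
    ploidy: int = DEFAULT_PLOIDY
    lam: float = DEFAULT_LAMBDA
    gc_bias: tuple = DEFAULT_GC_BIAS
    gc_range: tuple = DEFAULT_GC_RANGE
    n_chroms: int = 1
    private_event_rate: float = 0.0  # expected private events per cell
    dispersion: float | None = None  # None -> Poisson; else NB with this shape
    seed: int | None = None

    def validate(self):
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.clones is not None:
            if sum(c.fraction for c in self.clones) > 1 + 1e-9:
                raise ValueError("clone fractions must sum to <= 1")
            for clone in self.clones:
                for ev in clone.events:
                    if ev.cn < 0:
                        raise ValueError("event CN must be >= 0")
                    if not (0 <= ev.start < ev.end <= self.n_bins):
                        raise ValueError(f"event [{ev.start}, {ev.end}) out of bin range")


@dataclass
class GroundTruth:
    cn: np.ndarray           # (n_bins, n_cells) integer CN
    clone_labels: list       # per cell: clone index or None
    bias: np.ndarray         # injected B_true(g_b) per bin (centered)
    gc: np.ndarray
    chrom: np.ndarray
    cells: list = field(default_factory=list)


def simulate_genome(length: int, gc_start: float = 0.5, gc_end: float | None = None,
                    seed=None, centromere_frac: float = 0.0):
    """Random sequence whose windowed GC follows a linear gradient.

    Returns (sequence, exclusion) where exclusion is a centromere-like
    (start, end) interval in the middle of the sequence covering
    ``centromere_frac`` of it, or None.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)
    if gc_end is None:
        gc_end = gc_start
    p_gc = np.linspace(gc_start, gc_end, length)
    is_gc = rng.random(length) < p_gc
    strong = rng.integers(0, 2, length)
    bases = np.where(is_gc, np.where(strong, ord("G"), ord("C")),
                     np.where(strong, ord("A"), ord("T"))).astype(np.uint8)
    seq = bases.tobytes().decode("ascii")
    exclusion = None
    if centromere_frac > 0:
        half = int(length * centromere_frac / 2)
        mid = length // 2
        exclusion = (mid - half, mid + half)
    return seq, exclusion


def random_events(rng, n_bins: int, n_events: int = DEFAULT_N_EVENTS,
                  cn_choices=DEFAULT_EVENT_CN, length_range=DEFAULT_EVENT_LEN,
                  min_gap: int = 5) -> list[CNVEvent]:
    """Non-overlapping random CNV events spread over the bin range."""
    lo_len, hi_len = length_range
    events = []
    attempts = 0
    occupied = np.zeros(n_bins, dtype=bool)
    while len(events) < n_events and attempts < 10000:
        attempts += 1
        length = int(rng.integers(lo_len, hi_len + 1))
        start = int(rng.integers(0, n_bins - length))
        lo = max(0, start - min_gap)
        hi = min(n_bins, start + length + min_gap)
        if occupied[lo:hi].any():
            continue
        occupied[start:start + length] = True
        events.append(CNVEvent(start=start, end=start + length,
                               cn=int(rng.choice(cn_choices))))
    if len(events) < n_events:
        raise ValueError("could not place requested events without overlap")
    events.sort(key=lambda ev: ev.start)
    return events


def _materialize_clones(config: SimulationConfig, rng) -> list:
    if config.clones is not None:
        return config.clones
    events = random_events(rng, config.n_bins)
    return [CloneSpec(fraction=DEFAULT_CLONE_FRACTION, events=events)]


def _cn_from_events(n_bins: int, ploidy: int, events) -> np.ndarray:
    cn = np.full(n_bins, ploidy, dtype=int)
    for ev in events:
        cn[ev.start:ev.end] = ev.cn
    return cn


def simulate_population(config: SimulationConfig, rng=None):
    """Generate (GroundTruth, counts) for a clonal single-cell population.

    counts[b, i] ~ Poisson(lam * c_b(i)/ploidy * exp(B(g_b))) with
    B the injected exp-quadratic GC bias, centered to mean 0 over bins.
    Cells of a clone carry its events exactly; optional private
    events perturb individual cells at ``private_event_rate``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clones = _materialize_clones(config, rng)

    gc = rng.uniform(*config.gc_range, size=config.n_bins)
    b1, b2 = config.gc_bias
    dev = gc - gc.mean()
    bias = b1 * dev + b2 * dev ** 2
    bias = bias - bias.mean()

    chrom = _chrom_labels(config.n_bins, config.n_chroms)

    clone_sizes = [int(round(c.fraction * config.n_cells)) for c in clones]
    if sum(clone_sizes) > config.n_cells:
        raise ValueError("clone fractions imply more cells than n_cells")
    labels: list = []
    for k, size in enumerate(clone_sizes):
        labels.extend([k] * size)
    labels.extend([None] * (config.n_cells - len(labels)))

    cn = np.empty((config.n_bins, config.n_cells), dtype=int)
    for i, lab in enumerate(labels):
        events = list(clones[lab].events) if lab is not None else []
        if config.private_event_rate > 0:
            n_priv = rng.poisson(config.private_event_rate)
            if n_priv:
                events = events + random_events(rng, config.n_bins, n_events=n_priv)
        cn[:, i] = _cn_from_events(config.n_bins, config.ploidy, events)

    mean = config.lam * (cn / config.ploidy) * np.exp(bias)[:, None]
    if config.dispersion is None:
        counts = rng.poisson(mean)
    else:
        shape = config.dispersion
        counts = rng.negative_binomial(shape, shape / (shape + mean))
    cells = [f"cell{i:04d}" for i in range(config.n_cells)]
    truth = GroundTruth(cn=cn, clone_labels=labels, bias=bias, gc=gc,
                        chrom=chrom, cells=cells)
    return truth, counts


def _chrom_labels(n_bins: int, n_chroms: int) -> np.ndarray:
    sizes = np.full(n_chroms, n_bins // n_chroms)
    sizes[: n_bins - sizes.sum()] += 1
    return np.repeat([f"chr{i + 1}" for i in range(n_chroms)], sizes)


def scatter_read_positions(counts_col: np.ndarray, binning, rng) -> np.ndarray:
    """Uniform read positions within each non-excluded bin for one cell.

    Returns an array of (chrom, pos) records matching the bin counts.
    """
    usable = binning.usable
    chroms = []
    positions = []
    for count, (_, row) in zip(counts_col, usable.iterrows()):
        if count == 0:
            continue
        pos = rng.integers(row["start"], row["end"], size=int(count))
        positions.append(np.sort(pos))
        chroms.extend([row["chrom"]] * int(count))
    pos_all = np.concatenate(positions) if positions else np.empty(0, dtype=int)
    return np.array(chroms, dtype=object), pos_all
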