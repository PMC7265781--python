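"""One-shot pipeline driver: bins -> count -> profile -> clust.

The driver works from files (resumable: a stage whose outputs exist and
are newer than its inputs is skipped) and is also usable fully in memory
via :func:`analyze_population`, which takes a counts matrix with bin GC
and chromosome labels and returns profiles plus the clonal structure.
All randomness flows from the single top-level seed; per-cell work is
parallelizable with results identical to serial execution because every
cell receives its own pre-spawned random stream.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import binning as binning_mod
from . import clonal, io, profiling, simulate
from .config import PipelineConfig

log = logging.getLogger("scnpipe")


@dataclass
class PopulationAnalysis:
    cells: list
    ratio_matrix: np.ndarray
    seg_matrix: np.ndarray
    cn_matrix: np.ndarray
    qc: pd.DataFrame
    clone_result: clonal.CloneResult
    profiles: list


def _profile_one(cell_id, counts_col, gc, chrom, prof_cfg, seed_seq):
    rng = np.random.default_rng(seed_seq)
    ratio = profiling.gc_correct_arrays(
        counts_col, gc, chrom, cell_id=cell_id, span=prof_cfg.lowess_span,
        iters=prof_cfg.lowess_iters, pseudocount=prof_cfg.pseudocount)
    seg = profiling.segment_profile(
        ratio, alpha=prof_cfg.alpha, min_width=prof_cfg.min_width,
        n_perm=prof_cfg.seg_perm, ci_halfwidth=prof_cfg.ci_halfwidth, rng=rng)
    cnp = profiling.quantize(seg, m_lo=prof_cfg.m_lo, m_hi=prof_cfg.m_hi,
                             m_step=prof_cfg.m_step,
                             flag_threshold=prof_cfg.quantize_error_flag)
    return ratio, seg, cnp


def analyze_population(counts: np.ndarray, gc: np.ndarray, chrom: np.ndarray,
                       cells: list, config: PipelineConfig | None = None,
                       seed: int | None = None, workers: int = 1) -> PopulationAnalysis:
    """Count matrix (bins x cells) -> integer CN profiles -> clonal structure."""
    if config is None:
        config = PipelineConfig()
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    _sim_ss, prof_parent, clonal_ss = root.spawn(3)
    cell_seeds = prof_parent.spawn(len(cells))

    prof_cfg = config.profiling
    results = Parallel(n_jobs=max(1, workers))(
        delayed(_profile_one)(cells[i], counts[:, i], gc, chrom, prof_cfg, cell_seeds[i])
        for i in range(len(cells)))

    n_bins = counts.shape[0]
    ratio_matrix = np.column_stack([r.log_ratio for r, _, _ in results])
    seg_matrix = np.column_stack([s.seg_values for _, s, _ in results])
    cn_matrix = np.column_stack([c.cn for _, _, c in results])
    qc = pd.DataFrame({
        "cell_id": cells,
        "total_reads": counts.sum(axis=0),
        "multiplier": [c.multiplier for _, _, c in results],
        "quantize_error": [c.quantize_error for _, _, c in results],
        "flagged": [c.flagged for _, _, c in results],
        "n_segments": [len(c.segments) for _, _, c in results],
    })

    cl_cfg = config.clonal
    changepoints = []
    for _, _, cnp in results:
        changepoints.extend(clonal.extract_changepoints(cnp, halfwidth=cl_cfg.halfwidth))
    clone_result = clonal.clonal_analysis(
        changepoints, cells, rng=np.random.default_rng(clonal_ss),
        combine=cl_cfg.combine, linkage=cl_cfg.linkage, n_perm=cl_cfg.n_perm,
        fdr_threshold=cl_cfg.fdr_threshold, nshare_min=cl_cfg.nshare_min,
        share_pct=cl_cfg.share_pct, min_clone_size=cl_cfg.min_clone_size,
        subclone_recursion=cl_cfg.subclone_recursion)
    return PopulationAnalysis(cells=list(cells), ratio_matrix=ratio_matrix,
                              seg_matrix=seg_matrix, cn_matrix=cn_matrix, qc=qc,
                              clone_result=clone_result, profiles=results)


# ---------------------------------------------------------------------------
# file-based driver

def _fresh(outputs, inputs) -> bool:
    """True if all outputs exist and are no older than every input."""
    if not all(os.path.exists(p) for p in outputs):
        return False
    out_m = min(os.path.getmtime(p) for p in outputs)
    in_m = max((os.path.getmtime(p) for p in inputs if os.path.exists(p)), default=0.0)
    return out_m >= in_m


def run_pipeline(config: PipelineConfig, outdir, workers: int | None = None) -> str:
    """Execute the full pipeline into ``outdir``; returns the directory.

    With a genome configured, bins are built from FASTA and per-cell read
    tables in ``<outdir>/reads`` are counted; otherwise the built-in
    simulator provides counts (bins x cells) with known truth.  Stage
    outputs already present and newer than their inputs are reused.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    if workers is None:
        workers = config.workers
    _save_config_if_changed(config, os.path.join(outdir, "config.yaml"))
    paths = {name: os.path.join(outdir, name) for name in (
        "bins.tsv", "counts.tsv", "gc.tsv", "truth_cn.tsv", "clone_truth.tsv",
        "ratios.tsv", "seg.tsv", "segments.tsv", "cn.tsv", "qc.tsv",
        "dissimilarity.tsv", "tree.newick", "clones.tsv",
        "incidence_pos.tsv", "incidence_neg.tsv")}
    cfg_path = os.path.join(outdir, "config.yaml")

    try:
        counts, gc, chrom, cells = _stage_counts(config, outdir, paths, cfg_path)
        _stage_analyze(config, counts, gc, chrom, cells, paths, cfg_path, workers)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    return outdir


def _save_config_if_changed(config, path):
    """Rewrite the frozen config only when it differs, so resumption works."""
    text = config.to_yaml()
    if os.path.exists(path):
        with open(path) as fh:
            if fh.read() == text:
                return
    with open(path, "w") as fh:
        fh.write(text)


def _stage_counts(config, outdir, paths, cfg_path):
    if config.binning.genome:
        return _counts_from_reads(config, outdir, paths, cfg_path)
    return _counts_from_simulation(config, paths, cfg_path)


def _counts_from_simulation(config, paths, cfg_path):
    sim = config.simulate
    outputs = [paths["counts.tsv"], paths["gc.tsv"], paths["truth_cn.tsv"],
               paths["clone_truth.tsv"]]
    if _fresh(outputs, [cfg_path]):
        log.info("simulate: outputs fresh, skipping")
        counts, cells = io.read_matrix(paths["counts.tsv"])
        gc_df = pd.read_csv(paths["gc.tsv"], sep="\t")
        truth_cn, _ = io.read_matrix(paths["truth_cn.tsv"])
        return counts, gc_df["gc"].to_numpy(), gc_df["chrom"].to_numpy(), cells
    root = np.random.SeedSequence(config.seed)
    sim_ss = root.spawn(3)[0]
    rng = np.random.default_rng(sim_ss)
    sim_config = simulate.SimulationConfig(
        n_cells=sim.n_cells, n_bins=sim.n_bins, lam=sim.lam, ploidy=sim.ploidy,
        clones=None if sim.clone_fraction > 0 else [],
        gc_bias=(sim.gc_bias_linear, sim.gc_bias_quadratic),
        n_chroms=sim.n_chroms, private_event_rate=sim.private_event_rate)
    if sim.clone_fraction > 0:
        events = simulate.random_events(rng, sim.n_bins, n_events=sim.n_events)
        sim_config.clones = [simulate.CloneSpec(fraction=sim.clone_fraction,
                                                events=events)]
    truth, counts = simulate.simulate_population(sim_config, rng=rng)
    io.write_matrix(paths["counts.tsv"], counts, truth.cells)
    pd.DataFrame({"chrom": truth.chrom, "gc": truth.gc, "bias": truth.bias}).to_csv(
        paths["gc.tsv"], sep="\t", index=False)
    io.write_matrix(paths["truth_cn.tsv"], truth.cn, truth.cells)
    pd.DataFrame({"cell_id": truth.cells,
                  "clone": [("" if l is None else str(l)) for l in truth.clone_labels]}
                 ).to_csv(paths["clone_truth.tsv"], sep="\t", index=False)
    log.info("simulate: %d cells x %d bins", counts.shape[1], counts.shape[0])
    return counts, truth.gc, truth.chrom, truth.cells


def _counts_from_reads(config, outdir, paths, cfg_path):
    bcfg = config.binning
    if not _fresh([paths["bins.tsv"]], [bcfg.genome, cfg_path]):
        genome = io.read_fasta(bcfg.genome)
        mask = binning_mod.build_mappability(genome, bcfg.read_length)
        exclusions = io.read_bed(bcfg.exclude) if bcfg.exclude else None
        gb = binning_mod.equipartition(mask, bcfg.n_bins, exclusions)
        gb = binning_mod.annotate_gc(genome, gb)
        io.write_binning(paths["bins.tsv"], gb)
        log.info("bins: %d bins over %d chromosomes", len(gb.bins),
                 gb.bins["chrom"].nunique())
    gb = io.read_binning(paths["bins.tsv"])
    reads_dir = os.path.join(outdir, "reads")
    if not os.path.isdir(reads_dir):
        raise FileNotFoundError(f"reads directory {reads_dir} not found")
    read_files = sorted(os.listdir(reads_dir))
    cells = [os.path.splitext(f)[0] for f in read_files]
    if not _fresh([paths["counts.tsv"]],
                  [paths["bins.tsv"]] + [os.path.join(reads_dir, f) for f in read_files]):
        cols = []
        for fname in read_files:
            fpath = os.path.join(reads_dir, fname)
            if fname.endswith((".sam", ".bam")):
                reads = io.read_sam_positions(fpath)
            else:
                reads = pd.read_csv(fpath, sep="\t")
            cbc = profiling.count_cell(reads, gb, cell_id=os.path.splitext(fname)[0],
                                       mapq_min=config.profiling.mapq_min)
            cols.append(cbc.counts)
            log.info("count: %s -> %d assigned, %d discarded", fname,
                     int(cbc.counts.sum()), cbc.discarded)
        io.write_matrix(paths["counts.tsv"], np.column_stack(cols), cells)
    counts, cells = io.read_matrix(paths["counts.tsv"])
    usable = gb.usable
    return counts, usable["gc"].to_numpy(), usable["chrom"].to_numpy(), cells


def _stage_analyze(config, counts, gc, chrom, cells, paths, cfg_path, workers):
    outputs = [paths[n] for n in ("ratios.tsv", "seg.tsv", "cn.tsv", "qc.tsv",
                                  "dissimilarity.tsv", "tree.newick", "clones.tsv",
                                  "incidence_pos.tsv", "incidence_neg.tsv")]
    if _fresh(outputs, [paths["counts.tsv"], cfg_path]):
        log.info("profile/clust: outputs fresh, skipping")
        return
    analysis = analyze_population(counts, gc, chrom, cells, config,
                                  seed=config.seed, workers=workers)
    io.write_matrix(paths["ratios.tsv"], analysis.ratio_matrix, cells)
    io.write_matrix(paths["seg.tsv"], analysis.seg_matrix, cells)
    io.write_matrix(paths["cn.tsv"], analysis.cn_matrix, cells)
    seg_rows = []
    for (_, _, cnp) in analysis.profiles:
        for s, e, cn_val, mean_ratio in cnp.segments:
            seg_rows.append((cnp.cell_id, cnp.chrom[s], s, e, e - s, cn_val, mean_ratio))
    io.write_seg_table(paths["segments.tsv"], pd.DataFrame(
        seg_rows, columns=["cell", "chrom", "start_bin", "end_bin", "n_bins",
                           "cn", "seg_mean"]))
    analysis.qc.to_csv(paths["qc.tsv"], sep="\t", index=False)
    cres = analysis.clone_result
    io.write_matrix(paths["dissimilarity.tsv"], cres.dissimilarity, cells,
                    index_name="cell")
    io.write_newick(paths["tree.newick"], cres.linkage, cells)
    cres.assignments.to_csv(paths["clones.tsv"], sep="\t", index=False)
    tables = clonal.build_incidence(
        [cp for (_, _, cnp) in analysis.profiles
         for cp in clonal.extract_changepoints(cnp, config.clonal.halfwidth)], cells)
    io.write_matrix(paths["incidence_pos.tsv"], tables.pos, cells, index_name="feature")
    io.write_matrix(paths["incidence_neg.tsv"], tables.neg, cells, index_name="feature")
    log.info("clust: %d clones", len(cres.clones))
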