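"""End-to-end demo pipeline: simulate -> call peaks -> compare -> insulation
-> report.

Runs the whole analysis on synthetic data with ground truth, writing all
declared outputs plus a manifest under a run directory.  Deterministic under
the configured seed; paths in the manifest are relative to the run directory
so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, features, insulation, io, peakcalling, report, synthetic
from .features import ctcf_like_pwm
from .io import BedRecord
from .peakcalling import CallerConfig, window_nb_size
from .synthetic import SimulationConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    n_chroms: int = 1
    chrom_length_bp: int = 500_000
    gc_fraction: float = 0.42
    n_sites: int = 30
    phospho_fraction: float = 0.2
    n_genes: int = 20
    pwm_p_cutoff: float = 3e-5
    contact_bins: int = 58
    contact_resolution_bp: int = 25_000
    contact_depth: float = 400.0
    n_codon_reads: int = 5000
    codon_mutant_fraction: float = 0.14
    codon_error_rate: float = 0.002
    de_alpha: float = 0.01
    de_n_up: int = 118
    de_n_down: int = 257
    de_n_null: int = 12000
    caller: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)


@dataclass
class RunManifest:
    version: str
    config: dict
    seeds: dict
    outputs: dict  # name -> relative path
    checksums: dict  # relative path -> sha256
    summary: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial: dict) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_manifest = partial


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Execute the full synthetic-to-report pipeline under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    summary: dict = {}
    seeds = {"genome": config.seed, "sim": config.seed,
             "genes": config.seed + 7, "contacts": config.seed + 11,
             "codon": config.seed + 13, "de": config.seed + 17}
    stage = "setup"

    def emit(name: str, fname: str, writer) -> Path:
        path = outdir / fname
        writer(path)
        outputs[name] = fname
        return path

    try:
        # ---- simulate ------------------------------------------------
        stage = "simulate"
        sim = SimulationConfig(seed=config.seed, n_sites=config.n_sites,
                               phospho_fraction=config.phospho_fraction,
                               **config.sim)
        pwm = ctcf_like_pwm()
        genome = synthetic.generate_genome(config.n_chroms, config.chrom_length_bp,
                                           config.gc_fraction, seed=seeds["genome"])
        genome, sites = synthetic.plant_sites(genome, pwm, sim)
        chip_total, inp = synthetic.simulate_tags(genome, sites, sim)
        phospho_sites = [s for s in sites if s.phospho]
        phospho_sim = SimulationConfig(**{**asdict(sim), "seed": sim.seed + 1000})
        chip_phospho, _ = synthetic.simulate_tags(genome, phospho_sites, phospho_sim)

        emit("genome", "genome.fa", lambda p: io.write_fasta(p, genome.sequence))
        emit("truth_sites", "truth_sites.bed", lambda p: io.write_bed(p, [
            BedRecord(s.chrom, s.start, s.end,
                      f"site_{i}_m{s.n_motifs}" + ("_P" if s.phospho else ""),
                      s.affinity, "+") for i, s in enumerate(sites)]))
        emit("chip_total", "chip_total.bedGraph",
             lambda p: io.write_bedgraph(p, chip_total))
        emit("chip_phospho", "chip_phospho.bedGraph",
             lambda p: io.write_bedgraph(p, chip_phospho))
        emit("input", "input.bedGraph", lambda p: io.write_bedgraph(p, inp))

        # ---- call peaks ---------------------------------------------
        stage = "callpeaks"
        caller_kwargs = dict(config.caller)
        caller_kwargs.setdefault(
            "nb_size", window_nb_size(sim.nb_size, CallerConfig().window_bp))
        caller = CallerConfig(**caller_kwargs)
        peaks_total, log_total = peakcalling.call_peaks(chip_total, inp, caller,
                                                        label="total")
        peaks_phospho, log_phospho = peakcalling.call_peaks(chip_phospho, inp,
                                                            caller, label="phospho")
        emit("peaks_total", "peaks_total.bed",
             lambda p: io.write_peaks_bed(p, peaks_total))
        emit("peaks_phospho", "peaks_phospho.bed",
             lambda p: io.write_peaks_bed(p, peaks_phospho))
        for nm, log in (("windows_total", log_total), ("windows_phospho", log_phospho)):
            df = pd.DataFrame([(w.chrom, w.start, w.end, w.k_chip, w.k_input,
                                w.mu, w.z) for w in log],
                              columns=["chrom", "start", "end", "k_chip",
                                       "k_input", "mu", "z"])
            emit(nm, f"{nm}.tsv",
                 lambda p, d=df: d.to_csv(p, sep="\t", index=False,
                                          float_format="%.6g"))
        summary["n_peaks_total"] = len(peaks_total)
        summary["n_peaks_phospho"] = len(peaks_phospho)

        # ---- compare -------------------------------------------------
        stage = "compare"
        shared, shared_frac = features.intersect_peaks(peaks_phospho, peaks_total)
        emit("shared_peaks", "shared_peaks.bed",
             lambda p: io.write_peaks_bed(p, shared))
        summary["shared_fraction"] = shared_frac

        cov_total_on_total = features.peak_coverage(chip_total, peaks_total)
        cov_phospho_on_total = features.peak_coverage(chip_phospho, peaks_total)
        if len(peaks_total) >= 3:
            summary["r2_all_peaks"] = features.linear_r2(
                cov_total_on_total, cov_phospho_on_total)
        shared_on_total, _ = features.intersect_peaks(peaks_total, peaks_phospho)
        if len(shared_on_total) >= 1:
            cov_shared = features.peak_coverage(chip_total, shared_on_total)
            wt = features.wilcoxon_rank_sum(cov_shared, cov_total_on_total)
            summary["wilcoxon_shared_vs_all_p"] = wt.pvalue
            summary["wilcoxon_method"] = wt.method

        threshold = features.pwm_threshold(pwm, config.pwm_p_cutoff)
        hits = []
        for chrom in genome.chrom_names:
            hits.extend(features.scan_motifs(genome.sequence[chrom], pwm,
                                             threshold, chrom=chrom))
        emit("motifs", "motifs.bed", lambda p: io.write_bed(p, [
            BedRecord(h.chrom, h.start, h.end, "motif", h.score, h.strand)
            for h in hits]))
        motif_counts = features.count_motifs_in_peaks(hits, peaks_total)
        summary["median_motifs_per_peak"] = float(np.median(motif_counts)) \
            if len(motif_counts) else None

        genes = synthetic.simulate_genes(genome, config.n_genes,
                                         seed=seeds["genes"])
        dist, background = features.annotate_peaks(
            peaks_total, genes, chrom_lengths=genome.lengths)
        summary["feature_fractions"] = dist.fractions
        summary["feature_background"] = background.fractions if background else None
        cov = peakcalling.normalized_coverage(chip_total, inp, bin_bp=100)
        cov_bp = {c: np.repeat(v, 100)[:L] for (c, v), L in
                  zip(cov.items(), genome.chrom_lengths)}
        profile, n_skipped = features.metagene_profile(cov_bp, genes)
        emit("metagene", "metagene.tsv", lambda p: pd.DataFrame(
            {"bin": np.arange(len(profile)), "mean_coverage": profile}
        ).to_csv(p, sep="\t", index=False, float_format="%.6g"))
        summary["metagene_genes_skipped"] = n_skipped

        # ---- insulation ---------------------------------------------
        stage = "insulation"
        cm = synthetic.simulate_contact_matrix(
            config.contact_bins, config.contact_resolution_bp,
            sim.tad_boundaries, sim.boundary_depletion, sim.decay_exponent,
            config.contact_depth, seed=seeds["contacts"])
        emit("contact_matrix", "contact_matrix.tsv",
             lambda p: io.write_matrix(p, cm))
        norm = insulation.sqrt_coverage_normalize(cm)
        track = insulation.insulation_score(norm)

        def _write_insulation(path) -> None:
            chrom, rstart, _ = cm.region
            with open(path, "w") as fh:
                for i in np.flatnonzero(track.valid):
                    s = rstart + int(i) * cm.resolution_bp
                    fh.write(f"{chrom}\t{s}\t{s + cm.resolution_bp}\t"
                             f"{track.values[i]:.6g}\n")

        emit("insulation", "insulation.bedGraph", _write_insulation)
        bounds = insulation.delta_and_boundaries(track)
        emit("boundaries", "boundaries.bed", lambda p: io.write_bed(p, [
            BedRecord(cm.region[0], b.bin * cm.resolution_bp,
                      (b.bin + 1) * cm.resolution_bp, f"boundary_{k}",
                      b.strength, ".") for k, b in enumerate(bounds)]))
        left, right = sim.tad_boundaries[0], sim.tad_boundaries[-1]
        tad = insulation.tad_score(track, left, right)
        emit("tad_score", "tad_score.json", lambda p: io.write_json(p, {
            "left_bin": tad.left_bin, "right_bin": tad.right_bin,
            "tad_score": tad.tad_score,
            "detected_boundaries": [(b.bin, b.strength) for b in bounds]}))
        summary["tad_score"] = tad.tad_score
        summary["n_boundaries_detected"] = len(bounds)

        # ---- report --------------------------------------------------
        stage = "report"
        reads = synthetic.simulate_codon_reads(
            config.n_codon_reads, config.codon_mutant_fraction,
            config.codon_error_rate, seed=seeds["codon"])
        emit("codon_reads", "codon_reads.tsv",
             lambda p: reads.to_csv(p, sep="\t", index=False))
        tally = features.classify_codon_reads(reads)
        summary["glutamate_fraction"] = tally.glutamate_fraction

        de = synthetic.simulate_de_table(config.de_n_up, config.de_n_down,
                                         config.de_n_null, seed=seeds["de"],
                                         alpha=config.de_alpha)
        emit("de_table", "de_table.tsv",
             lambda p: de.to_csv(p, sep="\t", index=False, float_format="%.8g"))
        fr = report.report_de_fractions(de, alpha=config.de_alpha)
        summary["de"] = {"n_total": fr.n_total, "n_up": fr.n_up,
                         "n_down": fr.n_down, "pct_up": fr.pct_up,
                         "pct_down": fr.pct_down}
        # open-parameter values are logged on every run
        summary["config_logged"] = {
            "nb_size": caller.nb_size, "pseudocount": caller.pseudocount,
            "promoter_bp": 1000, "strength_floor": 0.1,
            "pwm_p_cutoff": config.pwm_p_cutoff}
        emit("report", "report.json", lambda p: io.write_json(p, summary))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        partial = {"failed_stage": stage, "outputs": outputs}
        io.write_json(outdir / "manifest.json", partial)
        raise StageError(stage, exc, partial) from exc

    checksums = {rel: _sha256(outdir / rel) for rel in outputs.values()}
    manifest = RunManifest(__version__, asdict(config), seeds, outputs,
                           checksums, summary)
    io.write_json(outdir / "manifest.json", asdict(manifest))
    return manifest
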