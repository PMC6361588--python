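"""Replicated simulation experiments over the synthetic bench.

Each function runs one of the package's standard parameter-recovery or
calibration designs end to end and returns the measured quantities.  These
designs define the study conditions under which the pipeline is validated:
a null genome for caller calibration, planted sites for recovery, a scaled
track plus NB noise for the R² design, a planted mean shift for the
rank-sum design, and graded boundary depletion for the TAD-score contract.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import features, insulation, peakcalling, synthetic
from .peakcalling import CallerConfig, window_nb_size
from .synthetic import SimulationConfig


def null_calibration(n_reps: int = 10, genome_length: int = 10_000_000,
                     seed: int = 100) -> dict:
    """Call windows on ChIP/input pairs with no planted sites.

    Returns the number of windows at z >= 6 and the exceedance rates at
    z in {2, 3} with their standard-normal expectations.
    """
    n6 = n2 = n3 = ntot = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(seed=seed + rep, n_sites=0)
        genome = synthetic.GenomeModel(["chr1"], [genome_length])
        chip, inp = synthetic.simulate_tags(genome, [], cfg)
        caller = CallerConfig(nb_size=window_nb_size(cfg.nb_size, 1000))
        wins = peakcalling.call_windows(chip, inp, caller, return_all=True)
        z = np.array([w.z for w in wins])
        ntot += len(z)
        n6 += int((z >= 6).sum())
        n2 += int((z >= 2).sum())
        n3 += int((z >= 3).sum())
    return {"n_windows": ntot, "z6_count": n6,
            "rate_z2": n2 / ntot, "rate_z3": n3 / ntot,
            "expected_z2": float(stats.norm.sf(2)),
            "expected_z3": float(stats.norm.sf(3))}


def overlaps_site(peak, site) -> bool:
    return (peak.chrom == site.chrom and peak.start < site.end
            and peak.end > site.start)


def site_recovery(n_seeds: int = 5, n_sites: int = 50,
                  genome_length: int = 2_000_000, seed: int = 0) -> dict:
    """Recovery of planted sites by the default caller.

    Returns the fraction of sites overlapped by a called peak and the
    maximum number of false peaks (peaks overlapping no site) per seed.
    """
    recovered = total = 0
    false_counts = []
    for rep in range(n_seeds):
        cfg = SimulationConfig(seed=seed + rep, n_sites=n_sites)
        pwm = features.ctcf_like_pwm()
        genome = synthetic.generate_genome(1, genome_length, 0.42,
                                           seed=seed + rep)
        genome, sites = synthetic.plant_sites(genome, pwm, cfg)
        chip, inp = synthetic.simulate_tags(genome, sites, cfg)
        caller = CallerConfig(nb_size=window_nb_size(cfg.nb_size, 1000))
        peaks, _ = peakcalling.call_peaks(chip, inp, caller)
        recovered += sum(any(overlaps_site(p, s) for p in peaks) for s in sites)
        total += len(sites)
        false_counts.append(sum(not any(overlaps_site(p, s) for s in sites)
                                for p in peaks))
    return {"recovered_fraction": recovered / total,
            "n_sites": total, "max_false_peaks": max(false_counts),
            "false_peaks_per_seed": false_counts}


def r2_recovery(n_peaks: int = 900, slope: float = 1.2,
                noise_size: float = 5.0, seed: int = 0) -> dict:
    """R² parameter-recovery design.

    Per-peak coverage x is drawn like site tag counts; y = slope*x + NB
    noise.  The constructed variance fraction Var(slope*x)/Var(y) is
    computed from the realized components and compared with linear_r2.
    """
    rng = np.random.default_rng(seed)
    affinity = rng.uniform(4.0, 16.0, size=n_peaks)
    mean_x = affinity * 200.0
    x = rng.negative_binomial(50, 50 / (50 + mean_x)).astype(float)
    noise_mean = 800.0
    noise = rng.negative_binomial(
        noise_size, noise_size / (noise_size + noise_mean), size=n_peaks
    ).astype(float)
    y = slope * x + noise
    target = float(np.var(slope * x) / np.var(y))
    return {"r2": features.linear_r2(x, y), "target": target,
            "n": n_peaks, "abs_error": abs(features.linear_r2(x, y) - target)}


def wilcoxon_shift_design(n_peaks: int = 250, shift: float = 1.6,
                          seed: int = 0) -> float:
    """Two-sided rank-sum p for shared-vs-all coverage with a planted
    multiplicative mean shift (the stronger-binding-subset design)."""
    rng = np.random.default_rng(seed)
    all_cov = rng.negative_binomial(10, 10 / (10 + 1000.0), size=n_peaks).astype(float)
    shared = rng.negative_binomial(10, 10 / (10 + shift * 1000.0),
                                   size=n_peaks).astype(float)
    return features.wilcoxon_rank_sum(shared, all_cov).pvalue


def wilcoxon_null_pvalues(n_reps: int = 200, n: int = 30, seed: int = 0) -> np.ndarray:
    """Rank-sum p-values over replicate null draws (both samples from the
    same distribution); should be approximately uniform."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        a = rng.negative_binomial(10, 10 / (10 + 1000.0), size=n).astype(float)
        b = rng.negative_binomial(10, 10 / (10 + 1000.0), size=n).astype(float)
        out[i] = features.wilcoxon_rank_sum(a, b).pvalue
    return out


def tad_score_vs_depletion(depletions=(0.1, 0.25, 0.4, 0.6, 0.8),
                           n_bins: int = 58, boundaries=(20, 38),
                           depth: float = 2000.0, n_seeds: int = 3,
                           seed: int = 0) -> list[float]:
    """Mean TAD score at each boundary-depletion level (weaker boundary =
    depletion closer to 1 = lower score expected)."""
    scores = []
    for depletion in depletions:
        vals = []
        for rep in range(n_seeds):
            cm = synthetic.simulate_contact_matrix(
                n_bins, 25_000, boundaries, depletion, 1.0, depth,
                seed=seed + 31 * rep + int(depletion * 1000))
            norm = insulation.sqrt_coverage_normalize(cm)
            track = insulation.insulation_score(norm)
            vals.append(insulation.tad_score(track, boundaries[0],
                                             boundaries[1]).tad_score)
        scores.append(float(np.mean(vals)))
    return scores
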