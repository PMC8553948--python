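"""Monte-Carlo calibration of HRC class distributions.

Pairs of pseudo-haploid individuals are simulated at fixed identity-by-
descent copy probabilities k — 0 (unrelated), 0.125 (2nd-degree) and
0.25 (1st-degree), the kinship coefficients realized in pseudo-haploid
sampling.  Per locus, individual x draws allele1 with probability
freq1; with probability k, y copies x's allele (IBD), otherwise y draws
independently from the same frequency.  Under this model the expected
multilocus HRC equals k for any non-fixed frequency spectrum, because
the estimator is frequency-corrected.

From the simulated distributions the module derives, per SNP count:
normal fits per class, threshold-crossing false-positive rates, and
posterior class probabilities for observed HRC estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SimulationRangeError
from .estimator import (CLASS_FIRST, CLASS_SECOND, CLASS_UNRELATED,
                        THRESHOLD_SECOND_FIRST, THRESHOLD_UNRELATED_SECOND)
from .panel import FrequencyPanel

log = logging.getLogger(__name__)

#: IBD-copy probability per canonical relatedness class.
CLASS_K = {CLASS_UNRELATED: 0.0, CLASS_SECOND: 0.125, CLASS_FIRST: 0.25}
K_LABELS = {v: k for k, v in CLASS_K.items()}

#: Hard-threshold HRC band per class k: [low, high).
CLASS_BANDS = {
    0.0: (-np.inf, THRESHOLD_UNRELATED_SECOND),
    0.125: (THRESHOLD_UNRELATED_SECOND, THRESHOLD_SECOND_FIRST),
    0.25: (THRESHOLD_SECOND_FIRST, np.inf),
}

#: Default SNP-count grid for calibration.
DEFAULT_SNP_GRID = (1_000, 2_500, 5_000, 10_000, 15_000, 20_000, 30_000)


@dataclass
class ClassDistributions:
    """Simulated HRC samples per relatedness class at one SNP count."""

    snp_count: int
    n_pairs: int
    samples: dict[float, np.ndarray]          # k -> hrc values, length n_pairs
    fitted: dict[float, tuple[float, float]]  # k -> (mean, sd)
    fit_kind: str = "normal"


def simulate_pair(panel_freqs: Sequence[float], k: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one pseudo-haploid pair at IBD-copy probability `k`.

    Returns two int8 vectors; 1 means the individual carries allele1.
    """
    f = np.asarray(panel_freqs, dtype=float)
    if not np.all((f > 0.0) & (f < 1.0)):
        raise ValueError("all panel frequencies must be strictly inside (0,1)")
    if not (0.0 <= k <= 1.0):
        raise ValueError(f"IBD-copy probability must be in [0,1], got {k}")
    x = (rng.random(f.size) < f).astype(np.int8)
    copy = rng.random(f.size) < k
    y_indep = (rng.random(f.size) < f).astype(np.int8)
    y = np.where(copy, x, y_indep)
    return x, y


def hrc_of_vectors(x: np.ndarray, y: np.ndarray, panel_freqs: Sequence[float],
                   mode: str = "mean_of_ratios") -> float:
    """Multilocus HRC of two simulated allele-indicator vectors.

    Same pseudo-haploid reduction as :func:`kinpile.estimator.pairwise_hrc`
    — per-locus ``(I - p)/(1 - p)`` in each direction, averaged — applied
    directly to 0/1 carrier vectors for speed.
    """
    f = np.asarray(panel_freqs, dtype=float)
    fx = np.where(x == 1, f, 1.0 - f)
    fy = np.where(y == 1, f, 1.0 - f)
    ident = (x == y).astype(float)
    if mode == "mean_of_ratios":
        return float(np.mean(0.5 * ((ident - fx) / (1.0 - fx) + (ident - fy) / (1.0 - fy))))
    if mode == "ratio_of_sums":
        r_xy = (ident - fx).sum() / (1.0 - fx).sum()
        r_yx = (ident - fy).sum() / (1.0 - fy).sum()
        return float(0.5 * (r_xy + r_yx))
    raise ValueError(f"unknown mode: {mode!r}")


def build_distributions(panel: FrequencyPanel | Sequence[float],
                        snp_counts: Sequence[int], n_pairs: int, seed: int,
                        classes: Sequence[float] = (0.0, 0.125, 0.25),
                        mode: str = "mean_of_ratios",
                        fit: str = "normal") -> dict[int, ClassDistributions]:
    """Simulate class distributions for each SNP count.

    Each simulated pair draws a fresh random locus subset from the panel
    (distribution width then reflects both locus and genotype sampling,
    as in real pairs which overlap different loci), then a genotype pair
    at its class's k.  Deterministic per seed.
    """
    freqs = (panel.loci["freq1"].to_numpy(dtype=float)
             if isinstance(panel, FrequencyPanel) else np.asarray(panel, dtype=float))
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    out: dict[int, ClassDistributions] = {}
    root = np.random.SeedSequence(seed)
    count_seeds = root.spawn(len(snp_counts))
    for count, count_ss in zip(snp_counts, count_seeds):
        if count > freqs.size:
            raise ValueError(f"snp_count {count} exceeds panel size {freqs.size}")
        samples: dict[float, np.ndarray] = {}
        fitted: dict[float, tuple[float, float]] = {}
        for k, class_ss in zip(classes, count_ss.spawn(len(classes))):
            rng = np.random.default_rng(class_ss)
            vals = np.empty(n_pairs)
            for i in range(n_pairs):
                subset = rng.choice(freqs.size, size=count, replace=False)
                f = freqs[subset]
                x, y = simulate_pair(f, k, rng)
                vals[i] = hrc_of_vectors(x, y, f, mode=mode)
            samples[k] = vals
            fitted[k] = (float(vals.mean()), float(vals.std(ddof=1)))
        out[count] = ClassDistributions(count, n_pairs, samples, fitted, fit_kind=fit)
    return out


def false_positive_rate(dist: ClassDistributions, class_k: float) -> float:
    """Fraction of a class's simulated HRC values outside its own band.

    Bands are the hard-threshold intervals: unrelated (-inf, 0.0625),
    2nd-degree [0.0625, 0.1875), 1st-degree [0.1875, inf).
    """
    if class_k not in dist.samples:
        raise KeyError(f"class k={class_k} not simulated")
    lo, hi = CLASS_BANDS[class_k]
    s = dist.samples[class_k]
    return float(np.mean((s < lo) | (s >= hi)))


def posterior(hrc: float, dist: ClassDistributions,
              priors: dict[float, float] | None = None) -> dict[str, float]:
    """Posterior class probabilities for an HRC estimate (equal priors).

    Each class's likelihood is the density of `hrc` under its fitted
    distribution; posteriors are likelihoods (times priors) renormalized
    to sum to 1.  If every density underflows the estimate lies outside
    all simulated ranges and no posterior can be assigned.
    """
    ks = sorted(dist.samples)
    if priors is None:
        priors = {k: 1.0 / len(ks) for k in ks}
    dens = {}
    for k in ks:
        if dist.fit_kind == "kde":
            dens[k] = float(stats.gaussian_kde(dist.samples[k])(hrc)[0]) * priors[k]
        else:
            mean, sd = dist.fitted[k]
            dens[k] = float(stats.norm.pdf(hrc, mean, sd)) * priors[k]
    total = sum(dens.values())
    if not np.isfinite(total) or total <= 0.0:
        raise SimulationRangeError(
            f"estimate {hrc:.4f} outside simulated range at {dist.snp_count} SNPs")
    return {K_LABELS[k]: dens[k] / total for k in ks}


def nearest_distributions(dists: dict[int, ClassDistributions],
                          n_snps: int) -> ClassDistributions:
    """Distribution set at the simulated SNP count nearest to `n_snps`."""
    if not dists:
        raise ValueError("no simulated distributions supplied")
    best = min(dists, key=lambda c: (abs(c - n_snps), c))
    if best != n_snps:
        log.info("using simulated distributions at %d SNPs for a pair with %d SNPs",
                 best, n_snps)
    return dists[best]


def save_distributions(dists: dict[int, ClassDistributions], path: str | Path) -> None:
    """Write simulated samples as long-format TSV (snp_count, k, pair, hrc)."""
    frames = []
    for count in sorted(dists):
        d = dists[count]
        for k, vals in d.samples.items():
            frames.append(pd.DataFrame({
                "snp_count": count, "k": k,
                "pair": np.arange(len(vals)), "hrc": vals}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.17g")


def load_distributions(path: str | Path) -> dict[int, ClassDistributions]:
    """Reload distributions written by :func:`save_distributions`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = {}
    for count, grp in df.groupby("snp_count"):
        samples = {float(k): sub["hrc"].to_numpy() for k, sub in grp.groupby("k")}
        fitted = {k: (float(v.mean()), float(v.std(ddof=1))) for k, v in samples.items()}
        n_pairs = len(next(iter(samples.values())))
        out[int(count)] = ClassDistributions(int(count), n_pairs, samples, fitted)
    return out


def plot_distributions(dists: dict[int, ClassDistributions],
                       path: str | Path) -> None:
    """Distribution-range plot: one row per SNP count, normal curve per class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = sorted(dists)
    fig, axes = plt.subplots(len(counts), 1, figsize=(7, 1.8 * len(counts)),
                             sharex=True, squeeze=False)
    colors = {0.0: "tab:gray", 0.125: "tab:orange", 0.25: "tab:red"}
    grid = np.linspace(-0.15, 0.45, 600)
    for ax, count in zip(axes[:, 0], counts):
        d = dists[count]
        for k in sorted(d.samples):
            mean, sd = d.fitted[k]
            ax.plot(grid, stats.norm.pdf(grid, mean, sd),
                    color=colors.get(k, "tab:blue"),
                    label=K_LABELS.get(k, f"k={k}"))
        for t in (THRESHOLD_UNRELATED_SECOND, THRESHOLD_SECOND_FIRST):
            ax.axvline(t, color="k", lw=0.6, ls="--")
        ax.set_ylabel(f"{count:,} SNPs", fontsize=8)
        ax.set_yticks([])
    axes[0, 0].legend(fontsize=8)
    axes[-1, 0].set_xlabel("HRC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
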