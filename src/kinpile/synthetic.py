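"""Synthetic data generators: frequency panels, pedigreed cohorts, pileups.

Everything downstream is testable without external downloads: panels
emulate a genome-wide set of non-fixed biallelic SNPs, cohorts carry a
known-truth pair structure generated under the simulator's IBD-copy
model, and pileup text emulates ultra-low-coverage shotgun data over the
panel positions.

The default frequency spectrum is uniform on [0.001, 0.999].  Its
per-locus estimator variance (~8) matches the variance scale observed
with genome-wide population panels, so false-positive-rate calibration
curves built on it land on the published scale (roughly 48% at 1,000
SNPs falling below 1% by 15,000).  A symmetric beta spectrum
(default alpha=beta=0.5) is available for heavier rare-variant tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import PseudoHaploidTable
from .panel import FrequencyPanel
from .simulate import simulate_pair

log = logging.getLogger(__name__)

FREQ_FLOOR = 0.001  # truncation bounds keeping every locus non-fixed
BASES = np.array(list("ACGT"))


@dataclass
class CohortTruth:
    """Known-truth pair structure of a synthetic cohort."""

    pairs: list[tuple[str, str, float]]  # (id_x, id_y, true IBD-copy probability)
    panel_ref: FrequencyPanel


def gen_freq_panel(n_loci: int, spectrum: str = "uniform",
                   alpha: float = 0.5, beta: float = 0.5,
                   seed: int = 0, chrom: str = "1") -> FrequencyPanel:
    """Generate a synthetic non-fixed biallelic frequency panel.

    Frequencies are drawn from the chosen spectrum and truncated to
    [0.001, 0.999]; alleles are random distinct bases; SNP ids encode
    position as ``chrom_pos``.  Deterministic per seed.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    if spectrum == "uniform":
        freqs = rng.uniform(0.0, 1.0, n_loci)
    elif spectrum == "beta":
        if alpha <= 0 or beta <= 0:
            raise ValueError(f"invalid beta spectrum parameters: alpha={alpha}, beta={beta}")
        freqs = rng.beta(alpha, beta, n_loci)
    else:
        raise ValueError(f"unknown spectrum: {spectrum!r}")
    freqs = np.clip(freqs, FREQ_FLOOR, 1.0 - FREQ_FLOOR)
    a1_idx = rng.integers(0, 4, n_loci)
    a2_idx = (a1_idx + rng.integers(1, 4, n_loci)) % 4
    pos = np.arange(1, n_loci + 1) * 100  # spaced, 1-based
    ids = [f"{chrom}_{p}" for p in pos]
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "id": ids,
                       "allele1": BASES[a1_idx], "allele2": BASES[a2_idx],
                       "freq1": freqs}).set_index("id")
    return FrequencyPanel(df)


def _vector_to_table(individual_id: str, vec: np.ndarray, panel: FrequencyPanel,
                     missing_mask: np.ndarray | None) -> PseudoHaploidTable:
    alleles = np.where(vec == 1, panel.loci["allele1"].to_numpy(),
                       panel.loci["allele2"].to_numpy())
    keep = np.ones(len(panel), dtype=bool) if missing_mask is None else ~missing_mask
    calls = pd.Series(alleles[keep], index=panel.ids[keep], dtype=object)
    return PseudoHaploidTable(individual_id, calls)


def gen_cohort(panel: FrequencyPanel, pairs: list[tuple[str, str, float]],
               missing_rate: float = 0.0, seed: int = 0,
               singles: tuple[str, ...] = ()
               ) -> tuple[dict[str, PseudoHaploidTable], CohortTruth]:
    """Generate a cohort with known pairwise relatedness truth.

    Each listed pair is generated jointly under the IBD-copy model at its
    true k; `singles` and all cross-pair combinations are unrelated by
    construction.  Calls are masked to missing independently per
    individual at `missing_rate`.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError(f"missing_rate must be in [0,1): {missing_rate}")
    seen_pairs: dict[frozenset, float] = {}
    seen_ids: set[str] = set()
    for id_x, id_y, k in pairs:
        key = frozenset((id_x, id_y))
        if key in seen_pairs:
            raise ValueError(f"pair {id_x}/{id_y} listed more than once")
        if not (0.0 <= k <= 1.0):
            raise ValueError(f"true k for pair {id_x}/{id_y} outside [0,1]: {k}")
        if id_x in seen_ids or id_y in seen_ids or id_x == id_y:
            raise ValueError(f"individual ids must be unique across pairs ({id_x}, {id_y})")
        seen_pairs[key] = k
        seen_ids.update((id_x, id_y))
    for s in singles:
        if s in seen_ids:
            raise ValueError(f"single {s!r} already used in a pair")
        seen_ids.add(s)

    rng = np.random.default_rng(seed)
    freqs = panel.loci["freq1"].to_numpy(dtype=float)
    tables: dict[str, PseudoHaploidTable] = {}

    def mask() -> np.ndarray | None:
        if missing_rate == 0.0:
            return None
        return rng.random(len(panel)) < missing_rate

    for id_x, id_y, k in pairs:
        x, y = simulate_pair(freqs, k, rng)
        tables[id_x] = _vector_to_table(id_x, x, panel, mask())
        tables[id_y] = _vector_to_table(id_y, y, panel, mask())
    for s in singles:
        v = (rng.random(len(panel)) < freqs).astype(np.int8)
        tables[s] = _vector_to_table(s, v, panel, mask())
    return tables, CohortTruth(list(pairs), panel)


def gen_pileup(table: PseudoHaploidTable, panel: FrequencyPanel,
               depth_mean: float = 1.0, error_rate: float = 0.0,
               seed: int = 0, constant_depth: int | None = None,
               base_quality: int = 37) -> str:
    """Emit samtools-mpileup-style text for one individual's calls.

    Depths are Poisson(`depth_mean`) per called locus (or fixed at
    `constant_depth`); zero-depth loci are omitted, as mpileup does.
    Each read shows the individual's allele except with probability
    `error_rate`, when it shows one of the three other bases uniformly.
    Qualities are constant at `base_quality` (Phred).
    """
    if depth_mean <= 0 and constant_depth is None:
        raise ValueError("depth_mean must be > 0")
    if not (0.0 <= error_rate <= 0.25):
        raise ValueError(f"error_rate must be in [0, 0.25]: {error_rate}")
    rng = np.random.default_rng(seed)
    qual_char = chr(33 + base_quality)
    sub = panel.loci.loc[panel.ids.intersection(table.calls.index)]
    order = np.argsort(sub["pos"].to_numpy(), kind="stable")
    sub = sub.iloc[order]
    calls = table.calls.loc[sub.index]
    if constant_depth is not None:
        depths = np.full(len(sub), constant_depth)
    else:
        depths = rng.poisson(depth_mean, len(sub))
    lines = []
    base_to_idx = {b: i for i, b in enumerate("ACGT")}
    for (lid, row), call, depth in zip(sub.iterrows(), calls, depths):
        if depth == 0:
            continue
        reads = []
        for _ in range(depth):
            if error_rate > 0.0 and rng.random() < error_rate:
                shift = int(rng.integers(1, 4))
                reads.append("ACGT"[(base_to_idx[call] + shift) % 4])
            else:
                reads.append(call)
        lines.append(f"{row['chrom']}\t{int(row['pos'])}\t{row['allele1']}\t"
                     f"{len(reads)}\t{''.join(reads)}\t{qual_char * len(reads)}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    """Write the cohort truth table as TSV (id_x, id_y, true_k)."""
    pd.DataFrame(truth.pairs, columns=["id_x", "id_y", "true_k"]).to_csv(
        path, sep="\t", index=False)
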