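"""Pairwise relatedness estimation from pseudo-haploid genotypes.

The estimator is Queller & Goodnight's frequency-weighted relatedness
coefficient.  For individuals x (alleles a, b) and y (alleles c, d) at
one locus, with population frequencies p:

    r_{xy,l} = (0.5*(Iac + Iad + Ibc + Ibd) - pa - pb) / (1 + Iab - pa - pb)

where I are allele-identity indicators.  The estimate is direction-
dependent; the symmetric per-locus value averages r_{xy,l} and r_{yx,l}.

On pseudo-haploid data (a=b, c=d) the formula reduces to
(I - p_a) / (1 - p_a), and the expected multilocus coefficient is half
the diploid relatedness coefficient — hence "halved relatedness
coefficient" (HRC): 0.25 for 1st-degree pairs, 0.125 for 2nd-degree,
0 for unrelated.  Hard classification thresholds sit at the class
mid-points, 0.1875 and 0.0625, with estimates in [0.0625, ~0.090)
reported as "2nd- or 3rd-degree" because 3rd-degree pairs (expected
HRC 0.0625) overlap that band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EstimatorError, NoOverlapError
from .genotypes import PseudoHaploidTable
from .panel import FrequencyPanel

log = logging.getLogger(__name__)

#: Hard class boundaries: mid-points between expected class HRC values.
THRESHOLD_UNRELATED_SECOND = 0.0625
THRESHOLD_SECOND_FIRST = 0.1875
#: Upper edge of the cautionary "2nd- or 3rd-degree" band.
SECOND_OR_THIRD_UPPER = 0.090

CLASS_UNRELATED = "unrelated"
CLASS_SECOND_OR_THIRD = "second_or_third_degree"
CLASS_SECOND = "second_degree"
CLASS_FIRST = "first_degree"

#: SNP-count confidence tiers (lower bounds).
TIER_HIGH_SNPS = 18_000
TIER_MEDIUM_SNPS = 11_000
TIER_LOW_SNPS = 4_000


def rxy_locus(a: str, b: str, c: str, d: str, p: Mapping[str, float]) -> float:
    """One-direction Queller–Goodnight value at a single locus.

    `a`, `b` are individual x's alleles; `c`, `d` individual y's; `p`
    maps each allele to its population frequency, strictly inside (0,1).
    """
    for allele in (a, b, c, d):
        freq = p[allele]
        if not (0.0 < freq < 1.0):
            raise EstimatorError(f"frequency of allele {allele!r} not in (0,1): {freq}")
    iac, iad = float(a == c), float(a == d)
    ibc, ibd = float(b == c), float(b == d)
    iab = float(a == b)
    den = 1.0 + iab - p[a] - p[b]
    if den == 0.0:
        raise EstimatorError(f"zero denominator at locus with alleles {a}{b}/{c}{d}")
    return (0.5 * (iac + iad + ibc + ibd) - p[a] - p[b]) / den


@dataclass
class PairedLoci:
    """Per-pair working set: overlapping non-missing calls with frequencies.

    ``freq_x``/``freq_y`` are the population frequencies of the allele
    each individual carries at the locus (allele2 carriers get
    ``1 - freq1``).
    """

    id_x: str
    id_y: str
    locus_ids: np.ndarray
    allele_x: np.ndarray
    allele_y: np.ndarray
    freq_x: np.ndarray
    freq_y: np.ndarray

    @property
    def n(self) -> int:
        return len(self.locus_ids)


@dataclass
class PairwiseResult:
    """Classified HRC estimate for one pair of individuals."""

    id_x: str
    id_y: str
    hrc: float
    n_snps: int
    class_label: str
    confidence_tier: str
    hrc_raw: float | None = None      # pre-normalization value, when normalized
    posteriors: dict[str, float] | None = None


def pair_loci(table_x: PseudoHaploidTable, table_y: PseudoHaploidTable,
              panel: FrequencyPanel) -> PairedLoci:
    """Intersect two call tables over the panel and attach frequencies.

    Calls whose allele is not one of the panel's two alleles at the locus
    are excluded (warning-logged); the result contains only loci
    non-missing in both individuals.
    """
    common = table_x.calls.index.intersection(table_y.calls.index)
    common = common.intersection(panel.ids)
    sub = panel.loci.loc[common]
    ax = table_x.calls.loc[common].to_numpy(dtype="U1")
    ay = table_y.calls.loc[common].to_numpy(dtype="U1")
    a1 = sub["allele1"].to_numpy(dtype="U1")
    a2 = sub["allele2"].to_numpy(dtype="U1")
    f1 = sub["freq1"].to_numpy(dtype=float)
    ok = ((ax == a1) | (ax == a2)) & ((ay == a1) | (ay == a2))
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("pair %s/%s: %d overlapping calls with off-panel alleles excluded",
                    table_x.individual_id, table_y.individual_id, n_bad)
    fx = np.where(ax == a1, f1, 1.0 - f1)[ok]
    fy = np.where(ay == a1, f1, 1.0 - f1)[ok]
    return PairedLoci(table_x.individual_id, table_y.individual_id,
                      common.to_numpy()[ok], ax[ok], ay[ok], fx, fy)


def pairwise_hrc(pair: PairedLoci, mode: str = "mean_of_ratios") -> PairwiseResult:
    """Multilocus HRC for one pair of pseudo-haploid individuals.

    Per locus the two directional Queller–Goodnight values (pseudo-
    haploid reduction ``(I - p)/(1 - p)``, each direction weighted by its
    own carrier frequency) are averaged.  ``mean_of_ratios`` (default)
    averages the symmetric per-locus values across loci;
    ``ratio_of_sums`` accumulates numerators and denominators separately
    per direction, forms the two multilocus ratios, and averages them.
    """
    if pair.n == 0:
        raise NoOverlapError(f"no overlapping SNPs for pair {pair.id_x}/{pair.id_y}")
    ident = (pair.allele_x == pair.allele_y).astype(float)
    if mode == "mean_of_ratios":
        rxy = (ident - pair.freq_x) / (1.0 - pair.freq_x)
        ryx = (ident - pair.freq_y) / (1.0 - pair.freq_y)
        hrc = float(np.mean(0.5 * (rxy + ryx)))
    elif mode == "ratio_of_sums":
        r_xy = (ident - pair.freq_x).sum() / (1.0 - pair.freq_x).sum()
        r_yx = (ident - pair.freq_y).sum() / (1.0 - pair.freq_y).sum()
        hrc = float(0.5 * (r_xy + r_yx))
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return PairwiseResult(pair.id_x, pair.id_y, hrc, pair.n,
                          classify(hrc), confidence_tier(pair.n))


def classify(hrc: float,
             t_unrel: float = THRESHOLD_UNRELATED_SECOND,
             t_band3: float = SECOND_OR_THIRD_UPPER,
             t_first: float = THRESHOLD_SECOND_FIRST) -> str:
    """Hard-threshold relatedness class of an HRC value.

    Boundary values assign to the higher-relatedness class (an HRC of
    exactly 0.1875 is 1st-degree) — conservative for downstream
    relative-exclusion workflows.
    """
    if not np.isfinite(hrc):
        raise EstimatorError(f"non-finite HRC: {hrc}")
    if not (0.0 < t_unrel < t_band3 < t_first):
        raise ValueError("thresholds must satisfy 0 < t_unrel < t_band3 < t_first")
    if hrc >= t_first:
        return CLASS_FIRST
    if hrc >= t_band3:
        return CLASS_SECOND
    if hrc >= t_unrel:
        return CLASS_SECOND_OR_THIRD
    return CLASS_UNRELATED


def confidence_tier(n_snps: int) -> str:
    """Confidence tier from the number of overlapping SNPs.

    high (>=18,000): all classes reliably assigned; medium (>=11,000):
    no false-positive related calls expected, false negatives possible;
    low (>=4,000): 1st-degree pairs still detectable as related;
    below_threshold otherwise (reported with a warning).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if n_snps >= TIER_HIGH_SNPS:
        return "high"
    if n_snps >= TIER_MEDIUM_SNPS:
        return "medium"
    if n_snps >= TIER_LOW_SNPS:
        return "low"
    return "below_threshold"


def compare_pair(table_x: PseudoHaploidTable, table_y: PseudoHaploidTable,
                 panel: FrequencyPanel, mode: str = "mean_of_ratios") -> PairwiseResult:
    """Convenience: intersect, estimate and classify in one call."""
    return pairwise_hrc(pair_loci(table_x, table_y, panel), mode=mode)


def normalize_unrelated(results: Sequence[PairwiseResult],
                        known_unrelated: Sequence[tuple[str, str]]
                        ) -> list[PairwiseResult]:
    """Correct HRC estimates by the mean of known-unrelated pairs.

    When the frequency panel poorly matches the test population's
    ancestry, all estimates shift upward; subtracting the average HRC of
    pairs known to be unrelated restores them to their expected ranges.
    Returns new results with ``hrc`` corrected (re-classified) and the
    original value kept in ``hrc_raw``.
    """
    if not known_unrelated:
        raise ValueError("known_unrelated must be non-empty")
    by_pair = {frozenset((r.id_x, r.id_y)): r for r in results}
    baseline = []
    for id_a, id_b in known_unrelated:
        key = frozenset((id_a, id_b))
        if key not in by_pair:
            raise KeyError(f"known-unrelated pair {id_a}/{id_b} not found in results")
        baseline.append(by_pair[key].hrc)
    shift = float(np.mean(baseline))
    log.info("normalization: subtracting known-unrelated mean HRC %.4f "
             "(%d pairs)", shift, len(baseline))
    out = []
    for r in results:
        corrected = r.hrc - shift
        out.append(replace(r, hrc=corrected, hrc_raw=r.hrc,
                           class_label=classify(corrected)))
    return out


def results_to_frame(results: Sequence[PairwiseResult]) -> pd.DataFrame:
    """Tabulate results (one row per pair) for reporting."""
    rows = []
    for r in results:
        row = {"id_x": r.id_x, "id_y": r.id_y, "n_snps": r.n_snps,
               "hrc": r.hrc if r.hrc_raw is None else r.hrc_raw,
               "hrc_normalized": r.hrc if r.hrc_raw is not None else np.nan,
               "class_label": r.class_label, "confidence_tier": r.confidence_tier}
        for label in (CLASS_UNRELATED, CLASS_SECOND, CLASS_FIRST):
            row[f"p_{label}"] = (r.posteriors or {}).get(label, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
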