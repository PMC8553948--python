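"""End-to-end pairwise-relatedness runs: calling, estimation, reporting.

Three consecutive steps: (1) pseudo-haploid calling from pileup text
(skipped entirely when PLINK genotypes are supplied), (2) per-pair
intersection of non-missing calls with panel frequencies, (3) HRC
estimation, classification and confidence tiering, with optional
known-unrelated normalization and simulation-based posteriors.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import KinpileError, NoOverlapError
from .estimator import (PairwiseResult, compare_pair, normalize_unrelated,
                        results_to_frame)
from .genotypes import PseudoHaploidTable, read_plink_text
from .panel import FrequencyPanel, load_frequency_panel
from .pileup import DEFAULT_MIN_BASE_QUALITY, call_pileup
from .simulate import load_distributions, nearest_distributions, posterior

log = logging.getLogger(__name__)

REPORT_COLUMNS = ["id_x", "id_y", "n_snps", "hrc", "hrc_normalized",
                  "class_label", "confidence_tier",
                  "p_unrelated", "p_second_degree", "p_first_degree"]


@dataclass
class RunConfig:
    """Configuration of one relatedness run."""

    panel: Path
    out_dir: Path
    pileups: list[Path] = field(default_factory=list)
    plink_prefix: Path | None = None
    plink_fmt: str = "tped"
    mode: str = "mean_of_ratios"
    t_unrel: float = 0.0625
    t_band3: float = 0.090
    t_first: float = 0.1875
    seed: int = 0
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY
    known_unrelated: list[tuple[str, str]] = field(default_factory=list)
    distributions: Path | None = None
    pairs_restrict: list[tuple[str, str]] | None = None
    threads: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.t_unrel < self.t_band3 < self.t_first):
            raise ValueError("thresholds must satisfy 0 < t_unrel < t_band3 < t_first")


def _individual_id(path: Path) -> str:
    stem = path.name
    for suffix in (".pileup", ".txt", ".gz"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return stem


def _load_tables(config: RunConfig, panel: FrequencyPanel
                 ) -> dict[str, PseudoHaploidTable]:
    if config.plink_prefix is not None:
        log.info("PLINK input supplied: starting from the pairwise step "
                 "(pileup calling skipped)")
        return read_plink_text(config.plink_prefix, config.plink_fmt, panel,
                               seed=config.seed)
    tables: dict[str, PseudoHaploidTable] = {}
    root = np.random.SeedSequence(config.seed)
    for path, ss in zip(config.pileups, root.spawn(len(config.pileups))):
        iid = _individual_id(Path(path))
        tables[iid] = call_pileup(Path(path), panel, iid,
                                  min_base_quality=config.min_base_quality,
                                  seed=np.random.default_rng(ss))
        log.info("called %s: %d pseudo-haploid genotypes", iid, tables[iid].n_calls)
    return tables


def run_relate(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the path of the TSV report.

    The report holds one row per pair (sorted by HRC descending, NA rows
    for zero-overlap pairs last) and a header recording seed, panel hash
    and version for reproducibility.
    """
    panel_path = Path(config.panel)
    if not panel_path.exists():
        raise FileNotFoundError(f"panel file not found: {panel_path}")
    panel = load_frequency_panel(panel_path)
    tables = _load_tables(config, panel)
    if len(tables) < 2:
        raise KinpileError(f"need >= 2 individuals, got {len(tables)}")

    pair_ids = list(itertools.combinations(sorted(tables), 2))
    if config.pairs_restrict is not None:
        wanted = {frozenset(p) for p in config.pairs_restrict}
        pair_ids = [p for p in pair_ids if frozenset(p) in wanted]

    def one_pair(ids: tuple[str, str]) -> PairwiseResult | tuple[str, str]:
        try:
            res = compare_pair(tables[ids[0]], tables[ids[1]], panel,
                               mode=config.mode)
        except NoOverlapError:
            log.warning("pair %s/%s has no overlapping SNPs; reported as NA",
                        ids[0], ids[1])
            return ids
        log.info("pair %s/%s: %d SNPs, HRC %.4f", ids[0], ids[1],
                 res.n_snps, res.hrc)
        return res

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            outcomes = list(pool.map(one_pair, pair_ids))
    else:
        outcomes = [one_pair(p) for p in pair_ids]
    results = [o for o in outcomes if isinstance(o, PairwiseResult)]
    na_pairs = [o for o in outcomes if not isinstance(o, PairwiseResult)]

    if config.known_unrelated:
        results = normalize_unrelated(results, config.known_unrelated)
    if config.distributions is not None:
        dists = load_distributions(config.distributions)
        for r in results:
            r.posteriors = posterior(r.hrc, nearest_distributions(dists, r.n_snps))

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / "relatedness_report.tsv"
    panel_md5 = hashlib.md5(panel_path.read_bytes()).hexdigest()

    frame = results_to_frame(results)
    if len(frame):
        frame = frame.sort_values(["hrc", "id_x", "id_y"],
                                  ascending=[False, True, True])
    with open(report_path, "w") as fh:
        fh.write(f"# kinpile {__version__} | seed={config.seed} | "
                 f"panel_md5={panel_md5} | mode={config.mode}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for _, row in frame.iterrows():
            fields = []
            for col in REPORT_COLUMNS:
                v = row[col]
                if isinstance(v, float):
                    fields.append("NA" if np.isnan(v) else f"{v:.6f}")
                else:
                    fields.append(str(v))
            fh.write("\t".join(fields) + "\n")
        for id_x, id_y in na_pairs:
            fh.write("\t".join([id_x, id_y] + ["NA"] * (len(REPORT_COLUMNS) - 2)) + "\n")
    log.info("wrote %s (%d pairs, %d NA)", report_path, len(results), len(na_pairs))
    return report_path
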