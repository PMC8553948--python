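"""Pseudo-haploid genotype tables and PLINK text I/O.

A pseudo-haploid genotype is a single allele per locus — the standard
representation for ultra-low-coverage ancient DNA, where at most one read
usually covers any given SNP.  :class:`PseudoHaploidTable` stores one
individual's non-missing calls as a pandas Series indexed by SNP id;
loci absent from the index are missing.

Diploid PLINK text input (.ped/.map or .tped/.tfam) is pseudo-
haploidized on read: homozygotes collapse to their allele, heterozygotes
are resolved by one random allele (seeded, with a logged count), and the
``0`` code or any allele not matching the panel becomes missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PlinkFormatError
from .panel import FrequencyPanel

log = logging.getLogger(__name__)

#: Missing-call sentinel (loci simply absent from ``calls``).
MISSING = None


@dataclass
class PseudoHaploidTable:
    """Single-allele calls for one individual at panel loci.

    ``calls`` holds only non-missing calls: a Series of single upper-case
    bases indexed by SNP id.  Every allele must be one of the panel's two
    alleles at that locus (enforced where tables are built).
    """

    individual_id: str
    calls: pd.Series

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PseudoHaploidTable({self.individual_id!r}, {self.n_calls} calls)"


def subsample_loci(table: PseudoHaploidTable, n: int, seed: int) -> PseudoHaploidTable:
    """Uniform random subset of `n` non-missing calls, without replacement.

    Deterministic per seed; original index order is preserved.
    """
    if n > table.n_calls:
        raise ValueError(
            f"requested {n} loci but {table.individual_id!r} has only "
            f"{table.n_calls} non-missing calls")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(table.n_calls, size=n, replace=False))
    return PseudoHaploidTable(table.individual_id, table.calls.iloc[keep])


def _resolve_genotype(a: str, b: str, a1: str, a2: str, rng: np.random.Generator,
                      counters: dict) -> str | None:
    """Collapse one diploid genotype to a pseudo-haploid call."""
    if a == "0" or b == "0":
        counters["missing"] += 1
        return MISSING
    if a not in (a1, a2) or b not in (a1, a2):
        counters["off_panel"] += 1
        return MISSING
    if a == b:
        return a
    counters["het"] += 1
    return a if rng.integers(2) == 0 else b


def read_plink_text(path_prefix: str | Path, fmt: str, panel: FrequencyPanel,
                    seed: int = 0) -> dict[str, PseudoHaploidTable]:
    """Read PLINK text genotypes (.ped/.map or .tped/.tfam), one table per individual.

    Heterozygous genotypes are pseudo-haploidized by a seeded random
    allele draw (count logged); alleles absent from the panel and the
    ``0`` missing code become missing; loci whose id is not in the panel
    are dropped with a logged count.
    """
    prefix = Path(path_prefix)
    rng = np.random.default_rng(seed)
    if fmt == "ped":
        tables = _read_ped(prefix, panel, rng)
    elif fmt == "tped":
        tables = _read_tped(prefix, panel, rng)
    else:
        raise ValueError(f"unsupported PLINK format: {fmt!r}")
    return tables


def _read_locus_ids(map_path: Path) -> list[str]:
    ids = []
    with open(map_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                continue
            if len(tokens) < 4:
                raise PlinkFormatError(f"{map_path}, line {lineno}: expected 4 columns")
            ids.append(tokens[1])
    return ids


def _finalize(individual_id: str, locus_ids: list[str], alleles: list[str | None],
              panel: FrequencyPanel, counters: dict) -> PseudoHaploidTable:
    in_panel = panel.ids
    data = {lid: al for lid, al in zip(locus_ids, alleles) if al is not None}
    series = pd.Series(data, dtype=object)
    keep = series.index.isin(in_panel)
    counters["dropped_loci"] += int((~keep).sum())
    return PseudoHaploidTable(individual_id, series[keep])


def _read_ped(prefix: Path, panel: FrequencyPanel, rng: np.random.Generator
              ) -> dict[str, PseudoHaploidTable]:
    locus_ids = _read_locus_ids(prefix.with_suffix(".map"))
    counters = {"het": 0, "missing": 0, "off_panel": 0, "dropped_loci": 0}
    panel_alleles = {lid: panel.alleles_of(lid) for lid in locus_ids if lid in panel.ids}
    tables: dict[str, PseudoHaploidTable] = {}
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                continue
            if len(tokens) != 6 + 2 * len(locus_ids):
                raise PlinkFormatError(
                    f"{prefix.with_suffix('.ped')}, line {lineno}: expected "
                    f"{6 + 2 * len(locus_ids)} fields (2 alleles per locus), got {len(tokens)}")
            iid = tokens[1]
            alleles: list[str | None] = []
            for j, lid in enumerate(locus_ids):
                a, b = tokens[6 + 2 * j].upper(), tokens[7 + 2 * j].upper()
                if lid not in panel_alleles:
                    alleles.append(MISSING)
                    continue
                a1, a2 = panel_alleles[lid]
                alleles.append(_resolve_genotype(a, b, a1, a2, rng, counters))
            tables[iid] = _finalize(iid, locus_ids, alleles, panel, counters)
    _log_counters(prefix, counters)
    return tables


def _read_tped(prefix: Path, panel: FrequencyPanel, rng: np.random.Generator
               ) -> dict[str, PseudoHaploidTable]:
    tfam = prefix.with_suffix(".tfam")
    iids = []
    with open(tfam) as fh:
        for raw in fh:
            tokens = raw.split()
            if tokens:
                iids.append(tokens[1])
    counters = {"het": 0, "missing": 0, "off_panel": 0, "dropped_loci": 0}
    locus_ids: list[str] = []
    per_ind: list[list[str | None]] = [[] for _ in iids]
    with open(prefix.with_suffix(".tped")) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                continue
            if len(tokens) != 4 + 2 * len(iids):
                raise PlinkFormatError(
                    f"{prefix.with_suffix('.tped')}, line {lineno}: expected "
                    f"{4 + 2 * len(iids)} fields (2 alleles per individual), got {len(tokens)}")
            lid = tokens[1]
            locus_ids.append(lid)
            known = lid in panel.ids
            a1a2 = panel.alleles_of(lid) if known else ("", "")
            for i in range(len(iids)):
                a, b = tokens[4 + 2 * i].upper(), tokens[5 + 2 * i].upper()
                if not known:
                    per_ind[i].append(MISSING)
                    continue
                per_ind[i].append(_resolve_genotype(a, b, a1a2[0], a1a2[1], rng, counters))
    tables = {iid: _finalize(iid, locus_ids, alleles, panel, counters)
              for iid, alleles in zip(iids, per_ind)}
    _log_counters(prefix, counters)
    return tables


def _log_counters(prefix: Path, counters: dict) -> None:
    if counters["het"]:
        log.info("%s: %d heterozygous genotypes resolved to one random allele",
                 prefix.name, counters["het"])
    if counters["off_panel"]:
        log.info("%s: %d genotypes with alleles absent from the panel set missing",
                 prefix.name, counters["off_panel"])
    if counters["dropped_loci"]:
        log.info("%s: %d calls at loci absent from the panel dropped",
                 prefix.name, counters["dropped_loci"])


def write_plink_text(tables: list[PseudoHaploidTable] | dict[str, PseudoHaploidTable],
                     panel: FrequencyPanel, path_prefix: str | Path,
                     loci: list[str] | None = None) -> None:
    """Write pseudo-haploid tables as transposed PLINK text (.tped/.tfam).

    Pseudo-haploid calls are written as homozygous diploid genotypes
    (``A A``); missing loci as ``0 0``.  Loci default to the union of
    called loci, in panel order.
    """
    if isinstance(tables, dict):
        tables = list(tables.values())
    prefix = Path(path_prefix)
    if loci is None:
        called = set()
        for t in tables:
            called.update(t.calls.index)
        loci = [lid for lid in panel.ids if lid in called]
    with open(prefix.with_suffix(".tfam"), "w") as fh:
        for t in tables:
            fh.write(f"{t.individual_id} {t.individual_id} 0 0 0 -9\n")
    with open(prefix.with_suffix(".tped"), "w") as fh:
        for lid in loci:
            row = panel.loci.loc[lid]
            fields = [str(row["chrom"]), lid, "0", str(int(row["pos"]))]
            for t in tables:
                al = t.calls.get(lid)
                fields.extend([al, al] if al is not None else ["0", "0"])
            fh.write(" ".join(fields) + "\n")
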