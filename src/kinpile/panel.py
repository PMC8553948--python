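"""Population allele-frequency panels.

A :class:`FrequencyPanel` holds the reference set of non-fixed biallelic
SNPs against which pseudo-haploid genotypes are called and the pairwise
relatedness estimator is evaluated.  Each locus carries the two observed
alleles and the population frequency of the first one; the frequency of
the second is its complement.

The on-disk format is the PLINK ``.frq`` dialect: whitespace-delimited
columns ``CHR SNP A1 A2 MAF [NCHROBS]`` where ``MAF`` is read as the
frequency of ``A1`` (not folded).  An optional ``POS`` column is accepted;
when absent, 1-based positions are recovered from SNP identifiers of the
form ``chrom_pos`` (or ``chrom:pos``), the convention used by genome-wide
frequency files in this workflow.  Panels whose positions cannot be
recovered still support genotype-id matching (the PLINK input path) but
not pileup-position matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import PanelFormatError

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Columns of the panel table, in canonical order.
PANEL_COLUMNS = ("chrom", "pos", "id", "allele1", "allele2", "freq1")


@dataclass
class FrequencyPanel:
    """Biallelic, non-fixed SNP panel with population allele frequencies.

    Parameters
    ----------
    loci
        DataFrame indexed by SNP id with columns ``chrom`` (str),
        ``pos`` (int, -1 when unknown), ``allele1``/``allele2`` (single
        upper-case bases) and ``freq1`` (frequency of allele1, strictly
        inside (0, 1)).

    Invariants are checked at construction: strict biallelism over
    {A,C,G,T}, non-fixed frequencies, unique SNP ids and unique
    (chrom, pos) among loci with known positions.
    """

    loci: pd.DataFrame
    _pos_index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.loci
        missing = [c for c in ("chrom", "pos", "allele1", "allele2", "freq1") if c not in df.columns]
        if missing:
            raise PanelFormatError(f"panel table missing columns: {missing}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise PanelFormatError(f"duplicate SNP id in panel: {dup!r}")
        a1 = df["allele1"].to_numpy()
        a2 = df["allele2"].to_numpy()
        bad = [i for i, (x, y) in enumerate(zip(a1, a2))
               if x not in VALID_BASES or y not in VALID_BASES or x == y]
        if bad:
            raise PanelFormatError(
                f"{len(bad)} loci violate strict biallelism (first: {df.index[bad[0]]!r})")
        f = df["freq1"].to_numpy(dtype=float)
        if not np.all((f > 0.0) & (f < 1.0)):
            raise PanelFormatError("panel contains fixed loci (freq1 at 0 or 1)")
        known = df.loc[df["pos"] >= 0, ["chrom", "pos"]]
        if known.duplicated().any():
            row = known[known.duplicated()].iloc[0]
            raise PanelFormatError(f"duplicate (chrom,pos) in panel: ({row['chrom']},{row['pos']})")
        if len(df) == 0:
            raise PanelFormatError("empty panel")

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def ids(self) -> pd.Index:
        return self.loci.index

    def position_lookup(self, chrom: str, pos: int) -> str | None:
        """Return the SNP id at (chrom, pos), or None if absent."""
        if self._pos_index is None:
            known = self.loci["pos"] >= 0
            object.__setattr__(
                self, "_pos_index",
                {(c, p): i for c, p, i in zip(
                    self.loci.loc[known, "chrom"],
                    self.loci.loc[known, "pos"],
                    self.loci.index[known])})
        return self._pos_index.get((str(chrom), int(pos)))

    def alleles_of(self, locus_id: str) -> tuple[str, str]:
        row = self.loci.loc[locus_id]
        return row["allele1"], row["allele2"]

    def freq_of_allele(self, locus_id: str, allele: str) -> float:
        """Population frequency of `allele` at `locus_id` (either panel allele)."""
        row = self.loci.loc[locus_id]
        if allele == row["allele1"]:
            return float(row["freq1"])
        if allele == row["allele2"]:
            return 1.0 - float(row["freq1"])
        raise KeyError(f"allele {allele!r} not part of locus {locus_id!r}")


def _derive_pos(snp_id: str) -> int:
    for sep in ("_", ":"):
        if sep in snp_id:
            tail = snp_id.rsplit(sep, 1)[1]
            if tail.isdigit():
                return int(tail)
    return -1


def load_frequency_panel(path: str | Path, fmt: str = "frq") -> FrequencyPanel:
    """Load a PLINK ``.frq``-dialect allele-frequency panel.

    Loci with non-ACGT allele codes (indels ``I``/``D``, multi-base
    strings, ``0``) and fixed loci (frequency 0 or 1) are dropped with a
    logged count; a panel left empty raises :class:`PanelFormatError`.
    """
    if fmt != "frq":
        raise ValueError(f"unsupported panel format: {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    colmap = {"CHR": 0, "SNP": 1, "A1": 2, "A2": 3, "MAF": 4}
    pos_col: int | None = None
    rows: list[tuple] = []
    n_nonacgt = 0
    n_fixed = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                continue
            if lineno == 1 and tokens[0].upper() == "CHR":
                upper = [t.upper() for t in tokens]
                try:
                    colmap = {name: upper.index(name) for name in ("CHR", "SNP", "A1", "A2", "MAF")}
                except ValueError as exc:
                    raise PanelFormatError(f"line 1: unrecognized header {raw!r}") from exc
                pos_col = upper.index("POS") if "POS" in upper else None
                continue
            need = max(colmap.values()) + 1 if pos_col is None else max(max(colmap.values()), pos_col) + 1
            if len(tokens) < need:
                raise PanelFormatError(f"line {lineno}: expected >= {need} columns, got {len(tokens)}")
            chrom = tokens[colmap["CHR"]]
            snp = tokens[colmap["SNP"]]
            a1 = tokens[colmap["A1"]].upper()
            a2 = tokens[colmap["A2"]].upper()
            try:
                freq = float(tokens[colmap["MAF"]])
            except ValueError:
                raise PanelFormatError(
                    f"line {lineno}: non-numeric frequency {tokens[colmap['MAF']]!r}") from None
            if not (0.0 <= freq <= 1.0):
                raise PanelFormatError(f"line {lineno}: frequency {freq} outside [0,1]")
            if a1 not in VALID_BASES or a2 not in VALID_BASES or a1 == a2:
                n_nonacgt += 1
                continue
            if freq == 0.0 or freq == 1.0:
                n_fixed += 1
                continue
            pos = int(tokens[pos_col]) if pos_col is not None else _derive_pos(snp)
            rows.append((chrom, pos, snp, a1, a2, freq))

    if n_nonacgt:
        log.info("%s: dropped %d non-biallelic-SNP loci", path.name, n_nonacgt)
    if n_fixed:
        log.info("%s: dropped %d fixed loci", path.name, n_fixed)
    if not rows:
        raise PanelFormatError(f"{path}: no usable loci after filtering "
                               f"({n_nonacgt} non-SNP, {n_fixed} fixed)")

    df = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    dup = df["id"].duplicated()
    if dup.any():
        raise PanelFormatError(f"{path}: duplicate SNP id {df.loc[dup, 'id'].iloc[0]!r}")
    df = df.set_index("id")
    return FrequencyPanel(df)


def write_frequency_panel(panel: FrequencyPanel, path: str | Path) -> None:
    """Write a panel back to the ``.frq`` dialect (full float precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(" CHR          SNP   A1   A2          MAF\n")
        for snp, row in panel.loci.iterrows():
            fh.write(f" {row['chrom']:>3} {snp:>12} {row['allele1']:>4} {row['allele2']:>4} "
                     f"{row['freq1']:.17g}\n")
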