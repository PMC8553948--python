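"""Random pseudo-haploid calling from samtools mpileup text.

The caller reads one pileup line per covered position (chrom, 1-based
pos, reference base, depth, read bases, base qualities), discards bases
below a Phred quality floor or not matching either panel allele, and
draws one surviving base uniformly at random as the individual's
pseudo-haploid call.  Positions are matched to the panel by (chrom,pos).
"""

from __future__ import annotations

import logging
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import PileupParseError
from .genotypes import MISSING, PseudoHaploidTable
from .panel import FrequencyPanel

log = logging.getLogger(__name__)

DEFAULT_MIN_BASE_QUALITY = 30

_BASE_CHARS = frozenset("ACGTNacgtn")
_GAP_CHARS = frozenset("*#<>")


@dataclass
class PileupSite:
    chrom: str
    pos: int
    ref: str
    bases: list[str | None]  # None for deletions / reference skips
    quals: list[int]


def _expand_bases(encoded: str, ref: str, line: str) -> list[str | None]:
    """Decode the mpileup base string into one entry per read."""
    out: list[str | None] = []
    i, n = 0, len(encoded)
    ref = ref.upper()
    while i < n:
        ch = encoded[i]
        if ch == "^":           # read start; next char is mapping quality
            i += 2
            continue
        if ch == "$":           # read end marker
            i += 1
            continue
        if ch in "+-":          # indel: sign, length, sequence
            j = i + 1
            while j < n and encoded[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"malformed indel in pileup line: {line!r}")
            i = j + int(encoded[i + 1:j])
            continue
        if ch in ".,":
            out.append(ref)
        elif ch in _BASE_CHARS:
            out.append(ch.upper())
        elif ch in _GAP_CHARS:
            out.append(None)
        else:
            raise PileupParseError(f"unexpected character {ch!r} in pileup line: {line!r}")
        i += 1
    return out


def parse_pileup_line(line: str) -> PileupSite:
    """Parse one samtools mpileup text line."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise PileupParseError(f"expected >= 4 tab-separated fields: {line!r}")
    chrom, pos_s, ref = fields[0], fields[1], fields[2]
    try:
        pos = int(pos_s)
        depth = int(fields[3])
    except ValueError:
        raise PileupParseError(f"non-integer position or depth: {line!r}") from None
    if depth == 0 or len(fields) < 6:
        return PileupSite(chrom, pos, ref.upper(), [], [])
    bases = _expand_bases(fields[4], ref, line)
    quals = [ord(c) - 33 for c in fields[5]]
    if len(bases) != len(quals):
        raise PileupParseError(
            f"base/quality length mismatch ({len(bases)} vs {len(quals)}): {line!r}")
    return PileupSite(chrom, pos, ref.upper(), bases, quals)


def call_pseudo_haploid(pileup_line: str, panel: FrequencyPanel,
                        min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
                        rng: np.random.Generator | None = None
                        ) -> tuple[str, str | None] | None:
    """Random pseudo-haploid call from one pileup line.

    Returns ``(locus_id, allele)`` — allele is ``None`` (missing) when no
    base survives the quality floor and panel-allele filter — or ``None``
    when the position is not a panel locus (skipped, debug-logged).
    """
    if rng is None:
        rng = np.random.default_rng()
    site = parse_pileup_line(pileup_line)
    locus_id = panel.position_lookup(site.chrom, site.pos)
    if locus_id is None:
        log.debug("position %s:%d not in panel; skipped", site.chrom, site.pos)
        return None
    a1, a2 = panel.alleles_of(locus_id)
    survivors = [b for b, q in zip(site.bases, site.quals)
                 if b in (a1, a2) and q >= min_base_quality]
    if not survivors:
        return locus_id, MISSING
    return locus_id, survivors[int(rng.integers(len(survivors)))]


def call_pileup(source: str | Path | Iterable[str], panel: FrequencyPanel,
                individual_id: str,
                min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
                seed: int | np.random.Generator = 0) -> PseudoHaploidTable:
    """Call pseudo-haploid genotypes for one individual from pileup text.

    `source` may be a file path or an iterable of pileup lines.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_path = isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists())
    if is_path:
        fh = open(source)
        lines: Iterable[str] = fh
    else:
        fh = None
        lines = source.splitlines() if isinstance(source, str) else source
    calls: dict[str, str] = {}
    try:
        for line in lines:
            if not line.strip():
                continue
            result = call_pseudo_haploid(line, panel, min_base_quality, rng)
            if result is None:
                continue
            locus_id, allele = result
            if allele is not MISSING:
                calls[locus_id] = allele
    finally:
        if fh is not None:
            fh.close()
    return PseudoHaploidTable(individual_id, pd.Series(calls, dtype=object))


def bam_to_pileup(bam_path: str | Path, out_path: str | Path,
                  positions_bed: str | Path | None = None,
                  reference: str | Path | None = None,
                  min_mapping_quality: int = 30) -> Path:
    """Convenience wrapper: run ``samtools mpileup`` on a BAM file.

    Thin shell around the external pileup engine; the tested calling core
    consumes the resulting text.  Requires ``samtools`` on PATH.
    """
    cmd = ["samtools", "mpileup", "-B", "-q", str(min_mapping_quality)]
    if positions_bed is not None:
        cmd += ["-l", str(positions_bed)]
    if reference is not None:
        cmd += ["-f", str(reference)]
    cmd.append(str(bam_path))
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        subprocess.run(cmd, stdout=fh, check=True)
    return out_path
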