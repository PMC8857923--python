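"""Repeat-element CpG_o/e and its relation to gene body methylation.

Repeats are scored like gene bodies (per-element CpG_o/e on the extracted
genomic substring, forward strand — the statistic is reverse-complement
invariant) after three filters: element length strictly greater than a
minimum (default 50 bp), family copy number strictly greater than a minimum
(default 10, counted on the unfiltered annotation so filters commute), and
zero overlap with any gene body interval (a single shared base disqualifies).
Coordinates are BED-style 0-based half-open throughout.

The module also provides the panel-level contrasts: per-species sign of
(mean repeat − mean gene body) CpG_o/e, and Pearson correlations with named
outlier species excluded before computation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import seqstats

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int, str]  # contig, start, end, family_id

DEFAULT_MIN_LEN = 50
DEFAULT_MIN_COPIES = 10


@dataclass
class RepeatAnnotation:
    """Repeat intervals (0-based half-open) plus, optionally, the genome."""

    intervals: list[Interval]
    genome: Mapping[str, str] | None = None

    def validate(self) -> None:
        for contig, start, end, fam in self.intervals:
            if not fam:
                raise ValueError(f"empty family id at {contig}:{start}-{end}")
            if not (0 <= start < end):
                raise ValueError(f"bad interval {contig}:{start}-{end}")
            if self.genome is not None and end > len(self.genome[contig]):
                raise ValueError(f"interval {contig}:{start}-{end} exceeds contig")


@dataclass(frozen=True)
class RepeatStats:
    """Per-species repeat methylation summary."""

    species: str
    mean_repeat_cpg_oe: float
    repeat_content: float
    n_elements: int
    n_families: int
    n_undefined: int = 0


def read_bed(path: str | Path, default_family: str = "feature") -> list[Interval]:
    """Read BED intervals; the 4th column (when present) is the family id."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            fam = parts[3] if len(parts) > 3 and parts[3] else default_family
            out.append((contig, start, end, fam))
    return out


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, fam in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{fam}\n")


def _overlaps_any(iv: Interval, genes_by_contig: dict[str, np.ndarray]) -> bool:
    contig, start, end, _ = iv
    arr = genes_by_contig.get(contig)
    if arr is None or arr.size == 0:
        return False
    # arr columns: start, end (sorted by start); overlap iff start < g_end and end > g_start
    idx = np.searchsorted(arr[:, 0], end)  # genes with g_start < end
    return bool(np.any(arr[:idx, 1] > start))


def filter_repeats(
    annotation: RepeatAnnotation,
    min_len: int = DEFAULT_MIN_LEN,
    min_copies: int = DEFAULT_MIN_COPIES,
    gene_intervals: Sequence[Interval] = (),
) -> RepeatAnnotation:
    """Apply the three repeat filters (all strict; order-independent).

    Keeps elements with length > min_len, whose family occurs > min_copies
    times in the input annotation, and which share no base with any gene
    interval.  Raises with per-filter attrition counts if nothing survives.
    """
    annotation.validate()
    family_sizes = Counter(fam for _, _, _, fam in annotation.intervals)
    genes_by_contig: dict[str, np.ndarray] = {}
    for contig in {iv[0] for iv in gene_intervals}:
        rows = sorted((s, e) for c, s, e, _ in gene_intervals if c == contig)
        genes_by_contig[contig] = np.array(rows).reshape(-1, 2)
    kept: list[Interval] = []
    attrition = Counter()
    for iv in annotation.intervals:
        contig, start, end, fam = iv
        if end - start <= min_len:
            attrition["too_short"] += 1
        elif family_sizes[fam] <= min_copies:
            attrition["low_copy"] += 1
        elif _overlaps_any(iv, genes_by_contig):
            attrition["gene_overlap"] += 1
        else:
            kept.append(iv)
    if annotation.intervals and not kept:
        raise ValueError(f"no repeat elements survive filtering: {dict(attrition)}")
    logger.info("repeat filter: %d kept / %d, attrition=%s",
                len(kept), len(annotation.intervals), dict(attrition))
    return RepeatAnnotation(intervals=kept, genome=annotation.genome)


def union_coverage(intervals: Sequence[Interval]) -> int:
    """Total bases covered by the union of intervals (per-contig merge)."""
    total = 0
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end, _ in intervals:
        by_contig.setdefault(contig, []).append((start, end))
    for spans in by_contig.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def repeat_cpg_oe(
    annotation: RepeatAnnotation,
    genome: Mapping[str, str] | None = None,
    species: str = "",
) -> RepeatStats:
    """Per-element CpG_o/e on extracted substrings, averaged unweighted.

    Elements whose ratio is undefined (no C, no G, or no usable window) are
    excluded and counted.  repeat_content is union coverage over genome size.
    """
    genome = genome or annotation.genome
    if genome is None:
        raise ValueError("a genome is required to extract repeat sequences")
    if not annotation.intervals:
        raise ValueError("empty repeat annotation")
    values = []
    n_undef = 0
    for contig, start, end, _ in annotation.intervals:
        counts = seqstats.count_dinucleotides(genome[contig][start:end])
        oe = seqstats.compute_cpg_oe(counts)
        if oe is None:
            n_undef += 1
        else:
            values.append(oe)
    if n_undef:
        logger.info("%s: %d repeat elements had undefined CpG_o/e", species, n_undef)
    genome_len = sum(len(s) for s in genome.values())
    return RepeatStats(
        species=species,
        mean_repeat_cpg_oe=float(np.mean(values)) if values else float("nan"),
        repeat_content=union_coverage(annotation.intervals) / genome_len,
        n_elements=len(annotation.intervals),
        n_families=len({fam for _, _, _, fam in annotation.intervals}),
        n_undefined=n_undef,
    )


@dataclass(frozen=True)
class ContrastRecord:
    """Panel-level sign contrast of repeat vs gene-body CpG_o/e."""

    n_compared: int
    n_repeat_higher: int
    exceptions: tuple[str, ...]  # species where repeats are LOWER than gene bodies
    ties: tuple[str, ...]


def repeat_vs_gene_contrast(table: pd.DataFrame) -> ContrastRecord:
    """Count species where repeat CpG_o/e exceeds gene-body CpG_o/e.

    Uses rows of a species table carrying both means; ties count as
    non-exceptions but are flagged.
    """
    both = table.dropna(subset=["mean_gene_body_cpg_oe", "mean_repeat_cpg_oe"])
    if both.empty:
        raise ValueError("no species with both gene-body and repeat means")
    diffs = both["mean_repeat_cpg_oe"] - both["mean_gene_body_cpg_oe"]
    exceptions = tuple(both.loc[diffs < 0, "species"])
    ties = tuple(both.loc[diffs == 0, "species"])
    return ContrastRecord(
        n_compared=int(len(both)),
        n_repeat_higher=int((diffs > 0).sum()),
        exceptions=exceptions,
        ties=ties,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float, float]:
    """Pearson r with its t-statistic: (r, t, df, two-sided p).

    t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2.  Degenerate inputs (n < 3, zero
    variance, |r| = 1) raise rather than returning an unusable statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(sps.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("perfect correlation: t undefined")
    df = n - 2
    t = r * np.sqrt(df) / np.sqrt(1 - r * r)
    p = 2 * sps.t.sf(abs(t), df)
    return r, float(t), float(df), float(p)


def correlate_table(
    table: pd.DataFrame,
    x_col: str,
    y_col: str,
    exclude: Sequence[str] = (),
) -> dict:
    """Pearson correlation between two species-table columns.

    Named species are excluded before computation (and logged); rows missing
    either value are dropped.
    """
    excluded = set(exclude)
    sub = table[~table["species"].isin(excluded)].dropna(subset=[x_col, y_col])
    dropped = sorted(set(table["species"]) & excluded)
    if dropped:
        logger.info("correlation %s~%s excludes %s", y_col, x_col, dropped)
    r, t, df, p = pearson_correlation(sub[x_col].to_numpy(), sub[y_col].to_numpy())
    return {"x": x_col, "y": y_col, "n": int(len(sub)), "r": r, "t": t, "df": df,
            "p_value": p, "excluded": dropped}
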