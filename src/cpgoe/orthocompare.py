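"""Conserved-vs-nonconserved gene contrasts of CpG_o/e.

Genes shared as orthologs across a whole species panel (e.g. "ten-way
orthologs") are presumed constitutively expressed and, under gene body
methylation, should sit lower on the CpG_o/e scale than the remaining genes.
This module consumes an orthogroups table in the Orthofinder
``Orthogroups.tsv`` dialect (one row per orthogroup, one column per species,
comma-separated gene ids), derives the n-way shared gene sets, and contrasts
the two gene classes per species with a Welch two-sample t-test.  A
complementary 2x2 enrichment test asks whether shared genes are
over-represented below a CpG_o/e threshold (species median by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqstats import GeneStat

logger = logging.getLogger(__name__)

#: orthogroup id -> species -> gene ids
OrthologPartition = dict[str, dict[str, list[str]]]


@dataclass(frozen=True)
class ClassComparison:
    """Welch contrast of ortholog-shared vs remaining genes in one species."""

    species: str
    n_in: int
    n_out: int
    mean_in: float
    mean_out: float
    t_stat: float
    df: float
    p_value: float
    direction: str  # "negative" when shared genes have lower CpG_o/e


def read_orthogroups(path: str | Path, panel_species: Sequence[str] | None = None) -> OrthologPartition:
    """Parse an Orthogroups.tsv file (first column orthogroup id).

    Empty cells become empty lists; ids are whitespace-trimmed.  When
    ``panel_species`` is given, header species must all be known.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    species_cols = list(df.columns[1:])
    if panel_species is not None:
        unknown = [s for s in species_cols if s not in set(panel_species)]
        if unknown:
            raise ValueError(f"orthogroups file names unknown species: {unknown}")
    partition: OrthologPartition = {}
    for _, row in df.iterrows():
        partition[row[og_col]] = {
            sp: [g.strip() for g in row[sp].split(",") if g.strip()] for sp in species_cols
        }
    return partition


def write_orthogroups(partition: OrthologPartition, path: str | Path) -> None:
    species = sorted({sp for groups in partition.values() for sp in groups})
    rows = [
        {"Orthogroup": og, **{sp: ", ".join(genes.get(sp, [])) for sp in species}}
        for og, genes in partition.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def nway_shared_genes(
    partition: OrthologPartition, species_list: Sequence[str]
) -> dict[str, set[str]]:
    """Per-species gene sets from orthogroups represented in every listed species."""
    known = {sp for groups in partition.values() for sp in groups}
    missing = [s for s in species_list if s not in known]
    if missing:
        raise ValueError(f"species not present in partition: {missing}")
    shared: dict[str, set[str]] = {sp: set() for sp in species_list}
    for groups in partition.values():
        if all(groups.get(sp) for sp in species_list):
            for sp in species_list:
                shared[sp].update(groups[sp])
    return shared


def single_copy_shared_genes(
    partition: OrthologPartition, species_list: Sequence[str]
) -> dict[str, set[str]]:
    """As nway_shared_genes but restricted to single-copy orthogroups."""
    shared: dict[str, set[str]] = {sp: set() for sp in species_list}
    for groups in partition.values():
        if all(len(groups.get(sp, [])) == 1 for sp in species_list):
            for sp in species_list:
                shared[sp].add(groups[sp][0])
    return shared


def welch_ttest(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_ortholog_classes(
    stats: Sequence[GeneStat], shared_ids: set[str], species: str = ""
) -> ClassComparison:
    """Welch contrast of CpG_o/e between shared (in) and remaining (out) genes."""
    passing = [(s.id, s.cpg_oe) for s in stats if s.passed_filter and s.cpg_oe is not None]
    x_in = np.array([v for gid, v in passing if gid in shared_ids])
    x_out = np.array([v for gid, v in passing if gid not in shared_ids])
    if len(x_in) < 2:
        raise ValueError(f"{species or 'species'}: ortholog class has {len(x_in)} genes")
    if len(x_out) < 2:
        raise ValueError(f"{species or 'species'}: non-ortholog class has {len(x_out)} genes")
    t, df, p = welch_ttest(x_in, x_out)
    diff = float(np.mean(x_in) - np.mean(x_out))
    return ClassComparison(
        species=species,
        n_in=len(x_in),
        n_out=len(x_out),
        mean_in=float(np.mean(x_in)),
        mean_out=float(np.mean(x_out)),
        t_stat=t,
        df=df,
        p_value=p,
        direction="negative" if diff < 0 else ("positive" if diff > 0 else "zero"),
    )


def low_cpg_enrichment(
    stats: Sequence[GeneStat],
    shared_ids: set[str],
    threshold_rule: str = "species_median",
    fixed_threshold: float = 0.75,
) -> tuple[float, float]:
    """Fisher exact test: are shared genes enriched below a CpG_o/e threshold?

    Builds the 2x2 table (ortholog membership x below-threshold), returns the
    sample odds ratio (Haldane 0.5 correction when any cell is zero) and the
    two-sided Fisher exact p-value.  The threshold is the species median of
    CpG_o/e or a fixed value.
    """
    passing = [(s.id, s.cpg_oe) for s in stats if s.passed_filter and s.cpg_oe is not None]
    if not passing:
        raise ValueError("no passing genes")
    vals = np.array([v for _, v in passing])
    if threshold_rule == "species_median":
        threshold = float(np.median(vals))
    elif threshold_rule == "fixed":
        threshold = fixed_threshold
    else:
        raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    in_mask = np.array([gid in shared_ids for gid, _ in passing])
    low_mask = vals < threshold
    a = int(np.sum(in_mask & low_mask))
    b = int(np.sum(in_mask & ~low_mask))
    c = int(np.sum(~in_mask & low_mask))
    d = int(np.sum(~in_mask & ~low_mask))
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError(f"degenerate 2x2 margin for table [[{a},{b}],[{c},{d}]]")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def compare_panel(
    stats_by_species: Mapping[str, Sequence[GeneStat]],
    partition: OrthologPartition,
    species_list: Sequence[str] | None = None,
    mode: str = "nway",
) -> pd.DataFrame:
    """Per-species ortholog contrasts over a panel; one output row per species.

    ``mode`` selects the shared-gene definition: "nway" (>=1 gene per species
    per orthogroup) or "single_copy" (exactly one per species).
    """
    species = list(species_list or stats_by_species.keys())
    finder = nway_shared_genes if mode == "nway" else single_copy_shared_genes
    shared = finder(partition, species)
    rows = []
    for sp in species:
        try:
            cmp_ = compare_ortholog_classes(stats_by_species[sp], shared[sp], species=sp)
        except ValueError as exc:
            logger.warning("ortholog contrast skipped for %s: %s", sp, exc)
            continue
        rows.append(
            {
                "species": sp,
                "n_out": cmp_.n_out,
                "n_in": cmp_.n_in,
                "mean_out": cmp_.mean_out,
                "mean_in": cmp_.mean_in,
                "t_stat": cmp_.t_stat,
                "df": cmp_.df,
                "p_value": cmp_.p_value,
                "direction": cmp_.direction,
            }
        )
    return pd.DataFrame(rows)
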