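"""Cross-species comparison of CpG_o/e distributions.

Each species is summarised as a normalised histogram of its per-gene CpG_o/e
values on shared bin edges; species are then clustered hierarchically by
histogram shape, which groups taxa with similar gene body methylation
landscapes.  Panel-level queries run over a species table (one row per
species with taxonomy, mean gene-body CpG_o/e and, where surveyed, mean
repeat CpG_o/e and methylation-machinery presence flags).

A transcription of the published 76-species cnidarian survey ships with the
package (``load_species_table``), as does the ten-species ortholog contrast
table (``load_ortholog_table``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .seqstats import GeneStat, passing_values

DEFAULT_BIN_WIDTH = 0.05
DEFAULT_CEILING = 2.0
MIN_GENES = 50


def default_edges(bin_width: float = DEFAULT_BIN_WIDTH, ceiling: float = DEFAULT_CEILING) -> np.ndarray:
    n_bins = int(round(ceiling / bin_width))
    return np.linspace(0.0, ceiling, n_bins + 1)


@dataclass
class SpeciesProfile:
    """Binned, normalised CpG_o/e distribution of one species."""

    species: str
    edges: np.ndarray
    histogram: np.ndarray
    mean_cpg_oe: float
    n_genes: int
    taxon_class: str = ""
    ordinal_group: str = ""
    usable: bool = True


def bin_distribution(
    stats: Sequence[GeneStat],
    edges: np.ndarray | None = None,
    species: str = "",
    taxon_class: str = "",
    ordinal_group: str = "",
    min_genes: int = MIN_GENES,
) -> SpeciesProfile:
    """Histogram of passing genes' CpG_o/e (values above the last edge dropped).

    Frequencies are counts/total so they sum to 1; the profile mean is the
    unbinned arithmetic mean over passing genes.  Profiles built from fewer
    than ``min_genes`` genes are flagged unusable rather than raised, so a
    panel run can drop them and continue.
    """
    if edges is None:
        edges = default_edges()
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    vals = passing_values(stats)
    in_range = vals[vals <= edges[-1]]
    counts, _ = np.histogram(in_range, bins=edges)
    total = counts.sum()
    hist = counts / total if total > 0 else counts.astype(float)
    return SpeciesProfile(
        species=species,
        edges=edges,
        histogram=hist,
        mean_cpg_oe=float(np.mean(vals)) if len(vals) else float("nan"),
        n_genes=int(total),
        taxon_class=taxon_class,
        ordinal_group=ordinal_group,
        usable=total >= min_genes,
    )


def profile_distance(a: SpeciesProfile, b: SpeciesProfile, metric: str = "euclidean") -> float:
    """Distance between two histograms on identical edges."""
    if not np.array_equal(a.edges, b.edges):
        raise ValueError("profiles have mismatched bin edges")
    if metric == "euclidean":
        return float(np.linalg.norm(a.histogram - b.histogram))
    if metric == "correlation":
        r = np.corrcoef(a.histogram, b.histogram)[0, 1]
        return float(1.0 - r)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class ClusterResult:
    """Hierarchical clustering of species profiles (merge tree + leaf order)."""

    species: list[str]
    linkage: np.ndarray
    leaf_order: list[str]
    metric: str
    method: str
    profiles: list[SpeciesProfile] = field(repr=False, default_factory=list)

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.species, (int(v) for v in labels)))


def cluster_species(
    profiles: Sequence[SpeciesProfile],
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of usable species profiles by histogram shape.

    Profiles are sorted lexicographically by species name before the distance
    matrix is built, so the result is permutation-invariant and ties resolve
    deterministically.
    """
    usable = sorted((p for p in profiles if p.usable), key=lambda p: p.species)
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable profiles, got {len(usable)}")
    n = len(usable)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = profile_distance(usable[i], usable[j], metric)
    link = hierarchy.linkage(squareform(dmat, checks=False), method=method)
    order = hierarchy.leaves_list(link)
    names = [p.species for p in usable]
    return ClusterResult(
        species=names,
        linkage=link,
        leaf_order=[names[i] for i in order],
        metric=metric,
        method=method,
        profiles=list(usable),
    )


def profiles_to_frame(profiles: Sequence[SpeciesProfile]) -> pd.DataFrame:
    """Species-by-bin frequency matrix (bin midpoints as columns)."""
    if not profiles:
        return pd.DataFrame()
    edges = profiles[0].edges
    mids = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame(
        [p.histogram for p in profiles],
        index=[p.species for p in profiles],
        columns=[f"{m:.3f}" for m in mids],
    )


def plot_heatmap(result: ClusterResult, path: str | Path | None = None):
    """Render the clustered profile matrix as a heatmap (presentation by-product)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_name = {p.species: p for p in result.profiles}
    mat = np.array([by_name[s].histogram for s in result.leaf_order])
    fig, ax = plt.subplots(figsize=(8, 0.3 * len(result.leaf_order) + 2))
    edges = result.profiles[0].edges
    im = ax.imshow(mat, aspect="auto", cmap="viridis", extent=(edges[0], edges[-1], len(mat), 0))
    ax.set_yticks(np.arange(len(mat)) + 0.5, result.leaf_order, fontsize=6)
    ax.set_xlabel("CpG o/e")
    fig.colorbar(im, ax=ax, label="frequency")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Species tables (panel-level summaries)
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "species",
    "taxon_class",
    "ordinal_group",
    "mean_gene_body_cpg_oe",
    "mean_repeat_cpg_oe",
    "dnmt_absent",
    "mbd_absent",
]


def load_species_table() -> pd.DataFrame:
    """The packaged 76-species survey table (means, taxonomy, machinery flags)."""
    with resources.files("cpgoe.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df


def load_ortholog_table() -> pd.DataFrame:
    """The packaged ten-species ortholog-vs-rest contrast table."""
    with resources.files("cpgoe.data").joinpath("table2.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def panel_summary(table: pd.DataFrame, low_threshold: float = 0.75) -> dict:
    """Panel-level summary of a species table.

    Reports species/taxon counts, the extreme mean gene-body CpG_o/e values
    with the species attaining them, the count of species strictly below
    ``low_threshold`` (the conventional substantial-methylation cutoff), and
    the grand mean.
    """
    if table.empty:
        raise ValueError("empty species table")
    if table["species"].duplicated().any():
        dupes = table.loc[table["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in table: {dupes}")
    means = table["mean_gene_body_cpg_oe"]
    imin, imax = means.idxmin(), means.idxmax()
    return {
        "n_species": int(len(table)),
        "n_classes": int(table["taxon_class"].nunique()),
        "n_ordinal_groups": int(table["ordinal_group"].nunique()),
        "min_mean_cpg_oe": float(means[imin]),
        "min_species": str(table.loc[imin, "species"]),
        "max_mean_cpg_oe": float(means[imax]),
        "max_species": str(table.loc[imax, "species"]),
        "n_below_threshold": int((means < low_threshold).sum()),
        "low_threshold": float(low_threshold),
        "grand_mean": float(means.mean()),
    }
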