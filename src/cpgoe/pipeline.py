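"""Panel orchestration: scan → modality → cluster → ortho → repeats.

One YAML config drives a whole species panel.  Species-level failures are
isolated (the species is dropped with a logged reason and the run continues);
panel-level stages re-check their minimum species counts.  All outputs are
deterministic functions of (inputs, config, seed), and a JSON manifest
records parameters, seeds and per-stage attrition so any number in any
output file can be reproduced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, comparative, modality, orthocompare, repeats, seqstats

logger = logging.getLogger(__name__)


@dataclass
class SpeciesSpec:
    name: str
    fasta: str
    genome: str | None = None
    repeats_bed: str | None = None
    genes_bed: str | None = None
    taxon_class: str = ""
    ordinal_group: str = ""


@dataclass
class PanelConfig:
    species: list[SpeciesSpec]
    out_dir: str = "panel_out"
    orthogroups: str | None = None
    ortho_species: list[str] | None = None
    min_len: int = 300
    ceiling: float = 2.0
    bin_width: float = 0.05
    k_max: int = 5
    seed: int = 0
    min_height_frac: float = 0.05
    min_mass: float = 0.05
    min_separation: float = 0.10
    restarts: int = 20
    cluster_metric: str = "euclidean"
    cluster_method: str = "average"
    correlation_exclude: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ValueError("species names must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        species = [SpeciesSpec(**entry) for entry in raw.pop("species")]
        return cls(species=species, **raw)


@dataclass
class PanelResult:
    summary: pd.DataFrame
    modality: pd.DataFrame
    profiles: list[comparative.SpeciesProfile]
    cluster: comparative.ClusterResult | None
    ortho: pd.DataFrame | None
    repeat_stats: pd.DataFrame | None
    contrast: repeats.ContrastRecord | None
    correlations: list[dict]
    manifest: dict
    failed_species: dict[str, str]


def _modality_row(call: modality.ModalityCall, k_max: int) -> dict:
    row = {
        "species": call.species,
        "kde_label": call.kde_label,
        "n_modes": len(call.kde_modes),
        "mode_locations": ",".join(f"{m.location:.4f}" for m in call.kde_modes),
        "gmm_best_k": call.gmm_best_k,
        "gmm_label": call.final_label_gmm,
        "n_used": call.n_used,
    }
    for k in range(1, k_max + 1):
        row[f"bic_{k}"] = call.gmm_bic_table.get(k)
    return row


def run_panel(config: PanelConfig) -> PanelResult:
    """Run every stage over the panel, writing TSVs + manifest to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mod_cfg = modality.ModalityConfig(
        ceiling=config.ceiling,
        min_height_frac=config.min_height_frac,
        min_mass=config.min_mass,
        min_separation=config.min_separation,
        k_max=config.k_max,
        restarts=config.restarts,
        seed=config.seed,
    )
    edges = comparative.default_edges(config.bin_width, config.ceiling)

    stats_by_species: dict[str, list[seqstats.GeneStat]] = {}
    failed: dict[str, str] = {}
    attrition: dict[str, dict] = {}
    summary_rows = []
    modality_rows = []
    profiles: list[comparative.SpeciesProfile] = []
    repeat_rows = []

    for spec in config.species:
        try:
            records = seqstats.read_fasta(spec.fasta)
            stats = seqstats.profile_species(records, min_len=config.min_len,
                                             ceiling=config.ceiling)
        except (OSError, ValueError) as exc:
            logger.warning("species %s dropped: %s", spec.name, exc)
            failed[spec.name] = str(exc)
            continue
        stats_by_species[spec.name] = stats
        n_pass = sum(s.passed_filter for s in stats)
        attrition[spec.name] = {"genes_in": len(stats), "genes_passing": n_pass}
        seqstats.write_stats_tsv(stats, out / f"{spec.name}.genestats.tsv")

        call = modality.classify_species(seqstats.passing_values(stats),
                                         species=spec.name, config=mod_cfg)
        modality_rows.append(_modality_row(call, config.k_max))

        profile = comparative.bin_distribution(
            stats, edges=edges, species=spec.name,
            taxon_class=spec.taxon_class, ordinal_group=spec.ordinal_group,
        )
        profiles.append(profile)

        row = {
            "species": spec.name,
            "taxon_class": spec.taxon_class,
            "ordinal_group": spec.ordinal_group,
            "mean_gene_body_cpg_oe": profile.mean_cpg_oe,
            "mean_repeat_cpg_oe": None,
            "n_genes": profile.n_genes,
        }

        if spec.genome and spec.repeats_bed:
            try:
                genome = {r.id: r.seq for r in seqstats.read_fasta(spec.genome)}
                annot = repeats.RepeatAnnotation(
                    intervals=repeats.read_bed(spec.repeats_bed), genome=genome
                )
                gene_iv = repeats.read_bed(spec.genes_bed) if spec.genes_bed else []
                filtered = repeats.filter_repeats(annot, gene_intervals=gene_iv)
                rstats = repeats.repeat_cpg_oe(filtered, species=spec.name)
                row["mean_repeat_cpg_oe"] = rstats.mean_repeat_cpg_oe
                repeat_rows.append(
                    {
                        "species": spec.name,
                        "mean_repeat_cpg_oe": rstats.mean_repeat_cpg_oe,
                        "repeat_content": rstats.repeat_content,
                        "n_elements": rstats.n_elements,
                        "n_families": rstats.n_families,
                    }
                )
            except (OSError, ValueError, KeyError) as exc:
                logger.warning("repeat stage skipped for %s: %s", spec.name, exc)
        summary_rows.append(row)

    summary = pd.DataFrame(summary_rows)
    modality_df = pd.DataFrame(modality_rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    modality_df.to_csv(out / "modality.tsv", sep="\t", index=False)
    comparative.profiles_to_frame(profiles).to_csv(out / "profiles.tsv", sep="\t")

    cluster = None
    usable = [p for p in profiles if p.usable]
    if len(usable) >= 3:
        cluster = comparative.cluster_species(
            usable, metric=config.cluster_metric, method=config.cluster_method
        )
        pd.DataFrame({"leaf_order": cluster.leaf_order}).to_csv(
            out / "cluster_leaves.tsv", sep="\t", index=False
        )
    else:
        logger.warning("clustering skipped: %d usable profiles", len(usable))

    ortho_df = None
    if config.orthogroups:
        try:
            partition = orthocompare.read_orthogroups(
                config.orthogroups, panel_species=list(stats_by_species)
            )
            ortho_species = config.ortho_species or list(stats_by_species)
            ortho_species = [s for s in ortho_species if s in stats_by_species]
            ortho_df = orthocompare.compare_panel(stats_by_species, partition,
                                                  species_list=ortho_species)
            ortho_df.to_csv(out / "ortholog_contrast.tsv", sep="\t", index=False)
        except (OSError, ValueError) as exc:
            logger.warning("ortholog stage skipped: %s", exc)

    repeat_df = pd.DataFrame(repeat_rows) if repeat_rows else None
    contrast = None
    correlations: list[dict] = []
    if repeat_df is not None and not repeat_df.empty:
        repeat_df.to_csv(out / "repeat_stats.tsv", sep="\t", index=False)
        merged = summary.dropna(subset=["mean_repeat_cpg_oe"])
        if not merged.empty:
            contrast = repeats.repeat_vs_gene_contrast(summary)
        corr_table = summary.merge(
            repeat_df[["species", "repeat_content"]], on="species", how="inner"
        )
        for x, y in [
            ("repeat_content", "mean_gene_body_cpg_oe"),
            ("repeat_content", "mean_repeat_cpg_oe"),
            ("mean_repeat_cpg_oe", "mean_gene_body_cpg_oe"),
        ]:
            try:
                correlations.append(
                    repeats.correlate_table(corr_table, x, y,
                                            exclude=config.correlation_exclude)
                )
            except ValueError as exc:
                logger.warning("correlation %s~%s skipped: %s", y, x, exc)
        if correlations:
            pd.DataFrame(correlations).to_csv(out / "correlations.tsv", sep="\t", index=False)

    manifest = {
        "cpgoe_version": __version__,
        "seed": config.seed,
        "min_len": config.min_len,
        "ceiling": config.ceiling,
        "bin_width": config.bin_width,
        "k_max": config.k_max,
        "cluster_metric": config.cluster_metric,
        "cluster_method": config.cluster_method,
        "species_attrition": attrition,
        "failed_species": failed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PanelResult(
        summary=summary,
        modality=modality_df,
        profiles=profiles,
        cluster=cluster,
        ortho=ortho_df,
        repeat_stats=repeat_df,
        contrast=contrast,
        correlations=correlations,
        manifest=manifest,
        failed_species=failed,
    )
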