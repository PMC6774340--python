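"""End-to-end gradient analysis: QC -> binning -> bootstraps -> metrics ->
ordination -> trend table, with an optional per-landscape stratification.

The pipeline is deterministic given the configuration seed: every bootstrap
stream is a named child of the root seed, the ordination subsample is a
fixed replicate slice, and all tables are written with a fixed float format,
so identical configurations produce byte-identical report bundles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .survey import (SurveyDataset, qc_filter, read_image_table,
                     read_specimen_table, write_image_table,
                     write_specimen_table)
from .simulate import preset_config, simulate_survey, ground_truth_table
from .binning import (CoverClassPartition, partition_equal_count,
                      class_summary_table)
from .bootstrap import (SpecimenIndex, bootstrap_by_area, bootstrap_by_count,
                        class_rng)
from .metrics import (abundance_matrix, biovolume_replicates,
                      density_replicates, diversity_replicates,
                      group_density_replicates, richness_replicates)
from .ordination import bray_curtis, class_ellipses, nmds_embed, orient_axes
from .trends import ClassSummary, trend_table

log = logging.getLogger("noduleco")

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the survey study's stated values."""

    k: int = 10                     # nodule-cover classes
    min_count: int = 500            # count-rule stopping threshold
    reps: int = 1000                # bootstrap replicates per class
    area_low: float = 650.0         # m^2, area-rule window
    area_high: float = 670.0
    ci_level: float = 0.95
    altitude_min: float = 2.0       # m, QC window
    altitude_max: float = 4.0
    ord_subsample: int = 100        # replicates per class entering the nMDS
    ord_restarts: int = 16
    ord_max_iter: int = 300
    ord_tol: float = 1e-6
    shared_breakpoints: bool = False  # reuse metazoan classes for xenophyophores
    stratify_by_landscape: bool = False
    n_top_species: int = 4          # named species rows in the trend table
    n_profile_species: int = 15     # species in the per-class profile table
    exact_p: bool = True            # exact Spearman enumeration for k <= 10
    seed: int = 0
    image_table: str | None = None
    specimen_table: str | None = None
    out_dir: str | None = None

    def resolved(self) -> dict:
        # out_dir is where the echo itself lands; leaving it out keeps two
        # runs of the same analysis byte-identical wherever they are written
        d = {"noduleco_version": __version__, **asdict(self)}
        d.pop("out_dir")
        return d


def load_dataset(config: PipelineConfig) -> SurveyDataset:
    if not config.image_table or not config.specimen_table:
        raise ValueError("config must set image_table and specimen_table "
                         "(or pass a dataset to run_pipeline)")
    images = read_image_table(config.image_table)
    specimens = read_specimen_table(config.specimen_table)
    return SurveyDataset(images=images, specimens=specimens)


# ---------------------------------------------------------------------------
# stage helpers


def stock_summaries(dataset: SurveyDataset, config: PipelineConfig,
                    group: str = "metazoan",
                    partition: CoverClassPartition | None = None,
                    species_universe: tuple | None = None):
    """Count-rule bootstraps and per-class density summary for one group.

    Returns ``(partition, bootstrap sets, ClassSummary of density)``; the
    workhorse behind both the report and the parameter-recovery checks.
    """
    if partition is None:
        partition = partition_equal_count(dataset.images, dataset.specimens,
                                          k=config.k, focal_group=group)
    if species_universe is None:
        species_universe = tuple(sorted({sp.morphospecies
                                         for sp in dataset.specimens}))
    by_image: dict = {}
    for sp in dataset.specimens:
        by_image.setdefault(sp.image_id, []).append(sp)
    bsets = []
    for c in partition.classes:
        images = [im for im in dataset.images if im.image_id in set(c.image_ids)]
        specimens = [sp for iid in c.image_ids for sp in by_image.get(iid, [])]
        index = SpecimenIndex.build(images, specimens, focal_group=group,
                                    species_universe=species_universe)
        rng = class_rng(config.seed, c.class_index, "count", group)
        bsets.append(bootstrap_by_count(index, c.class_index,
                                        min_count=config.min_count,
                                        reps=config.reps, rng=rng))
    summary = ClassSummary.from_replicates(
        f"{group} density (ind m-2)",
        {b.class_index: density_replicates(b, group=group) for b in bsets},
        center="mean", level=config.ci_level)
    return partition, bsets, summary


# ---------------------------------------------------------------------------
# the full pipeline


def run_pipeline(config: PipelineConfig,
                 dataset: SurveyDataset | None = None) -> dict:
    """Execute the full gradient analysis; returns the report bundle.

    The bundle maps table names to DataFrames; when ``config.out_dir`` is
    set, each table is also written as TSV together with the resolved
    configuration, a manifest, and a run log.
    """
    stage = ["load"]
    try:
        if dataset is None:
            dataset = load_dataset(config)
        bundle = _analyse(config, dataset, stratify=True, stage=stage)
        stage[0] = "write"
        if config.out_dir:
            _write_bundle(bundle, config)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage[0]!r} failed: {exc}") from exc


def _analyse(config: PipelineConfig, dataset: SurveyDataset,
             stratify: bool, stage: list | None = None) -> dict:
    stage = stage if stage is not None else ["qc"]
    stage[0] = "qc"
    log.info("quality control: %d raw images", len(dataset.images))
    kept = qc_filter(dataset.images, config.altitude_min, config.altitude_max)
    data = dataset.subset_images(kept)
    log.info("QC kept %d images, %d specimens", len(data.images),
             len(data.specimens))
    bundle = _analyse_pooled(config, data, stage)
    if stratify and config.stratify_by_landscape:
        for landscape in sorted({im.landscape for im in data.images}):
            stage[0] = f"stratified:{landscape}"
            sub = data.subset_images(
                [im for im in data.images if im.landscape == landscape])
            sub_bundle = _analyse_pooled(config, sub, stage)
            for name, table in sub_bundle.items():
                bundle[f"{landscape}/{name}"] = table
    return bundle


def _analyse_pooled(config: PipelineConfig, data: SurveyDataset,
                    stage: list | None = None) -> dict:
    stage = stage if stage is not None else [""]
    stage[0] = "binning+bootstrap"
    universe = tuple(sorted({sp.morphospecies for sp in data.specimens}))
    # --- binning + count-rule bootstraps + standing stocks
    meta_part, meta_sets, meta_density = stock_summaries(
        data, config, "metazoan", species_universe=universe)
    xeno_part = (meta_part if config.shared_breakpoints else None)
    xeno_part, xeno_sets, xeno_density = stock_summaries(
        data, config, "xenophyophore", partition=xeno_part,
        species_universe=universe)
    covers = meta_part.mean_covers
    xeno_covers = xeno_part.mean_covers

    stage[0] = "metrics"
    summaries = [meta_density]
    per_class = {b.class_index: b for b in meta_sets}
    summaries.append(ClassSummary.from_replicates(
        "metazoan biovolume density (mL m-2)",
        {c: biovolume_replicates(b) for c, b in per_class.items()},
        center="median", level=config.ci_level))

    # --- functional groups (metazoans)
    for grouping, labels in (("life_habit", ("NA", "FM")),
                             ("feeding", ("suspension", "deposit",
                                          "predator", "scavenger"))):
        frames = {c: group_density_replicates(b, grouping)
                  for c, b in per_class.items()}
        for lab in labels:
            if all(lab in f.columns for f in frames.values()):
                summaries.append(ClassSummary.from_replicates(
                    f"{lab} metazoan density (ind m-2)",
                    {c: f[lab].to_numpy() for c, f in frames.items()},
                    center="mean", level=config.ci_level))

    # --- diversity (count-controlled, metazoans)
    div = {c: diversity_replicates(b) for c, b in per_class.items()}
    for col, name in (("S_N", "morphospecies richness (S_N)"),
                      ("expH", "exponential Shannon (exp H')"),
                      ("invD", "inverse Simpson (1/D)")):
        summaries.append(ClassSummary.from_replicates(
            name, {c: f[col].to_numpy() for c, f in div.items()},
            center="mean", level=config.ci_level))

    # --- S_A (area-controlled, metazoans)
    area_sets = []
    for c in meta_part.classes:
        index = per_class[c.class_index].index
        rng = class_rng(config.seed, c.class_index, "area", "metazoan")
        area_sets.append(bootstrap_by_area(
            index, c.class_index, area_low=config.area_low,
            area_high=config.area_high, reps=config.reps, rng=rng))
    summaries.append(ClassSummary.from_replicates(
        "morphospecies density (S_A)",
        {b.class_index: richness_replicates(b) for b in area_sets},
        center="mean", level=config.ci_level))

    # --- per-morphospecies profiles
    totals = pd.Series(0.0, index=list(universe))
    for b in meta_sets:
        totals = totals.add(pd.Series(b.abundance_matrix().sum(axis=0),
                                      index=list(universe)), fill_value=0.0)
    meta_mask = meta_sets[0].index.species_group == "metazoan"
    meta_species = [s for s, m in zip(universe, meta_mask) if m]
    ranked = totals.loc[meta_species].sort_values(ascending=False)
    profile_species = list(ranked.index[:config.n_profile_species])
    species_summaries = {}
    for s in profile_species:
        mask = np.array([name == s for name in universe])
        species_summaries[s] = ClassSummary.from_replicates(
            s, {c: density_replicates(b, species_mask=mask)
                for c, b in per_class.items()},
            center="mean", level=config.ci_level)
    summaries.extend(species_summaries[s]
                     for s in profile_species[:config.n_top_species])

    # --- ordination (count-controlled metazoan samples, subsampled)
    stage[0] = "ordination"
    m = min(config.ord_subsample, config.reps)
    sub_sets = []
    for b in meta_sets:
        sub = _subsample_set(b, m)
        sub_sets.append(sub)
    mat = abundance_matrix(sub_sets, transform="sqrt", group="metazoan")
    D = bray_curtis(mat.to_numpy())
    labels = mat.index.get_level_values("class_index").to_numpy()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(99,)))
    result = nmds_embed(D, dims=2, restarts=config.ord_restarts,
                        max_iter=config.ord_max_iter, tol=config.ord_tol,
                        rng=rng, labels=labels)
    cover_by_class = dict(zip((c.class_index for c in meta_part.classes),
                              covers))
    result = orient_axes(result, cover_by_class)
    ellipses = class_ellipses(result, level=config.ci_level)
    d1 = {c: result.coordinates[labels == c, 0]
          for c in sorted(set(labels.tolist()))}
    summaries.append(ClassSummary.from_replicates(
        "nMDS dimension 1", d1, center="mean", level=config.ci_level))

    # --- trend table
    stage[0] = "trend"
    meta_trend = trend_table(summaries, covers, exact=config.exact_p)
    xeno_trend = trend_table([xeno_density], xeno_covers,
                             exact=config.exact_p)
    trends = pd.concat([xeno_trend, meta_trend], ignore_index=True)

    # --- assemble bundle
    bundle = {
        "partition_metazoan": class_summary_table(meta_part),
        "partition_xenophyophore": class_summary_table(xeno_part),
        "class_summaries": _summaries_frame(
            summaries + [xeno_density], covers, xeno_covers,
            xeno_parameter=xeno_density.parameter),
        "trend_table": trends,
        "ordination_coords": pd.DataFrame({
            "class_index": labels,
            "replicate": mat.index.get_level_values("replicate"),
            "d1": result.coordinates[:, 0],
            "d2": result.coordinates[:, 1],
        }),
        "ordination_ellipses": pd.DataFrame([{
            "class_index": e.class_index,
            "centroid_d1": e.centroid[0],
            "centroid_d2": e.centroid[1],
            "semi_major": e.semi_axes[0],
            "semi_minor": e.semi_axes[1],
            "angle_deg": e.angle_deg,
        } for e in ellipses]),
        "ordination_info": pd.DataFrame([{
            "stress1": result.stress,
            "converged": result.converged,
            "restarts": result.restarts_used,
            "n_samples": len(labels),
        }]),
        "morphospecies_profiles": _summaries_frame(
            [species_summaries[s] for s in profile_species], covers, None),
        "bootstrap_audit": _audit_frame(meta_sets, xeno_sets),
    }
    return bundle


def _audit_frame(meta_sets, xeno_sets) -> pd.DataFrame:
    """Per-replicate statistic audit (class_index, replicate, statistic, value)."""
    rows = []
    for name, sets in (("metazoan density (ind m-2)", meta_sets),
                       ("xenophyophore density (ind m-2)", xeno_sets)):
        group = sets[0].index.focal_group
        for b in sets:
            dens = density_replicates(b, group=group)
            rows.append(pd.DataFrame({
                "class_index": b.class_index,
                "replicate": np.arange(b.reps),
                "statistic": name,
                "value": dens,
            }))
    return pd.concat(rows, ignore_index=True)


def _subsample_set(b, m: int):
    from dataclasses import replace
    return replace(
        b,
        draw_indices=b.draw_indices[:m],
        focal_counts=b.focal_counts[:m],
        total_areas=b.total_areas[:m],
        _abundance=None,
    )


def _summaries_frame(summaries, covers, xeno_covers,
                     xeno_parameter: str | None = None) -> pd.DataFrame:
    rows = []
    for s in summaries:
        use = (xeno_covers if xeno_parameter is not None
               and s.parameter == xeno_parameter else covers)
        for i, c in enumerate(s.class_index):
            rows.append({
                "parameter": s.parameter,
                "class_index": int(c),
                "mean_cover": float(np.asarray(use)[i]),
                "center_kind": s.center_kind,
                "center": float(s.center[i]),
                "ci_low": float(s.ci_low[i]),
                "ci_high": float(s.ci_high[i]),
            })
    return pd.DataFrame(rows)


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for name, table in sorted(bundle.items()):
        path = out / f"{name}.tsv"
        path.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        names.append(f"{name}.tsv")
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True))
    (out / "manifest.tsv").write_text(
        "file\n" + "\n".join(["resolved_config.yaml"] + names) + "\n")
    log.info("report bundle written to %s (%d tables)", out, len(names))


# ---------------------------------------------------------------------------
# fixtures


def generate_fixture(preset: str, seed: int = 0,
                     out_dir: str | None = None) -> SurveyDataset:
    """Simulate a preset survey; optionally write its tables + ground truth."""
    cfg = preset_config(preset, seed=seed)
    dataset = simulate_survey(cfg)
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_image_table(dataset.images, out / "images.tsv")
        write_specimen_table(dataset.specimens, out / "specimens.tsv")
        ground_truth_table(cfg.species_pool).to_csv(
            out / "ground_truth.tsv", sep="\t", index=False)
        (out / "provenance.yaml").write_text(
            yaml.safe_dump(dataset.provenance, sort_keys=True))
    return dataset
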