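"""End-to-end orchestration and command-line interface.

Runs the stages in acquisition order — simulate (or load) multiplexed
fields, align rounds and correct illumination, enhance and segment puncta,
assemble and classify synapses, extract features, embed and cluster, and
test conditions — writing CSV artifacts and a provenance log after each
stage.  Re-running with the same configuration reproduces every CSV
byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import image_processing as ip
from . import statistics as stats_mod
from . import subtype_clustering as sc
from .feature_extraction import (
    build_feature_table,
    normalize_to_untreated,
    synapse_features,
)
from .synapse_assembly import (
    Synapse,
    assemble_synapses,
    puncta_from_labels,
    size_filter,
)
from .synthetic_data import (
    ALL_TARGETS,
    ANCHOR_TARGET,
    SYNAPTIC_TARGETS,
    GroundTruth,
    MultiplexedField,
    SynthConfig,
    generate_cohort,
    load_cohort,
    write_tiff,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every stage parameter of an end-to-end run.

    Unknown keys in a config file are rejected; the full parameter set is
    echoed into ``run_config.yaml`` in the output directory for provenance.
    """

    output_dir: str = "synaptomap_run"
    seed: int = 0
    simulate: bool = True
    manifest: str | None = None
    write_images: bool = False
    # synthetic cohort (used when simulate=True); replaces SynthConfig defaults
    synth: dict = field(default_factory=dict)
    # stage toggles (each later stage requires the earlier ones)
    do_assemble: bool = True
    do_features: bool = True
    do_cluster: bool = True
    do_stats: bool = True
    # image processing
    illumination_radius: int = ip.ILLUMINATION_RADIUS
    tophat_radius: int = ip.TOPHAT_RADIUS
    trim_lo: float = 0.05
    trim_hi: float = 0.05
    k_sd: float = 2.0
    min_peak_distance: int = 3
    smoothing_sigma: float = 1.0
    # assembly
    dendrite_max_distance: float = 8.0
    # features
    feature_mode: str = "paper"
    # clustering
    subsample_quota: int = sc.DEFAULT_SUBSAMPLE_QUOTA
    correlation_cutoff: float = sc.DEFAULT_CORRELATION_CUTOFF
    min_cluster_size: int = sc.DEFAULT_MIN_CLUSTER_SIZE
    n_neighbors: int = sc.DEFAULT_N_NEIGHBORS
    min_dist: float = sc.DEFAULT_MIN_DIST
    # statistics
    n_shuffles: int = stats_mod.DEFAULT_N_SHUFFLES
    n_boot: int = stats_mod.DEFAULT_N_BOOT
    mask_bound: float = stats_mod.DEFAULT_MASK_BOUND
    pixel_size_um: float = 0.187

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def synth_config(self) -> SynthConfig:
        known = {f.name for f in dataclasses.fields(SynthConfig)}
        unknown = set(self.synth) - known
        if unknown:
            raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
        kwargs = dict(self.synth)
        kwargs.setdefault("seed", self.seed)
        return SynthConfig(**kwargs)


# --------------------------------------------------------------------------
# Per-field processing
# --------------------------------------------------------------------------


@dataclass
class ProcessedField:
    """Aligned, corrected, enhanced images and masks of one field."""

    field: MultiplexedField
    corrected: dict[str, np.ndarray]
    enhanced: dict[str, np.ndarray]
    nuclei_mask: np.ndarray
    dendrite_mask: np.ndarray


def process_field(mfield: MultiplexedField, config: RunConfig) -> ProcessedField:
    """Align rounds, correct illumination, enhance puncta, build masks."""
    aligned = ip.align_rounds(mfield)
    corrected: dict[str, np.ndarray] = {}
    for target in ALL_TARGETS:
        try:
            img = aligned.image_for(target)
        except KeyError:
            continue
        corrected[target] = ip.correct_illumination(img, config.illumination_radius)
    enhanced = {
        t: ip.white_tophat(corrected[t], config.tophat_radius)
        for t in SYNAPTIC_TARGETS
        if t in corrected
    }
    nuclei, dendrite = ip.segment_compartments(
        corrected.get("DAPI", np.zeros(aligned.shape)),
        corrected.get("MAP2", np.zeros(aligned.shape)),
        trim_lo=config.trim_lo,
        trim_hi=config.trim_hi,
        k_sd=config.k_sd,
    )
    return ProcessedField(aligned, corrected, enhanced, nuclei, dendrite)


def compute_thresholds(
    processed: list[ProcessedField], config: RunConfig
) -> dict[str, float]:
    """Per-target robust-background thresholds from untreated fields only.

    Each target's threshold is the average of per-image thresholds over
    every untreated field, then reused verbatim for treated fields so both
    groups are segmented identically.
    """
    untreated = [p for p in processed if p.field.treatment == "untreated"]
    if not untreated:
        untreated = processed
        logger.warning("no untreated fields; thresholds use all fields")
    thresholds = {}
    for target in SYNAPTIC_TARGETS:
        images = [p.enhanced[target] for p in untreated if target in p.enhanced]
        if not images:
            continue
        thresholds[target] = ip.robust_background_threshold(
            images, config.trim_lo, config.trim_hi, config.k_sd
        )
    return thresholds


def assemble_field(
    proc: ProcessedField, thresholds: dict[str, float], config: RunConfig
) -> tuple[list[Synapse], dict]:
    """Segment every target channel, apply the rules, assemble synapses."""
    puncta_by_target = {}
    for target, enhanced in proc.enhanced.items():
        objects = ip.segment_puncta(
            enhanced,
            thresholds[target],
            min_peak_distance=config.min_peak_distance,
            smoothing_sigma=config.smoothing_sigma,
            target=target,
        )
        puncta_by_target[target] = size_filter(puncta_from_labels(objects))
    synapses, counts = assemble_synapses(
        puncta_by_target,
        proc.nuclei_mask,
        proc.dendrite_mask,
        dendrite_max_distance=config.dendrite_max_distance,
    )
    mf = proc.field
    for syn in synapses:
        syn.replicate_id = mf.replicate_id
        syn.treatment = mf.treatment
        syn.field_id = mf.field_id
    counts["puncta_detected"] = sum(len(v) for v in puncta_by_target.values())
    counts["synapses"] = len(synapses)
    return synapses, counts


# --------------------------------------------------------------------------
# Orchestrated run
# --------------------------------------------------------------------------


def run(config: RunConfig, fields: list[MultiplexedField] | None = None,
        truth: GroundTruth | None = None) -> Path:
    """Execute all enabled stages; return the output directory.

    ``fields`` may be passed directly (e.g. from a generator call); when
    absent they come from simulation or from ``config.manifest``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if fields is None:
        if config.simulate:
            synth = config.synth_config()
            fields, truth, manifest = generate_cohort(
                synth, out_dir=out / "images" if config.write_images else None
            )
            manifest.to_csv(out / "manifest.csv", index=False)
            truth.synapses.to_csv(out / "ground_truth_synapses.csv", index=False)
            truth.fields.to_csv(out / "ground_truth_fields.csv", index=False)
        else:
            if not config.manifest:
                raise ValueError("manifest path required when simulate=False")
            fields = load_cohort(config.manifest, pixel_size_um=config.pixel_size_um)
            if not fields:
                raise ValueError(f"manifest {config.manifest} lists no fields")

    logger.info("processing %d fields", len(fields))
    processed = [process_field(f, config) for f in fields]
    thresholds = compute_thresholds(processed, config)
    with open(out / "thresholds.json", "w") as fh:
        json.dump({k: float(v) for k, v in thresholds.items()}, fh, indent=2,
                  sort_keys=True)

    if not config.do_assemble:
        with open(out / "run_config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
        return out

    all_synapses: list[Synapse] = []
    feature_rows = []
    density_rows = []
    stage_counts = []
    for proc in processed:
        synapses, counts = assemble_field(proc, thresholds, config)
        counts.update(
            replicate=proc.field.replicate_id, field=proc.field.field_id,
            treatment=proc.field.treatment,
        )
        stage_counts.append(counts)
        all_synapses.extend(synapses)
        for syn in synapses:
            feature_rows.append(synapse_features(syn, proc.corrected))
        class_counts = {
            label: sum(1 for s in synapses if s.class_label == label)
            for label in ("excitatory", "inhibitory", "dual", "unknown")
        }
        try:
            dens = stats_mod.synapse_density(
                class_counts, proc.dendrite_mask, config.pixel_size_um
            )
        except ValueError:
            continue
        density_rows.append(
            {
                "replicate": proc.field.replicate_id,
                "field": proc.field.field_id,
                "treatment": proc.field.treatment,
                **dens,
            }
        )
    if config.write_images:
        qc = out / "qc"
        qc.mkdir(exist_ok=True)
        for proc in processed:
            tag = f"rep{proc.field.replicate_id:02d}_field{proc.field.field_id:02d}"
            write_tiff(qc / f"{tag}_dendrite_mask.tif",
                       proc.dendrite_mask.astype(np.uint16) * 65535)
            write_tiff(qc / f"{tag}_nuclei_mask.tif",
                       proc.nuclei_mask.astype(np.uint16) * 65535)
            for t, img in proc.enhanced.items():
                write_tiff(qc / f"{tag}_enhanced_{t}.tif", img)
    pd.DataFrame(stage_counts).to_csv(out / "stage_counts.csv", index=False)
    pd.DataFrame(density_rows).to_csv(out / "field_densities.csv", index=False)

    synapse_table = pd.DataFrame(
        [
            {
                "replicate": s.replicate_id,
                "treatment": s.treatment,
                "field": s.field_id,
                "anchor_id": s.anchor.id,
                "class": s.class_label,
                "row": s.anchor.centroid[0],
                "col": s.anchor.centroid[1],
                **{
                    f"n_{t}": len(s.children_of(t))
                    for t in SYNAPTIC_TARGETS
                    if t != ANCHOR_TARGET
                },
            }
            for s in all_synapses
        ]
    )
    synapse_table.to_csv(out / "synapses.csv", index=False)

    if not config.do_features:
        with open(out / "run_config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
        return out

    table = build_feature_table(feature_rows, mode=config.feature_mode)
    table = normalize_to_untreated(table)
    table.data.to_csv(out / "features.csv", index=False)

    assignment = None
    clustered = None
    if config.do_cluster and len(table.data) >= 10:
        sub = sc.subsample_replicates(table, config.subsample_quota, config.seed)
        meta_cols = [c for c in sub.columns if "__" not in c]
        numeric = sub[[c for c in sub.columns if "__" in c]]
        pruned, dropped = sc.prune_correlated_features(
            numeric, config.correlation_cutoff
        )
        scaled, _ = sc.center_scale(pruned)
        model, coords = sc.fit_embedding(
            scaled, seed=config.seed,
            n_neighbors=config.n_neighbors, min_dist=config.min_dist,
        )
        assignment = sc.cluster_embedding(coords, config.min_cluster_size)
        clustered = sub.copy()
        clustered["umap_1"] = coords[:, 0]
        clustered["umap_2"] = coords[:, 1]
        clustered["cluster"] = assignment.labels
        clustered[meta_cols + ["umap_1", "umap_2", "cluster"]].to_csv(
            out / "embedding.csv", index=False
        )
        profiles = sc.cluster_profiles(sub, assignment)
        profiles.to_csv(out / "cluster_profiles.csv", index=False)
        with open(out / "dropped_features.json", "w") as fh:
            json.dump({"all_na": list(table.dropped_columns),
                       "correlated": dropped}, fh, indent=2)

    if config.do_stats:
        stats_table = clustered if clustered is not None else table.data
        comparisons = stats_mod.compare_conditions(
            stats_table,
            assignment=assignment,
            n_shuffles=config.n_shuffles,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        comparisons.to_csv(out / "comparisons.csv", index=False)
        if assignment is not None:
            summaries = stats_mod.cluster_correlation_matrices(
                stats_table, assignment, mask_bound=config.mask_bound
            )
            for summ in summaries:
                summ.masked.to_csv(out / f"correlation_cluster{summ.cluster_id}.csv")

    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return out


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------


def _load_config(config_path, **overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    for key, val in overrides.items():
        if val is not None:
            setattr(cfg, key, val)
    return cfg


@click.group()
def cli():
    """Multiplexed synapse phenotyping pipeline."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--out", required=True, type=click.Path())
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--fields-per-replicate", default=5, show_default=True, type=int)
@click.option("--image-size", default=256, show_default=True, type=int)
def simulate(out, seed, fields_per_replicate, image_size):
    """Generate a synthetic cohort as TIFFs + manifest + ground truth."""
    config = SynthConfig(
        seed=seed,
        fields_per_replicate=fields_per_replicate,
        image_shape=(image_size, image_size),
    )
    generate_cohort(config, out_dir=out)
    click.echo(f"cohort written to {out}")


@cli.command(name="run")
@click.option("--simulate", "do_simulate", is_flag=True, default=False)
@click.option("--manifest", type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
@click.option("--skip-cluster", is_flag=True, default=False)
@click.option("--skip-stats", is_flag=True, default=False)
def run_command(do_simulate, manifest, config_path, out, seed, skip_cluster, skip_stats):
    """Run all stages end to end (simulate or read a manifest)."""
    cfg = _load_config(config_path, output_dir=out, seed=seed, manifest=manifest)
    if do_simulate:
        cfg.simulate = True
    elif manifest:
        cfg.simulate = False
    if skip_cluster:
        cfg.do_cluster = False
    if skip_stats:
        cfg.do_stats = False
    out_dir = run(cfg)
    click.echo(f"artifacts written to {out_dir}")


def _partial_run(config_path, out, seed, manifest, **toggles):
    cfg = _load_config(config_path, output_dir=out, seed=seed, manifest=manifest)
    if manifest:
        cfg.simulate = False
    for key, val in toggles.items():
        setattr(cfg, key, val)
    return run(cfg)


@cli.command()
@click.option("--manifest", type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
def process(manifest, config_path, out, seed):
    """Align, correct, enhance, and compute thresholds only."""
    out_dir = _partial_run(config_path, out, seed, manifest,
                           do_assemble=False, do_features=False,
                           do_cluster=False, do_stats=False)
    click.echo(f"processing artifacts written to {out_dir}")


@cli.command()
@click.option("--manifest", type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
def assemble(manifest, config_path, out, seed):
    """Segment, assemble, and classify synapses without featurizing."""
    out_dir = _partial_run(config_path, out, seed, manifest,
                           do_features=False, do_cluster=False, do_stats=False)
    click.echo(f"synapse table written to {out_dir}")


@cli.command()
@click.option("--manifest", type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
def features(manifest, config_path, out, seed):
    """Process, assemble, and featurize without clustering or statistics."""
    out_dir = _partial_run(config_path, out, seed, manifest,
                           do_cluster=False, do_stats=False)
    click.echo(f"features written to {out_dir}")


@cli.command()
@click.option("--manifest", type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
def cluster(manifest, config_path, out, seed):
    """Run through embedding + clustering, skipping statistics."""
    out_dir = _partial_run(config_path, out, seed, manifest, do_stats=False)
    click.echo(f"clustering written to {out_dir}")


@cli.command()
@click.option("--manifest", type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
def stats(manifest, config_path, out, seed):
    """Full run including the statistics stage."""
    out_dir = _partial_run(config_path, out, seed, manifest)
    click.echo(f"statistics written to {out_dir}")


if __name__ == "__main__":
    cli()
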