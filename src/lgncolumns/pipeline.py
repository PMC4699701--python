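"""Pipeline orchestration: config, staged execution, tabular/JSON outputs.

All randomness flows from a single master seed in the config.  Per-use
seeds are derived from ``numpy.random.SeedSequence(master).spawn`` in a
fixed documented order: one child per group (simulation), one child per
group (order metrics), then one child for the latent scan.  Identical
config + seed therefore reproduce bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .columns import (
    DepthProfile,
    RayleighFit,
    UnitColumn,
    count_profile,
    fit_rayleigh,
    reconstruct_column,
    spread_profile,
    unitize,
)
from .core import Dataset, Group
from .errors import ConfigError, StageError
from .latents import LatentScan, assemble_profiles, pls_latent_scan
from .maps import (
    align_stack,
    build_map_stack,
    cumulative_trajectory,
    orient_stack,
)
from .order import end_to_end_order, topography_profile, topology_profile
from .synthetic import SyntheticConfig, make_columns

log = logging.getLogger("lgncolumns")

SUMMARY_VERSION = 1
STAGES = ("simulate", "reconstruct", "maps", "order", "latents", "report")


@dataclass
class GroupSpec:
    group: Group
    synthetic: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)  # cells/injections/mesh/pial files


@dataclass
class PipelineConfig:
    seed: int
    out_dir: Path
    groups: list[GroupSpec]
    n_bins: int = 20
    n_levels: int = 21
    n_perm: int = 199
    max_latents: int = 8
    folds: str | int = "loo"
    pls_orientation: str = "rows"
    reference_group: str = "WT"


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML/JSON pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if "seed" not in raw:
        raise ConfigError(f"{path}: config missing required key 'seed'")
    if "groups" not in raw or not raw["groups"]:
        raise ConfigError(f"{path}: config must list at least one group")
    groups = []
    for entry in raw["groups"]:
        try:
            group = Group(entry["group"])
        except (KeyError, ValueError):
            raise ConfigError(f"bad group entry: {entry!r}") from None
        groups.append(
            GroupSpec(
                group=group,
                synthetic=entry.get("synthetic", {}) or {},
                paths=entry.get("paths", {}) or {},
            )
        )
    pls = raw.get("pls", {})
    return PipelineConfig(
        seed=int(raw["seed"]),
        out_dir=Path(raw.get("out_dir", "results")),
        groups=groups,
        n_bins=int(raw.get("n_bins", 20)),
        n_levels=int(raw.get("n_levels", 21)),
        n_perm=int(raw.get("n_perm", 199)),
        max_latents=int(pls.get("max_latents", 8)),
        folds=pls.get("folds", "loo"),
        pls_orientation=pls.get("orientation", "rows"),
        reference_group=raw.get("reference_group", "WT"),
    )


@dataclass
class GroupResult:
    dataset: Dataset
    unit_columns: list[UnitColumn]
    paths: dict
    counts: DepthProfile
    spread: DepthProfile
    rayleigh: RayleighFit
    maps: list
    steps: list
    trajectory: object
    topology: list
    end_to_end: object
    topography: list


def _load_or_simulate(spec: GroupSpec, seed_child) -> Dataset:
    if spec.paths:
        cells = lio.read_cells(spec.paths["cells"])
        injections = lio.read_injections(spec.paths["injections"])
        mesh = lio.read_mesh(spec.paths["mesh"], spec.paths["pial"])
        dataset = Dataset(cells=cells, injections=injections, mesh=mesh, group=spec.group)
    else:
        params = dict(spec.synthetic)
        params.setdefault("seed", int(seed_child.generate_state(1)[0] % (2**31)))
        params["group"] = spec.group
        dataset, _ = make_columns(SyntheticConfig(**params))
    dataset.validate()
    return dataset


def analyze_group(
    dataset: Dataset,
    n_bins: int,
    levels: np.ndarray,
    n_perm: int,
    order_seed,
    volume_scale: float = 1.0,
) -> GroupResult:
    """Run reconstruction, maps and order metrics for one group."""
    paths, units = {}, []
    for animal in dataset.animal_ids:
        try:
            path = reconstruct_column(dataset.cells_for(animal), dataset.mesh, animal)
            units.append(unitize(dataset.cells_for(animal), path))
            paths[animal] = path
        except Exception as exc:
            raise StageError("reconstruct", animal, exc) from exc
    group_name = dataset.group.value
    counts = count_profile(units, n_bins=n_bins, group=group_name)
    spread = spread_profile(units, volume_scale=volume_scale, n_bins=n_bins, group=group_name)
    radii = np.concatenate([u.r_um[~u.clipped] for u in units])
    rayleigh = fit_rayleigh(radii[radii > 0])
    stack = build_map_stack(paths, levels)
    direction = np.mean(
        [p.ventral_point - p.pial_point for p in paths.values()], axis=0
    )
    stack = orient_stack(stack, direction)
    steps = align_stack(stack)
    trajectory = cumulative_trajectory(steps, depths=levels)
    if not isinstance(order_seed, np.random.SeedSequence):
        order_seed = np.random.SeedSequence(order_seed)
    seeds = order_seed.spawn(3)
    topo = topology_profile(stack, n_perm=n_perm, seed=seeds[0])
    ends = end_to_end_order(stack, n_perm=n_perm, seed=np.random.default_rng(seeds[1]))
    inj = {
        r.animal_id: np.array([r.ap_mm, r.ml_mm])
        for r in dataset.injections
    }
    topog = topography_profile(inj, stack, n_perm=n_perm, seed=seeds[2])
    return GroupResult(
        dataset=dataset,
        unit_columns=units,
        paths=paths,
        counts=counts,
        spread=spread,
        rayleigh=rayleigh,
        maps=stack,
        steps=steps,
        trajectory=trajectory,
        topology=topo,
        end_to_end=ends,
        topography=topog,
    )


# ---------------------------------------------------------------------------
# tabular output helpers


def _profile_frame(profile: DepthProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": profile.group,
            "kind": profile.kind,
            "bin_lo": profile.edges[:-1],
            "bin_hi": profile.edges[1:],
            "mean": profile.mean,
            "sem": profile.sem,
            "n": profile.n_columns,
        }
    )


def _order_frame(results, group: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": group,
            "comparison": [r.comparison for r in results],
            "depth": [r.depth for r in results],
            "raw_P": [r.raw_product for r in results],
            "norm_Pt": [r.normalized_pt for r in results],
            "p_value": [r.p_value for r in results],
            "n_points": [r.n_points for r in results],
            "n_perm": [r.n_perm for r in results],
        }
    )


def _round(x, nd=10):
    return float(np.round(float(x), nd))


def _summarize_group(res: GroupResult) -> dict:
    return {
        "n_columns": len(res.unit_columns),
        "n_cells": int(sum(u.n_cells for u in res.unit_columns)),
        "n_clipped": int(sum(u.n_clipped for u in res.unit_columns)),
        "mean_column_length_um": _round(
            np.mean([p.total_length_um for p in res.paths.values()])
        ),
        "profiles": {
            "counts": [_round(v) for v in res.counts.mean],
            "spread_um": [_round(v) for v in np.nan_to_num(res.spread.mean)],
            "topology_norm_pt": [_round(r.normalized_pt) for r in res.topology],
            "topography_norm_pt": [_round(r.normalized_pt) for r in res.topography],
        },
        "rayleigh_sigma_um": _round(res.rayleigh.sigma_um),
        "cumulative_rotation_rad": [
            _round(v) for v in res.trajectory.cumulative_rotation_rad
        ],
        "cumulative_expansion": [_round(v) for v in res.trajectory.cumulative_expansion],
        "end_to_end": {
            "norm_pt": _round(res.end_to_end.normalized_pt),
            "p_value": _round(res.end_to_end.p_value),
        },
    }


def run_pipeline(config: PipelineConfig | str | Path, stages=None) -> dict:
    """Execute the pipeline and write per-stage tables plus a JSON summary.

    ``stages`` selects which outputs are written (all computation that a
    requested stage depends on still runs in memory); default all.
    Returns the summary dict.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    stages = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    levels = np.round(np.linspace(0.0, 1.0, config.n_levels), 10)

    master = np.random.SeedSequence(config.seed)
    n_groups = len(config.groups)
    children = master.spawn(2 * n_groups + 1)
    sim_seeds = children[:n_groups]
    order_seeds = children[n_groups : 2 * n_groups]
    pls_seed = int(children[-1].generate_state(1)[0] % (2**31))

    t0 = time.perf_counter()
    datasets = []
    for spec, child in zip(config.groups, sim_seeds):
        try:
            datasets.append(_load_or_simulate(spec, child))
        except Exception as exc:
            raise StageError("simulate", spec.group.value, exc) from exc
    log.info("simulate: %d groups in %.2fs", n_groups, time.perf_counter() - t0)

    ref = config.reference_group
    volumes = {d.group.value: d.mesh.volume_um3 for d in datasets}
    v_ref = volumes.get(ref, next(iter(volumes.values())))

    results: dict[str, GroupResult] = {}
    for dataset, oseed in zip(datasets, order_seeds):
        t1 = time.perf_counter()
        scale = (v_ref / volumes[dataset.group.value]) ** (1.0 / 3.0)
        results[dataset.group.value] = analyze_group(
            dataset, config.n_bins, levels, config.n_perm, oseed, volume_scale=scale
        )
        log.info(
            "group %s: %d columns analysed in %.2fs",
            dataset.group.value,
            len(results[dataset.group.value].unit_columns),
            time.perf_counter() - t1,
        )

    scan: LatentScan | None = None
    if len(results) >= 1:
        matrix = assemble_profiles(
            {g: r.counts for g, r in results.items()},
            {g: r.spread for g, r in results.items()},
            {g: r.topology for g, r in results.items()},
            {g: r.topography for g, r in results.items()},
            depths=levels,
        )
        max_latents = min(config.max_latents, min(matrix.n_rows, matrix.n_levels) - 1)
        try:
            scan = pls_latent_scan(
                matrix,
                max_latents=max_latents,
                folds=config.folds,
                seed=pls_seed,
                orientation=config.pls_orientation,
            )
        except Exception as exc:
            raise StageError("latents", None, exc) from exc

    # ---- write outputs -------------------------------------------------
    for g, res in results.items():
        if "simulate" in stages and not any(s.paths for s in config.groups):
            lio.write_cells(res.dataset.cells, out / f"{g}_cells.csv")
            lio.write_injections(res.dataset.injections, out / f"{g}_injections.csv")
            lio.write_mesh(res.dataset.mesh, out / f"{g}_mesh.off", out / f"{g}_pial.txt")
        if "reconstruct" in stages:
            pd.concat(
                [_profile_frame(res.counts), _profile_frame(res.spread)]
            ).to_csv(out / f"{g}_profiles.csv", index=False)
        if "maps" in stages:
            rows = [
                {"depth": m.depth, "animal_id": a, "u_um": c[0], "v_um": c[1]}
                for m in res.maps
                for a, c in zip(m.animal_ids, m.coords)
            ]
            pd.DataFrame(rows).to_csv(out / f"{g}_maps.csv", index=False)
            pd.DataFrame(
                {
                    "depth": res.trajectory.depths,
                    "cum_theta_rad": res.trajectory.cumulative_rotation_rad,
                    "cum_expansion": res.trajectory.cumulative_expansion,
                }
            ).to_csv(out / f"{g}_trajectory.csv", index=False)
        if "order" in stages:
            frame = pd.concat(
                [
                    _order_frame(res.topology, g),
                    _order_frame([res.end_to_end], g),
                    _order_frame(res.topography, g),
                ]
            )
            frame.to_csv(out / f"{g}_order.csv", index=False)
    if scan is not None and "latents" in stages:
        pd.DataFrame(
            {
                "n_latents": scan.n_latents,
                "pct_var_explained": scan.pct_var_explained,
                "cv_mse": scan.cv_mse,
                "fold_scheme": scan.fold_scheme,
                "seed": scan.seed,
            }
        ).to_csv(out / "latent_scan.csv", index=False)

    summary = {
        "version": SUMMARY_VERSION,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "groups": {g: _summarize_group(res) for g, res in results.items()},
    }
    if scan is not None:
        summary["latents"] = {
            "n_latents": [int(n) for n in scan.n_latents],
            "pct_var_explained": [_round(v) for v in scan.pct_var_explained],
            "cv_mse": [_round(v, 12) for v in scan.cv_mse],
            "fold_scheme": scan.fold_scheme,
            "best_by_cv": scan.best_by_cv,
        }
    if "report" in stages:
        lio.write_summary_json(summary, out / "summary.json")
    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return summary
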