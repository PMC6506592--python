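"""End-to-end orchestration: synthesize -> statistics -> FST/DAPC ->
calibrate/assign/weight -> dispersal -> joint report.

A run is driven by a single YAML config with named sections (see
:func:`load_config` for the dialect) and one root seed.  Each stage writes
its outputs under ``<output_dir>/<stage>/`` before the next stage starts,
so a failed run leaves a usable manifest of completed stages, and any stage
can be re-run in isolation from the saved intermediates.  Reports are
regenerable byte-identically from the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from . import dispersal, genio, parentage, structure, synthgen
from ._rng import child_seed

log = logging.getLogger("larvorigin")


@dataclass
class RunConfig:
    """Validated run configuration (one section per pipeline stage)."""

    population_model: synthgen.PopulationModel
    cohort_spec: synthgen.CohortSpec
    parentage_config: parentage.ParentageConfig
    field_spec: synthgen.FieldSpec
    release_spec: dispersal.ReleaseSpec
    ovm_schedule: dispersal.OvmSchedule
    regions: dict[str, Polygon]
    region_mapping: dict[str, str]  # adult population -> dispersal region
    output_dir: Path = Path("out")
    seed: int = 0
    dapc_k_max: int = 6
    fst_n_perm: int = 0
    raw: dict = dc_field(default_factory=dict)


def _square_polygon(center_lon: float, center_lat: float, side_deg: float) -> Polygon:
    h = side_deg / 2.0
    return Polygon(
        [
            (center_lon - h, center_lat - h),
            (center_lon + h, center_lat - h),
            (center_lon + h, center_lat + h),
            (center_lon - h, center_lat + h),
        ]
    )


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Sections: ``population_model``, ``cohort_spec``, ``parentage``,
    ``field_spec``, ``release_spec``, ``ovm_schedule`` (list of
    [age_min, age_max, depth] bands), ``regions`` (name -> either a
    coordinate ring ``[[lon, lat], ...]`` or a square
    ``{center: [lon, lat], side_deg: s}``), ``region_mapping``
    (adult population -> region name), ``output_dir``, ``seed``.
    Every section is validated before any stage runs.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if seed is None:
        seed = int(raw.get("seed", 0))

    pm_raw = dict(raw.get("population_model", {}))
    pm_raw.setdefault("seed", child_seed(seed, "population_model"))
    pm = synthgen.PopulationModel(**pm_raw)

    cs_raw = dict(raw.get("cohort_spec", {}))
    if "sites" in cs_raw:
        cs_raw["sites"] = tuple(cs_raw["sites"])
    if "months" in cs_raw:
        cs_raw["months"] = tuple(cs_raw["months"])
    if "source_mixture" not in cs_raw or not cs_raw["source_mixture"]:
        cs_raw["source_mixture"] = {p: 1.0 / pm.n_pops for p in pm.pop_names}
    cs = synthgen.CohortSpec(**cs_raw)

    pc_raw = dict(raw.get("parentage", {}))
    pc_raw.setdefault("seed", child_seed(seed, "parentage"))
    pc = parentage.ParentageConfig(**pc_raw)

    fs = synthgen.FieldSpec(**raw["field_spec"]) if "field_spec" in raw else synthgen.FieldSpec(
        lon_min=-84.0, lon_max=-79.0, lat_min=22.0, lat_max=26.0,
        grid_step=0.1, t_span=30 * 86400.0, t_step=86400.0,
        pattern="double_gyre", params={"amplitude": 0.2, "period": 30 * 86400.0},
    )

    rs_raw = dict(raw.get("release_spec", {}))
    if "polygons" in rs_raw:
        rs_raw["polygons"] = {
            k: tuple(v) for k, v in rs_raw["polygons"].items()
        }
    else:
        rs_raw["polygons"] = {
            "BigMunson": (-81.387, 24.617, 64.0),
            "LongKey": (-80.84, 24.803, 64.0),
        }
    if "release_times" in rs_raw:
        rs_raw["release_times"] = tuple(float(t) for t in rs_raw["release_times"])
    rs_raw.setdefault("seed", child_seed(seed, "release"))
    rs = dispersal.ReleaseSpec(**rs_raw)

    ovm_raw = raw.get("ovm_schedule")
    ovm = (
        dispersal.OvmSchedule(tuple(tuple(b) for b in ovm_raw))
        if ovm_raw
        else dispersal.OvmSchedule(((0.0, rs.duration_days, rs.release_depth),))
    )

    regions: dict[str, Polygon] = {}
    for name, spec_r in raw.get("regions", {}).items():
        if isinstance(spec_r, Mapping):
            clon, clat = spec_r["center"]
            regions[name] = _square_polygon(clon, clat, float(spec_r["side_deg"]))
        else:
            regions[name] = Polygon([tuple(p) for p in spec_r])
    mapping = dict(raw.get("region_mapping", {}))
    for pop, region in mapping.items():
        if regions and region not in regions:
            raise ValueError(f"region_mapping points to unknown region {region!r}")

    return RunConfig(
        population_model=pm,
        cohort_spec=cs,
        parentage_config=pc,
        field_spec=fs,
        release_spec=rs,
        ovm_schedule=ovm,
        regions=regions,
        region_mapping=mapping,
        output_dir=Path(raw.get("output_dir", "out")),
        seed=seed,
        dapc_k_max=int(raw.get("dapc_k_max", 6)),
        fst_n_perm=int(raw.get("fst_n_perm", 0)),
        raw=raw,
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=True, float_format="%.10g")
    return _digest(path)


@dataclass
class RunReport:
    """Machine-readable manifest of a pipeline run."""

    config_echo: dict
    seed: int
    stages: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config_echo,
                "stages": self.stages,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
            default=str,
        )

    def to_text(self) -> str:
        lines = [f"larvorigin run (seed {self.seed})", "=" * 34]
        for stage, info in self.stages.items():
            lines.append(f"[{stage}]")
            for k, v in info.items():
                if k == "outputs":
                    for f, d in v.items():
                        lines.append(f"  out: {f}  sha256:{d}")
                else:
                    lines.append(f"  {k}: {v}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_synthesize(config: RunConfig):
    """Generate adult and postlarva genotypes plus the velocity field."""
    out = config.output_dir / "synth"
    out.mkdir(parents=True, exist_ok=True)
    freqs = synthgen.make_allele_freqs(config.population_model)
    n_pops = config.population_model.n_pops
    sizes_all = synthgen.DEFAULT_ADULT_SIZES
    if n_pops == len(sizes_all) and config.population_model.pop_names == list(sizes_all):
        n_per_pop = dict(sizes_all)
    else:
        n_per_pop = {p: 30 for p in config.population_model.pop_names}
    adults = synthgen.simulate_adults(freqs, n_per_pop, seed=child_seed(config.seed, "adults"))
    cohorts = synthgen.simulate_cohorts(
        freqs, adults, config.cohort_spec, seed=child_seed(config.seed, "cohorts")
    )
    field = synthgen.make_velocity_field(config.field_spec)
    genio.write_genepop(adults, out / "adults.gen", group_column="pop")
    genio.write_genepop(cohorts, out / "postlarvae.gen", group_column="cohort")
    synthgen.write_truth_table(cohorts, out / "truth.csv")
    field.to_netcdf(out / "field.nc")
    return freqs, adults, cohorts, field


def run_all(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order and assemble the report."""
    t0 = time.time()
    report = RunReport(config_echo=config.raw, seed=config.seed)
    out_root = config.output_dir
    log.info("run_all: output under %s, seed %d", out_root, config.seed)

    # synth ---------------------------------------------------------------
    freqs, adults, cohorts, field = stage_synthesize(config)
    synth_dir = out_root / "synth"
    report.stages["synth"] = {
        "n_adults": adults.n_individuals,
        "n_postlarvae": cohorts.n_individuals,
        "outputs": {
            f.name: _digest(f) for f in sorted(synth_dir.iterdir())
        },
    }

    # stats ---------------------------------------------------------------
    log.info("stage stats")
    summaries = genio.locus_summaries(
        adults.concat(cohorts), grouping=None, n_perm=199,
        seed=child_seed(config.seed, "hwe"),
    )
    stats_df = genio.summaries_to_frame(summaries)
    d = _write_csv(stats_df, out_root / "stats" / "locus_summaries.csv")
    obs_freqs = genio.allele_frequencies(adults, grouping="pop")
    d2 = _write_csv(obs_freqs.to_frame(), out_root / "stats" / "allele_frequencies.csv")
    report.stages["stats"] = {
        "n_loci": len(stats_df),
        "outputs": {"locus_summaries.csv": d, "allele_frequencies.csv": d2},
    }

    # fst -----------------------------------------------------------------
    log.info("stage fst")
    cohort_tables = cohorts.split_by("cohort")
    fm = structure.fst_matrix(
        cohort_tables, n_perm=config.fst_n_perm, seed=child_seed(config.seed, "fst")
    )
    d = _write_csv(fm.to_frame(), out_root / "fst" / "fst_matrix.csv")
    for name in fm.excluded:
        report.warnings.append(f"cohort {name} excluded from FST (<2 typed individuals)")
    report.stages["fst"] = {
        "n_cohorts": len(fm.labels),
        "theta_range": [float(np.min(fm.theta)), float(np.max(fm.theta))],
        "outputs": {"fst_matrix.csv": d},
    }

    # dapc ----------------------------------------------------------------
    log.info("stage dapc")
    dapc_res = structure.DAPC(
        cohorts, k_max=config.dapc_k_max, seed=child_seed(config.seed, "dapc")
    ).fit()
    comp = structure.cluster_composition(
        dapc_res, cohorts.metadata["cohort"].to_numpy()
    )
    d1 = _write_csv(dapc_res.assignments_frame(), out_root / "dapc" / "assignments.csv")
    d2 = _write_csv(
        pd.DataFrame(
            {"k": np.arange(1, len(dapc_res.bic_profile) + 1), "bic": dapc_res.bic_profile}
        ),
        out_root / "dapc" / "bic_profile.csv",
    )
    d3 = _write_csv(comp, out_root / "dapc" / "cluster_composition.csv")
    report.stages["dapc"] = {
        "selected_k": dapc_res.k,
        "n_pca": dapc_res.n_pca,
        "outputs": {
            "assignments.csv": d1, "bic_profile.csv": d2, "cluster_composition.csv": d3,
        },
    }

    # parentage -----------------------------------------------------------
    log.info("stage parentage (calibration + assignment)")
    model = parentage.ParentageModel(cohorts, adults, config.parentage_config)
    pres = model.fit()
    d1 = _write_csv(pres.assignments, out_root / "parentage" / "assignments.csv")
    weights = pres.source_weights()
    d2 = _write_csv(weights, out_root / "parentage" / "source_weights.csv")
    outs = {"assignments.csv": d1, "source_weights.csv": d2}
    if pres.confidence_curve is not None:
        d3 = _write_csv(pres.confidence_curve, out_root / "parentage" / "confidence_curve.csv")
        outs["confidence_curve.csv"] = d3
    report.stages["parentage"] = {
        "critical_lod": pres.critical_lod,
        "n_resolved": pres.n_resolved,
        "pct_resolved": round(100.0 * pres.n_resolved / cohorts.n_individuals, 2),
        "outputs": outs,
    }

    # dispersal -----------------------------------------------------------
    log.info("stage dispersal")
    traj = dispersal.track(config.release_spec, field, config.ovm_schedule)
    origins = dispersal.origin_summary(traj, config.regions) if config.regions else None
    d1 = _write_csv(traj.to_dataframe(), out_root / "dispersal" / "trajectories.csv")
    outs = {"trajectories.csv": d1}
    if origins is not None:
        d2 = _write_csv(origins.table, out_root / "dispersal" / "origins.csv")
        outs["origins.csv"] = d2
    status, counts = np.unique(traj.status, return_counts=True)
    report.stages["dispersal"] = {
        "n_particles": traj.n_particles,
        "status_counts": {
            dispersal.STATUS_NAMES[int(s)]: int(c) for s, c in zip(status, counts)
        },
        "outputs": outs,
    }

    # compare -------------------------------------------------------------
    if origins is not None and config.region_mapping:
        log.info("stage compare")
        joint = compare_methods(weights, origins, config.region_mapping)
        d = _write_csv(joint.table, out_root / "compare" / "joint.csv")
        report.stages["compare"] = {
            "rank_concordance": joint.rank_concordance,
            "unmapped": joint.unmapped,
            "outputs": {"joint.csv": d},
        }

    report.stages["timing"] = {"wall_seconds": round(time.time() - t0, 1)}
    (out_root / "report.json").write_text(report.to_json())
    (out_root / "report.txt").write_text(report.to_text())
    return report


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based, ties share the mean rank)."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rank_concordance(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rho by the explicit average-rank correlation formula."""
    rx = _average_ranks(np.asarray(x, dtype=float))
    ry = _average_ranks(np.asarray(y, dtype=float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


@dataclass
class MethodComparison:
    """Genetic weighted % joined with biophysical origin % per region."""

    table: pd.DataFrame
    rank_concordance: float
    unmapped: list[str]


def compare_methods(
    source_weights: pd.DataFrame,
    origins: "dispersal.OriginSummary",
    region_mapping: Mapping[str, str],
) -> MethodComparison:
    """Join the two methods on region names and compute rank concordance."""
    totals = (
        source_weights[source_weights["site"] == "total"]
        .set_index("population")["total_weighted"]
    )
    unmapped = [p for p in totals.index if p not in region_mapping]
    rows = []
    genetic_by_region: dict[str, float] = {}
    for pop, wt in totals.items():
        region = region_mapping.get(pop)
        if region is None:
            continue
        genetic_by_region[region] = genetic_by_region.get(region, 0.0) + float(wt)
    for region, wt in genetic_by_region.items():
        phys = float(origins.region_means.get(region, 0.0))
        rows.append((region, wt, phys))
    table = pd.DataFrame(
        rows, columns=["region", "genetic_weighted_pct", "dispersal_origin_pct"]
    )
    rho = (
        spearman_rank_concordance(
            table["genetic_weighted_pct"].to_numpy(),
            table["dispersal_origin_pct"].to_numpy(),
        )
        if len(table) >= 2
        else float("nan")
    )
    return MethodComparison(table=table, rank_concordance=rho, unmapped=unmapped)
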