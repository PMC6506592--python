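"""Synthetic genotype datasets with known truth, and analytic current fields.

Every downstream stage of the pipeline (diversity statistics, FST/DAPC,
parentage assignment, particle tracking) is exercised on data generated
here, so each generator carries an explicit truth channel: source population
and true parent id for every postlarva, and closed-form velocity patterns
for the tracker.

Population structure is emulated with the Balding-Nichols model: population
allele frequencies are Dirichlet draws around a shared ancestral frequency
vector with concentration ``(1 - F) / F``, which gives E[p] = p_anc and
Var[p] = F p_anc (1 - p_anc) — i.e. populations differentiated at FST = F.

Default scales mirror the study system: 15 adult populations genotyped at 14
microsatellite loci (sample sizes as collected, total 799) and two
settlement sites sampled monthly (~2030 postlarvae over 24 lunar months),
but every count is configurable so tests can run reduced versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .genio import MISSING, AlleleFrequencyTable, GenotypeTable
from .dispersal import VelocityField

# Adult sample sizes per population as collected in the study system
# (15 locations, total 799 adults).
DEFAULT_ADULT_SIZES: dict[str, int] = {
    "NC": 40, "BE": 49, "GOM": 16, "W-FL": 39, "DT": 50,
    "lFK": 119, "mFK": 77, "E-FL": 49, "BH": 54, "BZ": 48,
    "NI": 22, "DR": 36, "CR": 102, "SK": 49, "VZ": 49,
}

DEFAULT_SITES = ("LongKey", "BigMunson")


@dataclass
class PopulationModel:
    """Structured-population allele-frequency model (Balding-Nichols).

    ``fst_target`` may be a scalar (shared by all populations) or one value
    per population.  ``ancestral_freqs`` is one simplex vector per locus;
    allele codes are assigned 1..K per locus.
    """

    n_pops: int
    n_loci: int = 14
    alleles_per_locus: list[int] | None = None
    ancestral_freqs: list[np.ndarray] | None = None
    fst_target: float | Sequence[float] = 0.05
    pop_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_loci < 1:
            raise ValueError("n_pops and n_loci must be positive")
        if self.pop_names is None:
            self.pop_names = [f"pop{i + 1}" for i in range(self.n_pops)]
        if len(self.pop_names) != self.n_pops:
            raise ValueError("pop_names length must equal n_pops")
        if self.alleles_per_locus is None:
            rng = child_rng(self.seed, "alleles_per_locus")
            self.alleles_per_locus = [int(k) for k in rng.integers(8, 13, self.n_loci)]
        if len(self.alleles_per_locus) != self.n_loci:
            raise ValueError("alleles_per_locus length must equal n_loci")
        if any(k < 1 for k in self.alleles_per_locus):
            raise ValueError("alleles_per_locus must be >= 1")
        if self.ancestral_freqs is None:
            rng = child_rng(self.seed, "ancestral_freqs")
            self.ancestral_freqs = [
                rng.dirichlet(np.ones(k)) for k in self.alleles_per_locus
            ]
        if len(self.ancestral_freqs) != self.n_loci:
            raise ValueError("ancestral_freqs length must equal n_loci")
        for j, vec in enumerate(self.ancestral_freqs):
            vec = np.asarray(vec, dtype=float)
            if abs(vec.sum() - 1.0) > 1e-12 or np.any(vec < 0):
                raise ValueError(f"ancestral frequency vector {j} is not a simplex")
            self.ancestral_freqs[j] = vec
        fst = np.broadcast_to(np.asarray(self.fst_target, dtype=float), (self.n_pops,))
        if np.any(fst < 0) or np.any(fst >= 1):
            raise ValueError("fst_target must lie in [0, 1)")
        self._fst = fst.copy()


@dataclass
class CohortSpec:
    """Monthly settlement cohorts at a set of sites.

    ``source_mixture`` maps ``(site, month) -> {population: weight}`` (or a
    single shared mapping); each postlarva draws its source population from
    the month's mixture.  With probability ``prop_parent_sampled`` its true
    parent is one of the genotyped adults of that population.
    """

    sites: tuple[str, ...] = DEFAULT_SITES
    months: tuple[str, ...] = tuple(f"m{i + 1:02d}" for i in range(24))
    n_per_month: int = 45
    source_mixture: Mapping = dc_field(default_factory=dict)
    prop_parent_sampled: float = 0.3
    error_rate: float = 0.01
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        for p in (self.prop_parent_sampled, self.error_rate, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_per_month < 1:
            raise ValueError("n_per_month must be positive")

    def mixture_for(self, site: str, month: str) -> dict[str, float]:
        mix = self.source_mixture
        if (site, month) in mix:
            mix = mix[(site, month)]
        elif month in mix and isinstance(mix[month], Mapping):
            mix = mix[month]
        total = float(sum(mix.values()))
        if not mix or abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights for {site}/{month} must sum to 1")
        return {str(k): float(v) for k, v in mix.items()}


@dataclass
class FieldSpec:
    """Analytic velocity-field recipe on a regular lon/lat/time grid."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    grid_step: float
    t_span: float  # seconds
    t_step: float  # seconds
    pattern: str = "uniform"
    params: dict = dc_field(default_factory=dict)
    depths: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid step must be positive")
        if self.t_step <= 0 or self.t_span < self.t_step:
            raise ValueError("need at least 2 time steps")


# ---------------------------------------------------------------------------
# genotype generators
# ---------------------------------------------------------------------------


def make_allele_freqs(model: PopulationModel) -> AlleleFrequencyTable:
    """Draw per-population allele frequencies under Balding-Nichols drift.

    For population with target F > 0, the locus frequency vector is
    Dirichlet(p_anc * (1 - F) / F); F = 0 copies the ancestral vector.
    Deterministic under ``model.seed``.
    """
    rng = child_rng(model.seed, "allele_freqs")
    loci = [f"L{j + 1:02d}" for j in range(model.n_loci)]
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    genes: dict[str, dict[str, int]] = {}
    for i, pop in enumerate(model.pop_names):
        f = model._fst[i]
        freqs[pop] = {}
        genes[pop] = {}
        for j, locus in enumerate(loci):
            anc = model.ancestral_freqs[j]
            if f == 0.0:
                vec = anc.copy()
            else:
                conc = anc * (1.0 - f) / f
                # Dirichlet with tiny concentrations can return exact zeros;
                # clip and renormalise to keep a valid simplex.
                vec = rng.dirichlet(np.maximum(conc, 1e-9))
                vec = np.maximum(vec, 1e-12)
                vec = vec / vec.sum()
            freqs[pop][locus] = {a + 1: float(v) for a, v in enumerate(vec)}
            genes[pop][locus] = 0  # model frequencies, not sample estimates
    return AlleleFrequencyTable(
        loci=loci, groups=list(model.pop_names), freqs=freqs, gene_counts=genes
    )


def _draw_hwe_genotypes(
    rng: np.random.Generator, vec: Mapping[int, float], n: int
) -> np.ndarray:
    codes = np.array(list(vec.keys()), dtype=np.int32)
    p = np.array(list(vec.values()), dtype=float)
    p = p / p.sum()
    draws = rng.choice(codes, size=(n, 2), p=p)
    return np.sort(draws, axis=1).astype(np.int32)


def simulate_adults(
    freqs: AlleleFrequencyTable,
    n_per_pop: Mapping[str, int],
    seed: int = 0,
) -> GenotypeTable:
    """Sample HWE adult genotypes (two independent allele draws per locus)."""
    rng = child_rng(seed, "adults")
    for pop in n_per_pop:
        if pop not in freqs.groups:
            raise KeyError(f"unknown population id {pop!r}")
        if n_per_pop[pop] < 1:
            raise ValueError("n_per_pop must be positive")
    ids: list[str] = []
    pops: list[str] = []
    rows: list[np.ndarray] = []
    for pop, n in n_per_pop.items():
        for k in range(n):
            ids.append(f"{pop}-{k + 1:03d}")
            pops.append(pop)
        block = np.empty((n, len(freqs.loci), 2), dtype=np.int32)
        for j, locus in enumerate(freqs.loci):
            block[:, j, :] = _draw_hwe_genotypes(rng, freqs.vector(pop, locus), n)
        rows.append(block)
    calls = np.concatenate(rows, axis=0)
    metadata = pd.DataFrame({"pop": pops}, index=pd.Index(ids, name="id"))
    return GenotypeTable(loci=list(freqs.loci), ids=ids, calls=calls, metadata=metadata)


def simulate_cohorts(
    freqs: AlleleFrequencyTable,
    adults: GenotypeTable,
    spec: CohortSpec,
    seed: int = 0,
) -> GenotypeTable:
    """Simulate settled postlarvae with a recorded truth channel.

    Each postlarva draws a source population from its month's mixture.  With
    probability ``prop_parent_sampled`` a genotyped adult of that population
    is its true parent: at every locus one allele is transmitted uniformly
    from the parent's two and the other gamete is an HWE draw from the
    population's frequencies.  Otherwise both gametes are population draws
    and ``true_parent_id`` is recorded as ``"unsampled"``.  Typing noise is
    then applied via :func:`apply_typing_noise`.
    """
    rng = child_rng(seed, "cohorts")
    adult_pops = adults.metadata["pop"].to_numpy()
    pool_by_pop = {
        pop: np.flatnonzero(adult_pops == pop) for pop in pd.unique(adult_pops)
    }
    ids: list[str] = []
    meta_rows: list[tuple] = []
    rows: list[np.ndarray] = []
    counter = 0
    for site in spec.sites:
        for month in spec.months:
            mix = spec.mixture_for(site, month)
            pops = list(mix)
            w = np.array([mix[p] for p in pops])
            src = rng.choice(len(pops), size=spec.n_per_month, p=w / w.sum())
            for s in src:
                pop = pops[s]
                counter += 1
                pid = f"PL-{counter:05d}"
                sampled = rng.random() < spec.prop_parent_sampled
                geno = np.empty((len(freqs.loci), 2), dtype=np.int32)
                if sampled:
                    pool = pool_by_pop.get(pop)
                    if pool is None or pool.size == 0:
                        raise ValueError(f"no genotyped adults for population {pop!r}")
                    parent_idx = int(rng.choice(pool))
                    parent_id = adults.ids[parent_idx]
                    for j, locus in enumerate(freqs.loci):
                        pg = adults.calls[parent_idx, j]
                        if pg[0] == MISSING:
                            # untyped parent locus: transmit from the model freqs
                            transmitted = _draw_hwe_genotypes(
                                rng, freqs.vector(pop, locus), 1
                            )[0, 0]
                        else:
                            transmitted = pg[rng.integers(2)]
                        other = _draw_hwe_genotypes(rng, freqs.vector(pop, locus), 1)[0, 0]
                        geno[j] = sorted((int(transmitted), int(other)))
                else:
                    parent_id = "unsampled"
                    for j, locus in enumerate(freqs.loci):
                        geno[j] = _draw_hwe_genotypes(rng, freqs.vector(pop, locus), 1)[0]
                ids.append(pid)
                rows.append(geno)
                meta_rows.append((site, month, pop, parent_id, bool(sampled)))
    metadata = pd.DataFrame(
        meta_rows,
        columns=["site", "month", "source_pop", "true_parent_id", "parent_sampled"],
        index=pd.Index(ids, name="id"),
    )
    metadata["cohort"] = metadata["site"] + "/" + metadata["month"]
    table = GenotypeTable(
        loci=list(freqs.loci), ids=ids, calls=np.stack(rows), metadata=metadata
    )
    if spec.error_rate > 0 or spec.missing_rate > 0:
        table, _ = apply_typing_noise(
            table, spec.error_rate, spec.missing_rate,
            seed=seed, freqs=freqs, pop_column="source_pop",
        )
    return table


def apply_typing_noise(
    table: GenotypeTable,
    error_rate: float,
    missing_rate: float,
    seed: int = 0,
    freqs: AlleleFrequencyTable | None = None,
    pop_column: str = "pop",
) -> tuple[GenotypeTable, dict[str, int]]:
    """Apply genotyping error and missingness cell-wise.

    Per individual x locus, independently: with ``missing_rate`` the genotype
    becomes missing; otherwise with ``error_rate`` it is replaced by a random
    HWE genotype drawn from that individual's population frequencies (pooled
    observed frequencies when ``freqs`` is None).  Returns the perturbed table
    and a report ``{"n_missing": ..., "n_mistyped": ...}``.
    """
    if not (0.0 <= error_rate <= 1.0 and 0.0 <= missing_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    rng = child_rng(seed, "typing_noise")
    calls = table.calls.copy()
    n, L = table.n_individuals, table.n_loci
    u = rng.random((n, L))
    make_missing = u < missing_rate
    mistype = (~make_missing) & (rng.random((n, L)) < error_rate)

    if freqs is None:
        from .genio import allele_frequencies

        pooled = allele_frequencies(table, grouping=None)
        get_vec = lambda pop, locus: pooled.vector("all", locus)  # noqa: E731
        pops = np.array(["all"] * n)
    else:
        get_vec = freqs.vector
        if pop_column in table.metadata.columns:
            pops = table.metadata[pop_column].to_numpy()
        else:
            pops = np.array([freqs.groups[0]] * n)

    n_mistyped = 0
    for i, j in zip(*np.nonzero(mistype)):
        locus = table.loci[j]
        vec = get_vec(str(pops[i]), locus)
        calls[i, j] = _draw_hwe_genotypes(rng, vec, 1)[0]
        n_mistyped += 1
    calls[make_missing] = MISSING
    out = GenotypeTable(
        loci=list(table.loci), ids=list(table.ids), calls=calls,
        metadata=table.metadata.copy(),
    )
    report = {"n_missing": int(make_missing.sum()), "n_mistyped": n_mistyped}
    return out, report


# ---------------------------------------------------------------------------
# analytic velocity fields
# ---------------------------------------------------------------------------

_M_PER_DEG = 111_320.0


def make_velocity_field(spec: FieldSpec) -> VelocityField:
    """Fill a gridded velocity field from a named analytic pattern.

    Patterns: ``uniform`` (params u0, v0 in m/s); ``solid_body`` (params
    omega rad/s, lon0, lat0 — u = -omega*dy, v = omega*dx with dx, dy local
    metric distances from the centre); ``double_gyre`` (params amplitude m/s,
    period s — the standard two-cell recirculation on the unit-normalised
    domain); ``composite`` (params patterns: list of sub-specs, summed).
    """
    lon = np.arange(spec.lon_min, spec.lon_max + spec.grid_step / 2, spec.grid_step)
    lat = np.arange(spec.lat_min, spec.lat_max + spec.grid_step / 2, spec.grid_step)
    time = np.arange(0.0, spec.t_span + spec.t_step / 2, spec.t_step)
    LON, LAT = np.meshgrid(lon, lat)  # (ny, nx)

    def eval_pattern(pattern: str, params: dict, t: float) -> tuple[np.ndarray, np.ndarray]:
        if pattern == "uniform":
            u0 = float(params.get("u0", 0.0))
            v0 = float(params.get("v0", 0.0))
            return np.full_like(LON, u0), np.full_like(LON, v0)
        if pattern == "solid_body":
            omega = float(params.get("omega", 1e-6))
            lon0 = float(params.get("lon0", (spec.lon_min + spec.lon_max) / 2))
            lat0 = float(params.get("lat0", (spec.lat_min + spec.lat_max) / 2))
            dx = (LON - lon0) * _M_PER_DEG * np.cos(np.radians(lat0))
            dy = (LAT - lat0) * _M_PER_DEG
            return -omega * dy, omega * dx
        if pattern == "double_gyre":
            A = float(params.get("amplitude", 0.1))
            period = float(params.get("period", 30 * 86400.0))
            eps = float(params.get("eps", 0.0))
            x = (LON - spec.lon_min) / (spec.lon_max - spec.lon_min) * 2.0
            y = (LAT - spec.lat_min) / (spec.lat_max - spec.lat_min)
            w = 2 * np.pi / period
            a = eps * np.sin(w * t)
            b = 1 - 2 * eps * np.sin(w * t)
            fx = a * x**2 + b * x
            dfx = 2 * a * x + b
            u = -np.pi * A * np.sin(np.pi * fx) * np.cos(np.pi * y)
            v = np.pi * A * np.cos(np.pi * fx) * np.sin(np.pi * y) * dfx
            return u, v
        if pattern == "composite":
            u = np.zeros_like(LON)
            v = np.zeros_like(LON)
            for sub in params["patterns"]:
                su, sv = eval_pattern(sub["pattern"], sub.get("params", {}), t)
                u += su
                v += sv
            return u, v
        raise ValueError(f"unknown velocity pattern {pattern!r}")

    u = np.empty((time.size, lat.size, lon.size))
    v = np.empty_like(u)
    for it, t in enumerate(time):
        u[it], v[it] = eval_pattern(spec.pattern, spec.params, float(t))
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise ValueError("velocity field contains non-finite values")
    depth = np.asarray(spec.depths, dtype=float) if spec.depths else None
    if depth is not None:
        u = np.repeat(u[:, None, :, :], depth.size, axis=1)
        v = np.repeat(v[:, None, :, :], depth.size, axis=1)
    return VelocityField(lon=lon, lat=lat, time=time, u=u, v=v, depth=depth)


def write_truth_table(table: GenotypeTable, path) -> None:
    """Write the postlarva truth channel (source pop, true parent) to CSV."""
    cols = [c for c in ("site", "month", "source_pop", "true_parent_id", "parent_sampled")
            if c in table.metadata.columns]
    df = table.metadata[cols].copy()
    df.insert(0, "individual_id", table.metadata.index)
    df.to_csv(path, index=False)
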