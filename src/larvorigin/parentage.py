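"""Single-parent likelihood (LOD) assignment of postlarvae to candidate adults.

The direct genetic method: for each postlarva and each candidate adult, the
LOD score is the natural log of the likelihood ratio "candidate is the
single parent" versus "candidate is unrelated", summed over the loci typed
in both.  Per locus, with genotyping-error rate ``eps``:

    numerator   = (1 - eps) * T(g_off | g_cand) + eps * P_HWE(g_off)
    denominator = P_HWE(g_off)

where ``T`` is the Mendelian single-parent transition probability (parent
transmits each of its two alleles with probability 1/2; the untransmitted
gamete is an HWE draw from the reference allele frequencies) and ``P_HWE``
is p^2 for a homozygote or 2pq for a heterozygote.  A locus with ``T = 0``
is a mismatch (Mendelian exclusion).

The acceptance threshold (critical LOD) is calibrated by Monte-Carlo
simulation at a stated confidence level: simulated offspring are scored
against candidate sets that contain the true parent with the supplied
sampling fraction, and the critical LOD is the smallest threshold at which
the fraction of best-candidate hits that are true parents reaches the
confidence level.  Accepted assignments additionally require a minimum
number of compared loci and tolerate a maximum number of mismatched loci.

Assignment counts are summarised into the sample-size-weighted source
statistic: per settlement site and adult population,
``weighted % = 100 * count / (N_adult * N_postlarvae_site)``, summed over
sites into a per-population total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .genio import MISSING, AlleleFrequencyTable, GenotypeTable

__all__ = [
    "ParentageConfig",
    "PairScore",
    "CalibrationError",
    "single_parent_transition",
    "locus_lod",
    "pair_lod",
    "calibrate_critical_lod",
    "assign_parentage",
    "weighted_source_proportions",
    "source_weight_table",
    "ParentageModel",
    "ParentageResults",
]


@dataclass
class ParentageConfig:
    """Tunable parameters of the parentage analysis.

    Defaults mirror the study: genotyping error 0.01, >10 loci compared
    (implemented as >=10, or >=11 with ``strict_gt``), at most 2 mismatched
    loci, 95% confidence, 10,000 simulated offspring, 98 candidate parents,
    candidate-parent sampling fraction 0.016.
    """

    error_rate: float = 0.01
    min_loci_compared: int = 10
    strict_gt: bool = False  # True: "more than 10" read literally (>= 11)
    max_mismatches: int = 2
    critical_lod: float | None = None
    confidence_level: float = 0.95
    n_sim_offspring: int = 10_000
    n_candidates: int = 98
    prop_sampled: float = 0.016
    lod_grid_step: float = 0.1
    freq_floor: float | None = None  # default 1/(2*N_pool + 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.error_rate, self.confidence_level, self.prop_sampled):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.error_rate >= 1.0:
            raise ValueError("error_rate must be < 1")
        for c in (self.min_loci_compared, self.n_sim_offspring, self.n_candidates):
            if c < 1:
                raise ValueError("counts must be positive")

    @property
    def effective_min_loci(self) -> int:
        return self.min_loci_compared + 1 if self.strict_gt else self.min_loci_compared


@dataclass
class PairScore:
    """LOD score of one offspring-candidate pair."""

    offspring_id: str
    candidate_id: str
    lod: float
    loci_compared: int
    mismatches: int


class CalibrationError(RuntimeError):
    """No threshold attains the requested confidence level."""

    def __init__(self, message: str, curve: pd.DataFrame | None = None) -> None:
        super().__init__(message)
        self.curve = curve


# ---------------------------------------------------------------------------
# per-locus likelihoods (scalar surface)
# ---------------------------------------------------------------------------


def _freq(freqs: Mapping[int, float], allele: int, floor: float) -> float:
    f = freqs.get(int(allele), 0.0)
    return f if f > 0 else floor


def single_parent_transition(
    g_off: Sequence[int], g_par: Sequence[int], freqs: Mapping[int, float],
    floor: float = 0.0,
) -> float:
    """Mendelian P(offspring genotype | one parent, other gamete HWE).

    The parent transmits each of its two alleles with probability 1/2; the
    untransmitted allele is drawn from ``freqs``.  Unordered-genotype
    probabilities are summed over consistent assignments.
    """
    a, b = int(g_off[0]), int(g_off[1])
    c, d = int(g_par[0]), int(g_par[1])
    t_a = 0.5 * ((a == c) + (a == d))  # P(parent transmits allele a)
    t_b = 0.5 * ((b == c) + (b == d))
    if a == b:
        return t_a * _freq(freqs, a, floor)
    return t_a * _freq(freqs, b, floor) + t_b * _freq(freqs, a, floor)


def _p_hwe(g: Sequence[int], freqs: Mapping[int, float], floor: float) -> float:
    a, b = int(g[0]), int(g[1])
    pa = _freq(freqs, a, floor)
    if a == b:
        return pa * pa
    return 2.0 * pa * _freq(freqs, b, floor)


def locus_lod(
    g_off: Sequence[int],
    g_cand: Sequence[int],
    freqs: Mapping[int, float],
    eps: float,
    floor: float = 0.0,
) -> tuple[float, bool]:
    """One locus' LOD term and Mendelian-mismatch flag.

    With eps > 0 the term is finite even at a mismatch (it equals ln(eps)).
    At eps = 0 a mismatch yields -inf; callers exclude such loci before
    summation and keep them only as mismatch bookkeeping.
    """
    den = _p_hwe(g_off, freqs, floor)
    if den <= 0.0:
        raise ValueError(
            "offspring genotype has zero HWE probability "
            "(allele absent from freqs and floor disabled)"
        )
    T = single_parent_transition(g_off, g_cand, freqs, floor)
    num = (1.0 - eps) * T + eps * den
    is_mismatch = T == 0.0
    if num <= 0.0:
        return -math.inf, is_mismatch
    return math.log(num / den), is_mismatch


def pair_lod(
    offspring: tuple[str, np.ndarray],
    candidate: tuple[str, np.ndarray],
    loci: Sequence[str],
    freqs: AlleleFrequencyTable,
    config: ParentageConfig,
    freq_group: str | None = None,
) -> PairScore:
    """Sum locus LODs over loci typed in both genotypes.

    ``offspring``/``candidate`` are (id, calls) with calls of shape
    (n_loci, 2).  Loci missing in either genotype are skipped.
    """
    group = freq_group or freqs.groups[0]
    off_id, g_off = offspring
    cand_id, g_cand = candidate
    floor = _default_floor(freqs, group, config)
    lod = 0.0
    compared = 0
    mism = 0
    for j, locus in enumerate(loci):
        if g_off[j, 0] == MISSING or g_cand[j, 0] == MISSING:
            continue
        if freqs.is_absent(group, locus):
            continue
        term, is_mm = locus_lod(
            g_off[j], g_cand[j], freqs.vector(group, locus), config.error_rate, floor
        )
        compared += 1
        if is_mm:
            mism += 1
        if math.isfinite(term):
            lod += term
    return PairScore(off_id, cand_id, lod, compared, mism)


def _default_floor(
    freqs: AlleleFrequencyTable, group: str, config: ParentageConfig
) -> float:
    if config.freq_floor is not None:
        return config.freq_floor
    genes = freqs.gene_counts.get(group, {})
    n_pool = max(genes.values()) // 2 if genes else 0
    if n_pool == 0:
        return 1e-3  # model frequencies carry no gene counts
    return 1.0 / (2 * n_pool + 1)


# ---------------------------------------------------------------------------
# vectorised scoring engine
# ---------------------------------------------------------------------------


def _locus_arrays(
    freqs: AlleleFrequencyTable, group: str, loci: Sequence[str], floor: float
) -> list[tuple[np.ndarray, np.ndarray] | None]:
    """Per locus: (allele codes sorted, frequency lookup by code).

    Returned frequency arrays are dense over code values for O(1) lookup;
    codes absent from the table get the floor frequency.
    """
    out = []
    for locus in loci:
        if freqs.is_absent(group, locus):
            out.append(None)
            continue
        vec = freqs.vector(group, locus)
        max_code = max(vec)
        dense = np.full(max_code + 2, floor)
        for code, f in vec.items():
            dense[code] = f if f > 0 else floor
        out.append((np.array(sorted(vec)), dense))
    return out


def _score_matrix(
    off_calls: np.ndarray,  # (n_off, L, 2)
    cand_calls: np.ndarray,  # (n_cand, L, 2)
    freqs: AlleleFrequencyTable,
    config: ParentageConfig,
    loci: Sequence[str],
    group: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LOD, loci_compared, mismatches for all offspring x candidate pairs."""
    eps = config.error_rate
    floor = _default_floor(freqs, group, config)
    locus_info = _locus_arrays(freqs, group, loci, floor)
    n_off, L, _ = off_calls.shape
    n_cand = cand_calls.shape[0]
    lod = np.zeros((n_off, n_cand))
    compared = np.zeros((n_off, n_cand), dtype=np.int32)
    mism = np.zeros((n_off, n_cand), dtype=np.int32)
    for j in range(L):
        info = locus_info[j]
        if info is None:
            continue
        _, dense = info
        oa = off_calls[:, j, 0]
        ob = off_calls[:, j, 1]
        off_typed = oa != MISSING
        ca = cand_calls[:, j, 0]
        cb = cand_calls[:, j, 1]
        cand_typed = ca != MISSING

        # dense lookups need non-negative indices; missing rows masked after
        oa_ = np.where(off_typed, oa, 0)
        ob_ = np.where(off_typed, ob, 0)
        fa = dense[np.clip(oa_, 0, dense.size - 1)]
        fb = dense[np.clip(ob_, 0, dense.size - 1)]
        hom = oa_ == ob_
        den = np.where(hom, fa * fa, 2.0 * fa * fb)  # (n_off,)

        t_a = 0.5 * (
            (oa_[:, None] == ca[None, :]).astype(float)
            + (oa_[:, None] == cb[None, :])
        )
        t_b = 0.5 * (
            (ob_[:, None] == ca[None, :]).astype(float)
            + (ob_[:, None] == cb[None, :])
        )
        T = np.where(
            hom[:, None], t_a * fa[:, None], t_a * fb[:, None] + t_b * fa[:, None]
        )
        num = (1.0 - eps) * T + eps * den[:, None]
        both = off_typed[:, None] & cand_typed[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.log(num / den[:, None])
        term = np.where(both, term, 0.0)
        term = np.where(np.isfinite(term), term, 0.0)  # eps=0 mismatches: bookkeeping only
        lod += term
        compared += both
        mism += both & (T == 0.0)
    return lod, compared, mism


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _sample_hwe(
    rng: np.random.Generator, locus_info, n: int, L: int
) -> np.ndarray:
    calls = np.empty((n, L, 2), dtype=np.int32)
    for j in range(L):
        info = locus_info[j]
        if info is None:
            calls[:, j, :] = MISSING
            continue
        codes, dense = info
        p = np.array([dense[c] for c in codes])
        p = p / p.sum()
        calls[:, j, :] = np.sort(rng.choice(codes, size=(n, 2), p=p), axis=1)
    return calls


def _trialwise_lod(
    off: np.ndarray,  # (m, L, 2)
    cands: np.ndarray,  # (m, n_cand, L, 2)
    locus_info,
    eps: float,
) -> np.ndarray:
    """LOD of each trial's offspring against its own candidate set (m, n_cand)."""
    m, L, _ = off.shape
    n_cand = cands.shape[1]
    lod = np.zeros((m, n_cand))
    for j in range(L):
        info = locus_info[j]
        if info is None:
            continue
        _, dense = info
        oa = off[:, j, 0]
        ob = off[:, j, 1]
        fa = dense[oa]
        fb = dense[ob]
        hom = oa == ob
        den = np.where(hom, fa * fa, 2.0 * fa * fb)  # (m,)
        ca = cands[:, :, j, 0]
        cb = cands[:, :, j, 1]
        t_a = 0.5 * ((oa[:, None] == ca).astype(float) + (oa[:, None] == cb))
        t_b = 0.5 * ((ob[:, None] == ca).astype(float) + (ob[:, None] == cb))
        T = np.where(hom[:, None], t_a * fa[:, None], t_a * fb[:, None] + t_b * fa[:, None])
        num = (1.0 - eps) * T + eps * den[:, None]
        with np.errstate(divide="ignore"):
            term = np.log(num / den[:, None])
        lod += np.where(np.isfinite(term), term, np.log(np.finfo(float).tiny))
    return lod


def calibrate_critical_lod(
    freqs_pool: AlleleFrequencyTable,
    config: ParentageConfig,
    group: str | None = None,
) -> tuple[float, pd.DataFrame]:
    """Monte-Carlo calibration of the critical LOD at the confidence level.

    Each trial draws a true parent from the pooled frequencies, creates an
    offspring by single-parent Mendelian transmission, builds a candidate
    set of ``n_candidates`` unrelated HWE genotypes — the true parent
    replacing one of them with probability ``prop_sampled`` — applies the
    error model to every genotype, and records the best candidate's LOD and
    whether it is the true parent.  ``confidence(t)`` is the fraction of
    trials with best LOD >= t whose best candidate is the true parent,
    smoothed to be non-decreasing in t (cumulative max); the critical LOD is
    the smallest grid point (step ``lod_grid_step``) reaching the confidence
    level.

    Returns (critical_lod, confidence_curve); raises
    :class:`CalibrationError` (curve attached) when no threshold attains the
    level.
    """
    group = group or freqs_pool.groups[0]
    loci = freqs_pool.loci
    L = len(loci)
    floor = _default_floor(freqs_pool, group, config)
    locus_info = _locus_arrays(freqs_pool, group, loci, floor)
    rng = child_rng(config.seed, "lod_calibration")
    n_tr = config.n_sim_offspring
    n_cand = config.n_candidates

    parents = _sample_hwe(rng, locus_info, n_tr, L)
    # Mendelian offspring: one allele from the parent, one from the pool
    offspring = np.empty_like(parents)
    which = rng.integers(2, size=(n_tr, L))
    transmitted = parents[np.arange(n_tr)[:, None], np.arange(L)[None, :], which]
    other = _sample_hwe(rng, locus_info, n_tr, L)[:, :, 0]
    offspring[:, :, 0] = np.minimum(transmitted, other)
    offspring[:, :, 1] = np.maximum(transmitted, other)

    include = rng.random(n_tr) < config.prop_sampled
    slot = rng.integers(n_cand, size=n_tr)

    def mistype(calls: np.ndarray, r: np.random.Generator) -> np.ndarray:
        if config.error_rate == 0:
            return calls
        out = calls.copy()
        flat = out.reshape(-1, L, 2)
        hit = r.random(flat.shape[:2]) < config.error_rate
        for j in range(L):
            rows = np.flatnonzero(hit[:, j])
            if rows.size and locus_info[j] is not None:
                codes, dense = locus_info[j]
                p = np.array([dense[c] for c in codes])
                p = p / p.sum()
                draws = np.sort(r.choice(codes, size=(rows.size, 2), p=p), axis=1)
                flat[rows, j, :] = draws
        return out

    offspring = mistype(offspring, rng)
    parents_typed = mistype(parents, rng)

    best_lod = np.empty(n_tr)
    best_is_true = np.zeros(n_tr, dtype=bool)
    block = 2000  # trials per scoring block, bounds peak memory
    for start in range(0, n_tr, block):
        stop = min(start + block, n_tr)
        m = stop - start
        cands = _sample_hwe(rng, locus_info, m * n_cand, L).reshape(m, n_cand, L, 2)
        cands = mistype(cands.reshape(m * n_cand, L, 2), rng).reshape(m, n_cand, L, 2)
        inc = include[start:stop]
        cands[np.flatnonzero(inc), slot[start:stop][inc]] = parents_typed[start:stop][inc]
        lod = _trialwise_lod(
            offspring[start:stop], cands, locus_info, config.error_rate
        )
        k = np.argmax(lod, axis=1)
        best_lod[start:stop] = lod[np.arange(m), k]
        best_is_true[start:stop] = inc & (k == slot[start:stop])

    step = config.lod_grid_step
    t_max = max(step, float(np.ceil(best_lod.max() / step) * step))
    grid = np.round(np.arange(0.0, t_max + step / 2, step), 10)
    n_above = np.array([(best_lod >= t).sum() for t in grid])
    n_true = np.array([(best_is_true & (best_lod >= t)).sum() for t in grid])
    with np.errstate(invalid="ignore", divide="ignore"):
        conf = np.where(n_above > 0, n_true / np.maximum(n_above, 1), 0.0)
    conf_smooth = np.maximum.accumulate(conf)
    curve = pd.DataFrame(
        {"threshold": grid, "n_trials_above": n_above,
         "n_true_above": n_true, "confidence": conf,
         "confidence_smoothed": conf_smooth}
    )
    ok = np.flatnonzero((conf_smooth >= config.confidence_level) & (n_above > 0))
    if ok.size == 0:
        raise CalibrationError(
            "no LOD threshold attains the requested confidence level; "
            "consider more informative loci or a lower error rate",
            curve=curve,
        )
    return float(grid[ok[0]]), curve


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def assign_parentage(
    postlarvae: GenotypeTable,
    adults: GenotypeTable,
    freqs_pool: AlleleFrequencyTable,
    config: ParentageConfig,
    freq_group: str | None = None,
) -> pd.DataFrame:
    """Score every postlarva against every adult and apply acceptance filters.

    Accept iff best LOD >= critical LOD, loci compared >= the minimum, and
    mismatches <= the maximum; an exact LOD tie between distinct candidates
    is rejected with reason ``tie``.  Returns one row per postlarva:
    (offspring_id, site, best_candidate, population, lod, second_lod,
    loci_compared, mismatches, accepted, reason).
    """
    if adults.n_individuals == 0:
        raise ValueError("empty adult table")
    if config.critical_lod is None:
        raise ValueError("critical_lod must be set (supply or calibrate first)")
    if postlarvae.loci != adults.loci:
        raise ValueError("locus sets differ between postlarvae and adults")
    group = freq_group or freqs_pool.groups[0]
    lod, compared, mism = _score_matrix(
        postlarvae.calls, adults.calls, freqs_pool, config, postlarvae.loci, group
    )
    adult_pop = (
        adults.metadata["pop"].to_numpy()
        if "pop" in adults.metadata.columns
        else np.array(["?"] * adults.n_individuals)
    )
    sites = (
        postlarvae.metadata["site"].to_numpy()
        if "site" in postlarvae.metadata.columns
        else np.array([""] * postlarvae.n_individuals)
    )
    rows = []
    for i in range(postlarvae.n_individuals):
        order = np.argsort(lod[i])[::-1]
        b = int(order[0])
        best = lod[i, b]
        second = lod[i, order[1]] if len(order) > 1 else -np.inf
        tie = len(order) > 1 and best == second
        reason = ""
        if compared[i, b] < config.effective_min_loci:
            reason = "few_loci"
        elif mism[i, b] > config.max_mismatches:
            reason = "many_mismatches"
        elif best < config.critical_lod:
            reason = "low_lod"
        elif tie:
            reason = "tie"
        accepted = reason == ""
        rows.append(
            (
                postlarvae.ids[i],
                sites[i],
                adults.ids[b],
                adult_pop[b],
                float(best),
                float(second),
                int(compared[i, b]),
                int(mism[i, b]),
                accepted,
                reason,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "offspring_id", "site", "best_candidate", "population", "lod",
            "second_lod", "loci_compared", "mismatches", "accepted", "reason",
        ],
    )


# ---------------------------------------------------------------------------
# weighted source statistic (Table-1 arithmetic)
# ---------------------------------------------------------------------------


def source_weight_table(
    counts: pd.DataFrame,
    adult_sizes: Mapping[str, int],
    site_totals: Mapping[str, int],
) -> pd.DataFrame:
    """Sample-size-weighted source proportions from assignment counts.

    ``counts`` is sites x populations (rows: settlement sites, columns:
    adult populations).  Output rows per population and site:
    ``percent = 100*count/N_site`` and
    ``weighted = 100*count/(N_adult*N_site)``, plus per-population
    ``total = sum over sites of weighted``.
    """
    for site in counts.index:
        if site not in site_totals:
            raise KeyError(f"unknown settlement site {site!r}")
    for pop in counts.columns:
        if pop not in adult_sizes:
            raise KeyError(f"unknown adult population {pop!r}")
    rows = []
    for pop in counts.columns:
        n_adult = adult_sizes[pop]
        total_weighted = 0.0
        for site in counts.index:
            c = float(counts.loc[site, pop])
            n_site = site_totals[site]
            pct = 100.0 * c / n_site
            wt = 100.0 * c / (n_adult * n_site)
            total_weighted += wt
            rows.append((pop, site, c, n_adult, n_site, pct, wt, np.nan))
        rows.append((pop, "total", counts[pop].sum(), n_adult, np.nan, np.nan, np.nan, total_weighted))
    return pd.DataFrame(
        rows,
        columns=[
            "population", "site", "count", "N_adult", "N_postlarvae_site",
            "percent", "weighted", "total_weighted",
        ],
    )


def weighted_source_proportions(
    assignments: pd.DataFrame,
    adult_sizes: Mapping[str, int],
    site_totals: Mapping[str, int],
) -> pd.DataFrame:
    """Aggregate accepted assignments into the weighted source table."""
    acc = assignments[assignments["accepted"]]
    pops = list(adult_sizes)
    sites = list(site_totals)
    counts = pd.DataFrame(0.0, index=sites, columns=pops)
    for _, row in acc.iterrows():
        if row["population"] not in adult_sizes:
            raise KeyError(f"unknown adult population {row['population']!r}")
        if row["site"] not in site_totals:
            raise KeyError(f"unknown settlement site {row['site']!r}")
        counts.loc[row["site"], row["population"]] += 1
    return source_weight_table(counts, adult_sizes, site_totals)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class ParentageModel:
    """Single-parent LOD assignment model.

    Built from the postlarva and adult genotype tables; ``fit()`` calibrates
    the critical LOD (unless supplied in the config) and assigns every
    postlarva, returning a :class:`ParentageResults`.

    By default LOD denominators and calibration both use the pooled
    all-adults allele frequencies; pass ``freqs`` to override.
    """

    def __init__(
        self,
        postlarvae: GenotypeTable,
        adults: GenotypeTable,
        config: ParentageConfig | None = None,
        freqs: AlleleFrequencyTable | None = None,
    ) -> None:
        from .genio import allele_frequencies

        self.postlarvae = postlarvae
        self.adults = adults
        self.config = config or ParentageConfig()
        if freqs is None:
            freqs = allele_frequencies(adults, grouping=None).pooled()
        self.freqs = freqs

    def fit(self) -> "ParentageResults":
        config = self.config
        curve = None
        critical = config.critical_lod
        if critical is None:
            critical, curve = calibrate_critical_lod(self.freqs, config)
            config = ParentageConfig(**{**config.__dict__, "critical_lod": critical})
        assignments = assign_parentage(self.postlarvae, self.adults, self.freqs, config)
        return ParentageResults(
            model=self,
            config=config,
            critical_lod=critical,
            confidence_curve=curve,
            assignments=assignments,
        )


@dataclass
class ParentageResults:
    """Fitted parentage assignment: per-postlarva scores and acceptance."""

    model: ParentageModel
    config: ParentageConfig
    critical_lod: float
    confidence_curve: pd.DataFrame | None
    assignments: pd.DataFrame

    @property
    def n_resolved(self) -> int:
        return int(self.assignments["accepted"].sum())

    def source_weights(
        self,
        adult_sizes: Mapping[str, int] | None = None,
        site_totals: Mapping[str, int] | None = None,
    ) -> pd.DataFrame:
        if adult_sizes is None:
            adult_sizes = (
                self.model.adults.metadata["pop"].value_counts().to_dict()
            )
        if site_totals is None:
            site_totals = (
                self.model.postlarvae.metadata["site"].value_counts().to_dict()
            )
        return weighted_source_proportions(self.assignments, adult_sizes, site_totals)

    def summary(self) -> str:
        n = len(self.assignments)
        acc = self.assignments["accepted"]
        lines = [
            "Single-parent LOD assignment",
            "============================",
            f"postlarvae scored:    {n}",
            f"candidate adults:     {self.model.adults.n_individuals}",
            f"critical LOD:         {self.critical_lod:.2f} "
            f"({100 * self.config.confidence_level:.0f}% confidence)",
            f"error rate (eps):     {self.config.error_rate}",
            f"filters:              >= {self.config.effective_min_loci} loci, "
            f"<= {self.config.max_mismatches} mismatches",
            f"resolved assignments: {self.n_resolved} "
            f"({100 * self.n_resolved / max(n, 1):.1f}%)",
        ]
        if not acc.all():
            reasons = self.assignments.loc[~acc, "reason"].value_counts()
            lines.append("rejections:           " + ", ".join(
                f"{k}={v}" for k, v in reasons.items()
            ))
        top = (
            self.assignments[acc]
            .groupby("population")["offspring_id"].count()
            .sort_values(ascending=False)
            .head(5)
        )
        if len(top):
            lines.append("top source pops:      " + ", ".join(
                f"{k}({v})" for k, v in top.items()
            ))
        return "\n".join(lines)

    def plot_confidence_curve(self, ax=None):
        import matplotlib.pyplot as plt

        if self.confidence_curve is None:
            raise ValueError("no calibration curve (critical LOD was supplied)")
        if ax is None:
            _, ax = plt.subplots()
        c = self.confidence_curve
        ax.plot(c["threshold"], c["confidence_smoothed"], label="confidence")
        ax.axhline(self.config.confidence_level, color="0.6", ls=":")
        ax.axvline(self.critical_lod, color="0.6", ls="--", label="critical LOD")
        ax.set_xlabel("LOD threshold")
        ax.set_ylabel("fraction of best hits that are true parents")
        ax.legend()
        return ax
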