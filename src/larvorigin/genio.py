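"""Genotype containers, GenePop I/O, and per-locus diversity statistics.

The central container is :class:`GenotypeTable`: a rectangular array of
diploid microsatellite calls (individuals x loci x 2 allele codes) plus a
per-individual metadata frame.  Allele codes are positive integers; missing
genotypes are stored as the :data:`MISSING` sentinel, never as 0 (0 is only
the on-disk GenePop missing code).

The GenePop dialect is fixed to the 3-digits-per-allele form: a title line,
one locus name per line (or one comma-separated line), ``POP`` separators,
and individual lines ``id ,  003005 000000`` where ``000`` encodes a missing
allele.  The population label of a block is recovered from the first
individual id: everything before the last ``-`` (the writer emits ids of the
form ``<group>-<number>``), or the whole id when there is no dash.

Diversity statistics follow the conventions of the standard microsatellite
toolchain: unbiased expected heterozygosity (Nei, ``2n/(2n-1)`` correction),
polymorphic information content, rarefied allelic richness, a seeded
Monte-Carlo exact test for Hardy-Weinberg equilibrium, and the Brookfield-1
null-allele estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING: int = -1


class GenepopParseError(ValueError):
    """Raised when a GenePop file violates the fixed 3-digit dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Diploid multi-locus genotypes with per-individual metadata.

    Parameters
    ----------
    loci : list of str
        Ordered locus names.
    ids : list of str
        Ordered individual identifiers (unique).
    calls : ndarray of shape (n_individuals, n_loci, 2), int
        Allele codes (positive integers); both entries ``MISSING`` for an
        untyped genotype.  Within a genotype the allele pair is unordered;
        calls are normalised so the smaller code comes first.
    metadata : DataFrame
        Indexed by individual id.  Group labels (``pop``, ``site``,
        ``month`` ...) and optional truth columns (``source_pop``,
        ``true_parent_id``, ``parent_sampled``) live here.
    """

    loci: list[str]
    ids: list[str]
    calls: np.ndarray
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        if self.calls.shape != (len(self.ids), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.ids)}, {len(self.loci)}, 2)"
            )
        typed = self.calls[..., 0] != MISSING
        if np.any((self.calls <= 0) & typed[..., None] & (self.calls != MISSING)):
            raise ValueError("allele codes must be positive integers")
        # half-missing genotypes are treated as missing outright
        half = (self.calls[..., 0] == MISSING) ^ (self.calls[..., 1] == MISSING)
        if half.any():
            self.calls[half] = MISSING
        self.calls = np.sort(self.calls, axis=2)
        neg = self.calls[..., 0] == MISSING
        self.calls[neg] = MISSING  # keep (MISSING, MISSING) ordering canonical
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=pd.Index(self.ids, name="id"))
        else:
            self.metadata = self.metadata.loc[self.ids]

    # -- basic views ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): genotype present."""
        return self.calls[..., 0] != MISSING

    def subset(self, indices: Sequence[int] | np.ndarray) -> "GenotypeTable":
        indices = np.asarray(indices, dtype=np.intp)
        return GenotypeTable(
            loci=list(self.loci),
            ids=[self.ids[i] for i in indices],
            calls=self.calls[indices].copy(),
            metadata=self.metadata.iloc[indices].copy(),
        )

    def split_by(self, key: str) -> dict[str, "GenotypeTable"]:
        """Split into one table per distinct value of metadata column ``key``."""
        if key not in self.metadata.columns:
            raise KeyError(f"metadata column {key!r} not found")
        out: dict[str, GenotypeTable] = {}
        values = self.metadata[key].to_numpy()
        for val in pd.unique(values):
            idx = np.flatnonzero(values == val)
            out[str(val)] = self.subset(idx)
        return out

    def concat(self, other: "GenotypeTable") -> "GenotypeTable":
        if self.loci != other.loci:
            raise ValueError("locus sets differ")
        return GenotypeTable(
            loci=list(self.loci),
            ids=self.ids + other.ids,
            calls=np.concatenate([self.calls, other.calls], axis=0),
            metadata=pd.concat([self.metadata, other.metadata]),
        )


@dataclass
class AlleleFrequencyTable:
    """Per-group, per-locus allele relative frequencies with gene counts.

    ``freqs[group][locus]`` is a dict ``allele_code -> frequency``;
    ``gene_counts[group][locus]`` is twice the number of typed individuals.
    A group x locus cell with zero typed individuals is *absent* (the locus
    key is missing from that group's dict).
    """

    loci: list[str]
    groups: list[str]
    freqs: dict[str, dict[str, dict[int, float]]]
    gene_counts: dict[str, dict[str, int]]

    def vector(self, group: str, locus: str) -> dict[int, float]:
        try:
            return self.freqs[group][locus]
        except KeyError:
            raise KeyError(f"no frequencies for group={group!r} locus={locus!r}")

    def is_absent(self, group: str, locus: str) -> bool:
        return locus not in self.freqs.get(group, {})

    def pooled(self, name: str = "pooled") -> "AlleleFrequencyTable":
        """Pool gene counts across groups into a single-group table."""
        freqs: dict[str, dict[int, float]] = {}
        genes: dict[str, int] = {}
        for locus in self.loci:
            counts: dict[int, float] = {}
            total = 0
            for g in self.groups:
                if self.is_absent(g, locus):
                    continue
                gc = self.gene_counts[g][locus]
                total += gc
                for a, f in self.freqs[g][locus].items():
                    counts[a] = counts.get(a, 0.0) + f * gc
            if total > 0:
                freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
                genes[locus] = total
        return AlleleFrequencyTable(
            loci=list(self.loci), groups=[name], freqs={name: freqs}, gene_counts={name: genes}
        )

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per group x locus x allele."""
        rows = []
        for g in self.groups:
            for locus in self.loci:
                if self.is_absent(g, locus):
                    continue
                gc = self.gene_counts[g][locus]
                for a, f in self.freqs[g][locus].items():
                    rows.append((g, locus, a, f, gc))
        return pd.DataFrame(rows, columns=["group", "locus", "allele", "frequency", "gene_count"])


@dataclass
class LocusSummary:
    """Per-locus diversity summary for one group (or the pooled sample)."""

    locus: str
    n_typed: int
    Na: int
    Ho: float
    He: float
    PIC: float
    hwe_p: float
    null_freq: float
    group: str = "all"


# ---------------------------------------------------------------------------
# GenePop I/O
# ---------------------------------------------------------------------------


def _block_label(first_id: str) -> str:
    return first_id.rsplit("-", 1)[0] if "-" in first_id else first_id


def read_genepop(path: str | Path, group_column: str = "pop") -> GenotypeTable:
    """Read a GenePop file (3-digit allele dialect) into a GenotypeTable."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be GenePop")
    loci: list[str] = []
    i = 1  # skip title
    while i < len(lines) and lines[i].strip().upper() != "POP":
        part = lines[i].strip()
        if part:
            loci.extend(name.strip() for name in part.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP separator found")
    ids: list[str] = []
    calls_rows: list[np.ndarray] = []
    groups: list[str] = []
    current_block: list[str] = []
    block_first_id: str | None = None

    def flush_block() -> None:
        nonlocal block_first_id
        block_first_id = None

    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.upper() == "POP":
            flush_block()
            continue
        if "," not in line:
            raise GenepopParseError(f"line {i}: expected 'id , genotypes'")
        ind_id, geno_part = line.split(",", 1)
        ind_id = ind_id.strip()
        fields = geno_part.split()
        if len(fields) != len(loci):
            raise GenepopParseError(
                f"line {i}: {len(fields)} genotype fields for {len(loci)} loci"
            )
        row = np.empty((len(loci), 2), dtype=np.int32)
        for j, tok in enumerate(fields):
            if len(tok) != 6 or not tok.isdigit():
                raise GenepopParseError(
                    f"line {i}: genotype field {tok!r} is not six digits"
                )
            a1, a2 = int(tok[:3]), int(tok[3:])
            row[j, 0] = MISSING if a1 == 0 else a1
            row[j, 1] = MISSING if a2 == 0 else a2
        if block_first_id is None:
            block_first_id = ind_id
        ids.append(ind_id)
        groups.append(_block_label(block_first_id))
        calls_rows.append(row)
    if not ids:
        raise GenepopParseError("no individuals found")
    metadata = pd.DataFrame({group_column: groups}, index=pd.Index(ids, name="id"))
    return GenotypeTable(loci=loci, ids=ids, calls=np.stack(calls_rows), metadata=metadata)


def write_genepop(
    table: GenotypeTable,
    path: str | Path,
    group_column: str = "pop",
    title: str = "larvorigin genotypes",
) -> None:
    """Write a GenotypeTable as GenePop (3-digit alleles, 000 = missing)."""
    if group_column not in table.metadata.columns:
        raise KeyError(f"metadata column {group_column!r} not found")
    if np.any(table.calls > 999):
        raise ValueError("allele codes above 999 cannot be written in 3-digit GenePop")
    out = [title]
    out.extend(table.loci)
    values = table.metadata[group_column].to_numpy()
    for group in pd.unique(values):
        out.append("POP")
        for idx in np.flatnonzero(values == group):
            tokens = []
            for j in range(table.n_loci):
                a1, a2 = table.calls[idx, j]
                if a1 == MISSING:
                    tokens.append("000000")
                else:
                    tokens.append(f"{a1:03d}{a2:03d}")
            out.append(f"{table.ids[idx]} ,  " + " ".join(tokens))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# allele frequencies and summaries
# ---------------------------------------------------------------------------


def allele_frequencies(
    table: GenotypeTable, grouping: str | None = "pop"
) -> AlleleFrequencyTable:
    """Observed allele relative frequencies per group x locus.

    Missing genotypes contribute to neither numerator nor denominator.  With
    ``grouping=None`` the whole table forms a single group ``"all"``.
    """
    if grouping is None:
        groups = {"all": table}
    else:
        groups = table.split_by(grouping)
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    genes: dict[str, dict[str, int]] = {}
    for gname, gtab in groups.items():
        freqs[gname] = {}
        genes[gname] = {}
        typed = gtab.typed_mask()
        for j, locus in enumerate(gtab.loci):
            alleles = gtab.calls[typed[:, j], j, :].ravel()
            if alleles.size == 0:
                continue  # absent: zero typed individuals at this locus
            codes, counts = np.unique(alleles, return_counts=True)
            total = int(alleles.size)
            freqs[gname][locus] = {
                int(c): float(n) / total for c, n in zip(codes, counts)
            }
            genes[gname][locus] = total
    return AlleleFrequencyTable(
        loci=list(table.loci), groups=list(groups), freqs=freqs, gene_counts=genes
    )


def observed_heterozygosity(table: GenotypeTable, locus_index: int) -> tuple[float, int]:
    typed = table.typed_mask()[:, locus_index]
    n = int(typed.sum())
    if n == 0:
        return float("nan"), 0
    g = table.calls[typed, locus_index]
    return float(np.mean(g[:, 0] != g[:, 1])), n


def unbiased_expected_heterozygosity(freq_vector: Mapping[int, float], n_typed: int) -> float:
    """Nei's unbiased He = (2n / (2n - 1)) * (1 - sum p_i^2)."""
    s2 = sum(p * p for p in freq_vector.values())
    if n_typed < 1:
        return float("nan")
    return (2 * n_typed) / (2 * n_typed - 1) * (1.0 - s2)


def pic(freq_vector: Mapping[int, float]) -> float:
    """Polymorphic information content: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = np.array(list(freq_vector.values()))
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2 * s2 - s4)


def null_allele_estimate(Ho: float, He: float) -> float:
    """Brookfield-1 null-allele frequency estimate (He - Ho)/(1 + He), floored at 0."""
    if not (0.0 <= Ho <= 1.0 and 0.0 <= He <= 1.0):
        raise ValueError("Ho and He must lie in [0, 1]")
    return max(0.0, (He - Ho) / (1.0 + He))


def _log_genotype_array_prob(geno_counts: Mapping[tuple[int, int], int]) -> float:
    """Log conditional probability of a genotype array given its allele counts.

    Levene's exact distribution: P = n! * prod(a_i!) * 2^h / ((2n)! * prod(n_ij!))
    with n individuals, a_i allele counts, h heterozygotes.
    """
    n = sum(geno_counts.values())
    allele_counts: dict[int, int] = {}
    h = 0
    logdenom = 0.0
    for (a, b), k in geno_counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + k
        allele_counts[b] = allele_counts.get(b, 0) + k
        if a != b:
            h += k
        logdenom += gammaln(k + 1)
    return (
        gammaln(n + 1)
        + sum(gammaln(c + 1) for c in allele_counts.values())
        + h * math.log(2.0)
        - gammaln(2 * n + 1)
        - logdenom
    )


def hwe_exact_test(
    table: GenotypeTable,
    group: str | None,
    locus: str,
    n_perm: int = 999,
    seed: int = 0,
    grouping: str = "pop",
) -> float:
    """Monte-Carlo exact test for Hardy-Weinberg equilibrium at one locus.

    The statistic is the Levene conditional probability of the observed
    genotype array given the allele counts; the null distribution is sampled
    by randomly re-pairing the observed allele multiset.  ``p = (1 + #{perm
    with prob <= observed}) / (n_perm + 1)``.  A monomorphic locus has p = 1
    by definition.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if group is not None:
        table = table.split_by(grouping)[group]
    j = table.loci.index(locus)
    typed = table.typed_mask()[:, j]
    genos = table.calls[typed, j]
    if genos.size == 0:
        return 1.0
    alleles = genos.ravel()
    if np.unique(alleles).size < 2:
        return 1.0
    # Under re-pairing the allele counts are invariant, so only the variable
    # part of the Levene log-probability is compared:
    # s = h*ln(2) - sum_ij ln(n_ij!).
    def variable_part(pairs: np.ndarray) -> float:
        key = pairs[:, 0].astype(np.int64) * 100_000 + pairs[:, 1]
        uk, cnt = np.unique(key, return_counts=True)
        h = int(cnt[(uk // 100_000) != (uk % 100_000)].sum())
        return h * math.log(2.0) - float(gammaln(cnt + 1).sum())

    s_obs = variable_part(np.sort(genos, axis=1))
    rng = np.random.default_rng(seed)
    n_le = 0
    pool = alleles.copy()
    for _ in range(n_perm):
        rng.shuffle(pool)
        pairs = np.sort(pool.reshape(-1, 2), axis=1)
        if variable_part(pairs) <= s_obs + 1e-12:
            n_le += 1
    return (1 + n_le) / (n_perm + 1)


def allelic_richness(
    table: GenotypeTable, group: str | None, locus: str, g: int, grouping: str = "pop"
) -> float:
    """Rarefied allelic richness: expected allele count in a sample of ``g`` genes.

    ``AR(g) = sum_i [1 - C(N - N_i, g) / C(N, g)]`` with N total genes and
    N_i copies of allele i.
    """
    if group is not None:
        table = table.split_by(grouping)[group]
    j = table.loci.index(locus)
    typed = table.typed_mask()[:, j]
    alleles = table.calls[typed, j].ravel()
    N = int(alleles.size)
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds gene count N={N}")
    if g < 1:
        raise ValueError("g must be positive")
    _, counts = np.unique(alleles, return_counts=True)
    denom = math.comb(N, g)
    return float(sum(1.0 - math.comb(N - int(ni), g) / denom for ni in counts))


def locus_summaries(
    table: GenotypeTable,
    grouping: str | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> list[LocusSummary]:
    """Per-locus diversity summaries (pooled by default, or per group)."""
    if grouping is None:
        group_tables = {"all": table}
    else:
        group_tables = table.split_by(grouping)
    out: list[LocusSummary] = []
    for gname, gtab in group_tables.items():
        aft = allele_frequencies(gtab, grouping=None)
        for j, locus in enumerate(gtab.loci):
            if aft.is_absent("all", locus):
                continue
            vec = aft.vector("all", locus)
            Ho, n_typed = observed_heterozygosity(gtab, j)
            He = unbiased_expected_heterozygosity(vec, n_typed)
            hwe_p = hwe_exact_test(gtab, None, locus, n_perm=n_perm, seed=seed + j)
            out.append(
                LocusSummary(
                    locus=locus,
                    n_typed=n_typed,
                    Na=len(vec),
                    Ho=Ho,
                    He=He,
                    PIC=pic(vec),
                    hwe_p=hwe_p,
                    null_freq=null_allele_estimate(Ho, min(He, 1.0)),
                    group=gname,
                )
            )
    return out


def summaries_to_frame(summaries: Iterable[LocusSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.group, s.locus, s.n_typed, s.Na, s.Ho, s.He, s.PIC, s.hwe_p, s.null_freq)
            for s in summaries
        ],
        columns=["group", "locus", "n_typed", "Na", "Ho", "He", "PIC", "hwe_p", "null_freq"],
    )
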