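"""Indirect genetic method: pairwise FST and DAPC clustering.

FST uses the Weir & Cockerham (1984) theta estimator: per locus and allele,
variance components a (among populations), b (among individuals within
populations) and c (within individuals) are computed from sample sizes,
allele frequencies and heterozygote frequencies; theta is the ratio of sums
``sum(a) / sum(a + b + c)`` over alleles and loci.  Small-sample theta may
be negative and is reported as computed.

DAPC (discriminant analysis of principal components) follows the adegenet
recipe: the genotype matrix is coded as per-allele counts (0/1/2, missing
imputed to the column mean), centred/scaled, reduced by PCA, clustered by
k-means over k = 1..k_max, the number of clusters selected by the k-means
BIC ``n*ln(WSS/n) + k*ln(n)``, and the retained principal components
separated by linear discriminant analysis on the selected clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genio import GenotypeTable

__all__ = [
    "weir_cockerham_theta",
    "pairwise_fst",
    "fst_permutation_p",
    "fst_matrix",
    "FstMatrix",
    "DAPC",
    "DAPCResults",
    "dapc_fit",
    "cluster_composition",
]


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components_locus(
    genotypes: list[np.ndarray],
) -> tuple[float, float, float] | None:
    """Variance components (a, b, c) summed over alleles for one locus.

    ``genotypes``: one (n_i, 2) array of allele codes per population (typed
    individuals only).  Returns None when the locus is undefined (fewer than
    two populations with >= 1 typed individual, or n_c <= 0).
    """
    pops = [g for g in genotypes if len(g) > 0]
    r = len(pops)
    if r < 2:
        return None
    n_i = np.array([len(g) for g in pops], dtype=float)
    nbar = n_i.mean()
    n_total = n_i.sum()
    nc = (n_total - (n_i**2).sum() / n_total) / (r - 1)
    if nbar <= 1.0 or nc <= 0.0:
        return None
    alleles = np.unique(np.concatenate([g.ravel() for g in pops]))
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([np.mean(g == al) for g in pops])
        h_i = np.array([np.mean((g[:, 0] == al) ^ (g[:, 1] == al)) for g in pops])
        pbar = (n_i * p_i).sum() / n_total
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / n_total
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def weir_cockerham_theta(
    tables: list[GenotypeTable],
) -> tuple[float, list[str]]:
    """Multi-population, multi-locus WC84 theta (ratio of sums over loci).

    Returns (theta, skipped_loci).  Raises if every locus is undefined.
    """
    if len(tables) < 2:
        raise ValueError("need at least two groups")
    loci = tables[0].loci
    for t in tables[1:]:
        if t.loci != loci:
            raise ValueError("locus sets differ between groups")
    num = den = 0.0
    skipped: list[str] = []
    for j, locus in enumerate(loci):
        genos = []
        for t in tables:
            typed = t.typed_mask()[:, j]
            genos.append(t.calls[typed, j, :])
        comps = _wc_components_locus(genos)
        if comps is None:
            skipped.append(locus)
            continue
        a, b, c = comps
        num += a
        den += a + b + c
    if den == 0.0 and num == 0.0:
        if len(skipped) == len(loci):
            raise ValueError("all loci undefined for theta")
        return 0.0, skipped
    if den == 0.0:
        raise ValueError("theta undefined: zero total variance")
    return num / den, skipped


def pairwise_fst(tableA: GenotypeTable, tableB: GenotypeTable) -> float:
    """WC84 theta between two groups (negative values reported as computed)."""
    theta, _ = weir_cockerham_theta([tableA, tableB])
    return theta


def fst_permutation_p(
    tableA: GenotypeTable,
    tableB: GenotypeTable,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value: individuals shuffled between the two groups.

    p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    obs = pairwise_fst(tableA, tableB)
    merged = tableA.concat(tableB)
    nA = tableA.n_individuals
    rng = np.random.default_rng(seed)
    n_ge = 0
    idx = np.arange(merged.n_individuals)
    for _ in range(n_perm):
        rng.shuffle(idx)
        pa = merged.subset(idx[:nA])
        pb = merged.subset(idx[nA:])
        try:
            if pairwise_fst(pa, pb) >= obs - 1e-15:
                n_ge += 1
        except ValueError:
            n_ge += 1  # undefined permutation counted conservatively
    return (1 + n_ge) / (n_perm + 1)


@dataclass
class FstMatrix:
    """Symmetric pairwise theta matrix with optional permutation p-values."""

    labels: list[str]
    theta: np.ndarray
    p_values: np.ndarray | None = None
    n_permutations: int = 0
    excluded: list[str] = dc_field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, gi in enumerate(self.labels):
            for j, gj in enumerate(self.labels):
                if j <= i:
                    continue
                p = self.p_values[i, j] if self.p_values is not None else np.nan
                rows.append((gi, gj, self.theta[i, j], p))
        return pd.DataFrame(rows, columns=["group1", "group2", "theta", "p"])

    def plot_heatmap(self, ax=None):
        """Heatmap of pairwise theta (darker = stronger differentiation)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.theta, cmap="viridis_r")
        ax.set_xticks(range(len(self.labels)), self.labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(self.labels)), self.labels, fontsize=7)
        ax.figure.colorbar(im, ax=ax, label=r"pairwise $\theta$")
        return ax


def fst_matrix(
    cohort_tables: dict[str, GenotypeTable],
    n_perm: int = 0,
    seed: int = 0,
) -> FstMatrix:
    """All pairwise theta (and p-values when n_perm > 0) among cohorts.

    Cohorts with fewer than two typed individuals are excluded with a
    warning entry in ``excluded``.
    """
    usable = {}
    excluded = []
    for name, tab in cohort_tables.items():
        if tab.typed_mask().any(axis=1).sum() < 2:
            excluded.append(name)
        else:
            usable[name] = tab
    labels = list(usable)
    if len(labels) < 2:
        raise ValueError("need at least two usable cohorts")
    k = len(labels)
    theta = np.zeros((k, k))
    pvals = np.full((k, k), np.nan) if n_perm > 0 else None
    for i in range(k):
        for j in range(i + 1, k):
            th = pairwise_fst(usable[labels[i]], usable[labels[j]])
            theta[i, j] = theta[j, i] = th
            if n_perm > 0:
                p = fst_permutation_p(
                    usable[labels[i]], usable[labels[j]], n_perm, seed + 13 * i + j
                )
                pvals[i, j] = pvals[j, i] = p
    return FstMatrix(
        labels=labels, theta=theta, p_values=pvals,
        n_permutations=n_perm, excluded=excluded,
    )


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------


def allele_count_matrix(table: GenotypeTable) -> tuple[np.ndarray, list[str]]:
    """Per-allele 0/1/2 count design matrix with mean imputation of missing."""
    cols = []
    names = []
    typed = table.typed_mask()
    for j, locus in enumerate(table.loci):
        alleles = np.unique(table.calls[typed[:, j], j, :])
        for al in alleles:
            cnt = (table.calls[:, j, :] == al).sum(axis=1).astype(float)
            cnt[~typed[:, j]] = np.nan
            cols.append(cnt)
            names.append(f"{locus}.{al}")
    X = np.stack(cols, axis=1)
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    return X, names


def kmeans_bic(n: int, wss: float, k: int) -> float:
    """k-means BIC profile value: n*ln(WSS/n) + k*ln(n)."""
    return n * np.log(wss / n) + k * np.log(n)


@dataclass
class DAPCResults:
    """Fitted DAPC: selected clusters, BIC profile, discriminant functions."""

    k: int
    assignments: np.ndarray  # (n,) cluster labels 0..k-1
    bic_profile: np.ndarray  # (k_max,) BIC(k) for k = 1..k_max
    n_pca: int
    n_da: int
    explained_variance_ratio: np.ndarray
    pc_scores: np.ndarray  # (n, n_pca)
    da_scores: np.ndarray | None  # (n, n_da) discriminant coordinates
    ids: list[str]

    def summary(self) -> str:
        lines = [
            "DAPC results",
            "============",
            f"individuals:        {len(self.ids)}",
            f"retained PCs:       {self.n_pca} "
            f"({100 * self.explained_variance_ratio[: self.n_pca].sum():.1f}% variance)",
            f"selected clusters:  {self.k}",
            f"discriminants kept: {self.n_da}",
            "",
            "k    BIC",
        ]
        for i, b in enumerate(self.bic_profile, start=1):
            mark = "  <- selected" if i == self.k else ""
            lines.append(f"{i:<4d} {b:10.2f}{mark}")
        return "\n".join(lines)

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "cluster": self.assignments})

    def plot_bic(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ks = np.arange(1, len(self.bic_profile) + 1)
        ax.plot(ks, self.bic_profile, "o-")
        ax.axvline(self.k, color="0.6", ls="--")
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("BIC")
        return ax


class DAPC:
    """Discriminant analysis of principal components on a genotype table.

    Parameters
    ----------
    table : GenotypeTable
    k_max : int
        Largest cluster count examined by k-means (>= 2).
    n_pca : int or None
        Retained principal components; default the smallest number
        explaining >= 90% of design-matrix variance.
    n_da : int or None
        Retained discriminant functions (at most k - 1).
    """

    def __init__(
        self,
        table: GenotypeTable,
        k_max: int = 10,
        n_pca: int | None = None,
        n_da: int | None = None,
        seed: int = 0,
        n_restarts: int = 10,
    ) -> None:
        if k_max < 2:
            raise ValueError("k_max must be >= 2")
        self.table = table
        self.k_max = k_max
        self.n_pca = n_pca
        self.n_da = n_da
        self.seed = seed
        self.n_restarts = n_restarts

    def fit(self) -> DAPCResults:
        X, _ = allele_count_matrix(self.table)
        sd = X.std(axis=0)
        if np.all(sd == 0):
            raise ValueError("no polymorphism: design matrix is constant")
        keep = sd > 0
        Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        n = Xs.shape[0]
        if self.n_pca is not None and self.n_pca >= n:
            raise ValueError("n_pca must be smaller than the number of individuals")
        pca = PCA(n_components=min(n - 1, Xs.shape[1]), random_state=self.seed)
        scores_full = pca.fit_transform(Xs)
        evr = pca.explained_variance_ratio_
        if self.n_pca is None:
            n_pca = int(np.searchsorted(np.cumsum(evr), 0.90) + 1)
            n_pca = min(n_pca, scores_full.shape[1])
        else:
            n_pca = min(self.n_pca, scores_full.shape[1])
        scores = scores_full[:, :n_pca]

        bic = np.empty(self.k_max)
        labels_by_k: list[np.ndarray] = []
        for k in range(1, self.k_max + 1):
            if k == 1:
                wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
                labels_by_k.append(np.zeros(n, dtype=int))
            else:
                km = KMeans(
                    n_clusters=k, n_init=self.n_restarts, random_state=self.seed
                ).fit(scores)
                wss = float(km.inertia_)
                labels_by_k.append(km.labels_)
            bic[k - 1] = kmeans_bic(n, wss, k)
        k_sel = int(np.argmin(np.round(bic, 10)) + 1)  # ties break to lowest k
        labels = labels_by_k[k_sel - 1]

        if k_sel > 1:
            n_da = self.n_da if self.n_da is not None else k_sel - 1
            n_da = min(n_da, k_sel - 1)
            lda = LinearDiscriminantAnalysis(n_components=n_da)
            da_scores = lda.fit_transform(scores, labels)
        else:
            n_da, da_scores = 0, None
        return DAPCResults(
            k=k_sel,
            assignments=labels,
            bic_profile=bic,
            n_pca=n_pca,
            n_da=n_da,
            explained_variance_ratio=evr,
            pc_scores=scores,
            da_scores=da_scores,
            ids=list(self.table.ids),
        )


def dapc_fit(
    table: GenotypeTable,
    k_max: int = 10,
    n_pca: int | None = None,
    n_da: int | None = None,
    seed: int = 0,
) -> DAPCResults:
    """Functional wrapper over :class:`DAPC`."""
    return DAPC(table, k_max=k_max, n_pca=n_pca, n_da=n_da, seed=seed).fit()


def cluster_composition(
    results: DAPCResults, cohort_labels: np.ndarray | list[str]
) -> pd.DataFrame:
    """Per cohort (site x month), the proportion of members in each cluster.

    Rows sum to 1.
    """
    cohort_labels = np.asarray(cohort_labels)
    if cohort_labels.shape[0] != len(results.ids):
        raise ValueError("cohort labels must cover all individuals")
    df = pd.DataFrame({"cohort": cohort_labels, "cluster": results.assignments})
    comp = (
        df.groupby("cohort", sort=False)["cluster"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    comp = comp.reindex(columns=range(results.k), fill_value=0.0)
    return comp
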