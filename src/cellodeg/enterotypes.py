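"""Species-level enterotyping of microbiome samples.

Samples (rows of a relative-abundance table) are clustered with Partitioning
Around Medoids (PAM) on Bray-Curtis dissimilarity. The number of clusters is
selected over k = 2..6 by the Calinski-Harabasz (CH) index computed from
k-means on Hellinger-transformed abundances (Euclidean space), with the mean
silhouette width from PAM on Bray-Curtis reported alongside. Cluster
reproducibility is assessed by bootstrap resampling with maximum-Jaccard
matching of clusters.

Note the deliberate two-space design: final enterotype labels come from PAM
on Bray-Curtis of *untransformed* relative abundances, while the CH index is
evaluated on the *Hellinger-transformed* table — this mirrors the common
enterotyping workflow and surprises users, so it is called out here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .stats import kw_dunn  # noqa: F401  (re-exported: group comparisons live here)

__all__ = [
    "validate_abundance",
    "hellinger",
    "bray_curtis",
    "PAMMedoids",
    "pam",
    "EnterotypeModel",
    "EnterotypeResult",
    "select_k",
    "bootstrap_stability",
    "CoreTaxonReport",
    "core_taxa",
    "kw_dunn",
]


def validate_abundance(table: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Validate a samples x species relative-abundance table.

    Rows not summing to 1 within `atol` are renormalized with a warning;
    negative values are rejected.
    """
    values = table.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance table contains negative values")
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("abundance table contains all-zero rows")
    if not np.allclose(sums, 1.0, atol=atol):
        warnings.warn("abundance rows do not sum to 1; renormalizing",
                      UserWarning, stacklevel=2)
    return table.div(sums, axis=0)


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: entry-wise square root of relative abundances."""
    table = validate_abundance(table)
    return np.sqrt(table)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix between samples.

    D(x, y) = 1 - 2 * sum_i min(x_i, y_i) / sum_i (x_i + y_i).
    """
    values = table.to_numpy(dtype=float)
    d = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


class PAMMedoids(BaseEstimator, ClusterMixin):
    """Partitioning Around Medoids on a precomputed dissimilarity matrix.

    Small instances (C(n, k) <= `exact_combinations`) are solved exactly by
    enumerating medoid sets, since single-swap descent can stall in local
    optima that exhaustive search avoids. Larger instances use the classic
    deterministic BUILD phase (greedy medoid seeding) followed by SWAP
    iterations until no single medoid/non-medoid exchange reduces the total
    within-cluster dissimilarity. Ties are broken by smallest index, so the
    fit is fully deterministic either way.

    Parameters
    ----------
    n_clusters : int
        Number of medoids k (k >= 1; k < n_samples).
    max_iter : int
        Cap on SWAP passes.
    exact_combinations : int
        Enumerate all medoid sets when C(n, k) is at most this bound.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster index of each sample, 0..k-1 ordered by medoid index.
    medoid_indices_ : ndarray of shape (k,)
        Row indices of the medoids, sorted ascending.
    inertia_ : float
        Total dissimilarity of samples to their nearest medoid.
    """

    def __init__(self, n_clusters: int = 3, max_iter: int = 300,
                 exact_combinations: int = 10_000):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.exact_combinations = exact_combinations

    def fit(self, X, y=None):
        from itertools import combinations
        from math import comb

        D = np.asarray(X, dtype=float)
        n = D.shape[0]
        k = self.n_clusters
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("X must be a square dissimilarity matrix")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("dissimilarity matrix must be symmetric")
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if k >= n and k != 1:
            raise ValueError(f"n_clusters={k} must be < n_samples={n}")

        if comb(n, k) <= self.exact_combinations:
            best_cost, best_set = np.inf, None
            for cand in combinations(range(n), k):
                cost = D[:, cand].min(axis=1).sum()
                if cost < best_cost - 1e-12:
                    best_cost, best_set = cost, cand
            return self._finalize(D, list(best_set))

        # BUILD: first medoid minimizes total dissimilarity; subsequent
        # medoids maximize the summed reduction in nearest-medoid distance.
        medoids = [int(np.argmin(D.sum(axis=1)))]
        dn = D[medoids[0]].copy()  # distance to nearest medoid
        while len(medoids) < k:
            gains = np.maximum(dn[None, :] - D, 0.0).sum(axis=1)
            gains[medoids] = -np.inf
            j = int(np.argmax(gains))
            medoids.append(j)
            dn = np.minimum(dn, D[j])

        medoids = sorted(medoids)
        # SWAP
        for _ in range(self.max_iter):
            Dm = D[:, medoids]  # (n, k)
            idx1 = np.argmin(Dm, axis=1)
            d1 = Dm[np.arange(n), idx1]
            Dm_inf = Dm.copy()
            Dm_inf[np.arange(n), idx1] = np.inf
            d2 = Dm_inf.min(axis=1)
            current = d1.sum()
            non_medoids = np.setdiff1d(np.arange(n), medoids)
            best = (0.0, None, None)
            for jpos in range(len(medoids)):
                base = np.where(idx1 == jpos, d2, d1)
                costs = np.minimum(base[:, None], D[:, non_medoids]).sum(axis=0)
                h = int(np.argmin(costs))
                delta = costs[h] - current
                if delta < best[0] - 1e-12:
                    best = (delta, jpos, non_medoids[h])
            if best[1] is None:
                break
            medoids[best[1]] = int(best[2])
            medoids = sorted(medoids)

        return self._finalize(D, medoids)

    def _finalize(self, D: np.ndarray, medoids: list[int]):
        n = D.shape[0]
        medoids_arr = np.array(sorted(medoids), dtype=int)
        labels = np.argmin(D[:, medoids_arr], axis=1)
        labels[medoids_arr] = np.arange(len(medoids_arr))  # medoids label themselves
        self.medoid_indices_ = medoids_arr
        self.labels_ = labels
        self.inertia_ = float(D[np.arange(n), medoids_arr[labels]].sum())
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def pam(D, k: int, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """PAM clustering of a dissimilarity matrix; returns (labels, medoids).

    `seed` is accepted for interface symmetry; BUILD+SWAP is deterministic.
    """
    model = PAMMedoids(n_clusters=k).fit(np.asarray(D, dtype=float))
    return model.labels_, model.medoid_indices_


@dataclass
class EnterotypeResult:
    """Enterotype discovery output."""

    k_selected: int
    labels: pd.Series  # sample -> cluster 1..k
    medoids: list  # medoid sample id per cluster
    ch_by_k: dict[int, float]
    sil_by_k: dict[int, float]
    low_support: bool
    boot_jaccard: dict[int, float] = field(default_factory=dict)


class EnterotypeModel(BaseEstimator, ClusterMixin):
    """Enterotype discovery with cluster-number selection.

    fit(table) computes, for each k in `k_range`, the CH index from k-means
    (best of `n_init` initializations) on the Hellinger-transformed table and
    the mean silhouette width from PAM on Bray-Curtis. k is selected as the
    CH argmax; final labels come from PAM on Bray-Curtis of the untransformed
    relative abundances.

    Attributes
    ----------
    k_selected_ : int
    labels_ : ndarray (1..k per sample)
    medoid_samples_ : list of sample ids
    ch_by_k_, sil_by_k_ : dict k -> score
    low_support_ : bool — True when max silhouette < 0.25 (weak structure)
    """

    def __init__(self, k_range=(2, 3, 4, 5, 6), n_init: int = 100,
                 random_state: int | None = None):
        self.k_range = k_range
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        table = validate_abundance(
            X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        )
        n = table.shape[0]
        ks = [int(k) for k in self.k_range]
        if n <= max(ks):
            raise ValueError("need more samples than the largest candidate k")
        H = np.sqrt(table.to_numpy(dtype=float))
        D = bray_curtis(table).to_numpy()
        if np.allclose(D, 0.0, atol=1e-12):
            raise ValueError("degenerate table: all samples identical")

        ch: dict[int, float] = {}
        sil: dict[int, float] = {}
        pam_labels: dict[int, PAMMedoids] = {}
        for k in ks:
            km = KMeans(n_clusters=k, n_init=self.n_init,
                        random_state=self.random_state).fit(H)
            ch[k] = float(calinski_harabasz_score(H, km.labels_))
            model = PAMMedoids(n_clusters=k).fit(D)
            pam_labels[k] = model
            sil[k] = float(silhouette_score(D, model.labels_, metric="precomputed"))

        k_sel = max(ks, key=lambda k: ch[k])
        k_sil = max(ks, key=lambda k: sil[k])
        if k_sil != k_sel:
            warnings.warn(
                f"silhouette favors k={k_sil} while CH selects k={k_sel}",
                UserWarning, stacklevel=2,
            )
        final = pam_labels[k_sel]
        self.k_selected_ = k_sel
        self.labels_ = final.labels_ + 1  # enterotypes numbered 1..k
        self.medoid_samples_ = [table.index[i] for i in final.medoid_indices_]
        self.ch_by_k_ = ch
        self.sil_by_k_ = sil
        self.low_support_ = max(sil.values()) < 0.25
        self._table_index = table.index
        return self

    def result_(self) -> EnterotypeResult:
        return EnterotypeResult(
            k_selected=self.k_selected_,
            labels=pd.Series(self.labels_, index=self._table_index,
                             name="enterotype"),
            medoids=self.medoid_samples_,
            ch_by_k=self.ch_by_k_,
            sil_by_k=self.sil_by_k_,
            low_support=self.low_support_,
        )


def select_k(table: pd.DataFrame, k_range=range(2, 7), n_init: int = 100,
             seed: int | None = None) -> EnterotypeResult:
    """Functional wrapper over :class:`EnterotypeModel`."""
    model = EnterotypeModel(k_range=tuple(k_range), n_init=n_init,
                            random_state=seed).fit(table)
    return model.result_()


def bootstrap_stability(table: pd.DataFrame, k: int, B: int = 500,
                        seed: int | None = None) -> dict[int, float]:
    """Bootstrap cluster stability: per-cluster mean Jaccard over B resamples.

    For each resample (samples drawn with replacement) the resampled
    dissimilarity matrix is reclustered with PAM; each original cluster is
    matched to its maximum-Jaccard counterpart among the new clusters
    (Jaccard computed over resample positions), and the per-cluster Jaccard
    is averaged over the B resamples.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    table = validate_abundance(table)
    D = bray_curtis(table).to_numpy()
    n = D.shape[0]
    ref_labels, _ = pam(D, k)
    rng = np.random.default_rng(seed)
    sums = np.zeros(k)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        Db = D[np.ix_(idx, idx)]
        try:
            lb, _ = pam(Db, k)
        except ValueError:
            continue  # degenerate resample (fewer distinct points than k)
        orig = ref_labels[idx]
        for c in range(k):
            members = orig == c
            if not members.any():
                continue
            best = 0.0
            for c2 in np.unique(lb):
                new = lb == c2
                jac = (members & new).sum() / (members | new).sum()
                best = max(best, jac)
            sums[c] += best
    return {c: float(sums[c] / B) for c in range(k)}


@dataclass
class CoreTaxonReport:
    species_id: str
    prevalence: float
    mean_abundance: float
    is_core: bool


def core_taxa(table: pd.DataFrame, prevalence_threshold: float = 0.70,
              presence_abund: float = 0.0001) -> list[CoreTaxonReport]:
    """Core-taxon calling: present (abundance > presence_abund) in more than
    `prevalence_threshold` of samples."""
    table = validate_abundance(table)
    values = table.to_numpy(dtype=float)
    prev = (values > presence_abund).mean(axis=0)
    means = values.mean(axis=0)
    return [
        CoreTaxonReport(species_id=str(sp), prevalence=float(p),
                        mean_abundance=float(m),
                        is_core=bool(p > prevalence_threshold))
        for sp, p, m in zip(table.columns, prev, means)
    ]
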