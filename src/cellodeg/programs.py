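"""Per-cell expression programs: normalization, module scores, O2 signature.

The central quantity is the bidirectional oxygen-dependence score. Two gene
sets contrast aerobic respiration (cytochrome bo oxidase *cyoABCD*, succinate
dehydrogenase *sdhABCD*, core TCA genes *icd*, *sucABCD*) against
microoxic/anaerobic respiration and fermentation (cytochrome bd *cydABX*,
fumarate reductase *frdABCD*, nitrate/nitrite respiration *narGHIJ*, *nrfA*,
fermentation genes *pflB*, *ldhA*, *adhE*). Each set receives a
binned-control module score on log-normalized expression, and

    O2 score = score(O2+) - score(O2-),

z-standardized over the scored cell population as O2 score_z. Positive
values indicate an aerobic-like transcriptional state. A rank-based
(UCell-style) score provides an orthogonal implementation for robustness
checks.

Feature identifiers carry genome-level prefixes ("GenomeID|GeneID"); gene
symbols are mapped onto features by suffix match or an explicit map, and
each set must match at least three features for scoring to proceed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .stats import RankSumResult, bh_adjust, rank_sum

__all__ = [
    "O2_PLUS_GENES",
    "O2_MINUS_GENES",
    "UMIMatrix",
    "GeneSetPair",
    "ModuleScoreParams",
    "lognorm",
    "ModuleScorer",
    "module_score",
    "O2SignatureScorer",
    "o2_score",
    "rank_score",
    "map_symbols_to_features",
    "cluster_filters",
    "marker_genes",
    "lpmo_contrast",
    "correlate",
    "covariate_check",
    "pca_kmeans_clusters",
]

O2_PLUS_GENES = (
    "cyoA", "cyoB", "cyoC", "cyoD",
    "sdhA", "sdhB", "sdhC", "sdhD",
    "icd", "sucA", "sucB", "sucC", "sucD",
)
O2_MINUS_GENES = (
    "cydA", "cydB", "cydX",
    "frdA", "frdB", "frdC", "frdD",
    "narG", "narH", "narI", "narJ",
    "nrfA", "pflB", "ldhA", "adhE",
)


@dataclass
class UMIMatrix:
    """Sparse cells x genes UMI count matrix with metadata.

    Feature ids are expected to carry "GenomeID|GeneID" prefixes. nFeature
    (detected genes per cell) and nCount (UMIs per cell) are derived, not
    stored.
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    sample_ids: list[str] | None = None
    clusters: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length does not match matrix rows")
        if self.counts.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length does not match matrix columns")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("UMI counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    @property
    def n_counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, idx: np.ndarray) -> "UMIMatrix":
        idx = np.asarray(idx)
        return UMIMatrix(
            counts=self.counts[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            sample_ids=([self.sample_ids[i] for i in idx]
                        if self.sample_ids is not None else None),
            clusters=(self.clusters[idx] if self.clusters is not None else None),
        )


@dataclass
class GeneSetPair:
    """Aerobic (O2+) / anaerobic (O2-) marker gene symbols."""

    o2_plus: tuple[str, ...] = O2_PLUS_GENES
    o2_minus: tuple[str, ...] = O2_MINUS_GENES
    min_matched: int = 3


@dataclass
class ModuleScoreParams:
    """Binned-control module-score parameters (AddModuleScore conventions)."""

    nbin: int = 24
    ctrl: int = 100
    seed: int = 1

    def __post_init__(self) -> None:
        if self.nbin < 2:
            raise ValueError("nbin must be >= 2")
        if self.ctrl < 1:
            raise ValueError("ctrl must be >= 1")


def lognorm(matrix: UMIMatrix, scale: float = 10_000.0) -> sp.csr_matrix:
    """Log-normalize: entry = ln(1 + scale * count / nCount_cell).

    Scale-invariant per cell (doubling a cell's counts leaves its normalized
    values unchanged). Cells with zero total counts are an error — they
    should have been removed by the feature filter.
    """
    ncount = matrix.n_counts_per_cell
    if (ncount <= 0).any():
        raise ValueError("zero-count cell encountered; filter cells first")
    X = sp.csr_matrix(matrix.counts, dtype=float, copy=True)
    inv = scale / ncount
    X = sp.diags(inv) @ X
    X.data = np.log1p(X.data)
    return sp.csr_matrix(X)


def map_symbols_to_features(feature_ids: Sequence[str], symbols: Sequence[str],
                            symbol_map: Mapping[str, Sequence[str]] | None = None,
                            ) -> tuple[list[int], list[str]]:
    """Map gene symbols to feature-matrix column indices.

    Default rule: a feature "Genome|gene" matches symbol "gene" by its suffix
    after the last "|" (exact, case-sensitive). An explicit symbol -> feature
    id map overrides the rule (needed when symbols repeat across genomes and
    only some genomes should contribute). Returns (column indices, unmapped
    symbols).
    """
    idx_of = {f: i for i, f in enumerate(feature_ids)}
    suffix: dict[str, list[int]] = {}
    for i, f in enumerate(feature_ids):
        suffix.setdefault(f.rsplit("|", 1)[-1], []).append(i)
    cols: list[int] = []
    unmapped: list[str] = []
    for s in symbols:
        if symbol_map is not None and s in symbol_map:
            hit = [idx_of[f] for f in symbol_map[s] if f in idx_of]
        else:
            hit = suffix.get(s, [])
        if hit:
            cols.extend(hit)
        else:
            unmapped.append(s)
    return sorted(set(cols)), unmapped


class ModuleScorer(BaseEstimator):
    """Binned-control gene-set module scoring (AddModuleScore conventions).

    fit(X) ranks genes by mean normalized expression across cells and splits
    them into `nbin` equal-frequency bins (ties broken by feature-id order).
    score(columns) then samples, per set gene, `ctrl` control genes from the
    gene's bin excluding all set genes (without replacement; with replacement
    when the bin holds fewer than `ctrl` eligible genes) and returns

        score(cell) = mean expression over set genes
                      - mean expression over all sampled controls.

    Adding a constant to every entry of the expression layer leaves the
    score unchanged (shift cancellation); the control draw is fixed by
    `random_state`.
    """

    def __init__(self, nbin: int = 24, ctrl: int = 100, random_state: int = 1):
        self.nbin = nbin
        self.ctrl = ctrl
        self.random_state = random_state

    def fit(self, X, feature_ids: Sequence[str] | None = None):
        ModuleScoreParams(self.nbin, self.ctrl, self.random_state)  # validate
        X = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X, dtype=float)
        self._X = X
        n_genes = X.shape[1]
        self.feature_ids_ = (list(feature_ids) if feature_ids is not None
                             else [str(i) for i in range(n_genes)])
        means = np.asarray(X.mean(axis=0)).ravel()
        # equal-frequency binning on the rank of mean expression; ties in the
        # mean broken by feature-id order for determinism
        order = np.lexsort((np.array(self.feature_ids_), means))
        ranks = np.empty(n_genes, dtype=int)
        ranks[order] = np.arange(n_genes)
        self.bins_ = (ranks * self.nbin) // n_genes
        self.gene_means_ = means
        return self

    def _col_mean(self, cols: Sequence[int]) -> np.ndarray:
        sub = self._X[:, list(cols)]
        return np.asarray(sub.mean(axis=1)).ravel()

    def score(self, set_cols: Sequence[int]) -> np.ndarray:
        """Per-cell module score for the gene set given as column indices."""
        set_cols = sorted(set(int(c) for c in set_cols))
        if not set_cols:
            raise ValueError("empty gene set")
        rng = np.random.default_rng(self.random_state)
        set_mask = np.zeros(len(self.feature_ids_), dtype=bool)
        set_mask[set_cols] = True
        ctrl_cols: list[int] = []
        for c in set_cols:
            pool = np.flatnonzero((self.bins_ == self.bins_[c]) & ~set_mask)
            if pool.size == 0:
                continue
            replace = pool.size < self.ctrl
            take = rng.choice(pool, size=min(self.ctrl, pool.size) if not replace
                              else self.ctrl, replace=replace)
            ctrl_cols.extend(take.tolist())
        if not ctrl_cols:
            raise ValueError("no eligible control genes for this set")
        return self._col_mean(set_cols) - self._col_mean(ctrl_cols)

    def score_symbols(self, symbols: Sequence[str],
                      symbol_map: Mapping[str, Sequence[str]] | None = None,
                      min_matched: int = 1) -> np.ndarray:
        cols, unmapped = map_symbols_to_features(self.feature_ids_, symbols,
                                                 symbol_map)
        if len(cols) < min_matched:
            raise ValueError(
                f"gene set matches {len(cols)} features (< {min_matched} "
                f"required); unmapped symbols: {unmapped}"
            )
        return self.score(cols)


def module_score(norm_matrix, feature_ids: Sequence[str],
                 gene_set: Sequence[str],
                 params: ModuleScoreParams | None = None,
                 symbol_map: Mapping[str, Sequence[str]] | None = None,
                 min_matched: int = 1) -> np.ndarray:
    """Functional wrapper over :class:`ModuleScorer`."""
    params = params or ModuleScoreParams()
    scorer = ModuleScorer(params.nbin, params.ctrl, params.seed)
    scorer.fit(norm_matrix, feature_ids)
    return scorer.score_symbols(gene_set, symbol_map, min_matched)


class O2SignatureScorer(BaseEstimator):
    """Bidirectional O2 score: module_score(O2+) - module_score(O2-), plus z.

    fit_transform returns a per-cell score table with S_plus, S_minus,
    o2_score and o2_score_z (z-standardized over the scored population,
    population sd).
    """

    def __init__(self, pair: GeneSetPair | None = None, nbin: int = 24,
                 ctrl: int = 100, random_state: int = 1,
                 symbol_map: Mapping[str, Sequence[str]] | None = None):
        self.pair = pair
        self.nbin = nbin
        self.ctrl = ctrl
        self.random_state = random_state
        self.symbol_map = symbol_map

    def fit_transform(self, norm_matrix, feature_ids: Sequence[str],
                      cell_ids: Sequence[str] | None = None) -> pd.DataFrame:
        pair = self.pair or GeneSetPair()
        scorer = ModuleScorer(self.nbin, self.ctrl, self.random_state)
        scorer.fit(norm_matrix, feature_ids)
        s_plus = scorer.score_symbols(pair.o2_plus, self.symbol_map,
                                      pair.min_matched)
        s_minus = scorer.score_symbols(pair.o2_minus, self.symbol_map,
                                       pair.min_matched)
        o2 = s_plus - s_minus
        sd = o2.std(ddof=0)
        z = (o2 - o2.mean()) / sd if sd > 0 else np.zeros_like(o2)
        index = (pd.Index(cell_ids, name="cell") if cell_ids is not None
                 else pd.RangeIndex(len(o2), name="cell"))
        self.scorer_ = scorer
        return pd.DataFrame(
            {"S_plus": s_plus, "S_minus": s_minus,
             "o2_score": o2, "o2_score_z": z},
            index=index,
        )


def o2_score(norm_matrix, feature_ids: Sequence[str],
             pair: GeneSetPair | None = None,
             params: ModuleScoreParams | None = None,
             cell_ids: Sequence[str] | None = None,
             symbol_map: Mapping[str, Sequence[str]] | None = None,
             ) -> pd.DataFrame:
    """Functional wrapper over :class:`O2SignatureScorer`."""
    params = params or ModuleScoreParams()
    return O2SignatureScorer(pair, params.nbin, params.ctrl, params.seed,
                             symbol_map).fit_transform(norm_matrix, feature_ids,
                                                       cell_ids)


def rank_score(norm_matrix, feature_ids: Sequence[str],
               gene_set: Sequence[str], r_max: int = 1500,
               symbol_map: Mapping[str, Sequence[str]] | None = None,
               min_matched: int = 1) -> np.ndarray:
    """UCell-style rank-based per-cell score in [0, 1].

    Genes are ranked within each cell by expression descending (average
    ranks on ties), ranks capped at `r_max`, and

        score = 1 - (sum of capped set ranks - n(n+1)/2) / (n * r_max)

    with n the set size. Invariant under any strictly monotone transform of
    a cell's expression vector.
    """
    cols, unmapped = map_symbols_to_features(feature_ids, gene_set, symbol_map)
    if len(cols) < min_matched:
        raise ValueError(f"gene set matches {len(cols)} features; "
                         f"unmapped: {unmapped}")
    n_set = len(cols)
    if n_set > r_max:
        raise ValueError(f"set size {n_set} exceeds r_max={r_max}")
    X = (norm_matrix.toarray() if sp.issparse(norm_matrix)
         else np.asarray(norm_matrix, dtype=float))
    ranks = sps.rankdata(-X, axis=1, method="average")
    capped = np.minimum(ranks[:, cols], r_max)
    return 1.0 - (capped.sum(axis=1) - n_set * (n_set + 1) / 2.0) / (n_set * r_max)


def cluster_filters(cluster_labels: Sequence, sample_ids: Sequence,
                    min_cells: int = 100, min_samples: int = 2
                    ) -> tuple[list, pd.DataFrame]:
    """Retain clusters with >= min_cells cells appearing in >= min_samples samples.

    Returns (retained cluster labels, per-cluster report).
    """
    df = pd.DataFrame({"cluster": list(cluster_labels),
                       "sample": list(sample_ids)})
    rep = df.groupby("cluster").agg(
        n_cells=("sample", "size"), n_samples=("sample", "nunique")
    ).reset_index()
    rep["retained"] = (rep["n_cells"] >= min_cells) & (rep["n_samples"] >= min_samples)
    retained = rep.loc[rep["retained"], "cluster"].tolist()
    return retained, rep


def marker_genes(norm_matrix, feature_ids: Sequence[str],
                 labels: Sequence, log2fc_threshold: float = 0.25,
                 adj_p_threshold: float = 0.05,
                 pseudocount: float = 1e-9) -> pd.DataFrame:
    """One-vs-rest marker detection per cluster.

    Per gene and cluster: two-sided Wilcoxon rank-sum of in-cluster vs rest
    expression, BH adjustment across genes within the cluster, and log2 fold
    change of mean exp-shifted (expm1) expression with a pseudocount guard.
    Markers satisfy log2FC > `log2fc_threshold` and adj-P < `adj_p_threshold`.
    Clusters with fewer than 3 cells are skipped with a warning.
    """
    X = (norm_matrix.toarray() if sp.issparse(norm_matrix)
         else np.asarray(norm_matrix, dtype=float))
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("marker detection requires >= 2 clusters")
    expm = np.expm1(X)
    frames = []
    for c in uniq:
        mask = labels == c
        if mask.sum() < 3:
            warnings.warn(f"cluster {c!r} has <3 cells; skipped",
                          UserWarning, stacklevel=2)
            continue
        res = sps.mannwhitneyu(X[mask], X[~mask], axis=0,
                               alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
        lfc = np.log2((expm[mask].mean(axis=0) + pseudocount)
                      / (expm[~mask].mean(axis=0) + pseudocount))
        adj = bh_adjust(p)
        frames.append(pd.DataFrame({
            "cluster": c, "feature": list(feature_ids),
            "log2fc": lfc, "p": p, "p_adj": adj,
            "is_marker": (lfc > log2fc_threshold) & (adj < adj_p_threshold),
        }))
    return pd.concat(frames, ignore_index=True)


def lpmo_contrast(score: Sequence[float], lpmo_expression: Sequence[float]
                  ) -> RankSumResult:
    """Rank-sum contrast of scores between LPMO-positive (>0) and -negative cells."""
    score = np.asarray(score, dtype=float)
    lpmo = np.asarray(lpmo_expression, dtype=float)
    pos = lpmo > 0
    if not pos.any() or pos.all():
        raise ValueError("both LPMO-positive and LPMO-negative groups must be nonempty")
    return rank_sum(score[pos], score[~pos])


def correlate(score_table: pd.DataFrame,
              fdr_alpha: float = 0.05) -> dict:
    """Pairwise Spearman correlations among score columns, with BH FDR and
    average-linkage clustering on distance max(0, 1 - (rho + rho^T)/2).

    Pairwise-complete observations per pair; constant columns yield missing
    correlations and are excluded from the clustering.
    """
    cols = list(score_table.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            pair = score_table.iloc[:, [i, j]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                continue  # constant column: undefined rho
            r, p = sps.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    iu = np.triu_indices(k, 1)
    adj_flat = bh_adjust(pval[iu])
    p_adj = np.full((k, k), np.nan)
    p_adj[iu] = adj_flat
    p_adj.T[iu] = adj_flat
    np.fill_diagonal(p_adj, 0.0)

    dist = np.maximum(0.0, 1.0 - (rho + rho.T) / 2.0)
    np.fill_diagonal(dist, 0.0)
    # exclude columns with undefined correlations: greedily drop the column
    # with the most missing pairs until the submatrix is complete
    valid = np.ones(k, dtype=bool)
    while True:
        nan_counts = np.where(valid,
                              np.isnan(dist[:, valid]).sum(axis=1), -1)
        if nan_counts.max() <= 0:
            break
        valid[int(np.argmax(nan_counts))] = False
    Z = None
    if valid.sum() >= 2:
        sub = dist[np.ix_(valid, valid)]
        Z = linkage(squareform(sub, checks=False), method="average")
    return {
        "rho": pd.DataFrame(rho, index=cols, columns=cols),
        "p": pd.DataFrame(pval, index=cols, columns=cols),
        "p_adj": pd.DataFrame(p_adj, index=cols, columns=cols),
        "significant": pd.DataFrame(p_adj < fdr_alpha, index=cols, columns=cols),
        "distance": pd.DataFrame(dist, index=cols, columns=cols),
        "linkage": Z,
        "clustered_columns": [c for c, v in zip(cols, valid) if v],
    }


def covariate_check(o2_z: Sequence[float], n_feature: Sequence[float],
                    n_count: Sequence[float],
                    clusters: Sequence | None = None) -> dict:
    """Technical-covariate robustness of the O2 score.

    Reports Spearman correlations of o2_score_z with nFeature and nCount,
    residualizes o2_score_z on (log nFeature, log nCount) by OLS, and — when
    cluster labels are given — the Spearman correlation between cluster-level
    mean orderings before and after adjustment.
    """
    z = np.asarray(o2_z, dtype=float)
    nf = np.asarray(n_feature, dtype=float)
    nc = np.asarray(n_count, dtype=float)
    rho_nf, p_nf = sps.spearmanr(z, nf)
    rho_nc, p_nc = sps.spearmanr(z, nc)
    design = np.column_stack([np.ones_like(z), np.log(nf), np.log(nc)])
    beta, *_ = np.linalg.lstsq(design, z, rcond=None)
    resid = z - design @ beta
    out = {
        "rho_nfeature": float(rho_nf), "p_nfeature": float(p_nf),
        "rho_ncount": float(rho_nc), "p_ncount": float(p_nc),
        "residual": resid,
    }
    if clusters is not None:
        df = pd.DataFrame({"c": np.asarray(clusters), "before": z,
                           "after": resid})
        means = df.groupby("c").mean()
        rho_order, _ = sps.spearmanr(means["before"], means["after"])
        out["cluster_ordering_rho"] = float(rho_order)
    return out


def pca_kmeans_clusters(norm_matrix, n_clusters: int, n_pcs: int = 10,
                        seed: int = 0) -> np.ndarray:
    """Documented stand-in for upstream graph clustering: PCA + k-means.

    Used to produce cluster labels on synthetic data; externally produced
    labels are accepted everywhere labels are consumed.
    """
    X = (norm_matrix.toarray() if sp.issparse(norm_matrix)
         else np.asarray(norm_matrix, dtype=float))
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    return KMeans(n_clusters=n_clusters, n_init=10, random_state=seed
                  ).fit_predict(pcs)
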