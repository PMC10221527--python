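"""Taxa-table preprocessing and community summaries.

Rarefaction to a common depth, the abundance/prevalence retention rule,
alpha diversity (observed features, Shannon), Bray-Curtis dissimilarity,
principal-coordinates analysis and ANOSIM. Filtering defaults follow the
common 16S practice of keeping taxa with mean relative abundance > 0.05%
that are detected in more than 5% of individuals.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .containers import TaxaTable


def rarefy(table: TaxaTable, depth: int, seed: int = 0) -> TaxaTable:
    """Subsample every sample's counts to ``depth`` reads without replacement.

    Every output row sums to exactly ``depth``. Samples whose total is below
    the requested depth are reported by id and rejected.
    """
    counts = table.data.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction needs an integer count table")
    counts = counts.astype(np.int64)
    totals = counts.sum(axis=1)
    short = totals < depth
    if short.any():
        bad = [f"{sid} ({tot})" for sid, tot in
               zip(np.asarray(table.sample_ids)[short], totals[short])]
        raise ValueError(f"samples with fewer than {depth} reads: {', '.join(bad)}")
    rng = np.random.default_rng(seed)
    out = np.vstack([rng.multivariate_hypergeometric(row, depth) for row in counts])
    return table.with_data(pd.DataFrame(out, index=table.data.index,
                                        columns=table.data.columns))


def filter_taxa(table: TaxaTable, min_mean_relabund: float = 0.0005,
                min_prevalence: float = 0.05) -> TaxaTable:
    """Keep taxa with mean relative abundance strictly above
    ``min_mean_relabund`` that are detected in strictly more than
    ``min_prevalence`` of the samples. Column order is preserved and the
    retained columns keep their original values (no renormalization)."""
    rel = table.relative_abundance()
    mean_ab = rel.mean(axis=0)
    prev = (table.data > 0).mean(axis=0)
    keep = (mean_ab > min_mean_relabund) & (prev > min_prevalence)
    if not keep.any():
        warnings.warn("no taxa pass the abundance/prevalence filter", stacklevel=2)
    return table.with_data(table.data.loc[:, keep])


def observed_features(sample_counts) -> int:
    """Number of taxa with abundance > 0 in one sample."""
    arr = np.asarray(sample_counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    return int((arr > 0).sum())


def shannon(sample_counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i over detected taxa."""
    arr = np.asarray(sample_counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero sample has undefined diversity")
    p = arr[arr > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def alpha_diversity(table: TaxaTable, base: float = 2.0) -> pd.DataFrame:
    return pd.DataFrame(
        {"observed_features": [observed_features(r) for r in table.data.to_numpy()],
         "shannon": [shannon(r, base=base) for r in table.data.to_numpy()]},
        index=table.data.index)


def bray_curtis(table: TaxaTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, BC(x,y) = sum|x-y| / sum(x+y)."""
    arr = table.data.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two samples")
    zero_rows = (arr.sum(axis=1) == 0)
    if zero_rows.sum() >= 2:
        bad = list(np.asarray(table.sample_ids)[zero_rows])
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    dm = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.data.index, columns=table.data.index)


def pcoa(distance_matrix: pd.DataFrame, k: int = 2):
    """Classical metric scaling of a distance matrix.

    Double-centers the squared distances, eigendecomposes the Gram matrix
    and returns coordinates on the axes with positive eigenvalues, ordered
    by descending eigenvalue. Negative eigenvalues (from non-Euclidean
    dissimilarities such as Bray-Curtis) are reported but contribute no
    axes; explained fractions are taken over the positive eigenvalues.

    Returns
    -------
    coords : DataFrame (samples x min(k, n_positive))
    explained : ndarray of per-axis fractions for the returned axes
    eigvals : ndarray, all eigenvalues in descending order
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-10, 1e-10 * abs(eigvals[0]))
    n_axes = int(min(k, pos.sum()))
    lam = eigvals[:n_axes]
    coords = eigvecs[:, :n_axes] * np.sqrt(lam)
    index = (distance_matrix.index if isinstance(distance_matrix, pd.DataFrame)
             else pd.RangeIndex(n))
    coords = pd.DataFrame(coords, index=index,
                          columns=[f"PCo{i + 1}" for i in range(n_axes)])
    explained = lam / eigvals[pos].sum() if pos.any() else np.zeros(0)
    return coords, explained, eigvals


def anosim(distance_matrix: pd.DataFrame, groups, n_perm: int | str = 999,
           seed: int = 0) -> tuple[float, float]:
    """ANOSIM R statistic with a permutation (or exact-enumeration) p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2, average ranks on ties. With ``n_perm="exact"`` the p-value
    is computed over every distinct assignment of labels to samples;
    otherwise it is the sampled permutation p with the +1 correction,
    p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    d = np.asarray(distance_matrix, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = list(labels[counts < 2])
        raise ValueError(f"groups with fewer than two samples: {small}")
    iu = np.triu_indices(d.shape[0], k=1)
    rank_d = rankdata(d[iu])
    r_obs = _anosim_r_from_ranks(rank_d, groups, iu)
    if n_perm == "exact":
        perms = set()
        hits = total = 0
        for perm in itertools.permutations(range(len(groups))):
            key = tuple(groups[list(perm)])
            if key in perms:
                continue
            perms.add(key)
            total += 1
            if _anosim_r_from_ranks(rank_d, np.asarray(key), iu) >= r_obs - 1e-12:
                hits += 1
        return r_obs, hits / total
    rng = np.random.default_rng(seed)
    hits = sum(
        _anosim_r_from_ranks(rank_d, rng.permutation(groups), iu) >= r_obs - 1e-12
        for _ in range(int(n_perm)))
    return r_obs, (1 + hits) / (1 + int(n_perm))


def _anosim_r_from_ranks(rank_d: np.ndarray, groups: np.ndarray, iu) -> float:
    within = groups[iu[0]] == groups[iu[1]]
    m = rank_d.size
    return float((rank_d[~within].mean() - rank_d[within].mean()) / (m / 2.0))
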