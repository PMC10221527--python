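"""Metabolite biomarker-panel workflow for a binary fatness phenotype.

PLS-DA variable-importance (VIP) scores plus a two-sided rank-sum test
pick the differential metabolites (VIP > 1 and p < 0.05); a bidirectional
AIC stepwise binary logistic regression over those candidates builds the
panel; ROC/AUC compares the panel score against each single marker. A
leave-one-out panel AUC is reported alongside the in-sample one to expose
selection optimism at small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .association import bh_adjust, spearman_partial


@dataclass
class BiomarkerPanel:
    members: list[str]
    intercept: float
    coefficients: dict[str, float]
    panel_auc: float
    loo_auc: float
    single_aucs: dict[str, float]
    differential_table: pd.DataFrame
    ridge_fallback: bool = False
    roc: pd.DataFrame = field(default=None, repr=False)


def _standardize_log(X: pd.DataFrame) -> pd.DataFrame:
    """log10 + z-score per column (zeros imputed at the column minimum)."""
    from .metabolome import transform_matrix
    return transform_matrix(X)


def plsda_vip(X, y, n_components: int = 2) -> pd.Series:
    """VIP scores from a PLS regression on the binary group label.

    ``X`` is a samples x metabolites matrix, already column-standardized.
    VIP_j = sqrt(p * sum_a SS_a (w_ja/||w_a||)^2 / sum_a SS_a), with SS_a
    the response variance explained by component a, so mean(VIP^2) = 1.
    """
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float)
    classes, counts = np.unique(yv, return_counts=True)
    if len(classes) != 2 or counts.min() < 3:
        raise ValueError("need two groups with at least 3 samples each")
    n, p = X.shape
    max_comp = int(min(n - 1, p))
    if n_components > max_comp:
        warnings.warn(f"reducing n_components from {n_components} to {max_comp}",
                      stacklevel=2)
        n_components = max_comp
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X.to_numpy(), yv - yv.mean())
    w = pls.x_weights_                      # p x A
    t = pls.x_scores_                       # n x A
    q = pls.y_loadings_.ravel()             # A
    ss = (q ** 2) * np.einsum("ia,ia->a", t, t)
    wn = w / np.linalg.norm(w, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn ** 2 @ ss) / ss.sum())
    return pd.Series(vip, index=X.columns, name="VIP")


def differential_metabolites(X_raw: pd.DataFrame, y,
                             vip_threshold: float = 1.0,
                             p_threshold: float = 0.05,
                             n_components: int = 2,
                             test: str = "ranksum") -> pd.DataFrame:
    """Per-metabolite differential table between the two groups.

    p-values come from the two-sided Wilcoxon rank-sum test on the raw
    intensities (Welch's t by ``test="welch"``); VIPs from PLS-DA on the
    standardized log intensities. The returned table carries raw-scale
    group means +- sd and a ``differential`` flag (VIP > threshold AND
    p < threshold).
    """
    yv = np.asarray(y)
    groups = np.unique(yv)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    g1, g0 = groups[::-1] if set(groups) == {0, 1} else (groups[1], groups[0])
    vips = plsda_vip(_standardize_log(X_raw), (yv == g1).astype(float),
                     n_components=n_components)
    rows = []
    for col in X_raw.columns:
        a = X_raw.loc[yv == g1, col].to_numpy(dtype=float)
        b = X_raw.loc[yv == g0, col].to_numpy(dtype=float)
        if test == "welch":
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append({
            "metabolite_id": col,
            f"mean_{g1}": a.mean(), f"sd_{g1}": a.std(ddof=1),
            f"mean_{g0}": b.mean(), f"sd_{g0}": b.std(ddof=1),
            "p_value": float(p), "VIP": float(vips[col])})
    table = pd.DataFrame(rows).set_index("metabolite_id")
    table["differential"] = (table["VIP"] > vip_threshold) & (table["p_value"] < p_threshold)
    return table.sort_values("p_value", kind="mergesort")


def _logit_llf(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Maximum-likelihood logistic fit; returns (llf, params, fallback).

    Perfect separation or non-convergence falls back to a lightly ridge-
    penalized fit whose log-likelihood is evaluated at the penalized
    coefficients.
    """
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200, method="lbfgs")
        if np.all(np.isfinite(fit.params)) and np.abs(fit.params).max() < 50:
            return float(fit.llf), np.asarray(fit.params), False
    except Exception:
        pass
    if X.shape[1] == 0:
        p1 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        llf = float(y.sum() * np.log(p1) + (len(y) - y.sum()) * np.log(1 - p1))
        return llf, np.array([np.log(p1 / (1 - p1))]), True
    lr = LogisticRegression(C=10.0, max_iter=2000)
    lr.fit(X, y)
    params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    eta = Xc @ params
    llf = float(-(np.logaddexp(0, -eta) * y + np.logaddexp(0, eta) * (1 - y)).sum())
    return llf, params, True


def stepwise_logistic(X: pd.DataFrame, y, max_steps: int = 50) -> tuple[list[str], np.ndarray, bool]:
    """Bidirectional AIC stepwise logistic regression from the null model.

    Returns the selected columns, the final (intercept-first) coefficient
    vector and a flag marking a ridge fallback (perfect separation).
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate metabolite")
    yv = np.asarray(y, dtype=float)
    cols = list(X.columns)
    selected: list[str] = []

    def aic(subset: list[str]) -> float:
        llf, _, _ = _logit_llf(X[subset].to_numpy(), yv)
        return 2 * (len(subset) + 1) - 2 * llf

    current = aic(selected)
    for _ in range(max_steps):
        moves: list[tuple[float, str, str]] = []
        for c in cols:
            if c not in selected:
                moves.append((aic(selected + [c]), "add", c))
        for c in selected:
            moves.append((aic([s for s in selected if s != c]), "drop", c))
        if not moves:
            break
        best_aic, action, col = min(moves, key=lambda m: m[0])
        if best_aic >= current - 1e-9:
            break
        current = best_aic
        if action == "add":
            selected.append(col)
        else:
            selected.remove(col)
    _, params, fallback = _logit_llf(X[selected].to_numpy(), yv)
    return selected, params, fallback


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC (Mann-Whitney with ties counted one half) plus ROC coordinates."""
    yv = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(yv)) != 2:
        raise ValueError("need both classes to compute an AUC")
    auc = float(roc_auc_score(yv, s))
    fpr, tpr, thr = roc_curve(yv, s)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def oriented_auc(scores, labels) -> float:
    """AUC reported on [0.5, 1]: the score is flipped if it ranks the
    classes the wrong way round."""
    auc, _ = roc_auc(scores, labels)
    return max(auc, 1.0 - auc)


def build_panel(X_raw: pd.DataFrame, y,
                vip_threshold: float = 1.0, p_threshold: float = 0.05,
                n_components: int = 2, test: str = "ranksum") -> BiomarkerPanel:
    """Full workflow: differential selection -> stepwise logistic -> ROC.

    ``y`` is a binary group label (1 = high-fatness). The panel score is
    the linear predictor of the final logistic fit on standardized log
    intensities; single-marker AUCs are oriented to [0.5, 1].
    """
    ys = pd.Series(np.asarray(y))
    if ys.dtype == object:
        yv = ys.map({"HFG": 1.0, "LFG": 0.0}).to_numpy(dtype=float)
        if np.isnan(yv).any():
            raise ValueError("string labels must be 'HFG'/'LFG'")
    else:
        yv = ys.to_numpy(dtype=float)
    diff = differential_metabolites(X_raw, yv, vip_threshold=vip_threshold,
                                    p_threshold=p_threshold,
                                    n_components=n_components, test=test)
    candidates = list(diff.index[diff["differential"]])
    Xz = _standardize_log(X_raw)
    if len(candidates) < 2:
        members, params, fallback = candidates, None, False
        if members:
            _, params, fallback = _logit_llf(Xz[members].to_numpy(), yv)
    else:
        members, params, fallback = stepwise_logistic(Xz[candidates], yv)

    if members and params is not None:
        score = params[0] + Xz[members].to_numpy() @ params[1:]
        panel_auc, roc_coords = roc_auc(score, yv)
        panel_auc = max(panel_auc, 1.0 - panel_auc)
        loo_auc = _loo_panel_auc(Xz[members].to_numpy(), yv)
        intercept = float(params[0])
        coeffs = dict(zip(members, map(float, params[1:])))
    else:
        score = np.zeros(len(yv))
        panel_auc, loo_auc, intercept, coeffs = 0.5, 0.5, 0.0, {}
        roc_coords = pd.DataFrame({"fpr": [0, 1], "tpr": [0, 1], "threshold": [np.inf, -np.inf]})

    single = {c: oriented_auc(Xz[c].to_numpy(), yv) for c in candidates}
    return BiomarkerPanel(members=list(members), intercept=intercept,
                          coefficients=coeffs, panel_auc=panel_auc,
                          loo_auc=loo_auc, single_aucs=single,
                          differential_table=diff, ridge_fallback=fallback,
                          roc=roc_coords)


def _loo_panel_auc(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out AUC of the fixed panel membership (coefficients refit
    without the held-out sample)."""
    n = len(y)
    scores = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        if len(np.unique(y[keep])) < 2:
            scores[i] = 0.0
            continue
        _, params, _ = _logit_llf(X[keep], y[keep])
        scores[i] = params[0] + X[i] @ params[1:]
    auc, _ = roc_auc(scores, y)
    return max(auc, 1.0 - auc)


def metabolite_taxa_heatmap_stats(metabolites: pd.DataFrame,
                                  taxa: pd.DataFrame,
                                  covariates: pd.DataFrame | None = None
                                  ) -> pd.DataFrame:
    """Spearman correlation grid between differential metabolites and
    differential taxa, BH-adjusted within the grid.

    Both inputs are samples x variables frames on a shared index; when
    covariates are given the correlation is the covariate-adjusted partial
    Spearman. Returns a tidy frame (metabolite, taxon, rho, p, q).
    """
    shared = metabolites.index.intersection(taxa.index).sort_values()
    met = metabolites.loc[shared]
    tax = taxa.loc[shared]
    from .association import covariate_design
    design = (covariate_design(covariates, shared) if covariates is not None else None)
    rows = []
    for m in met.columns:
        for t in tax.columns:
            try:
                rho, p = spearman_partial(met[m].to_numpy(), tax[t].to_numpy(), design)
            except ValueError:
                rho, p = np.nan, np.nan
            rows.append({"metabolite_id": m, "taxon_id": t, "rho": rho, "p_value": p})
    grid = pd.DataFrame(rows)
    ok = grid["p_value"].notna()
    grid["q_value"] = np.nan
    if ok.any():
        grid.loc[ok, "q_value"] = bh_adjust(grid.loc[ok, "p_value"].to_numpy())
    return grid
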