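"""Statistics layer for ROI peptide AUC tables.

Multivariate: autoscaling, two-class OPLS-DA (one predictive component plus
orthogonal components, NIPALS-style) with VIP scores and cross-validated
Q2, and Ward/Euclidean hierarchical clustering.  Univariate: Kruskal-Wallis
with Dunn's two-sided post hoc, Mann-Whitney U / Wilcoxon signed-rank
batches with Benjamini-Hochberg adjustment, Pearson correlation matrices
and coefficient-of-variation summaries.

The ROI table treats plaques as independent observations even though they
nest within patients — matching the source workflow; results carry a
``pooling`` flag recording this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "autoscale",
    "OplsdaModel",
    "oplsda_fit",
    "oplsda_predict",
    "vip_scores",
    "hca_ward",
    "kruskal_dunn",
    "pairwise_bh",
    "bh_adjust",
    "pearson_correlations",
    "cv_report",
]

POOLING_NOTE = "plaques pooled across patients (treated as independent)"


def autoscale(X) -> pd.DataFrame:
    """Center columns to mean 0 and scale to unit SD (n-1 denominator).

    Constant columns are dropped with a warning.  Accepts an array or
    DataFrame; returns a DataFrame.
    """
    X = pd.DataFrame(X).astype(float)
    if len(X) < 2:
        raise ValueError("autoscaling needs at least two rows")
    sd = X.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant column(s): {constant}")
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    return (X - X.mean(axis=0)) / sd


@dataclass
class OplsdaModel:
    """Fitted two-class OPLS-DA decomposition."""

    w: np.ndarray  # predictive weights (unit norm)
    t: np.ndarray  # predictive scores
    p: np.ndarray  # predictive loadings
    c: float  # y-loading of the predictive component
    W_orth: np.ndarray  # (n_vars, n_orth)
    P_orth: np.ndarray
    T_orth: np.ndarray  # (n_samples, n_orth)
    y_mean: float
    classes: tuple
    feature_names: list
    R2X: float
    R2Y: float
    Q2: float
    pooling: str = POOLING_NOTE


def _encode_two_class(y):
    y = np.asarray(y)
    classes = tuple(pd.unique(y))
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA needs exactly two classes, got {classes}")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < 3:
        raise ValueError("need at least 3 samples per class")
    return np.where(y == classes[0], 1.0, -1.0), classes


def _orth_deflate(X, y):
    """One predictive-weight estimate and one orthogonal component."""
    w = X.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = X @ w
    p = X.T @ t / (t @ t)
    w_o = p - (w @ p) * w
    norm = np.linalg.norm(w_o)
    if norm < 1e-12:
        return None  # no orthogonal variation left
    w_o /= norm
    t_o = X @ w_o
    p_o = X.T @ t_o / (t_o @ t_o)
    return w_o, t_o, p_o


def oplsda_fit(X, y, n_orth: int = 1, cv_folds: int = 7, seed: int = 0
               ) -> OplsdaModel:
    """Fit OPLS-DA with one predictive and ``n_orth`` orthogonal components.

    ``X`` must be autoscaled (rows = ROIs, columns = peptides); ``y`` holds
    two class labels.  Orthogonal components capture class-uncorrelated
    X-variation and are removed before the single predictive component is
    estimated.  Q2 comes from stratified ``cv_folds``-fold cross-validation
    of the class prediction (1 - PRESS/SS).
    """
    X = pd.DataFrame(X).astype(float)
    feature_names = list(X.columns)
    Xm = X.to_numpy()
    if n_orth >= min(Xm.shape) :
        raise ValueError(f"n_orth={n_orth} must be below rank(X)")
    y_num, classes = _encode_two_class(y)
    y0 = y_num - y_num.mean()

    def fit_core(Xtr, ytr):
        Xd = Xtr.copy()
        orth = []
        for _ in range(n_orth):
            res = _orth_deflate(Xd, ytr)
            if res is None:
                break
            w_o, t_o, p_o = res
            Xd = Xd - np.outer(t_o, p_o)
            orth.append((w_o, t_o, p_o))
        w = Xd.T @ ytr / (ytr @ ytr)
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        c = float(ytr @ t / (t @ t))
        return w, t, p, c, orth

    w, t, p, c, orth = fit_core(Xm, y0)
    ss_x = (Xm**2).sum()
    explained = np.outer(t, p)
    for _, t_o, p_o in orth:
        explained = explained + np.outer(t_o, p_o)
    R2X = float((explained**2).sum() / ss_x)
    resid_y = y0 - c * t
    R2Y = float(1.0 - (resid_y**2).sum() / (y0**2).sum())

    # stratified CV for Q2
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y0), dtype=int)
    for cls in classes:
        idx = np.nonzero(np.asarray(y) == cls)[0]
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % cv_folds
    press, ss = 0.0, float((y0**2).sum())
    for f in range(cv_folds):
        tr, te = folds != f, folds == f
        if te.sum() == 0 or len(np.unique(y_num[tr])) < 2:
            continue
        ytr = y_num[tr] - y_num[tr].mean()
        wf, _, _, cf, orthf = fit_core(Xm[tr], ytr)
        Xte = Xm[te].copy()
        for w_o, _, p_o in orthf:
            Xte = Xte - np.outer(Xte @ w_o, p_o)
        yhat = cf * (Xte @ wf) + y_num[tr].mean()
        press += float(((y_num[te] - yhat) ** 2).sum())
    Q2 = float(1.0 - press / ss)

    W_orth = (np.column_stack([o[0] for o in orth])
              if orth else np.empty((Xm.shape[1], 0)))
    T_orth = (np.column_stack([o[1] for o in orth])
              if orth else np.empty((Xm.shape[0], 0)))
    P_orth = (np.column_stack([o[2] for o in orth])
              if orth else np.empty((Xm.shape[1], 0)))
    return OplsdaModel(w=w, t=t, p=p, c=c, W_orth=W_orth, P_orth=P_orth,
                       T_orth=T_orth, y_mean=float(y_num.mean()),
                       classes=classes, feature_names=feature_names,
                       R2X=R2X, R2Y=R2Y, Q2=Q2)


def oplsda_predict(model: OplsdaModel, X) -> np.ndarray:
    """Predicted class labels for new (autoscaled-like) rows."""
    Xm = pd.DataFrame(X).astype(float).to_numpy().copy()
    for k in range(model.W_orth.shape[1]):
        t_o = Xm @ model.W_orth[:, k]
        Xm = Xm - np.outer(t_o, model.P_orth[:, k])
    score = model.c * (Xm @ model.w) + model.y_mean
    return np.where(score >= 0, model.classes[0], model.classes[1])


def vip_scores(model: OplsdaModel) -> pd.Series:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt(p * sum_a SSY_a w_aj^2 / sum_a SSY_a); with one predictive
    component this is sqrt(p) * |w_j|, so sum(VIP^2) = p.
    """
    if model.w is None:  # pragma: no cover - dataclass always fitted
        raise ValueError("model not fitted")
    n_vars = model.w.size
    vip = np.sqrt(n_vars * model.w**2 / (model.w**2).sum())
    return pd.Series(vip, index=model.feature_names, name="VIP")


def hca_ward(X) -> tuple[np.ndarray, np.ndarray]:
    """Ward (D2) agglomeration on Euclidean distances of autoscaled rows.

    Returns the scipy linkage matrix and the dendrogram leaf order.
    """
    X = pd.DataFrame(X).astype(float)
    if len(X) < 2:
        raise ValueError("need at least two rows to cluster")
    if X.isna().any().any():
        raise ValueError("NaNs in the matrix; impute or drop first")
    Z = hierarchy.linkage(X.to_numpy(), method="ward")
    return Z, hierarchy.leaves_list(Z)


@dataclass
class GroupTestResult:
    contrast: str
    method: str
    statistic: float
    p_raw: float
    p_adj: float
    extra: dict = field(default_factory=dict)


def kruskal_dunn(groups: dict) -> tuple[GroupTestResult, list[GroupTestResult]]:
    """Kruskal-Wallis H (tie-corrected) plus Dunn's two-sided post hoc.

    ``groups`` maps label -> 1-D samples.  Dunn's z uses pooled mean ranks
    with tie-corrected variance; two-sided p-values are multiplied by the
    number of pairwise comparisons (capped at 1).
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(samples)
    if np.unique(pooled).size == 1:  # all values tied: no evidence at all
        H, p_kw = 0.0, 1.0
    else:
        H, p_kw = sps.kruskal(*samples)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, start = {}, 0
    for g, s in zip(labels, samples):
        mean_ranks[g] = ranks[start : start + s.size].mean()
        start += s.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1))
    m = len(labels) * (len(labels) - 1) // 2
    posthoc = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            gi, gj = labels[i], labels[j]
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                         * (1.0 / samples[i].size + 1.0 / samples[j].size))
            z = (mean_ranks[gi] - mean_ranks[gj]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            posthoc.append(GroupTestResult(
                contrast=f"{gi}_vs_{gj}", method="dunn",
                statistic=float(z), p_raw=float(p),
                p_adj=float(min(1.0, p * m)),
                extra={"mean_rank_a": mean_ranks[gi],
                       "mean_rank_b": mean_ranks[gj]},
            ))
    omnibus = GroupTestResult(contrast="_".join(labels), method="kruskal",
                              statistic=float(H), p_raw=float(p_kw),
                              p_adj=float(p_kw))
    return omnibus, posthoc


def pairwise_bh(tests: list) -> list[GroupTestResult]:
    """Batch of two-group tests with Benjamini-Hochberg adjustment.

    Each entry is ``(name, a, b, paired)``.  Unpaired uses Mann-Whitney U
    (exact null when both groups have <= 8 values and no ties, normal
    approximation with continuity and tie correction otherwise); paired
    uses the Wilcoxon signed-rank test.  Adjusted p-values come from the
    step-up BH procedure across the supplied batch.
    """
    results = []
    for name, a, b, paired in tests:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if paired:
            if a.size != b.size:
                raise ValueError(f"{name}: paired samples need equal lengths")
            if np.allclose(a, b):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.wilcoxon(a, b)
            method = "wilcoxon"
        else:
            if a.size == 0 or b.size == 0:
                raise ValueError(f"{name}: empty sample")
            pooled = np.concatenate([a, b])
            exact = (a.size <= 8 and b.size <= 8
                     and np.unique(pooled).size == pooled.size)
            stat, p = sps.mannwhitneyu(
                a, b, alternative="two-sided",
                method="exact" if exact else "asymptotic",
            )
            method = "mannwhitney"
        results.append(GroupTestResult(contrast=str(name), method=method,
                                       statistic=float(stat),
                                       p_raw=float(p), p_adj=np.nan))
    if results:
        adj = multipletests([r.p_raw for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.p_adj = float(q)
    return results


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one batch."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def pearson_correlations(X) -> pd.DataFrame:
    """Pairwise Pearson r over columns, on rows complete for each pair.

    Constant columns yield NaN against everything (with a warning).
    """
    X = pd.DataFrame(X).astype(float)
    cols = list(X.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            pair = X[[ci, cj]].dropna()
            if len(pair) < 3:
                r = np.nan
            elif pair[ci].std() == 0 or pair[cj].std() == 0:
                warnings.warn(f"constant column in pair ({ci}, {cj}); r undefined")
                r = np.nan
            else:
                r = sps.pearsonr(pair[ci], pair[cj])[0]
            out.loc[ci, cj] = out.loc[cj, ci] = r
    return out


def cv_report(table: pd.DataFrame, value_cols: list, by: str
              ) -> tuple[pd.DataFrame, float]:
    """Coefficients of variation (percent) per group and their mean.

    CV = 100 * sd / mean per ``by``-group and value column (groups with a
    zero mean give NaN with a warning); the cumulative CV is the mean over
    all finite per-group, per-column CVs.
    """
    rows = []
    for key, sub in table.groupby(by):
        if len(sub) < 2:
            continue
        for col in value_cols:
            mean = sub[col].mean()
            if mean == 0:
                warnings.warn(f"group {key}, column {col}: zero mean, CV undefined")
                cv = np.nan
            else:
                cv = 100.0 * sub[col].std(ddof=1) / mean
            rows.append({by: key, "column": col, "cv_pct": cv})
    per_group = pd.DataFrame(rows)
    cumulative = float(np.nanmean(per_group["cv_pct"])) if len(per_group) else np.nan
    return per_group, cumulative
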