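"""Time-course serum metabolome analysis.

Feature filtering (>30% prevalence AND annotated), OPLS-DA with VIP
ranking for group discrimination, per-metabolite GLM association with
sampling day (day treated as a categorical factor, BH-FDR across
metabolites), and hierarchical clustering of the z-scored per-day mean
trajectories of time-associated metabolites into K clusters (default 6,
Euclidean distance, complete linkage).

All modelling operates on log10(1 + intensity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests


@dataclass
class MetaboliteTable:
    data: pd.DataFrame  # samples x metabolites, raw intensities >= 0
    dph: pd.Series  # per-sample day posthatch
    taxonomy: pd.DataFrame  # metabolite -> superclass/class/subclass

    def log_data(self) -> pd.DataFrame:
        return np.log10(1.0 + self.data)


def filter_features(
    data: pd.DataFrame,
    dph: pd.Series,
    taxonomy: pd.DataFrame,
    annotated: pd.Series | None = None,
    min_prevalence: float = 0.30,
) -> tuple[MetaboliteTable, dict]:
    """Two-step feature filter: keep features present in > 30% of samples
    (strict) AND annotated. Returns the table plus removal counts."""
    n = len(data)
    prev = (data > 0).sum(axis=0) / n
    prevalent = prev > min_prevalence + 1e-12
    if annotated is None:
        annotated = taxonomy.reindex(data.columns).notna().all(axis=1) & (
            taxonomy.reindex(data.columns)
            .apply(lambda c: c.astype(str).str.lower() != "unknown")
            .all(axis=1)
        )
    annotated = annotated.reindex(data.columns).fillna(False)
    keep = data.columns[prevalent & annotated]
    log = {
        "n_input": data.shape[1],
        "n_low_prevalence": int((~prevalent).sum()),
        "n_unannotated": int((prevalent & ~annotated).sum()),
        "n_kept": len(keep),
    }
    return (
        MetaboliteTable(data[keep], dph.reindex(data.index), taxonomy.reindex(keep)),
        log,
    )


@dataclass
class OplsResult:
    p1: pd.Series  # predictive scores, first predictive component
    scores: pd.DataFrame  # all predictive scores
    ortho_scores: pd.DataFrame
    vip: pd.Series
    explained_p1: float  # share of (filtered) X variance carried by P1


def opls_da(
    table: MetaboliteTable | pd.DataFrame,
    groups: pd.Series,
    n_orth: int = 1,
    scaling: str = "uv",
    n_pred: int | None = None,
) -> OplsResult:
    """Orthogonal PLS discriminant analysis with VIP.

    Groups are dummy-coded into a multi-response Y; ``n_orth``
    Y-orthogonal components are removed from X before a PLS2 fit with
    ``n_pred`` predictive components (default: number of groups - 1).
    VIP is the standard weighted-loading importance; mean squared VIP
    over metabolites equals 1 by construction.
    """
    x_df = table.log_data() if isinstance(table, MetaboliteTable) else table
    groups = groups.reindex(x_df.index)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"groups with a single sample: {list(sizes[sizes < 2].index)}")
    x = x_df.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropped {int(constant.sum())} constant metabolites")
        x = x[:, ~constant]
    cols = x_df.columns[~constant]
    x = x - x.mean(axis=0)
    if scaling == "uv":
        x = x / x.std(axis=0, ddof=1)
    elif scaling == "pareto":
        x = x / np.sqrt(x.std(axis=0, ddof=1))
    elif scaling != "none":
        raise ValueError("scaling must be uv|pareto|none")
    y = pd.get_dummies(groups).to_numpy(dtype=float)
    y = y - y.mean(axis=0)

    # orthogonal filtering (one Y-orthogonal component at a time)
    xf = x.copy()
    ortho_scores = []
    for _ in range(n_orth):
        u, s, vt = np.linalg.svd(xf.T @ y, full_matrices=False)
        w = u[:, 0]
        t = xf @ w
        p = xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-10:
            break
        w_o /= norm
        t_o = xf @ w_o
        p_o = xf.T @ t_o / (t_o @ t_o)
        xf = xf - np.outer(t_o, p_o)
        ortho_scores.append(t_o)

    a = n_pred if n_pred is not None else max(1, len(levels) - 1)
    a = min(a, xf.shape[1], xf.shape[0] - 1)
    pls = PLSRegression(n_components=a, scale=False)
    pls.fit(xf, y)
    t_scores = pls.x_scores_  # (n, a)
    w_mat = pls.x_weights_  # (p, a), unit-norm columns
    q = pls.y_loadings_  # (g, a)

    # VIP_j = sqrt(p * sum_a ssy_a w_ja^2 / sum_a ssy_a)
    ssy = (q**2).sum(axis=0) * (t_scores**2).sum(axis=0)
    p_feat = w_mat.shape[0]
    vip = np.sqrt(p_feat * (w_mat**2 @ ssy) / ssy.sum())

    p1 = pd.Series(t_scores[:, 0], index=x_df.index, name="P1")
    explained = float((t_scores[:, 0] ** 2).sum() / (x**2).sum())
    return OplsResult(
        p1=p1,
        scores=pd.DataFrame(
            t_scores, index=x_df.index, columns=[f"P{i+1}" for i in range(a)]
        ),
        ortho_scores=pd.DataFrame(
            np.column_stack(ortho_scores) if ortho_scores else np.empty((len(x_df), 0)),
            index=x_df.index,
        ),
        vip=pd.Series(vip, index=cols, name="VIP"),
        explained_p1=explained,
    )


def glm_time_association(
    table: MetaboliteTable | pd.DataFrame,
    dph: pd.Series | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite omnibus F-test of log-intensity on categorical day.

    Equivalent to a one-way normal-errors GLM per metabolite;
    Benjamini–Hochberg across metabolites; associated = p_adj < fdr.
    """
    if isinstance(table, MetaboliteTable):
        x = table.log_data()
        dph = table.dph
    else:
        x = np.log10(1.0 + table)
    if dph is None:
        raise ValueError("dph required")
    dph = dph.reindex(x.index)
    days = np.sort(dph.unique())
    if len(days) < 2:
        raise ValueError("need at least two time points")
    mat = x.to_numpy(dtype=float)
    n, p = mat.shape
    grand = mat.mean(axis=0)
    ssb = np.zeros(p)
    ssw = np.zeros(p)
    for d in days:
        sub = mat[(dph == d).to_numpy()]
        ssb += len(sub) * (sub.mean(axis=0) - grand) ** 2
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    df_b, df_w = len(days) - 1, n - len(days)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    pvals = stats.f.sf(f, df_b, df_w)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # constant metabolite -> null
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "F": f,
            "p": pvals,
            "p_adj": p_adj,
            "associated": p_adj < fdr,
        },
        index=x.columns,
    )


@dataclass
class TrajectoryClusters:
    labels: pd.Series  # metabolite -> cluster id (1..k)
    mean_trajectories: pd.DataFrame  # cluster x day, z-scored units
    linkage_method: str
    degenerate: bool = False  # fewer distinct profiles than k


def mean_trajectories(table: MetaboliteTable) -> pd.DataFrame:
    """Per-metabolite mean log-intensity trajectory over days,
    z-scored per metabolite (rows: metabolites, cols: days)."""
    log = table.log_data()
    means = log.groupby(table.dph.reindex(log.index)).mean().T  # metab x day
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0).replace(0.0, 1.0)
    return means.sub(mu, axis=0).div(sd, axis=0)


def cluster_trajectories(
    table: MetaboliteTable,
    metabolites: pd.Index | None = None,
    k: int = 6,
    method: str = "complete",
) -> TrajectoryClusters:
    """Hierarchical clustering of z-scored per-day mean trajectories.

    Euclidean distance, complete linkage (configurable), tree cut at k.
    Deterministic given input order.
    """
    traj = mean_trajectories(table)
    if metabolites is not None:
        traj = traj.loc[traj.index.intersection(metabolites)]
    if len(traj) < k:
        raise ValueError(f"k={k} exceeds the {len(traj)} metabolites")
    z = linkage(traj.to_numpy(), method=method, metric="euclidean")
    labels = fcluster(z, t=k, criterion="maxclust")
    degenerate = len(np.unique(labels)) < k
    if degenerate:
        warnings.warn("fewer distinct clusters than requested (degenerate profiles)")
    lab = pd.Series(labels, index=traj.index, name="cluster")
    means = traj.groupby(lab).mean()
    return TrajectoryClusters(lab, means, method, degenerate)


def cluster_composition(
    clusters: TrajectoryClusters, taxonomy: pd.DataFrame, level: str = "superclass"
) -> pd.DataFrame:
    """Per-cluster chemical-taxonomy proportions (rows sum to 1)."""
    df = pd.DataFrame(
        {
            "cluster": clusters.labels,
            level: taxonomy.reindex(clusters.labels.index)[level].fillna("unclassified"),
        }
    )
    counts = df.groupby(["cluster", level], observed=True).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
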