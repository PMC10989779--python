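"""Dirichlet multinomial mixture (DMM) community typing.

Samples are count vectors; each mixture component is a Dirichlet-compound
multinomial with its own parameter vector alpha_k, so components capture
both a mean composition and its overdispersion. "Community types" are the
mixture components; the number of types K is selected by the Laplace
approximation to the negative log model evidence (BIC reported alongside).

Absolute-abundance tables are first discretised to integer pseudo-counts
by binning log10(1 + copies/g) to the nearest integer, so that typing
operates on the absolute, not relative, scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp, polygamma

from .tables import FeatureTable

_EPS = 1e-10


@dataclass
class DmmModel:
    k: int
    weights: np.ndarray  # (K,)
    alpha: np.ndarray  # (K, p)
    responsibilities: pd.DataFrame  # samples x K, rows sum to 1
    log_likelihood: float
    ll_trace: list = field(default_factory=list)
    converged: bool = False
    laplace: float = float("nan")
    bic: float = float("nan")

    def assignments(self) -> pd.Series:
        return self.responsibilities.idxmax(axis=1).rename("community_type")


def discretize_absolute(table: FeatureTable) -> FeatureTable:
    """Bin a QMP table to integers: round(log10(1 + copies/g)).

    The result is a small-integer pseudo-count matrix suitable for DMM
    fitting; binning is monotone in the input.
    """
    if table.mode != "QMP":
        raise ValueError("discretize_absolute expects a QMP table")
    x = table.data.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative values")
    binned = np.rint(np.log10(1.0 + x)).astype(int)
    out = table.copy()
    out.data = pd.DataFrame(binned, index=table.samples, columns=table.taxa)
    out.mode = "counts"
    return out


def _dm_loglik(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial log-likelihood of each row of x under alpha.

    Includes the multinomial coefficient so values are true log pmf.
    """
    n = x.sum(axis=1)
    a0 = alpha.sum()
    const = gammaln(n + 1) - gammaln(x + 1).sum(axis=1)
    return (
        const
        + gammaln(a0)
        - gammaln(n + a0)
        + (gammaln(x + alpha) - gammaln(alpha)).sum(axis=1)
    )


def _fixed_point_alpha(
    x: np.ndarray, weights: np.ndarray, alpha: np.ndarray, n_inner: int = 10
) -> np.ndarray:
    """Minka fixed-point update of alpha for a weighted DM likelihood."""
    n = x.sum(axis=1)
    w = weights
    for _ in range(n_inner):
        a0 = alpha.sum()
        num = (w[:, None] * (digamma(x + alpha) - digamma(alpha))).sum(axis=0)
        den = (w * (digamma(n + a0) - digamma(a0))).sum()
        if den <= 0:
            break
        alpha = np.maximum(alpha * num / den, _EPS)
    return alpha


def _moment_alpha(x: np.ndarray) -> np.ndarray:
    """Method-of-moments DM estimate used for initialisation.

    Matches the mean composition and an overdispersion-derived precision.
    """
    props = x / np.maximum(x.sum(axis=1, keepdims=True), 1)
    m = props.mean(axis=0)
    v = props.var(axis=0)
    pos = (m > 0) & (m < 1) & (v > 0)
    if pos.any():
        s = np.median(m[pos] * (1 - m[pos]) / v[pos] - 1)
        s = float(np.clip(s, 1.0, 1e4))
    else:
        s = 10.0
    return np.maximum(m * s, _EPS)


def dmm_fit(
    table: FeatureTable | pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> DmmModel:
    """EM fit of a K-component Dirichlet multinomial mixture.

    E-step: responsibilities from component DM log-likelihoods.
    M-step: mixture weights and per-component alpha (Minka fixed point).
    The observed-data log-likelihood is non-decreasing across iterations.
    """
    data = table.data if isinstance(table, FeatureTable) else table
    x = data.to_numpy()
    if not np.allclose(x, np.rint(x)):
        raise ValueError(
            "DMM requires integer counts; discretise absolute abundances "
            "with discretize_absolute first"
        )
    x = np.rint(x).astype(float)
    n_samples, p = x.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_samples:
        raise ValueError("k exceeds the number of samples")

    rng = np.random.default_rng(seed)
    # init: k-means-style seeding on proportions -> per-cluster moment fits
    props = x / np.maximum(x.sum(axis=1, keepdims=True), 1)
    centers = props[rng.choice(n_samples, size=k, replace=False)]
    labels = np.argmin(
        ((props[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    alpha = np.empty((k, p))
    for j in range(k):
        members = x[labels == j] if (labels == j).sum() >= 2 else x
        alpha[j] = _moment_alpha(members)
        alpha[j] *= np.exp(rng.normal(0, 0.05, size=p))  # break exact ties
    weights = np.full(k, 1.0 / k)

    ll_trace: list[float] = []
    converged = False
    resp = np.full((n_samples, k), 1.0 / k)
    for _ in range(max_iter):
        # E-step
        log_comp = np.stack([_dm_loglik(x, alpha[j]) for j in range(k)], axis=1)
        log_joint = log_comp + np.log(np.maximum(weights, _EPS))
        ll = float(logsumexp(log_joint, axis=1).sum())
        resp = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))
        ll_trace.append(ll)
        if len(ll_trace) > 1 and abs(ll_trace[-1] - ll_trace[-2]) < tol:
            converged = True
            break
        # M-step
        weights = resp.mean(axis=0)
        for j in range(k):
            alpha[j] = _fixed_point_alpha(x, resp[:, j], alpha[j])

    samples_idx = data.index
    resp_df = pd.DataFrame(resp, index=samples_idx, columns=[f"T{j+1}" for j in range(k)])
    model = DmmModel(
        k=k,
        weights=weights,
        alpha=alpha,
        responsibilities=resp_df,
        log_likelihood=ll_trace[-1],
        ll_trace=ll_trace,
        converged=converged,
    )
    model.laplace = _laplace_criterion(x, model, resp)
    n_params = k * p + (k - 1)
    model.bic = -2 * model.log_likelihood + n_params * np.log(n_samples)
    return model


def _laplace_criterion(
    x: np.ndarray, model: DmmModel, resp: np.ndarray, prior_var: float = 10.0
) -> float:
    """MAP-Laplace approximation to the negative log model evidence.

    Parameters are log alpha with a weak Gaussian prior N(0, prior_var)
    per coordinate; the criterion is

        -ll + ||log alpha||^2 / (2 s^2) + (d/2) log s^2
            + (1/2) log det(-H + I/s^2) + ((K-1)/2) log n

    where H is the (block-diagonal, per-component) Hessian of the
    responsibility-weighted DM log-likelihood in log-alpha coordinates
    (rank-one plus diagonal). Including the prior normalisation makes
    directions the data do not constrain evidence-neutral, so duplicated
    components gain no spurious posterior-volume bonus. The mixture
    weights carry a BIC-style (K-1)/2 log n term. Smaller is better.
    """
    k, p = model.alpha.shape
    n = x.sum(axis=1)
    total_logdet = 0.0
    shrink = 0.0
    for j in range(k):
        a = model.alpha[j]
        w = resp[:, j]
        a0 = a.sum()
        # f(lambda) with lambda = log alpha; H = s * (a a^T) + diag(...)
        s = float((w * (polygamma(1, a0) - polygamma(1, n + a0))).sum())
        diag_extra = (a**2) * (
            (w[:, None] * (polygamma(1, x + a) - polygamma(1, a))).sum(axis=0)
        )
        grad_term = a * (
            (w[:, None] * (digamma(x + a) - digamma(a))).sum(axis=0)
            + (w * (digamma(a0) - digamma(n + a0))).sum()
        )
        neg_h = -(s * np.outer(a, a) + np.diag(diag_extra + grad_term))
        neg_h += (1.0 / prior_var) * np.eye(p)
        eigs = np.maximum(np.linalg.eigvalsh(neg_h), 1.0 / prior_var)
        total_logdet += float(np.log(eigs).sum())
        shrink += float((np.log(np.maximum(a, _EPS)) ** 2).sum()) / (2 * prior_var)
    d = k * p
    return float(
        -model.log_likelihood
        + shrink
        + 0.5 * d * np.log(prior_var)
        + 0.5 * total_logdet
        + 0.5 * (k - 1) * np.log(x.shape[0])
    )


def dmm_select(
    table: FeatureTable | pd.DataFrame,
    k_range=range(1, 6),
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> tuple[int, pd.DataFrame, dict[int, DmmModel]]:
    """Fit each K with multiple restarts; pick K by minimum Laplace.

    Returns (best_k, per-K criteria table, best model per K). Ks whose
    every restart fails to converge are flagged and excluded from
    selection (unless none converge, in which case all compete).
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty K range")
    models: dict[int, DmmModel] = {}
    rows = []
    for k in k_range:
        best = None
        for r in range(n_restarts):
            m = dmm_fit(table, k, seed=seed * 1009 + 31 * k + r, max_iter=max_iter, tol=tol)
            if best is None or m.log_likelihood > best.log_likelihood:
                best = m
        models[k] = best
        rows.append(
            {
                "k": k,
                "log_likelihood": best.log_likelihood,
                "laplace": best.laplace,
                "bic": best.bic,
                "converged": best.converged,
            }
        )
    crit = pd.DataFrame(rows).set_index("k")
    pool = crit[crit.converged] if crit.converged.any() else crit
    best_k = int(pool.laplace.idxmin())
    return best_k, crit, models


def type_frequencies(
    assignments: pd.Series, meta: pd.DataFrame, by=("segment", "dph")
) -> pd.DataFrame:
    """Community-type frequency table by the requested metadata strata."""
    df = meta.copy()
    df["community_type"] = assignments.reindex(df.index)
    return (
        df.groupby([*by, "community_type"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
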