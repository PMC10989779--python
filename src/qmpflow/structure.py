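"""Community structure: diversity, ordination, variance partitioning and
configuration matching.

Bray–Curtis dissimilarity and PCoA describe compositional turnover;
PERMANOVA partitions its variance across host factors (bird, segment, day
posthatch); Procrustes/protest quantifies agreement between two
ordinations of the same samples (absolute vs relative profiling, or
microbiota vs metabolome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist, squareform
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .tables import FeatureTable


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log by default)."""
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannon_per_sample(table: FeatureTable, base: float | None = None) -> pd.Series:
    return pd.Series(
        [shannon(row, base) for row in table.data.to_numpy()],
        index=table.samples,
        name="shannon",
    )


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y) (a semimetric)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray–Curtis undefined for two all-zero vectors")
    return float(braycurtis(x, y))


def bray_curtis_matrix(table: FeatureTable) -> pd.DataFrame:
    dm = squareform(pdist(table.data.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(dm, index=table.samples, columns=table.samples)


def adjacent_time_dissimilarity(table: FeatureTable, segment: str) -> pd.DataFrame:
    """All cross-time Bray–Curtis pairs between consecutive sampling days.

    Returns a long DataFrame (interval, dph_from, dph_to, sample_i,
    sample_j, bc). Intervals with an empty time point are skipped with a
    warning.
    """
    sub = table.subset(table.meta["segment"] == segment)
    days = sorted(sub.meta["dph"].unique())
    if len(days) < 2:
        raise ValueError("need at least two time points")
    rows = []
    for t0, t1 in zip(days[:-1], days[1:]):
        a = sub.data[sub.meta["dph"] == t0]
        b = sub.data[sub.meta["dph"] == t1]
        if a.empty or b.empty:
            warnings.warn(f"interval {t0}-{t1} skipped: empty time point")
            continue
        for si, xi in a.iterrows():
            for sj, xj in b.iterrows():
                rows.append(
                    {
                        "interval": f"{t0}-{t1}",
                        "dph_from": t0,
                        "dph_to": t1,
                        "sample_i": si,
                        "sample_j": sj,
                        "bc": bray_curtis(xi.to_numpy(), xj.to_numpy()),
                    }
                )
    return pd.DataFrame(rows)


def pcoa(dm: pd.DataFrame, n_axes: int | None = None):
    """Classical scaling (PCoA) of a distance matrix.

    Returns (coordinates DataFrame, eigenvalues array). Negative
    eigenvalues (Bray–Curtis is a semimetric) are reported as-is.
    """
    mat = np.asarray(dm, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    res = _skbio_pcoa(mat, number_of_dimensions=0)
    coords = pd.DataFrame(
        res.samples.to_numpy(), index=dm.index, columns=res.samples.columns
    )
    eig = res.eigvals.to_numpy()
    if n_axes is not None:
        coords = coords.iloc[:, :n_axes]
    return coords, eig


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_perm: int


def permanova(
    dm: pd.DataFrame, factor: pd.Series, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-factor PERMANOVA: pseudo-F from among/within squared distances.

    R^2 = SS_among / SS_total; p = (1 + #{perm F >= obs F}) / (1 + n_perm).
    """
    d2 = np.asarray(dm, dtype=float) ** 2
    labels = np.asarray(factor.reindex(dm.index))
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least two samples")
    n = len(labels)

    def _stat(lab):
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        df_among = len(groups) - 1
        df_within = n - len(groups)
        f = (ss_among / df_among) / (ss_within / df_within)
        return f, ss_among / ss_total

    f_obs, r2 = _stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _stat(rng.permutation(labels))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(r2), float(f_obs), float(p), n_perm)


def variance_partition(
    dm: pd.DataFrame, meta: pd.DataFrame, factors: list[str], n_perm: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Marginal (one-factor-at-a-time) PERMANOVA R^2 per factor.

    Each factor is tested in its own run; R^2 values are marginal shares
    of total squared-distance variance, not a sequential decomposition.
    """
    rows = []
    for i, f in enumerate(factors):
        res = permanova(dm, meta[f], n_perm=n_perm, seed=seed + i)
        rows.append(
            {"factor": f, "r_squared": res.r_squared, "pseudo_f": res.pseudo_f, "p": res.p_value}
        )
    return pd.DataFrame(rows)


@dataclass
class ProtestResult:
    m12: float
    p_value: float
    residuals: np.ndarray
    n_perm: int


def _procrustes_ss(a: np.ndarray, b: np.ndarray):
    """Symmetric Procrustes: returns (m2, per-sample residuals).

    Both configurations are centred and scaled to unit trace; the optimal
    rotation (reflections allowed) aligns b to a. m2 is the residual sum
    of squares; m12 = sqrt(1 - m2) is the Procrustes correlation.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    a = a / np.sqrt((a**2).sum())
    b = b / np.sqrt((b**2).sum())
    u, s, vt = np.linalg.svd(a.T @ b)
    scale = s.sum()
    rot = vt.T @ u.T
    b_rot = scale * (b @ rot)
    resid = np.sqrt(((a - b_rot) ** 2).sum(axis=1))
    m2 = 1.0 - scale**2
    return m2, resid


def protest(
    coords_a: pd.DataFrame | np.ndarray,
    coords_b: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> ProtestResult:
    """Procrustes randomisation test between two sample configurations.

    Samples must be in the same order. The permutation null shuffles the
    rows of the second configuration; the statistic is the Procrustes
    correlation m12 = sqrt(1 - m2).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("configurations must share samples")
    if a.shape[0] < 3:
        raise ValueError("need at least three samples")
    k = min(a.shape[1], b.shape[1])
    a, b = a[:, :k], b[:, :k]
    m2, resid = _procrustes_ss(a, b)
    m12 = float(np.sqrt(max(0.0, 1.0 - m2)))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(b.shape[0])
        m2_p, _ = _procrustes_ss(a, b[perm])
        if (1.0 - m2_p) >= (1.0 - m2) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return ProtestResult(m12, float(p), resid, n_perm)
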