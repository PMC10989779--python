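"""Deterministic vs stochastic community assembly: the two-step
βNTI / RC_Bray null-model framework.

For every pair of communities, βMNTD (abundance-weighted mean
nearest-taxon phylogenetic distance between communities) is compared to a
null distribution obtained by shuffling taxon labels across the tips of
the phylogeny; the z-score is βNTI. Pairs with |βNTI| >= 2 are assigned
to selection; the remainder are split by the Bray–Curtis Raup–Crick index
RC_Bray, whose null assembles random communities of the observed richness
and abundance from the regional species pool.

Process mapping (default ``convention="negative-selection"``):

    βNTI < -2                      -> heterogeneous_selection
    βNTI >  2                      -> homogeneous_selection
    |βNTI| < 2 and RC >  0.95      -> dispersal_limitation
    |βNTI| < 2 and RC < -0.95      -> homogenizing_dispersal
    |βNTI| < 2 and |RC| < 0.95     -> undominated

This default mapping is the one stated in the threshold table above; it is the
REVERSE of the more common convention in the assembly-null-model
literature (where βNTI > +2 denotes heterogeneous/variable selection).
``convention="stegen"`` swaps the two selection classes. Boundary values
are closed deliberately: |βNTI| == 2 joins the adjacent selection class
and |RC| == 0.95 is undominated.

Deterministic processes: the two selection classes. Stochastic:
dispersal limitation, homogenizing dispersal, undominated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .structure import bray_curtis

DETERMINISTIC = ("heterogeneous_selection", "homogeneous_selection")
STOCHASTIC = ("dispersal_limitation", "homogenizing_dispersal", "undominated")
PROCESSES = DETERMINISTIC + STOCHASTIC


def tip_distance_matrix(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Patristic distance matrix over the given tip labels.

    Raises if any requested taxon is absent from the tree.
    """
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxa if t not in by_label]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:10]}")
    p = len(taxa)
    d = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            d[i, j] = d[j, i] = pdm.patristic_distance(by_label[taxa[i]], by_label[taxa[j]])
    return d


def _bmntd_from_dist(fi: np.ndarray, fj: np.ndarray, d: np.ndarray) -> float:
    """βMNTD between two communities given a tip distance matrix.

    fi, fj are abundance vectors on the shared taxon index; a taxon
    present in both communities has nearest-taxon distance zero.
    """
    ii = np.flatnonzero(fi > 0)
    jj = np.flatnonzero(fj > 0)
    wi = fi[ii] / fi[ii].sum()
    wj = fj[jj] / fj[jj].sum()
    min_i = d[np.ix_(ii, jj)].min(axis=1)
    min_j = d[np.ix_(jj, ii)].min(axis=1)
    return float(0.5 * ((wi * min_i).sum() + (wj * min_j).sum()))


def beta_mntd(
    comm_i,
    comm_j,
    tree: dendropy.Tree,
    taxa: list[str],
    abundance_weighted: bool = True,
) -> float:
    """Abundance-weighted (default) or unweighted βMNTD between two
    communities whose abundance vectors are indexed by ``taxa``."""
    fi = np.asarray(comm_i, dtype=float)
    fj = np.asarray(comm_j, dtype=float)
    if not abundance_weighted:
        fi = (fi > 0).astype(float)
        fj = (fj > 0).astype(float)
    d = tip_distance_matrix(tree, list(taxa))
    return _bmntd_from_dist(fi, fj, d)


def beta_mntd_matrix(abund: np.ndarray, d: np.ndarray) -> np.ndarray:
    """All-pairs βMNTD for an (S, p) abundance matrix.

    Vectorised: for each community j, m_j[a] = min over j's taxa of
    d[a, b]; then βMNTD(i, j) = 0.5 * ((F M^T)_{ij} + (F M^T)_{ji}) on
    row-normalised F.
    """
    f = abund / abund.sum(axis=1, keepdims=True)
    s, p = f.shape
    m = np.empty((s, p))
    for j in range(s):
        jj = np.flatnonzero(abund[j] > 0)
        m[j] = d[:, jj].min(axis=1)
    cross = f @ m.T  # cross[i, j] = sum_a f_ia * m_j[a]
    return 0.5 * (cross + cross.T)


def beta_nti(
    comm_i,
    comm_j,
    tree_or_dist,
    taxa: list[str] | None = None,
    n_null: int = 999,
    seed: int = 0,
) -> float:
    """βNTI for one community pair: z-score of observed βMNTD against a
    taxa-label-shuffling null (labels permuted across tree tips,
    abundances held fixed). ``n_null`` must be >= 99."""
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    fi = np.asarray(comm_i, dtype=float)
    fj = np.asarray(comm_j, dtype=float)
    if isinstance(tree_or_dist, dendropy.Tree):
        d = tip_distance_matrix(tree_or_dist, list(taxa))
    else:
        d = np.asarray(tree_or_dist, dtype=float)
    obs = _bmntd_from_dist(fi, fj, d)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_null)
    p = d.shape[0]
    for b in range(n_null):
        perm = rng.permutation(p)
        nulls[b] = _bmntd_from_dist(fi, fj, d[np.ix_(perm, perm)])
    sd = nulls.std(ddof=1)
    if sd == 0:
        if abs(obs - nulls.mean()) < 1e-12:
            # permutation-invariant geometry (e.g. star tree): obs == null
            return 0.0
        warnings.warn("degenerate null (sd = 0); βNTI undefined")
        return float("nan")
    return float((obs - nulls.mean()) / sd)


def beta_nti_matrix(
    abund: np.ndarray, d: np.ndarray, n_null: int = 999, seed: int = 0
) -> np.ndarray:
    """All-pairs βNTI for an (S, p) abundance matrix (shared null draws).

    Each null permutation of tip labels is applied to every pair at once,
    which is the standard within-dataset randomisation.
    """
    obs = beta_mntd_matrix(abund, d)
    rng = np.random.default_rng(seed)
    s = abund.shape[0]
    acc = np.zeros((s, s))
    acc2 = np.zeros((s, s))
    for _ in range(n_null):
        perm = rng.permutation(d.shape[0])
        nb = beta_mntd_matrix(abund, d[np.ix_(perm, perm)])
        acc += nb
        acc2 += nb**2
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0) * n_null / (n_null - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / np.sqrt(var)
    z[(var < 1e-24) & (np.abs(obs - mean) < 1e-12)] = 0.0
    return z


def rc_bray(
    comm_i,
    comm_j,
    species_pool: "SpeciesPool",
    n_null: int = 999,
    seed: int = 0,
) -> float:
    """Bray–Curtis Raup–Crick index in [-1, 1].

    Null communities preserve each observed community's richness and
    total abundance: taxa are drawn without replacement with probability
    proportional to their pool occurrence frequency, then individuals are
    filled multinomially proportional to pool mean relative abundances of
    the drawn taxa. RC = 2 * [P(null BC < obs) + 0.5 * P(null BC = obs)] - 1.
    """
    xi = np.asarray(comm_i, dtype=float)
    xj = np.asarray(comm_j, dtype=float)
    pool = species_pool
    for x in (xi, xj):
        if np.any((x > 0) & (pool.occurrence <= 0)):
            raise ValueError("species pool missing a community's taxon")
    obs = bray_curtis(xi, xj)
    rng = np.random.default_rng(seed)
    less = equal = 0
    for _ in range(n_null):
        ni = _null_community(xi, pool, rng)
        nj = _null_community(xj, pool, rng)
        nb = bray_curtis(ni, nj)
        if nb < obs - 1e-12:
            less += 1
        elif abs(nb - obs) <= 1e-12:
            equal += 1
    return float(2.0 * ((less + 0.5 * equal) / n_null) - 1.0)


@dataclass
class SpeciesPool:
    """Regional pool summary: per-taxon occurrence frequency and mean
    relative abundance across the pool's communities."""

    occurrence: np.ndarray
    mean_relabund: np.ndarray

    @classmethod
    def from_matrix(cls, abund: np.ndarray) -> "SpeciesPool":
        abund = np.asarray(abund, dtype=float)
        occ = (abund > 0).mean(axis=0)
        rel = abund / np.maximum(abund.sum(axis=1, keepdims=True), 1e-300)
        return cls(occ, rel.mean(axis=0))


def _null_community(x: np.ndarray, pool: SpeciesPool, rng: np.random.Generator) -> np.ndarray:
    richness = int((x > 0).sum())
    total = int(round(x.sum()))
    p_occ = pool.occurrence / pool.occurrence.sum()
    avail = int((p_occ > 0).sum())
    chosen = rng.choice(len(x), size=min(richness, avail), replace=False, p=p_occ)
    null = np.zeros_like(x, dtype=float)
    if total <= 0 or len(chosen) == 0:
        return null
    w = pool.mean_relabund[chosen]
    if w.sum() <= 0:
        w = np.ones(len(chosen))
    w = w / w.sum()
    null[chosen] = rng.multinomial(total, w)
    return null


def classify_process(
    beta_nti_value: float, rc_bray_value: float | None = None, convention: str = "negative-selection"
) -> str:
    """Map (βNTI, RC_Bray) to one of the five assembly processes.

    ``convention="negative-selection"`` uses the sign mapping documented in this
    module; ``"stegen"`` swaps heterogeneous/homogeneous selection.
    RC_Bray may be omitted only when |βNTI| >= 2.
    """
    if convention not in ("negative-selection", "stegen"):
        raise ValueError("convention must be 'negative-selection' or 'stegen'")
    b = float(beta_nti_value)
    if not np.isfinite(b):
        raise ValueError("βNTI must be finite")
    if abs(b) >= 2:
        low, high = "heterogeneous_selection", "homogeneous_selection"
        if convention == "stegen":
            low, high = high, low
        return low if b < 0 else high
    if rc_bray_value is None or not np.isfinite(rc_bray_value):
        raise ValueError("RC_Bray required when |βNTI| < 2")
    r = float(rc_bray_value)
    if r > 0.95:
        return "dispersal_limitation"
    if r < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def pairwise_assembly(
    abund: pd.DataFrame,
    d: np.ndarray,
    n_null: int = 999,
    seed: int = 0,
    convention: str = "negative-selection",
    max_pairs: int | None = None,
) -> pd.DataFrame:
    """βNTI, RC_Bray and process for sample pairs of one community set.

    ``max_pairs`` caps the number of pairs (seeded subsample) so large
    sample sets stay tractable; RC_Bray is only computed where
    |βNTI| < 2.
    """
    x = abund.to_numpy(dtype=float)
    ids = list(abund.index)
    z = beta_nti_matrix(x, d, n_null=n_null, seed=seed)
    bm = beta_mntd_matrix(x, d)
    pool = SpeciesPool.from_matrix(x)
    s = len(ids)
    pairs = [(i, j) for i in range(s) for j in range(i + 1, s)]
    rng = np.random.default_rng(seed + 1)
    if max_pairs is not None and len(pairs) > max_pairs:
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]
    rows = []
    for i, j in pairs:
        b = float(z[i, j])
        rc = np.nan
        if np.isfinite(b) and abs(b) < 2:
            rc = rc_bray(
                x[i], x[j], pool, n_null=n_null,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        if np.isfinite(b):
            proc = classify_process(b, None if not np.isfinite(rc) else rc, convention)
        else:
            # zero-variance null (e.g. both communities span every taxon)
            proc = "undefined"
        rows.append(
            {
                "sample_i": ids[i],
                "sample_j": ids[j],
                "beta_mntd": float(bm[i, j]),
                "beta_nti": b,
                "rc_bray": rc,
                "process": proc,
            }
        )
    return pd.DataFrame(rows)


def summarize_processes(results: pd.DataFrame, grouping: list[str] | None = None) -> pd.DataFrame:
    """Per-group process fractions plus the deterministic/stochastic split.

    Pairs flagged "undefined" (degenerate βNTI null) are excluded from
    the fractions; their count is reported in ``n_undefined``.
    """
    if results.empty:
        raise ValueError("empty results")
    results = results.copy()
    def _frac(df):
        n_undef = int((df["process"] == "undefined").sum())
        df = df[df["process"] != "undefined"]
        if df.empty:
            out = {p: np.nan for p in PROCESSES}
            out.update(deterministic=np.nan, stochastic=np.nan, n_pairs=0,
                       n_undefined=n_undef)
            return pd.Series(out)
        counts = df["process"].value_counts()
        total = counts.sum()
        out = {p: counts.get(p, 0) / total for p in PROCESSES}
        out["deterministic"] = sum(out[p] for p in DETERMINISTIC)
        out["stochastic"] = sum(out[p] for p in STOCHASTIC)
        out["n_pairs"] = int(total)
        out["n_undefined"] = n_undef
        return pd.Series(out)

    if grouping:
        empty = [g for g, df in results.groupby(grouping) if df.empty]
        if empty:
            warnings.warn(f"empty groups omitted: {empty}")
        return results.groupby(grouping).apply(_frac, include_groups=False).reset_index()
    return _frac(results).to_frame().T
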