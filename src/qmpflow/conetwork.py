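"""Genus–genus co-occurrence networks from partial Spearman correlation.

Within each gut segment, every genus pair passing a 30% prevalence
filter is tested by partial Spearman correlation (by default
conditioning on day posthatch, rank-coded, to suppress shared temporal
trends). p-values come from the t-distribution with n - 2 - k degrees of
freedom; Benjamini–Hochberg FDR is applied across all pairs of the
network and edges with adjusted p <= 0.05 are retained, signed by the
correlation. Topology, keystone (top-degree) taxa, generalist/specialist
edges across segments, per-vertex negative:positive ratios, and the
absolute-vs-relative profiling consistency cross-tab are computed on the
retained-edge graph.

NOTE: the conditioning set is the single most consequential modelling
choice here and is recorded in every network's provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable


@dataclass
class CoNetwork:
    edges: pd.DataFrame  # genus_a, genus_b, rho, p, p_adj, sign
    vertices: list[str]  # all genera tested (post prevalence filter)
    segment: str = ""
    mode: str = "QMP"
    conditioning: str = "dph"
    alpha: float = 0.05
    all_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)  # incl. NS

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for _, e in self.edges.iterrows():
            g.add_edge(e.genus_a, e.genus_b, rho=e.rho, sign=e.sign)
        return g


@dataclass
class TopologySummary:
    n_vertices: int
    n_edges: int
    clustering: float
    avg_betweenness: float
    avg_separation: float
    empty: bool = False


def prevalence_filter(table: FeatureTable, min_prevalence: float = 0.30) -> FeatureTable:
    """Keep genera present (nonzero) in at least ``min_prevalence`` of
    samples; the boundary is inclusive ("at least 30%")."""
    n = len(table.samples)
    prev = (table.data > 0).sum(axis=0) / n
    keep = table.taxa[prev >= min_prevalence - 1e-12]
    if len(keep) == 0:
        warnings.warn("no genus passes the prevalence filter; empty network")
    out = table.copy()
    out.data = out.data[keep]
    return out


def _rank(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, x)


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed, the ranks of x and y are
    residualised on the (ranked) covariates plus an intercept, and the
    Pearson correlation of the residuals is the partial Spearman rho —
    identical to the recursive partial-correlation formula. p is
    two-sided from t with n - 2 - k df. A variable constant after
    ranking is undefined: returns (nan, 1.0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need >= 5 observations")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
    k = cov.shape[1]
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("constant variable after ranking; correlation undefined (NS)")
        return float("nan"), 1.0
    design = np.column_stack([np.ones(n), _rank(cov) if k else np.empty((n, 0))])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex, ey = rx - design @ beta_x, ry - design @ beta_y
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom == 0:
        warnings.warn("degenerate residuals; correlation undefined (NS)")
        return float("nan"), 1.0
    rho = float((ex * ey).sum() / denom)
    df = n - 2 - k
    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return rho, p


def _partial_spearman_matrix(data: np.ndarray, cov: np.ndarray):
    """All-pairs partial Spearman over the columns of data (vectorised)."""
    n, p = data.shape
    ranks = _rank(data)
    design = np.column_stack([np.ones(n), _rank(cov) if cov.shape[1] else np.empty((n, 0))])
    beta, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    resid = ranks - design @ beta
    sd = resid.std(axis=0)
    ok = sd > 1e-12
    resid_n = np.where(ok, resid / np.where(ok, sd, 1.0), 0.0)
    corr = (resid_n.T @ resid_n) / n
    corr = corr / np.outer(
        np.sqrt(np.diag(corr).clip(min=1e-300)), np.sqrt(np.diag(corr).clip(min=1e-300))
    )
    corr[~ok, :] = np.nan
    corr[:, ~ok] = np.nan
    df = n - 2 - cov.shape[1]
    rho_c = np.clip(corr, -1 + 1e-15, 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    pmat = 2 * stats.t.sf(np.abs(t), df)
    return corr, pmat


def build_network(
    table: FeatureTable,
    covariates: pd.DataFrame | str | None = "dph",
    alpha: float = 0.05,
    segment: str = "",
) -> CoNetwork:
    """Test all genus pairs, BH-correct within the network, retain edges
    at adjusted p <= alpha. The prevalence filter must have been applied
    already."""
    n = len(table.samples)
    if n < 5:
        raise ValueError("need >= 5 samples")
    if isinstance(covariates, str):
        if covariates == "dph":
            cov = table.meta[["dph"]].to_numpy(dtype=float)
            cond = "dph"
        elif covariates in (None, "none"):
            cov = np.empty((n, 0))
            cond = "none"
        else:
            raise ValueError("covariates must be 'dph', 'none', or a DataFrame")
    elif covariates is None:
        cov, cond = np.empty((n, 0)), "none"
    else:
        cov, cond = covariates.to_numpy(dtype=float), "custom"

    genera = list(table.taxa)
    data = table.data.to_numpy(dtype=float)
    corr, pmat = _partial_spearman_matrix(data, cov)
    pairs = list(combinations(range(len(genera)), 2))
    rows = []
    for i, j in pairs:
        rho, p = corr[i, j], pmat[i, j]
        if np.isnan(rho):
            rho, p = np.nan, 1.0
        rows.append({"genus_a": genera[i], "genus_b": genera[j], "rho": rho, "p": p})
    all_pairs = pd.DataFrame(rows, columns=["genus_a", "genus_b", "rho", "p"])
    if len(all_pairs):
        all_pairs["p_adj"] = multipletests(all_pairs["p"].fillna(1.0), method="fdr_bh")[1]
        all_pairs["sign"] = np.sign(all_pairs["rho"]).fillna(0).astype(int)
        edges = all_pairs[(all_pairs.p_adj <= alpha) & all_pairs.rho.notna()].reset_index(
            drop=True
        )
    else:
        all_pairs = all_pairs.assign(p_adj=[], sign=[])
        edges = all_pairs
    return CoNetwork(
        edges=edges,
        vertices=genera,
        segment=segment,
        mode=table.mode,
        conditioning=cond,
        alpha=alpha,
        all_pairs=all_pairs,
    )


def topology(net: CoNetwork) -> TopologySummary:
    """Topology metrics on the unweighted retained-edge graph.

    Clustering is the average of local clustering coefficients;
    betweenness is unnormalised and averaged over vertices; average
    separation is the mean shortest-path length over connected pairs
    only (disconnected pairs excluded).
    """
    g = net.graph()
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        return TopologySummary(0, 0, 0.0, 0.0, 0.0, empty=True)
    clustering = nx.average_clustering(g)
    btw = nx.betweenness_centrality(g, normalized=False)
    avg_btw = float(np.mean(list(btw.values())))
    total, count = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            count += len(lengths) - 1  # exclude self
    avg_sep = total / count if count else 0.0
    return TopologySummary(
        g.number_of_nodes(), g.number_of_edges(), float(clustering), avg_btw, float(avg_sep)
    )


def keystone(net: CoNetwork, top_n: int = 10) -> pd.DataFrame:
    """Top-degree taxa. Ties: higher summed |rho|, then lexical name."""
    if not len(net.edges):
        return pd.DataFrame(columns=["genus", "degree", "sum_abs_rho"])
    deg: dict[str, int] = {}
    strength: dict[str, float] = {}
    for _, e in net.edges.iterrows():
        for gname in (e.genus_a, e.genus_b):
            deg[gname] = deg.get(gname, 0) + 1
            strength[gname] = strength.get(gname, 0.0) + abs(e.rho)
    df = pd.DataFrame(
        {"genus": list(deg), "degree": list(deg.values()),
         "sum_abs_rho": [strength[g] for g in deg]}
    )
    df = df.sort_values(
        ["degree", "sum_abs_rho", "genus"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df.head(top_n)


def edge_sharing(nets: list[CoNetwork]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generalist/specialist labels across per-segment networks.

    Edge identity is the unordered genus pair; sign is ignored. Returns
    (per-edge table, per-segment specialist percentage).
    """
    if len(nets) < 2:
        raise ValueError("need at least two networks")
    membership: dict[tuple, set] = {}
    for net in nets:
        for _, e in net.edges.iterrows():
            key = tuple(sorted((e.genus_a, e.genus_b)))
            membership.setdefault(key, set()).add(net.segment)
    rows = [
        {
            "genus_a": k[0],
            "genus_b": k[1],
            "segments": ",".join(sorted(v)),
            "n_segments": len(v),
            "label": "specialist" if len(v) == 1 else "generalist",
        }
        for k, v in membership.items()
    ]
    edge_df = pd.DataFrame(rows)
    seg_rows = []
    for net in nets:
        keys = {tuple(sorted((e.genus_a, e.genus_b))) for _, e in net.edges.iterrows()}
        n_spec = sum(1 for k in keys if len(membership[k]) == 1)
        seg_rows.append(
            {
                "segment": net.segment,
                "n_edges": len(keys),
                "pct_specialist": 100.0 * n_spec / len(keys) if keys else 0.0,
            }
        )
    return edge_df, pd.DataFrame(seg_rows)


def sign_ratio(net: CoNetwork, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-vertex log10 negative:positive degree ratio.

    A pseudocount keeps the log finite; isolated vertices are omitted.
    """
    pos: dict[str, int] = {}
    neg: dict[str, int] = {}
    for _, e in net.edges.iterrows():
        d = pos if e.rho > 0 else neg
        for gname in (e.genus_a, e.genus_b):
            d[gname] = d.get(gname, 0) + 1
    vertices = sorted(set(pos) | set(neg))
    rows = []
    for v in vertices:
        np_, nn = pos.get(v, 0), neg.get(v, 0)
        ratio = np.log10((nn + pseudocount) / (np_ + pseudocount))
        rows.append(
            {
                "genus": v,
                "degree": np_ + nn,
                "n_positive": np_,
                "n_negative": nn,
                "log10_neg_pos": float(ratio),
                "dominance": "negative" if nn > np_ else ("positive" if np_ > nn else "even"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ConsistencyTable:
    counts: pd.DataFrame  # 3x3, rows = QMP category, cols = RMP category
    consistency_pct: float


def _categorize(net: CoNetwork) -> dict[tuple, str]:
    out = {}
    retained = {
        tuple(sorted((e.genus_a, e.genus_b))): ("Pos" if e.rho > 0 else "Neg")
        for _, e in net.edges.iterrows()
    }
    for _, row in net.all_pairs.iterrows():
        key = tuple(sorted((row.genus_a, row.genus_b)))
        out[key] = retained.get(key, "NS")
    return out


def qmp_rmp_consistency(net_qmp: CoNetwork, net_rmp: CoNetwork) -> ConsistencyTable:
    """3x3 cross-tab of pair categories (Pos/Neg/NS) between the
    absolute-mode and relative-mode networks; consistency is the diagonal
    share in percent. Pairs are restricted to the common genus universe
    (with a warning if the universes differ)."""
    cat_q = _categorize(net_qmp)
    cat_r = _categorize(net_rmp)
    common = set(cat_q) & set(cat_r)
    if len(common) != len(cat_q) or len(common) != len(cat_r):
        warnings.warn("genus universes differ; restricted to common pairs")
    cats = ["Pos", "Neg", "NS"]
    counts = pd.DataFrame(0, index=cats, columns=cats)
    for key in common:
        counts.loc[cat_q[key], cat_r[key]] += 1
    total = counts.to_numpy().sum()
    diag = np.trace(counts.to_numpy())
    pct = 100.0 * diag / total if total else 100.0
    return ConsistencyTable(counts, float(pct))
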