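"""Microbe–metabolite integration.

Conditional co-occurrence probabilities P(metabolite | microbe) come from
a low-rank softmax factorisation trained on paired microbiome–metabolome
samples:

    P(metabolite j | microbe i) = softmax_j(U_i . V_j + b_j)

fitted by gradient descent on the expected multinomial log-likelihood in
which, within each sample, microbe "tokens" occur in proportion to the
microbe counts and predict the sample's metabolite relative intensities.
The top 1% of (microbe, metabolite) pairs by conditional probability are
taken as putative positive co-occurrences, summarised as per-(segment x
domain, metabolite cluster) retention percentages and a merged bipartite
interaction network with top-degree key taxa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class InteractionMatrix:
    probabilities: pd.DataFrame  # microbes x metabolites, rows sum to 1
    u: np.ndarray  # microbe embeddings (m, d)
    v: np.ndarray  # metabolite embeddings (p, d)
    bias: np.ndarray  # metabolite bias (p,)
    loss_trace: list = field(default_factory=list)


def mmvec_fit(
    microbe_counts: pd.DataFrame,
    metabolite_intensities: pd.DataFrame,
    latent_dim: int = 3,
    epochs: int = 500,
    learning_rate: float = 0.1,
    seed: int = 0,
) -> InteractionMatrix:
    """Fit the low-rank softmax co-occurrence model.

    Both inputs are samples x features on a shared sample index. Microbe
    counts are converted to per-sample proportions (token weights) and
    metabolite intensities to per-sample relative intensities (the
    multinomial target), so the fit is invariant to per-sample scaling of
    either input. Full-batch gradient descent with backtracking (the step
    is halved and retried whenever the loss would increase), deterministic
    under a fixed seed.
    """
    if not microbe_counts.index.equals(metabolite_intensities.index):
        if set(microbe_counts.index) != set(metabolite_intensities.index):
            raise ValueError("sample mismatch between microbe and metabolite tables")
        metabolite_intensities = metabolite_intensities.loc[microbe_counts.index]
    if latent_dim < 0:
        raise ValueError("latent_dim must be >= 0")
    xm = microbe_counts.to_numpy(dtype=float)
    ym = metabolite_intensities.to_numpy(dtype=float)
    n, m = xm.shape
    p = ym.shape[1]
    pi = xm / np.maximum(xm.sum(axis=1, keepdims=True), 1e-300)  # token weights
    yr = ym / np.maximum(ym.sum(axis=1, keepdims=True), 1e-300)  # targets

    # sufficient statistics: per-microbe token mass and target mass
    c = pi.sum(axis=0)  # (m,)
    target = pi.T @ yr  # (m, p): sum_s pi_si * y_sj

    rng = np.random.default_rng(seed)
    d = latent_dim
    u = rng.normal(0, 0.1, size=(m, d))
    v = rng.normal(0, 0.1, size=(p, d))
    b = np.zeros(p)

    def _probs(u_, v_, b_):
        logits = u_ @ v_.T + b_ if d else np.broadcast_to(b_, (m, p)).copy()
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def _loss(pr):
        return float(-(target * np.log(np.maximum(pr, 1e-300))).sum())

    lr = learning_rate
    pr = _probs(u, v, b)
    loss = _loss(pr)
    trace = [loss]
    for _ in range(epochs):
        g_logits = c[:, None] * pr - target  # (m, p)
        if d:
            gu = g_logits @ v
            gv = g_logits.T @ u
        gb = g_logits.sum(axis=0)
        stepped = False
        while lr > 1e-8:
            u_n = u - lr * gu if d else u
            v_n = v - lr * gv if d else v
            b_n = b - lr * gb
            pr_n = _probs(u_n, v_n, b_n)
            loss_n = _loss(pr_n)
            if not math.isfinite(loss_n):
                raise FloatingPointError(
                    "divergent training loss; lower the learning rate"
                )
            if loss_n <= loss + 1e-12:
                u, v, b, pr, loss = u_n, v_n, b_n, pr_n, loss_n
                stepped = True
                break
            lr *= 0.5
        trace.append(loss)
        if not stepped:
            break
    probs = pd.DataFrame(
        pr, index=microbe_counts.columns, columns=metabolite_intensities.columns
    )
    return InteractionMatrix(probs, u, v, b, trace)


@dataclass
class InteractionSelection:
    retained: pd.DataFrame  # microbe, metabolite, probability [, segment...]
    fraction: float
    n_total: int


def select_top(
    interactions: InteractionMatrix | pd.DataFrame, fraction: float = 0.01
) -> InteractionSelection:
    """Global top-fraction selection over all (microbe, metabolite) pairs.

    Retains ceil(fraction * n_pairs) pairs by probability; ties at the
    cutoff are broken by stable (microbe, metabolite) ordering.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    probs = (
        interactions.probabilities
        if isinstance(interactions, InteractionMatrix)
        else interactions
    )
    long = probs.stack().rename("probability").reset_index()
    long.columns = ["microbe", "metabolite", "probability"]
    n_total = len(long)
    n_keep = math.ceil(fraction * n_total)
    long = long.sort_values(
        ["probability", "microbe", "metabolite"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return InteractionSelection(long.head(n_keep).reset_index(drop=True), fraction, n_total)


def merge_selections(parts: dict[tuple[str, str], InteractionSelection]) -> pd.DataFrame:
    """Merge per-(segment, domain) selections into one labelled table."""
    frames = []
    for (segment, domain), sel in parts.items():
        df = sel.retained.copy()
        df["segment"] = segment
        df["domain"] = domain
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def ratio_table(
    selection: pd.DataFrame,
    microbe_labels: pd.DataFrame,
    metabolite_clusters: pd.Series,
    totals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Percent of pairs retained per (segment x domain, metabolite cluster).

    ``microbe_labels`` maps microbe -> segment, domain (per stratum);
    ``totals`` gives the number of candidate pairs per stratum; when
    omitted it is computed as n_microbes(stratum) x n_metabolites(cluster).
    """
    sel = selection.copy()
    unlabeled = set(sel.microbe) - set(microbe_labels.index)
    if "segment" not in sel.columns:
        sel = sel.join(microbe_labels, on="microbe")
    if unlabeled and "segment" not in selection.columns:
        raise ValueError(f"unlabelled microbes: {sorted(unlabeled)[:5]}")
    missing_met = set(sel.metabolite) - set(metabolite_clusters.index)
    if missing_met:
        raise ValueError(f"metabolites without cluster label: {sorted(missing_met)[:5]}")
    sel["cluster"] = metabolite_clusters.reindex(sel.metabolite).to_numpy()
    counts = (
        sel.groupby(["segment", "domain", "cluster"], observed=True)
        .size()
        .rename("n_retained")
        .reset_index()
    )
    if totals is None:
        n_microbes = (
            microbe_labels.reset_index()
            .groupby(["segment", "domain"], observed=True)
            .size()
            .rename("n_microbes")
        )
        n_mets = metabolite_clusters.value_counts().rename("n_metabolites")
        counts = counts.join(n_microbes, on=["segment", "domain"]).join(
            n_mets, on="cluster"
        )
        counts["n_pairs"] = counts.n_microbes * counts.n_metabolites
    else:
        counts = counts.merge(totals, on=["segment", "domain", "cluster"])
    counts["pct_retained"] = 100.0 * counts.n_retained / counts.n_pairs
    return counts


def interaction_network(
    selection: pd.DataFrame, taxonomy: pd.DataFrame | None = None
) -> tuple[nx.Graph, pd.DataFrame, pd.DataFrame]:
    """Merged bipartite microbe–metabolite graph from retained pairs.

    Returns (graph, per-microbe degree ranking, per-chemical-category
    metabolite counts when a taxonomy with a 'superclass' column is
    given).
    """
    if selection.empty:
        raise ValueError("empty selection")
    g = nx.Graph()
    for _, row in selection.iterrows():
        g.add_node(("microbe", row.microbe), bipartite=0)
        g.add_node(("metabolite", row.metabolite), bipartite=1)
        g.add_edge(("microbe", row.microbe), ("metabolite", row.metabolite),
                   probability=row.probability)
    deg = (
        selection.groupby("microbe")["metabolite"]
        .nunique()
        .rename("degree")
        .sort_values(ascending=False)
        .reset_index()
    )
    if taxonomy is not None and "superclass" in taxonomy.columns:
        mets = selection["metabolite"].drop_duplicates()
        cats = (
            taxonomy.reindex(mets)["superclass"]
            .fillna("unclassified")
            .value_counts()
            .rename("n_metabolites")
            .reset_index()
        )
    else:
        cats = pd.DataFrame(columns=["superclass", "n_metabolites"])
    return g, deg, cats
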