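"""Microbial source tracking by expectation–maximisation.

A sink community's count vector is modelled as a multinomial draw from a
mixture of candidate source profiles plus an optional "unknown" source:

    P(taxon j in sink) = sum_k alpha_k * gamma_kj

where gamma_k are the source relative-abundance profiles and alpha the
mixing proportions being estimated. EM alternates per-read source
responsibilities (E) with closed-form alpha updates (M). By default the
known-source profiles are held fixed at their observed proportions (with
a small pseudocount), which makes the fit deterministic given the data;
joint re-estimation of the source profiles from their own counts (the
behaviour of full FEAST) is available behind ``refit_sources``.

The unknown-source profile is re-estimated only during a short burn-in
and then frozen: a freely re-estimated unknown is degenerate (its global
maximum-likelihood solution is to copy the sink and take all the mass),
so the burn-in shapes it from the sink mass the known sources cannot
explain, after which EM over fixed profiles is identifiable and its
likelihood still monotone.

Applied longitudinally along the gut, each segment is a sink and the
adjacent anterior segment of the same bird at the same day is the source
of interest: the reported quantity is the proportion of the sink
community contributed by the segment immediately upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .tables import SEGMENT_ORDER, FeatureTable

_PSEUDO = 1e-8


@dataclass
class SourceEstimate:
    sink_id: str
    source_ids: list[str]  # includes "unknown" when enabled
    proportions: np.ndarray  # alpha, sums to 1
    ll_trace: list = field(default_factory=list)
    converged: bool = False

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.source_ids, name=self.sink_id)


def feast_em(
    sink_counts,
    source_counts,
    source_ids=None,
    include_unknown: bool = True,
    refit_sources: bool = False,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-9,
    unknown_burn_in: int = 25,
    sink_id: str = "sink",
) -> SourceEstimate:
    """Estimate source mixing proportions for one sink community.

    Parameters
    ----------
    sink_counts : (p,) count vector
    source_counts : (K, p) matrix of source count vectors on the same
        taxon index.
    include_unknown : add an unknown source whose profile is estimated;
        initialised from the sink mass unexplained by the known sources.
    refit_sources : also re-estimate known-source profiles jointly from
        their own counts plus their sink-attributed counts.
    """
    x = np.asarray(sink_counts, dtype=float)
    y = np.atleast_2d(np.asarray(source_counts, dtype=float))
    if x.ndim != 1 or y.shape[1] != x.size:
        raise ValueError("sink and sources must share the taxon index")
    if x.sum() <= 0:
        raise ValueError("all-zero sink")
    if np.any(y.sum(axis=1) <= 0):
        raise ValueError("a source has zero depth")
    k_known = y.shape[0]
    if source_ids is None:
        source_ids = [f"source_{i+1}" for i in range(k_known)]
    source_ids = list(source_ids)

    gamma = (y + _PSEUDO) / (y + _PSEUDO).sum(axis=1, keepdims=True)
    n = x.sum()
    p_sink = x / n

    if include_unknown:
        # initialise the unknown from the sink mass the sources cannot
        # explain: non-negative least-squares residual of the sink
        # composition on the source profiles
        beta, _ = nnls(gamma.T, p_sink)
        unexplained = np.maximum(p_sink - beta @ gamma, 0.0) + _PSEUDO
        gamma = np.vstack([gamma, unexplained / unexplained.sum()])
        source_ids = source_ids + ["unknown"]
        alpha = np.concatenate([beta, [unexplained.sum()]])
        alpha = np.maximum(alpha, 0.02)
        alpha = alpha / alpha.sum()
    else:
        alpha = np.full(k_known, 1.0 / k_known)
    k = gamma.shape[0]

    ll_trace: list[float] = []
    converged = False
    support = x > 0
    xs = x[support]
    for it in range(max_iter):
        mix = alpha @ gamma  # (p,)
        ll = float((xs * np.log(mix[support])).sum())
        ll_trace.append(ll)
        # E-step: responsibility of source k for taxon j
        w = alpha[:, None] * gamma  # (k, p)
        w = w / np.maximum(w.sum(axis=0, keepdims=True), _PSEUDO**2)
        attributed = w * x[None, :]  # expected counts per source
        # M-step
        alpha = attributed.sum(axis=1) / n
        alpha = np.maximum(alpha, 0.0)
        alpha = alpha / alpha.sum()
        if include_unknown and it < unknown_burn_in:
            gu = attributed[-1] + _PSEUDO
            gamma[-1] = gu / gu.sum()
        if refit_sources:
            refit = y + attributed[:k_known] + _PSEUDO
            gamma[:k_known] = refit / refit.sum(axis=1, keepdims=True)
        if len(ll_trace) > 1 and abs(ll_trace[-1] - ll_trace[-2]) < tol * abs(ll_trace[-2]):
            converged = True
            break
    return SourceEstimate(sink_id, source_ids, alpha, ll_trace, converged)


def adjacent_segment_contribution(
    table: FeatureTable,
    segments=SEGMENT_ORDER,
    include_unknown: bool = True,
    **em_kwargs,
) -> pd.DataFrame:
    """Per-bird, per-day proportion of each sink segment sourced from its
    adjacent anterior segment.

    For each bird x day, every segment after the first is treated as a
    sink with all other same-bird same-day segments as sources (plus an
    unknown source); only the adjacent-anterior mixing proportion is
    reported. The first segment has no anterior source and yields no row.
    Missing segments skip that sink with a log record (warning).
    """
    segments = list(segments)
    meta = table.meta
    rows = []
    for (bird, dph), grp in meta.groupby(["bird", "dph"]):
        present = {s: sid for sid, s in grp["segment"].items()}
        for si, sink_seg in enumerate(segments):
            if si == 0:
                continue
            anterior = segments[si - 1]
            if sink_seg not in present or anterior not in present:
                warnings.warn(
                    f"bird {bird} dph {dph}: sink {sink_seg} skipped "
                    "(sink or anterior segment missing)"
                )
                continue
            sink_sid = present[sink_seg]
            source_segs = [s for s in segments if s != sink_seg and s in present]
            src_counts = np.stack(
                [table.data.loc[present[s]].to_numpy() for s in source_segs]
            )
            est = feast_em(
                table.data.loc[sink_sid].to_numpy(),
                src_counts,
                source_ids=source_segs,
                include_unknown=include_unknown,
                sink_id=sink_sid,
                **em_kwargs,
            )
            rows.append(
                {
                    "bird": bird,
                    "dph": dph,
                    "sink_segment": sink_seg,
                    "source_segment": anterior,
                    "proportion": float(est.as_series()[anterior]),
                    "unknown": float(est.as_series().get("unknown", np.nan)),
                    "converged": est.converged,
                }
            )
    return pd.DataFrame(rows)
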