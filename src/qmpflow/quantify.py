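"""qPCR calibration and the RMP -> QMP transform.

Quantitative microbiome profiling (QMP) rescales each sample's sequencing
proportions by an independently measured microbial load so that abundances
are absolute (marker-gene copies per gram of luminal content) rather than
compositional. The load comes from a qPCR standard curve:

    Ct = slope * log10(copies) + intercept

fitted over a 10-fold dilution series (10^3 .. 10^8 copies here). The
amplification efficiency implied by the slope is
``(10^(-1/slope) - 1) * 100`` percent; a perfectly doubling reaction has
slope -1/log10(2) = -3.3219 and efficiency 100%.

Loads are expressed as marker-gene copies per gram, not cells: no 16S
copy-number correction is applied by default (a hook exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable


class CalibrationError(ValueError):
    pass


@dataclass
class StandardCurve:
    """Fitted qPCR standard curve (Ct regressed on log10 copies)."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float  # percent
    domain: str = "bacteria"
    log10_range: tuple[float, float] = (3.0, 8.0)

    @property
    def ct_range(self) -> tuple[float, float]:
        lo, hi = self.log10_range
        a, b = self.slope * lo + self.intercept, self.slope * hi + self.intercept
        return (min(a, b), max(a, b))


def fit_standard_curve(log10_copies, ct, domain: str = "bacteria") -> StandardCurve:
    """OLS fit of Ct on log10 copies over a dilution series.

    Requires at least three distinct concentration points. slope is in
    Ct per log10-copies (negative for a valid curve).
    """
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size < 3 or np.unique(x).size < 3:
        raise CalibrationError("standard curve needs >=3 distinct concentration points")
    if np.ptp(x) == 0:
        raise CalibrationError("zero variance in log10_copies")
    res = stats.linregress(x, y)
    efficiency = (10.0 ** (-1.0 / res.slope) - 1.0) * 100.0
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(efficiency),
        domain=domain,
        log10_range=(float(x.min()), float(x.max())),
    )


def ct_to_load(
    curve: StandardCurve,
    ct,
    dilution_factor,
    sample_weight,
) -> np.ndarray:
    """Back-calculate copies per gram from Ct values.

    copies = 10 ** ((ct - intercept) / slope); load = copies *
    dilution_factor / sample_weight. Ct values outside the calibrated
    range are extrapolations and raise a warning.
    """
    ct = np.asarray(ct, dtype=float)
    weight = np.asarray(sample_weight, dtype=float)
    if np.any(weight <= 0):
        raise ValueError("sample_weight must be positive")
    lo, hi = curve.ct_range
    if np.any((ct < lo) | (ct > hi)):
        warnings.warn(
            "Ct outside calibrated range "
            f"[{lo:.2f}, {hi:.2f}]; load is an extrapolation",
            stacklevel=2,
        )
    copies = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return copies * np.asarray(dilution_factor, dtype=float) / weight


def qmp_transform(
    table: FeatureTable,
    loads: pd.Series | pd.DataFrame,
    copy_number: pd.Series | None = None,
) -> FeatureTable:
    """Scale each sample's proportions by its measured load -> QMP table.

    Parameters
    ----------
    loads
        Series of copies/g indexed by sample id, or a DataFrame with
        columns ``sample_id`` and ``load``.
    copy_number
        Optional per-taxon marker-gene copy numbers; when given, QMP
        values are divided by them (off by default — loads stay in
        copies/g).

    Samples with zero total abundance are excluded (with a warning);
    samples lacking a load raise an error naming them.
    """
    if isinstance(loads, pd.DataFrame):
        loads = loads.set_index("sample_id")["load"]
    totals = table.data.sum(axis=1)
    zero = totals[totals == 0].index
    keep = table.data.index.difference(zero)
    if len(zero):
        warnings.warn(f"excluded {len(zero)} zero-total samples: {list(zero)[:5]}")
    missing = keep.difference(loads.index)
    if len(missing):
        raise ValueError(f"no load measurement for samples: {list(missing)}")
    props = table.proportions().loc[keep]
    qmp = props.mul(loads.loc[keep], axis=0)
    if copy_number is not None:
        qmp = qmp.div(copy_number.reindex(qmp.columns), axis=1)
    return FeatureTable(
        qmp, table.meta.loc[keep], table.lineage, "QMP",
        {**table.provenance, "loads": "copies_per_gram"},
    )


def rmp_transform(table: FeatureTable) -> FeatureTable:
    """Row-normalise to relative abundances (RMP)."""
    return FeatureTable(
        table.proportions(), table.meta, table.lineage, "RMP", dict(table.provenance)
    )


_RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]
_PREFIX = dict(zip(_RANKS, ["d", "p", "c", "o", "f", "g", "s"]))


def _label_at_rank(lineage: str, rank: str) -> str:
    """Taxon label at a rank, falling back to the deepest named ancestor.

    A lineage missing its genus but carrying family Nectriaceae collapses
    to ``f_Nectriaceae``, mirroring the labelling convention of mixed-rank
    genus tables.
    """
    fields = [f.strip() for f in str(lineage).split(";")]
    named: dict[str, str] = {}
    for f in fields:
        if "__" in f:
            pre, _, name = f.partition("__")
            if name:
                for r, p in _PREFIX.items():
                    if pre.lstrip().lower() in (p, "k"):  # accept k__ for domain
                        named[r] = name
    want = _RANKS[: _RANKS.index(rank) + 1]
    if rank in named:
        return named[rank]
    for r in reversed(want):
        if r in named:
            return f"{_PREFIX[r]}_{named[r]}"
    return str(lineage)


def collapse_taxa(table: FeatureTable, rank: str = "genus") -> FeatureTable:
    """Sum columns within a taxonomic rank.

    Taxa whose lineage lacks the requested rank are pooled under their
    deepest named ancestor (``f_Family`` / ``o_Order``-style labels);
    malformed lineages keep the taxon as its own label with a warning.
    Per-sample totals are preserved exactly.
    """
    if rank not in _RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if table.lineage is None:
        return table.copy()
    labels = {}
    for taxon in table.taxa:
        lin = table.lineage.get(taxon)
        if lin is None or "__" not in str(lin):
            if lin is not None:
                warnings.warn(f"malformed lineage for {taxon!r}; kept as its own label")
            labels[taxon] = str(taxon)
        else:
            labels[taxon] = _label_at_rank(lin, rank)
    collapsed = table.data.T.groupby(table.taxa.map(labels)).sum().T
    return FeatureTable(collapsed, table.meta, None, table.mode, dict(table.provenance))


def impute_missing_loads(
    loads: pd.Series, meta: pd.DataFrame, enable: bool = False
) -> pd.Series:
    """Optionally impute failed-qPCR loads as the geometric mean of the
    sample's segment x DPH group; default policy is exclusion (no-op)."""
    if not enable:
        return loads.dropna()
    out = loads.copy()
    for sid in loads.index[loads.isna()]:
        seg, dph = meta.loc[sid, "segment"], meta.loc[sid, "dph"]
        grp = meta[(meta.segment == seg) & (meta.dph == dph)].index
        vals = loads.reindex(grp).dropna()
        if len(vals):
            out[sid] = float(np.exp(np.log(vals).mean()))
    return out.dropna()
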