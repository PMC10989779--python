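"""Feature tables and on-disk formats.

The central container is :class:`FeatureTable`: a samples x taxa abundance
matrix carrying per-sample metadata (bird, gut segment, day posthatch,
domain), optional taxon lineage strings, and a mode flag that records
whether values are raw counts, relative abundances (RMP) or absolute
abundances in marker-gene copies per gram (QMP).

Supported interchange formats are TSV (primary) and dense BIOM 1.0 JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MODES = ("counts", "RMP", "QMP")

#: canonical anterior-to-posterior ordering of the sampled gut segments
SEGMENT_ORDER = ("duodenum", "jejunum", "ileum", "cecum")


class TableValidationError(ValueError):
    """Raised when a feature table violates its structural contract."""


@dataclass
class FeatureTable:
    """Samples x taxa abundance matrix with sample metadata.

    Parameters
    ----------
    data
        DataFrame with samples as rows and taxa as columns. Values must be
        non-negative.
    meta
        DataFrame indexed by sample id. Expected columns (when present):
        ``bird``, ``segment``, ``dph``, ``domain``.
    lineage
        Optional Series mapping taxon id -> semicolon-delimited lineage
        string (``d__...;p__...;...;g__...``).
    mode
        One of ``counts``, ``RMP`` (rows sum to 1) or ``QMP`` (rows sum to
        the sample's microbial load in copies/g).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    lineage: pd.Series | None = None
    mode: str = "counts"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise TableValidationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if (self.data.to_numpy() < 0).any():
            bad = np.argwhere(self.data.to_numpy() < 0)[0]
            raise TableValidationError(
                f"negative abundance at sample {self.data.index[bad[0]]!r}, "
                f"taxon {self.data.columns[bad[1]]!r}"
            )
        missing = self.data.index.difference(self.meta.index)
        if len(missing):
            raise TableValidationError(f"samples missing from metadata: {list(missing)[:5]}")
        if self.data.index.has_duplicates:
            raise TableValidationError("duplicate sample ids")
        # keep metadata aligned to the matrix
        self.meta = self.meta.loc[self.data.index]

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def taxa(self) -> pd.Index:
        return self.data.columns

    def proportions(self) -> pd.DataFrame:
        """Row-normalised relative abundances (zero-sum rows stay zero)."""
        totals = self.data.sum(axis=1)
        safe = totals.replace(0.0, np.nan)
        return self.data.div(safe, axis=0).fillna(0.0)

    def subset(self, sample_mask) -> "FeatureTable":
        idx = self.data.index[sample_mask] if np.ndim(sample_mask) else sample_mask
        return FeatureTable(
            self.data.loc[idx], self.meta.loc[idx], self.lineage, self.mode,
            dict(self.provenance),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.data.copy(), self.meta.copy(),
            None if self.lineage is None else self.lineage.copy(),
            self.mode, dict(self.provenance),
        )


def write_feature_table(table: FeatureTable, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        table.data.to_csv(path, sep="\t", index_label="sample_id")
    elif fmt == "biom":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_feature_table(
    path: str | Path,
    fmt: str = "tsv",
    meta: pd.DataFrame | None = None,
    mode: str = "counts",
) -> FeatureTable:
    """Read a feature table, auto-detecting orientation for TSV.

    Orientation: the canonical layout is samples-as-rows. If metadata is
    supplied and the column labels (but not the row labels) match metadata
    sample ids, the matrix is transposed on read.
    """
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lineage = None
        if meta is not None:
            row_hit = df.index.isin(meta.index).mean()
            col_hit = df.columns.isin(meta.index).mean()
            if col_hit > row_hit:
                df = df.T
    elif fmt == "biom":
        df, lineage = _read_biom_json(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if meta is None:
        meta = pd.DataFrame(index=df.index)
    extra = meta.index.difference(df.index)
    meta = meta.loc[meta.index.intersection(df.index)]
    if len(extra):
        import warnings

        warnings.warn(f"{len(extra)} metadata samples absent from table were dropped")
    return FeatureTable(df, meta.reindex(df.index), lineage, mode)


# -- BIOM 1.0 JSON (dense) ------------------------------------------------
# biom-format is not available as a library here; the published JSON schema
# is small enough to serialise directly. Observation-major layout (rows =
# taxa) is the BIOM convention and is transposed on read.

def _write_biom_json(table: FeatureTable, path: Path) -> None:
    rows = []
    for taxon in table.taxa:
        md = None
        if table.lineage is not None and taxon in table.lineage.index:
            md = {"taxonomy": str(table.lineage[taxon]).split(";")}
        rows.append({"id": str(taxon), "metadata": md})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "qmpflow",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "float",
        "shape": [len(table.taxa), len(table.samples)],
        "rows": rows,
        "columns": [{"id": str(s), "metadata": None} for s in table.samples],
        "data": table.data.T.to_numpy().tolist(),
    }
    path.write_text(json.dumps(doc))


def _read_biom_json(path: Path) -> tuple[pd.DataFrame, pd.Series | None]:
    doc = json.loads(Path(path).read_text())
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    if doc["matrix_type"] == "dense":
        mat = np.asarray(doc["data"], dtype=float)
    else:  # sparse: list of [row, col, value]
        mat = np.zeros((len(taxa), len(samples)))
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    lineage_items = {
        r["id"]: ";".join(r["metadata"]["taxonomy"])
        for r in doc["rows"]
        if r.get("metadata") and "taxonomy" in r["metadata"]
    }
    lineage = pd.Series(lineage_items) if lineage_items else None
    df = pd.DataFrame(mat.T, index=samples, columns=taxa)
    return df, lineage
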