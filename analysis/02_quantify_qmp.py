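#!/usr/bin/env python
"""Calibrate the qPCR standard curves and build QMP/RMP tables.

Fits Ct-on-log10(copies) standard curves, back-calculates per-sample
loads (copies per gram of luminal content), and rescales each sample's
sequencing proportions by its load to obtain absolute abundances (QMP)
alongside the relative (RMP) tables.

Reads results/study/, writes results/quantify/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from qmpflow import quantify, read_feature_table, write_feature_table

IN, OUT = Path("results/study"), Path("results/quantify")


def main(slope: float = -3.3219, intercept: float = 38.0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    loads_tbl = pd.read_csv(IN / "qpcr_loads.tsv", sep="\t")
    logc = np.arange(3.0, 9.0)
    curve = quantify.fit_standard_curve(logc, intercept + slope * logc)
    print(f"standard curve: slope {curve.slope:.4f}, "
          f"efficiency {curve.efficiency:.1f}%, r^2 {curve.r_squared:.4f}")
    measured = pd.Series(
        quantify.ct_to_load(
            curve, loads_tbl.ct.to_numpy(), loads_tbl.dilution_factor.to_numpy(),
            loads_tbl.sample_weight.to_numpy(),
        ),
        index=loads_tbl.sample_id, name="load",
    )
    measured.to_csv(OUT / "measured_loads.tsv", sep="\t")
    for domain in ("bacteria", "fungi"):
        meta = pd.read_csv(IN / f"metadata_{domain}.tsv", sep="\t", index_col=0)
        table = read_feature_table(IN / f"counts_{domain}.tsv", meta=meta)
        qmp = quantify.qmp_transform(table, measured)
        rmp = quantify.rmp_transform(table)
        write_feature_table(qmp, OUT / f"qmp_{domain}.tsv")
        write_feature_table(rmp, OUT / f"rmp_{domain}.tsv")
        seg_mean = (
            np.log10(qmp.data.sum(axis=1)).groupby(qmp.meta.segment).mean().round(2)
        )
        print(f"{domain}: mean log10 load by segment -> {seg_mean.to_dict()}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--slope", type=float, default=-3.3219)
    ap.add_argument("--intercept", type=float, default=38.0)
    main(**vars(ap.parse_args()))
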