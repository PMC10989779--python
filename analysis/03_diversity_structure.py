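#!/usr/bin/env python
"""Diversity, succession, and the QMP-vs-RMP variance structure.

Computes per-sample Shannon diversity, adjacent-day Bray-Curtis
turnover per segment, a marginal PERMANOVA variance partition over
bird / segment / day, and the Procrustes (protest) agreement between
ordinations of absolute and relative profiles.

Reads results/quantify/, writes results/structure/.
"""

import argparse
from pathlib import Path

import pandas as pd

from qmpflow import read_feature_table, structure

IN_S, IN_Q, OUT = Path("results/study"), Path("results/quantify"), Path("results/structure")


def main(seed: int = 7, n_perm: int = 199) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    parts, adjacents, protests = [], [], []
    for domain in ("bacteria", "fungi"):
        meta = pd.read_csv(IN_S / f"metadata_{domain}.tsv", sep="\t", index_col=0)
        qmp = read_feature_table(IN_Q / f"qmp_{domain}.tsv", meta=meta, mode="QMP")
        rmp = read_feature_table(IN_Q / f"rmp_{domain}.tsv", meta=meta, mode="RMP")
        structure.shannon_per_sample(qmp).to_frame().join(qmp.meta).to_csv(
            OUT / f"shannon_{domain}.tsv", sep="\t"
        )
        dm = structure.bray_curtis_matrix(qmp)
        part = structure.variance_partition(
            dm, qmp.meta, ["bird", "segment", "dph"], n_perm=n_perm, seed=seed
        ).assign(domain=domain)
        parts.append(part)
        for seg in qmp.meta.segment.unique():
            adj = structure.adjacent_time_dissimilarity(qmp, seg)
            med = adj.groupby("interval", sort=False).bc.median().rename("median_bc")
            adjacents.append(med.to_frame().assign(domain=domain, segment=seg))
        coords_q, _ = structure.pcoa(dm)
        coords_r, _ = structure.pcoa(structure.bray_curtis_matrix(rmp))
        pro = structure.protest(
            coords_q.iloc[:, :2], coords_r.iloc[:, :2], n_perm=n_perm, seed=seed
        )
        protests.append({"domain": domain, "m12": pro.m12, "p": pro.p_value})
        print(f"{domain}: QMP-RMP protest m12 = {pro.m12:.3f} (p = {pro.p_value:.3f})")
    part_df = pd.concat(parts, ignore_index=True)
    part_df.to_csv(OUT / "variance_partition.tsv", sep="\t", index=False)
    pd.concat(adjacents).to_csv(OUT / "adjacent_time_bc.tsv", sep="\t")
    pd.DataFrame(protests).to_csv(OUT / "protest_qmp_rmp.tsv", sep="\t", index=False)
    print("variance partition (marginal R^2):")
    print(part_df.pivot(index="factor", columns="domain", values="r_squared").round(3))
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-perm", type=int, default=199, dest="n_perm")
    main(**vars(ap.parse_args()))
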