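#!/usr/bin/env python
"""Serum metabolome: filtering, discrimination, time association,
trajectory clusters.

Filters features (>30% prevalence, annotated), runs OPLS-DA across the
eight sampling days with VIP ranking, tests each metabolite's
association with day (categorical GLM, BH-FDR), and cuts the z-scored
mean trajectories of associated metabolites into six clusters.

Reads results/study/, writes results/metabolome/.
"""

import argparse
from pathlib import Path

import pandas as pd

from qmpflow import metabolome

IN, OUT = Path("results/study"), Path("results/metabolome")


def main(k: int = 6, fdr: float = 0.05, vip_cutoff: float = 1.5) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    data = pd.read_csv(IN / "metabolite_intensities.tsv", sep="\t", index_col=0)
    taxonomy = pd.read_csv(IN / "metabolite_taxonomy.tsv", sep="\t", index_col=0)
    dph = pd.Series(
        {s: int(s.split("_")[1].rstrip("d")) for s in data.index}, name="dph"
    )
    table, log = metabolome.filter_features(data, dph, taxonomy)
    print(f"feature filter: {log['n_input']} -> {log['n_kept']} "
          f"({log['n_low_prevalence']} low-prevalence, "
          f"{log['n_unannotated']} unannotated removed)")
    assoc = metabolome.glm_time_association(table, fdr=fdr)
    assoc.to_csv(OUT / "time_association.tsv", sep="\t")
    n_assoc = int(assoc.associated.sum())
    print(f"time-associated metabolites: {n_assoc} of {len(assoc)} (FDR < {fdr})")
    opls = metabolome.opls_da(table, table.dph.astype(str))
    opls.vip.to_frame().to_csv(OUT / "vip.tsv", sep="\t")
    opls.p1.to_frame().join(table.dph).to_csv(OUT / "p1_scores.tsv", sep="\t")
    print(f"OPLS-DA: {int((opls.vip > vip_cutoff).sum())} metabolites with "
          f"VIP > {vip_cutoff}")
    clusters = metabolome.cluster_trajectories(
        table, metabolites=assoc.index[assoc.associated], k=k
    )
    clusters.labels.to_frame().to_csv(OUT / "clusters.tsv", sep="\t")
    clusters.mean_trajectories.to_csv(OUT / "cluster_mean_trajectories.tsv", sep="\t")
    comp = metabolome.cluster_composition(clusters, taxonomy)
    comp.to_csv(OUT / "cluster_composition.tsv", sep="\t")
    sizes = clusters.labels.value_counts().sort_index()
    print(f"trajectory clusters (k={k}): sizes {sizes.to_dict()}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--k", type=int, default=6)
    ap.add_argument("--fdr", type=float, default=0.05)
    ap.add_argument("--vip-cutoff", type=float, default=1.5, dest="vip_cutoff")
    main(**vars(ap.parse_args()))
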