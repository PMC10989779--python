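#!/usr/bin/env python
"""Microbe-metabolite co-occurrence: conditional probabilities and the
top-1% interaction network.

Fits the low-rank softmax co-occurrence model per segment x domain on
paired microbiome-metabolome samples, takes the top 1% of (microbe,
metabolite) pairs by conditional probability, and summarises retention
per metabolite cluster plus the merged bipartite network's key taxa.

Reads results/quantify/ and results/metabolome/, writes results/integrate/.
"""

import argparse
from pathlib import Path

import pandas as pd

from qmpflow import integrate, read_feature_table
from qmpflow.tables import SEGMENT_ORDER

IN_S = Path("results/study")
IN_Q = Path("results/quantify")
IN_M = Path("results/metabolome")
OUT = Path("results/integrate")


def main(seed: int = 7, fraction: float = 0.01, epochs: int = 300) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mets = pd.read_csv(IN_S / "metabolite_intensities.tsv", sep="\t", index_col=0)
    clusters = pd.read_csv(IN_M / "clusters.tsv", sep="\t", index_col=0)["cluster"]
    taxonomy = pd.read_csv(IN_S / "metabolite_taxonomy.tsv", sep="\t", index_col=0)
    mets = mets[clusters.index]
    parts, label_rows = {}, []
    for domain in ("bacteria", "fungi"):
        meta = pd.read_csv(IN_S / f"metadata_{domain}.tsv", sep="\t", index_col=0)
        qmp = read_feature_table(IN_Q / f"qmp_{domain}.tsv", meta=meta, mode="QMP")
        for seg in SEGMENT_ORDER:
            sub = qmp.subset(qmp.meta.segment == seg)
            microbes = sub.data.copy()
            microbes.index = [
                f"{b}_{d:02d}d_serum" for b, d in zip(sub.meta.bird, sub.meta.dph)
            ]
            microbes = microbes.loc[
                microbes.index.intersection(mets.index),
                microbes.sum(axis=0) > 0,
            ]
            fit = integrate.mmvec_fit(
                microbes, mets.loc[microbes.index], epochs=epochs, seed=seed
            )
            parts[(seg, domain)] = integrate.select_top(fit, fraction)
            label_rows += [
                {"microbe": t, "segment": seg, "domain": domain}
                for t in microbes.columns
            ]
    merged = integrate.merge_selections(parts)
    merged.to_csv(OUT / "top_interactions.tsv", sep="\t", index=False)
    labels = pd.DataFrame(label_rows).drop_duplicates().set_index("microbe")
    ratio = integrate.ratio_table(merged, labels, clusters)
    ratio.to_csv(OUT / "retention_by_cluster.tsv", sep="\t", index=False)
    _, degree, categories = integrate.interaction_network(merged, taxonomy)
    degree.to_csv(OUT / "key_taxa.tsv", sep="\t", index=False)
    categories.to_csv(OUT / "metabolite_categories.tsv", sep="\t", index=False)
    best = ratio.sort_values("pct_retained", ascending=False).head(3)
    print("strongest segment x cluster retention (top 1% rule):")
    print(best[["segment", "domain", "cluster", "pct_retained"]]
          .round(2).to_string(index=False))
    print(f"top key taxa: {degree.head(5).microbe.tolist()}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--fraction", type=float, default=0.01)
    ap.add_argument("--epochs", type=int, default=300)
    main(**vars(ap.parse_args()))
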