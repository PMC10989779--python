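#!/usr/bin/env python
"""Deterministic vs stochastic assembly: βNTI / RC_Bray classification.

Within each segment and domain, computes βMNTD for sample pairs, its
z-score (βNTI) against a tip-shuffling null, RC_Bray for pairs inside
the |βNTI| < 2 band, classifies each pair into the five ecological
processes, and summarises the deterministic/stochastic split.

Reads results/study/, writes results/assembly/.
"""

import argparse
from pathlib import Path

import dendropy
import pandas as pd

from qmpflow import assembly, read_feature_table

IN, OUT = Path("results/study"), Path("results/assembly")


def main(seed: int = 7, n_null: int = 99, max_pairs: int = 60) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frames = []
    for domain in ("bacteria", "fungi"):
        meta = pd.read_csv(IN / f"metadata_{domain}.tsv", sep="\t", index_col=0)
        table = read_feature_table(IN / f"counts_{domain}.tsv", meta=meta)
        tree = dendropy.Tree.get(path=str(IN / f"tree_{domain}.nwk"), schema="newick")
        d = assembly.tip_distance_matrix(tree, list(table.taxa))
        for seg in table.meta.segment.unique():
            sub = table.subset(table.meta.segment == seg)
            res = assembly.pairwise_assembly(
                sub.data, d, n_null=n_null, seed=seed, max_pairs=max_pairs
            ).assign(domain=domain, segment=seg)
            frames.append(res)
    allres = pd.concat(frames, ignore_index=True)
    allres.to_csv(OUT / "pairs.tsv", sep="\t", index=False)
    summary = assembly.summarize_processes(allres, ["domain", "segment"])
    summary.to_csv(OUT / "summary.tsv", sep="\t", index=False)
    print("stochastic fraction by domain x segment:")
    print(
        summary.pivot(index="segment", columns="domain", values="stochastic").round(3)
    )
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-null", type=int, default=99, dest="n_null")
    ap.add_argument("--max-pairs", type=int, default=60, dest="max_pairs")
    main(**vars(ap.parse_args()))
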