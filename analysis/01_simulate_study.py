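#!/usr/bin/env python
"""Generate the synthetic longitudinal gut-microbiome + metabolome study.

Emulated design: 10 birds x 4 gut segments (duodenum, jejunum, ileum,
cecum) x 8 sampling days (1-42 posthatch), bacterial and fungal counts
with qPCR load measurements, a taxon phylogeny per domain, ~1000 serum
metabolites in six trajectory shapes, and planted ground truth for every
downstream stage.

Writes feature tables, metadata, loads, trees and truth sidecars under
results/study/.
"""

import argparse
from pathlib import Path

from qmpflow import synthio, write_feature_table

OUT = Path("results/study")


def main(seed: int = 7) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthio.SimConfig(seed=seed)
    study = synthio.simulate_study(cfg)
    for domain, table in study.tables.items():
        write_feature_table(table, OUT / f"counts_{domain}.tsv")
        table.lineage.rename("lineage").to_csv(OUT / f"lineage_{domain}.tsv", sep="\t")
        (OUT / f"tree_{domain}.nwk").write_text(
            study.trees[domain].as_string(schema="newick")
        )
        table.meta.to_csv(OUT / f"metadata_{domain}.tsv", sep="\t")
    study.loads.to_csv(OUT / "qpcr_loads.tsv", sep="\t", index=False)
    study.metabolites.to_csv(OUT / "metabolite_intensities.tsv", sep="\t")
    study.metabolite_taxonomy.to_csv(OUT / "metabolite_taxonomy.tsv", sep="\t")
    # ground-truth sidecars
    study.truth.loads.to_csv(OUT / "truth_loads.tsv", sep="\t", index=False)
    study.truth.occurrence.to_csv(OUT / "truth_occurrence.tsv", sep="\t", index=False)
    study.truth.source_proportions.to_csv(
        OUT / "truth_transmission.tsv", sep="\t", index=False
    )
    study.truth.metabolite_cluster.rename("template").to_csv(
        OUT / "truth_metabolite_templates.tsv", sep="\t"
    )
    n_b = study.tables["bacteria"].data.shape
    n_f = study.tables["fungi"].data.shape
    print(f"bacterial table: {n_b[0]} samples x {n_b[1]} taxa")
    print(f"fungal table:    {n_f[0]} samples x {n_f[1]} taxa")
    print(f"metabolites:     {study.metabolites.shape[1]} features, "
          f"{study.metabolites.shape[0]} serum samples")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    main(**vars(ap.parse_args()))
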