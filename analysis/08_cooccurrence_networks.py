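#!/usr/bin/env python
"""Per-segment co-occurrence networks and the QMP-vs-RMP comparison.

Pools bacteria and fungi per segment, applies the 30% prevalence
filter, tests all genus pairs by partial Spearman correlation
(conditioning on day posthatch), retains edges at BH-adjusted p <= 0.05,
and reports topology, keystone taxa, generalist/specialist edges,
negative:positive sign ratios, and the 3x3 QMP-vs-RMP correlation
consistency cross-tab.

Reads results/quantify/, writes results/conetwork/.
"""

import argparse
from pathlib import Path

import pandas as pd

from qmpflow import conetwork, read_feature_table
from qmpflow.tables import SEGMENT_ORDER, FeatureTable

IN_S, IN_Q, OUT = Path("results/study"), Path("results/quantify"), Path("results/conetwork")


def _pooled(mode: str, segment: str) -> FeatureTable:
    parts, meta = [], None
    for domain in ("bacteria", "fungi"):
        m = pd.read_csv(IN_S / f"metadata_{domain}.tsv", sep="\t", index_col=0)
        t = read_feature_table(IN_Q / f"{mode}_{domain}.tsv", meta=m, mode=mode.upper())
        sub = t.subset(t.meta.segment == segment)
        d = sub.data.copy()
        d.index = [f"{b}_{p}" for b, p in zip(sub.meta.bird, sub.meta.dph)]
        parts.append(d)
        if meta is None:
            meta = sub.meta.copy()
            meta.index = d.index
    joint = pd.concat(parts, axis=1)
    return FeatureTable(joint, meta.loc[joint.index], None, mode.upper())


def main(alpha: float = 0.05, min_prevalence: float = 0.30) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    nets, topo_rows, cons_rows = [], [], []
    for seg in SEGMENT_ORDER:
        fq = conetwork.prevalence_filter(_pooled("qmp", seg), min_prevalence)
        fr = conetwork.prevalence_filter(_pooled("rmp", seg), min_prevalence)
        net_q = conetwork.build_network(fq, alpha=alpha, segment=seg)
        net_r = conetwork.build_network(fr, alpha=alpha, segment=seg)
        nets.append(net_q)
        net_q.edges.assign(segment=seg).to_csv(
            OUT / f"edges_{seg}.tsv", sep="\t", index=False
        )
        conetwork.keystone(net_q).assign(segment=seg).to_csv(
            OUT / f"keystone_{seg}.tsv", sep="\t", index=False
        )
        conetwork.sign_ratio(net_q).assign(segment=seg).to_csv(
            OUT / f"sign_ratio_{seg}.tsv", sep="\t", index=False
        )
        topo = conetwork.topology(net_q)
        topo_rows.append({"segment": seg, **vars(topo)})
        cons = conetwork.qmp_rmp_consistency(net_q, net_r)
        cons.counts.to_csv(OUT / f"consistency_crosstab_{seg}.tsv", sep="\t")
        cons_rows.append({"segment": seg, "consistency_pct": cons.consistency_pct})
    topo_df = pd.DataFrame(topo_rows)
    topo_df.to_csv(OUT / "topology.tsv", sep="\t", index=False)
    _, sharing = conetwork.edge_sharing(nets)
    sharing.to_csv(OUT / "edge_sharing.tsv", sep="\t", index=False)
    cons_df = pd.DataFrame(cons_rows)
    cons_df.to_csv(OUT / "consistency.tsv", sep="\t", index=False)
    print("network topology (QMP):")
    print(topo_df.set_index("segment").round(3))
    print("QMP-vs-RMP correlation consistency (%):")
    print(cons_df.set_index("segment").round(1))
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--min-prevalence", type=float, default=0.30,
                    dest="min_prevalence")
    main(**vars(ap.parse_args()))
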