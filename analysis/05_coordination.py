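#!/usr/bin/env python
"""Expression-coordination networks and coordination switches.

For the estradiol-replaced conditions (CEN without insult, CES with),
computes pairwise Pearson coordination among the estrogen-signaling,
common-gene and neurotransmission genes, reports the cross-layer
synergism/antagonism/independence percentages, detects coordination
switches between the two conditions, and writes the ESG-CG-GLU network
edge list.
"""

import argparse
from pathlib import Path

from protectomics import io as pio
from protectomics.coordination import (
    build_network,
    condition_edges,
    cross_set_percentages,
    detect_switches,
    switch_census,
)
from protectomics.normalize import normalize_experiment
from protectomics.regulation import regulate

ap = argparse.ArgumentParser()
ap.add_argument("--data", type=Path, default=Path("results/data"))
ap.add_argument("--out", type=Path, default=Path("results/coordination"))
args = ap.parse_args()

spots = pio.read_spot_table(args.data / "spots.tsv")
design = pio.read_design_table(args.data / "design.tsv")
em, _, _ = normalize_experiment(spots, design)

panel = {gs.name: gs for gs in pio.read_gmt(pio.default_pathway_panel())}
cg = pio.read_gmt(pio.default_common_genes())[0]
nt_union = sorted({g for p in ("GLU", "GABA", "ACH", "DA", "5HT")
                   for g in panel[p].members})
universe = sorted(set(panel["ESG"].members) | set(nt_union))
universe = [g for g in universe
            if g in em.genes and em.mask["CEN"].loc[g].all()
            and em.mask["CES"].loc[g].all()]

args.out.mkdir(parents=True, exist_ok=True)
edges = {}
for cond in ("CEN", "CES"):
    e = condition_edges(em, cond, genes_a=universe)
    edges[cond] = e
    pio.write_table(e, args.out / f"coordination_{cond}.tsv")
    esg = [g for g in panel["ESG"].members if g in universe]
    nt = [g for g in nt_union if g in universe]
    s, a, i = cross_set_percentages(esg, nt, e)
    print(f"{cond}: {len(e)} pairs; ESG x neurotransmission coordination "
          f"S {s:.1f}% / A {a:.1f}% / I {i:.1f}%")

sw = detect_switches(edges["CEN"], edges["CES"])
pio.write_table(sw, args.out / "switches_CEN_to_CES.tsv")
n_sa = (sw["switch_type"] == "S->A").sum()
n_as = (sw["switch_type"] == "A->S").sum()
print(f"switches CEN -> CES: {n_sa} synergistic-to-antagonistic, "
      f"{n_as} antagonistic-to-synergistic, {len(sw)} total class changes")
census = switch_census(sw[sw["switch_type"].isin(["S->A", "A->S"])])
if not census.empty:
    top = census.sort_values("S->A", ascending=False).head(3)
    pio.write_table(top.reset_index(), args.out / "switch_census_top.tsv")
    print("busiest switch hubs:",
          ", ".join(f"{g} ({r['S->A']} S->A / {r['A->S']} A->S)"
                    for g, r in top.iterrows()))

reg = regulate(em, "CES:CEN")
net = build_network(panel["ESG"], panel["GLU"], cg.members, edges["CES"],
                    regulation=reg)
rows = [{"gene_a": a, "gene_b": b, **d} for a, b, d in net.edges(data=True)]
import pandas as pd
pio.write_table(pd.DataFrame(rows), args.out / "network_ESG_CG_GLU_CES.tsv")
print(f"ESG-CG-GLU network (CES): {net.number_of_nodes()} nodes, "
      f"{net.number_of_edges()} informative edges")
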