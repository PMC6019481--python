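#!/usr/bin/env python
"""Score the 12-pathway panel: percent regulated, WPR, TPR and PPR.

Reads the regulation tables of both comparisons, scores every pathway of
the packaged panel, and reports the protection quantifiers for the
(COS vs CON, CES vs CEN) pair: TPR is the percent reduction of the
regulated-gene fraction, PPR the percent reduction of the weighted
pathway regulation score.
"""

import argparse
from pathlib import Path

import pandas as pd

from protectomics import io as pio
from protectomics.pathway import score_pathways

ap = argparse.ArgumentParser()
ap.add_argument("--regulation", type=Path, default=Path("results/regulation"))
ap.add_argument("--out", type=Path, default=Path("results/pathways"))
args = ap.parse_args()

regulation = {}
for fn in sorted(args.regulation.glob("regulation_*.tsv")):
    cmp_name = fn.stem.removeprefix("regulation_").replace("_vs_", ":")
    regulation[cmp_name] = pd.read_csv(fn, sep="\t", index_col="gene")

gene_sets = pio.read_gmt(pio.default_pathway_panel())
scores = score_pathways(gene_sets, regulation,
                        protection_pair=("COS:CON", "CES:CEN"))

args.out.mkdir(parents=True, exist_ok=True)
pio.write_table(scores, args.out / "pathway_scores.tsv")

unprot = scores.query("comparison == 'COS:CON'").set_index("pathway")
print(f"scored {scores['pathway'].nunique()} pathways; "
      f"COS:CON mean regulated fraction "
      f"{unprot['pct_regulated'].mean():.1f}%, mean WPR "
      f"{unprot['WPR'].mean():.3f}")
prot = unprot.dropna(subset=["PPR"]).sort_values("PPR", ascending=False)
print("protection by pathway (TPR / PPR, %):")
for name, row in prot.iterrows():
    print(f"  {name:>5s}: TPR {row['TPR']:6.1f}  PPR {row['PPR']:6.1f}")
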