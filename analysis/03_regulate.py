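#!/usr/bin/env python
"""Call per-gene regulation with the flexible fold-change cut-off.

Re-runs the (deterministic, fast) normalization from the spot tables so
the spot-group-level values needed by the redundant-spot-corrected t-test
are in memory, then calls regulation for COS vs CON (insult without
protection) and CES vs CEN (insult under estradiol replacement), and
compares the calls against the planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from protectomics import io as pio
from protectomics.normalize import normalize_experiment
from protectomics.regulation import regulate

ap = argparse.ArgumentParser()
ap.add_argument("--data", type=Path, default=Path("results/data"))
ap.add_argument("--out", type=Path, default=Path("results/regulation"))
ap.add_argument("--alpha", type=float, default=0.05)
args = ap.parse_args()

spots = pio.read_spot_table(args.data / "spots.tsv")
design = pio.read_design_table(args.data / "design.tsv")
em, _, _ = normalize_experiment(spots, design)
truth = pd.read_csv(args.data / "truth_regulation.tsv", sep="\t")

args.out.mkdir(parents=True, exist_ok=True)
for cmp_name in ("COS:CON", "CES:CEN"):
    reg = regulate(em, cmp_name, alpha=args.alpha)
    fn = args.out / f"regulation_{cmp_name.replace(':', '_vs_')}.tsv"
    pio.write_table(reg.reset_index(), fn)

    q = reg["x"].notna()
    n_up = (reg["call"] == "up").sum()
    n_down = (reg["call"] == "down").sum()
    t = truth.query("comparison == @cmp_name").set_index("gene")
    planted = t.index[t["regulated"]]
    hits = (reg.loc[reg.index.intersection(planted), "call"] != "none").mean()
    onoff = reg["onoff"].value_counts()
    print(f"{cmp_name}: {q.sum()} genes quantified, {n_up} up / {n_down} down "
          f"({100 * (n_up + n_down) / q.sum():.1f}% regulated); "
          f"planted-gene recall {100 * hits:.1f}%; "
          f"{onoff.get('turned_on', 0)} ON / {onoff.get('turned_off', 0)} OFF")
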