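"""End-to-end runner: simulate -> normalize -> regulate -> pathway scores
-> coordination -> switches, with a machine-readable run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from protectomics import io as pio
from protectomics.coordination import condition_edges, detect_switches
from protectomics.normalize import normalize_experiment
from protectomics.pathway import score_pathways
from protectomics.regulation import regulate
from protectomics.synthetic import default_config, generate_experiment

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage parameters for one end-to-end run; defaults match each
    stage's documented defaults."""

    seed: int = 0
    n_genes: int = 500
    tol: float = 0.05
    max_iter: int = 100
    alpha: float = 0.05
    r_ind: float = 0.25
    cut_estimator: str = "plain"          # or "chi2"
    wpr_aggregation: str = "mean"         # or "sum"
    tpr_side_effect: bool = False
    test_scale: str = "log"               # or "raw"
    comparisons: tuple[str, str] = ("COS:CON", "CES:CEN")
    protection_pair: tuple[str, str] = ("COS:CON", "CES:CEN")
    coordination_conditions: tuple[str, ...] = ("CEN", "CES")
    coordination_genes: int = 200         # cap for the desk-scale pair run
    gmt: str | None = None                # None -> packaged synthetic panel
    spots: str | None = None              # None -> simulate
    design: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("comparisons", "protection_pair", "coordination_conditions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage, writing each stage's TSVs plus ``manifest.json``
    into ``out_dir``.  Deterministic for a fixed seed and config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="%(name)s: %(message)s")

    # --- stage: simulate (or load) --------------------------------------
    if config.spots is not None:
        spots = pio.read_spot_table(config.spots)
        design = pio.read_design_table(config.design)
        sim_cfg = None
    else:
        sim_cfg = default_config(seed=config.seed, n_genes=config.n_genes)
        spots, design, truth = generate_experiment(sim_cfg)
        pio.write_spot_table(spots, out / "spots.tsv")
        pio.write_design_table(design, out / "design.tsv")
        pio.write_table(truth.regulation, out / "truth_regulation.tsv")
        pio.write_table(truth.coordination, out / "truth_coordination.tsv")
        pio.write_table(truth.expression.reset_index(), out / "truth_expression.tsv")

    # --- stage: normalize -----------------------------------------------
    em, n_iter, delta = normalize_experiment(
        spots, design, tol=config.tol, max_iter=config.max_iter)
    log.info("normalize: converged in %d iterations (delta=%.4f)", n_iter, delta)
    pio.write_matrix(em, out / "expression_matrix.tsv")
    pio.write_condition_stats(em, out / "condition_stats.tsv")

    # --- stage: regulate --------------------------------------------------
    regulation = {}
    for cmp_name in config.comparisons:
        reg = regulate(em, cmp_name, alpha=config.alpha,
                       cut_estimator=config.cut_estimator,
                       test_scale=config.test_scale)
        regulation[cmp_name] = reg
        fn = out / f"regulation_{cmp_name.replace(':', '_vs_')}.tsv"
        pio.write_table(reg.reset_index(), fn)

    # --- stage: pathway scores -------------------------------------------
    gmt_path = Path(config.gmt) if config.gmt else pio.default_pathway_panel()
    gene_sets = pio.read_gmt(gmt_path)
    scores = score_pathways(
        gene_sets, regulation, protection_pair=config.protection_pair,
        aggregation=config.wpr_aggregation,
        side_effect_mode=config.tpr_side_effect,
    )
    pio.write_table(scores, out / "pathway_scores.tsv")

    # --- stage: coordination + switches ----------------------------------
    # one pair universe across conditions: genes valid in every replicate
    # of every coordination condition
    full = pd.Series(True, index=em.genes)
    for cond in config.coordination_conditions:
        full &= em.mask[cond].all(axis=1)
    genes = list(em.genes[full][: config.coordination_genes])
    edge_tables = {}
    for cond in config.coordination_conditions:
        edges = condition_edges(em, cond, genes_a=genes, alpha=config.alpha,
                                r_ind=config.r_ind,
                                use_log=config.test_scale == "log")
        edge_tables[cond] = edges
        pio.write_table(edges, out / f"coordination_{cond}.tsv")
    if len(config.coordination_conditions) >= 2:
        c1, c2 = config.coordination_conditions[:2]
        switches = detect_switches(edge_tables[c1], edge_tables[c2])
        pio.write_table(switches, out / f"switches_{c1}_to_{c2}.tsv")

    # --- manifest ----------------------------------------------------------
    import protectomics
    manifest = {
        "package": "protectomics",
        "version": protectomics.__version__,
        "python": sys.version.split()[0],
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "simulation": None if sim_cfg is None else {
            "n_genes": sim_cfg.n_genes, "seed": sim_cfg.seed,
            "n_planted": len(sim_cfg.planted_regulation),
        },
        "normalize": {"iterations": n_iter, "final_delta": delta},
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
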