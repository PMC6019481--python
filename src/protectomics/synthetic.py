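"""Spot-level two-channel microarray simulator with planted ground truth.

The generator emulates an Agilent 4x44k-style experiment run in the
"multiple yellow" design: two differently labelled biological replicates of
the *same* condition are co-hybridized on each array, four conditions
(CON, CEN, COS, CES) with four biological replicates each, redundant spots
probing the same gene, a constant-mean lognormal background, per-channel
label bias, and a configurable fraction of invalid spots (foreground below
twice the background).

Expression is lognormal: each gene has a base log-level, a per-gene
biological coefficient of variation among replicates, and spot-level
multiplicative technical noise.  Regulation is planted multiplicatively on
the condition means of COS (vs CON) and CES (vs CEN).  Inter-gene
correlation is planted through shared latent factors across replicates
(one factor per block per sample), which is what the downstream
coordination analysis is designed to detect.

Everything is drawn from a single seeded generator stream, so the same
seed and config reproduce the output tables byte-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("CON", "CEN", "COS", "CES")
CHANNELS = ("Cy3", "Cy5")
#: comparison -> condition whose mean carries the planted fold change
_COMPARISON_TARGET = {"COS:CON": "COS", "CES:CEN": "CES"}


@dataclass(frozen=True)
class CorrelationBlock:
    """A group of genes sharing one latent factor per sample.

    ``loadings`` are signed correlation-scale loadings in [-1, 1]: the
    planted Pearson correlation between genes *i* and *j* of the block is
    ``loadings[i] * loadings[j]``.  ``condition_flips`` negates the
    loading sign of the listed genes in the listed conditions, which is
    how synergistic-to-antagonistic coordination switches are planted.
    """

    genes: tuple[str, ...]
    loadings: tuple[float, ...]
    condition_flips: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.loadings):
            raise ValueError("loadings: must match the number of block genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("genes: duplicate gene in correlation block")
        arr = np.asarray(self.loadings, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("loadings: must be finite")
        if np.any(np.abs(arr) > 1.0):
            raise ValueError("loadings: |loading| must be <= 1")

    def loading_for(self, gene: str, condition: str) -> float:
        l = self.loadings[self.genes.index(gene)]
        if gene in self.condition_flips.get(condition, frozenset()):
            l = -l
        return l


def correlated_block(
    genes: Sequence[str],
    rho: float,
    signs: Sequence[int] | None = None,
    condition_flips: Mapping[str, frozenset[str]] | None = None,
) -> CorrelationBlock:
    """Convenience constructor: every pair gets planted |r| = ``rho``.

    Loadings are ``sign_i * sqrt(rho)`` so that the pairwise planted
    correlation is ``sign_i * sign_j * rho``.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho: must be in [0, 1]")
    if signs is None:
        signs = [1] * len(genes)
    load = tuple(s * float(np.sqrt(rho)) for s in signs)
    return CorrelationBlock(tuple(genes), load, condition_flips or {})


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated experiment.

    Counts and fractions are validated on construction; any violation is
    rejected with a message naming the offending field.
    """

    n_genes: int = 500
    conditions: tuple[str, ...] = CONDITIONS
    n_replicates_per_condition: int = 4
    spots_per_gene: int | tuple[int, int] = (1, 4)
    control_spot_fraction: float = 0.03
    background_mean: float = 30.0
    background_cv: float = 0.25
    expression_log_mean_range: tuple[float, float] = (4.5, 8.0)
    biological_cv_range: tuple[float, float] = (0.10, 0.50)
    technical_cv: float = 0.10
    planted_regulation: tuple[tuple[str, str, float], ...] = ()
    planted_correlation_blocks: tuple[CorrelationBlock, ...] = ()
    label_bias_factors: tuple[float, float] = (1.0, 1.35)
    invalid_spot_fraction: float = 0.05
    gene_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes: must be >= 1")
        if len(self.conditions) < 1:
            raise ValueError("conditions: must name at least one condition")
        if self.n_replicates_per_condition < 1:
            raise ValueError("n_replicates_per_condition: must be >= 1")
        if self.n_replicates_per_condition % 2 != 0:
            raise ValueError(
                "n_replicates_per_condition: must be even (two replicates "
                "are co-hybridized per array)"
            )
        spg = self.spots_per_gene
        if isinstance(spg, int):
            if spg < 1:
                raise ValueError("spots_per_gene: must be >= 1")
        else:
            lo, hi = spg
            if lo < 1 or hi < lo:
                raise ValueError("spots_per_gene: range must satisfy 1 <= lo <= hi")
        for name in ("control_spot_fraction", "invalid_spot_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name}: must be in [0, 1)")
        for name in ("background_mean", "technical_cv", "background_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        lo, hi = self.biological_cv_range
        if lo < 0 or hi < lo:
            raise ValueError("biological_cv_range: must satisfy 0 <= lo <= hi")
        if any(b <= 0 for b in self.label_bias_factors):
            raise ValueError("label_bias_factors: must be > 0")
        for gene, comparison, fc in self.planted_regulation:
            if comparison not in _COMPARISON_TARGET:
                raise ValueError(
                    f"planted_regulation: unknown comparison {comparison!r}"
                )
            if abs(fc) < 1.0:
                raise ValueError(
                    f"planted_regulation: |fold change| must be >= 1 (gene {gene})"
                )
        seen: set[tuple[str, str]] = set()
        for gene, comparison, _ in self.planted_regulation:
            if (gene, comparison) in seen:
                raise ValueError(
                    f"planted_regulation: gene {gene} planted twice in {comparison}"
                )
            seen.add((gene, comparison))

    @property
    def gene_list(self) -> list[str]:
        if self.gene_names is not None:
            if len(self.gene_names) != self.n_genes:
                raise ValueError("gene_names: length must equal n_genes")
            return list(self.gene_names)
        width = max(4, len(str(self.n_genes)))
        return [f"Gene{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def comparisons(self) -> tuple[str, ...]:
        return tuple(c for c in _COMPARISON_TARGET if
                     set(c.split(":")) <= set(self.conditions))


@dataclass
class TruthTables:
    """Planted ground truth emitted alongside the simulated spot table."""

    regulation: pd.DataFrame      # gene, comparison, fold_change, regulated
    coordination: pd.DataFrame    # gene_a, gene_b, condition, r_planted
    expression: pd.DataFrame      # gene x condition true mean level


def plant_coordination(
    factor: np.ndarray,
    loadings: Sequence[float],
    residual_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Realize latent-factor coordination for one block of genes.

    Returns an array of shape ``(n_genes, n_replicates)`` where gene *i*
    is ``loadings[i] * factor + sqrt(residual_var) * eps``.  The expected
    Pearson correlation between genes with loadings *a*, *b* is
    ``a*b / sqrt((a^2 + s2) * (b^2 + s2))`` with ``s2 = residual_var``
    (see :func:`expected_correlation`).
    """
    factor = np.asarray(factor, dtype=float)
    if factor.ndim != 1 or factor.size < 3:
        raise ValueError("factor: need at least 3 replicates")
    load = np.asarray(loadings, dtype=float)
    if not np.all(np.isfinite(load)):
        raise ValueError("loadings: must be finite")
    if residual_var < 0:
        raise ValueError("residual_var: must be >= 0")
    eps = rng.standard_normal((load.size, factor.size))
    return load[:, None] * factor[None, :] + np.sqrt(residual_var) * eps


def expected_correlation(a: float, b: float, residual_var: float) -> float:
    """Closed-form Pearson correlation planted by :func:`plant_coordination`."""
    return a * b / np.sqrt((a * a + residual_var) * (b * b + residual_var))


def _log_sd_from_cv(cv: np.ndarray | float) -> np.ndarray | float:
    # lognormal: CV^2 = exp(sigma^2) - 1
    return np.sqrt(np.log1p(np.square(cv)))


def generate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTables]:
    """Simulate one experiment.

    Returns ``(spot_table, design_table, truth)``.  The spot table has one
    row per spot and channel with columns ``array_id, channel, spot, gene,
    control_flag, fg, bg``; the design table maps each (array, channel) to
    its (condition, replicate) sample.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_list
    n_g = config.n_genes
    conds = config.conditions
    n_rep = config.n_replicates_per_condition

    gene_idx = {g: i for i, g in enumerate(genes)}
    for gene, comparison, _ in config.planted_regulation:
        if gene not in gene_idx:
            raise ValueError(f"planted_regulation: unknown gene {gene}")
    for block in config.planted_correlation_blocks:
        for g in block.genes:
            if g not in gene_idx:
                raise ValueError(f"planted_correlation_blocks: unknown gene {g}")

    # --- true condition means (log scale) -------------------------------
    lo, hi = config.expression_log_mean_range
    base_log = rng.uniform(lo, hi, size=n_g)
    cv_lo, cv_hi = config.biological_cv_range
    bio_cv = rng.uniform(cv_lo, cv_hi, size=n_g)
    log_sd = np.asarray(_log_sd_from_cv(bio_cv))

    log_mu = np.tile(base_log[:, None], (1, len(conds)))  # gene x condition
    cond_idx = {c: j for j, c in enumerate(conds)}
    for gene, comparison, fc in config.planted_regulation:
        target = _COMPARISON_TARGET[comparison]
        if target not in cond_idx:
            continue
        shift = np.log(abs(fc)) * (1.0 if fc > 0 else -1.0)
        log_mu[gene_idx[gene], cond_idx[target]] += shift

    # --- replicate-level deviations (biological variability) ------------
    # independent draws first; block genes are overwritten with
    # latent-factor realizations scaled to the gene's own log-sd.
    dev = rng.standard_normal((n_g, len(conds), n_rep)) * log_sd[:, None, None]
    in_block = np.zeros(n_g, dtype=bool)
    coord_rows: list[tuple[str, str, str, float]] = []
    for block in config.planted_correlation_blocks:
        bidx = [gene_idx[g] for g in block.genes]
        if np.any(in_block[bidx]):
            raise ValueError("planted_correlation_blocks: gene in two blocks")
        in_block[bidx] = True
        for c in conds:
            load = np.array([block.loading_for(g, c) for g in block.genes])
            f = rng.standard_normal(n_rep)
            eps = rng.standard_normal((len(bidx), n_rep))
            resid_sd = np.sqrt(np.clip(1.0 - load**2, 0.0, None))
            std_dev = load[:, None] * f[None, :] + resid_sd[:, None] * eps
            dev[bidx, cond_idx[c], :] = std_dev * log_sd[bidx, None]
        for i, ga in enumerate(block.genes):
            for j in range(i + 1, len(block.genes)):
                gb = block.genes[j]
                for c in conds:
                    r = block.loading_for(ga, c) * block.loading_for(gb, c)
                    coord_rows.append((ga, gb, c, r))

    levels = np.exp(log_mu[:, :, None] + dev)  # gene x condition x replicate

    # --- array layout ----------------------------------------------------
    n_pairs = n_rep // 2
    design_rows = []
    sample_of: dict[tuple[str, str], tuple[str, int]] = {}
    a = 0
    for c in conds:
        for j in range(n_pairs):
            a += 1
            array_id = f"A{a:02d}"
            for ch, rep in zip(CHANNELS, (2 * j + 1, 2 * j + 2)):
                design_rows.append((array_id, ch, c, rep))
                sample_of[(array_id, ch)] = (c, rep)
    design = pd.DataFrame(
        design_rows, columns=["array_id", "channel", "condition", "replicate"]
    )

    # --- spots -----------------------------------------------------------
    spg = config.spots_per_gene
    if isinstance(spg, int):
        n_spots = np.full(n_g, spg, dtype=int)
    else:
        n_spots = rng.integers(spg[0], spg[1] + 1, size=n_g)
    tech_sd = float(_log_sd_from_cv(config.technical_cv))
    bg_sd = float(_log_sd_from_cv(config.background_cv))
    bias = dict(zip(CHANNELS, config.label_bias_factors))

    rows: list[pd.DataFrame] = []
    n_gene_spots = int(n_spots.sum())
    gene_col = np.repeat(genes, n_spots)
    gidx_col = np.repeat(np.arange(n_g), n_spots)
    spot_col = np.concatenate([np.arange(1, k + 1) for k in n_spots])
    spot_ids = np.array(
        [f"{g}_s{s}" for g, s in zip(gene_col, spot_col)], dtype=object
    )
    n_ctrl = int(round(config.control_spot_fraction * n_gene_spots))

    for array_id, ch in sorted(sample_of):
        c, rep = sample_of[(array_id, ch)]
        true = levels[gidx_col, cond_idx[c], rep - 1]
        tech = np.exp(rng.normal(0.0, tech_sd, size=n_gene_spots)) if tech_sd > 0 \
            else np.ones(n_gene_spots)
        if config.background_mean > 0:
            bg = config.background_mean * np.exp(
                rng.normal(-0.5 * bg_sd**2, bg_sd, size=n_gene_spots)
            )
        else:
            bg = np.zeros(n_gene_spots)
        fg = true * bias[ch] * tech + bg
        n_bad = int(round(config.invalid_spot_fraction * n_gene_spots))
        if n_bad > 0:
            bad = rng.choice(n_gene_spots, size=n_bad, replace=False)
            fg = fg.copy()
            fg[bad] = bg[bad] * rng.uniform(1.0, 1.99, size=n_bad)
        frame = pd.DataFrame(
            {
                "array_id": array_id,
                "channel": ch,
                "spot": spot_ids,
                "gene": gene_col,
                "control_flag": False,
                "fg": fg,
                "bg": bg,
            }
        )
        if n_ctrl > 0:
            cbg = config.background_mean * np.exp(
                rng.normal(-0.5 * bg_sd**2, bg_sd, size=n_ctrl)
            ) if config.background_mean > 0 else np.zeros(n_ctrl)
            cfg_ = cbg * rng.uniform(0.5, 5.0, size=n_ctrl)
            frame = pd.concat(
                [
                    frame,
                    pd.DataFrame(
                        {
                            "array_id": array_id,
                            "channel": ch,
                            "spot": [f"ctrl_{i+1}" for i in range(n_ctrl)],
                            "gene": "",
                            "control_flag": True,
                            "fg": cfg_,
                            "bg": cbg,
                        }
                    ),
                ],
                ignore_index=True,
            )
        rows.append(frame)
    spots = pd.concat(rows, ignore_index=True)

    # --- truth tables ----------------------------------------------------
    planted = {(g, cmp_): fc for g, cmp_, fc in config.planted_regulation}
    reg_rows = []
    for cmp_ in config.comparisons:
        for g in genes:
            fc = planted.get((g, cmp_))
            reg_rows.append(
                (g, cmp_, fc if fc is not None else 1.0, fc is not None)
            )
    regulation = pd.DataFrame(
        reg_rows, columns=["gene", "comparison", "fold_change", "regulated"]
    )
    coordination = pd.DataFrame(
        coord_rows, columns=["gene_a", "gene_b", "condition", "r_planted"]
    )
    expression = pd.DataFrame(np.exp(log_mu), index=pd.Index(genes, name="gene"),
                              columns=list(conds))
    return spots, design, TruthTables(regulation, coordination, expression)


def default_config(
    seed: int = 0, n_genes: int = 500, panel_genes: bool = True
) -> SimulationConfig:
    """The default study-scale dataset.

    Twenty percent of genes carry a planted fold change in the unprotected
    comparison (COS vs CON) and five percent in the protected one (CES vs
    CEN), with |FC| cycling over 1.5–4 and alternating sign — emulating a
    strong insult with substantial protection.  Planted genes are spread
    evenly across the gene list, whose head carries the packaged pathway
    panel's symbols (``panel_genes=True``) so pathway scores are exercised.
    Noise defaults put the average per-gene cut-off (CUT) near the mid-1.4
    to 1.6 range typical of 4-replicate rodent array experiments.
    """
    names: tuple[str, ...] | None = None
    if panel_genes:
        from protectomics.io import (default_common_genes,
                                     default_pathway_panel, read_gmt)
        union: list[str] = []
        for gmt in (default_pathway_panel(), default_common_genes()):
            for gs in read_gmt(gmt):
                union.extend(g for g in gs.members if g not in union)
        if len(union) > n_genes:
            union = union[:n_genes]
        width = max(4, len(str(n_genes)))
        filler = [f"Gene{i + 1:0{width}d}"
                  for i in range(n_genes - len(union))]
        names = tuple(union + filler)
    cfg0 = SimulationConfig(n_genes=n_genes, seed=seed, gene_names=names)
    genes = cfg0.gene_list
    magnitudes = (1.5, 2.0, 2.5, 3.0, 4.0)
    planted: list[tuple[str, str, float]] = []
    n_unprot = int(round(0.20 * n_genes))
    n_prot = int(round(0.05 * n_genes))
    step = max(1, n_genes // max(n_unprot, 1))
    unprot_idx = [(i * step) % n_genes for i in range(n_unprot)]
    for i, gi in enumerate(unprot_idx):
        fc = magnitudes[i % len(magnitudes)] * (1 if i % 2 == 0 else -1)
        planted.append((genes[gi], "COS:CON", fc))
    for i, gi in enumerate(unprot_idx[::4][:n_prot]):
        fc = magnitudes[i % len(magnitudes)] * (1 if i % 2 == 0 else -1)
        planted.append((genes[gi], "CES:CEN", fc))
    blocks: tuple[CorrelationBlock, ...] = ()
    if n_genes >= 30:
        # coordinated co-expression with an insult-induced sign flip in
        # CES (synergistic-to-antagonistic switching) plus one mixed-sign
        # block stable across conditions
        blocks = (
            correlated_block(
                genes[10:18], rho=0.9,
                condition_flips={"CES": frozenset(genes[14:18])}),
            correlated_block(genes[20:26], rho=0.9,
                             signs=[1, 1, 1, 1, -1, -1]),
        )
    return dataclasses.replace(cfg0, planted_regulation=tuple(planted),
                               planted_correlation_blocks=blocks)
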