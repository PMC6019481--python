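"""Raw spot tables -> per-gene, per-sample expression matrix.

The chain mirrors standard two-color array pre-processing: spot validity
filtering (foreground at least twice background), background subtraction,
median normalization within each (array, label) channel, averaging of
redundant spots probing the same gene, and an iterative renormalization
across labels and conditions that stops once the average change of the
per-gene cross-condition expression ratios between successive iterations
falls below a tolerance (default 5%).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SPOT_COLUMNS = ["array_id", "channel", "spot", "gene", "control_flag", "fg", "bg"]


def validate_spots(spots: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the non-control spots whose foreground is at least
    twice the background.

    Negative fluorescence anywhere in the table is a hard error naming
    the offending row.  The filter is idempotent.
    """
    neg = (spots["fg"] < 0) | (spots["bg"] < 0)
    if neg.any():
        row = spots.index[neg][0]
        raise ValueError(f"negative fluorescence in spot table at row {row}")
    noncontrol = ~spots["control_flag"].astype(bool)
    valid = noncontrol & (spots["fg"] >= 2.0 * spots["bg"])
    kept = spots.loc[valid].copy()
    log.info(
        "validate_spots: kept %d/%d non-control spots (%d controls dropped)",
        len(kept), int(noncontrol.sum()), int((~noncontrol).sum()),
    )
    kept.attrs["n_input"] = len(spots)
    kept.attrs["n_noncontrol"] = int(noncontrol.sum())
    kept.attrs["n_valid"] = len(kept)
    return kept


def normalize_within_label(valid_spots: pd.DataFrame) -> pd.DataFrame:
    """Background-subtract and anchor each (array, label) channel to its
    median.

    Each valid spot's value is ``(fg - bg) / median(fg - bg)`` over the
    same-array same-label valid spots, so the median normalized value in
    every channel is exactly 1.
    """
    if valid_spots.empty:
        raise ValueError("no valid spots to normalize")
    out = valid_spots.copy()
    net = out["fg"] - out["bg"]
    med = net.groupby([out["array_id"], out["channel"]]).transform("median")
    if (med <= 0).any():
        grp = out.loc[med <= 0, ["array_id", "channel"]].iloc[0]
        raise ValueError(
            f"non-positive median signal in array {grp['array_id']} "
            f"channel {grp['channel']}"
        )
    out["value"] = net / med
    return out


@dataclass
class ExpressionMatrix:
    """Genes x (condition, replicate) normalized expression levels.

    ``values`` has a two-level column index (condition, replicate);
    ``mask`` is True where the gene had at least one valid spot in that
    sample; ``sem2`` holds the squared standard error of the redundant-spot
    mean (0 for singleton spots); ``spot_long`` keeps the per-spot-group
    values needed by the redundant-spot-corrected t-test.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    sem2: pd.DataFrame
    n_spots: pd.DataFrame
    spot_long: pd.DataFrame = field(repr=False)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def n_replicates(self, condition: str) -> int:
        return len(self.values[condition].columns)

    def condition_values(self, condition: str) -> pd.DataFrame:
        """Replicate values for one condition with invalid entries as NaN."""
        v = self.values[condition].where(self.mask[condition])
        return v

    def condition_stats(self, condition: str) -> pd.DataFrame:
        """Per-gene mean, pooled CV and valid-replicate count.

        The CV pools biological replicate spread with the redundant-spot
        measurement error: sqrt(Var_rep + mean(SEM_spot^2)) / mean.
        """
        v = self.condition_values(condition)
        n_valid = v.notna().sum(axis=1)
        mu = v.mean(axis=1)
        var_rep = v.var(axis=1, ddof=1)
        sem2 = self.sem2[condition].where(self.mask[condition]).mean(axis=1)
        pooled = np.sqrt(var_rep.fillna(0.0) + sem2.fillna(0.0))
        cv = pooled / mu
        return pd.DataFrame(
            {"mu": mu, "cv": cv, "n_valid": n_valid}, index=self.values.index
        )

    def quantifiable(self, condition: str) -> pd.Series:
        """Gene is quantifiable if valid in at least n-1 replicates."""
        n = self.n_replicates(condition)
        return self.mask[condition].sum(axis=1) >= n - 1

    def n_valid(self, condition: str) -> pd.Series:
        return self.mask[condition].sum(axis=1)

    def scale_samples(self, factors: pd.Series) -> None:
        """Divide each sample column (and its spot-level values) in place."""
        for col in self.values.columns:
            f = factors[col]
            self.values[col] = self.values[col] / f
            self.sem2[col] = self.sem2[col] / (f * f)
        idx = pd.MultiIndex.from_arrays(
            [self.spot_long["condition"], self.spot_long["replicate"]]
        )
        self.spot_long["value"] = (
            self.spot_long["value"].to_numpy() / factors.reindex(idx).to_numpy()
        )


def collapse_redundancy(
    normalized_spots: pd.DataFrame, design: pd.DataFrame
) -> ExpressionMatrix:
    """Average redundant spots per gene per sample, eliminating array
    redundancy; samples without a valid spot for a gene are masked out.
    """
    merged = normalized_spots.merge(design, on=["array_id", "channel"],
                                    how="left", validate="many_to_one")
    if merged["condition"].isna().any():
        bad = merged.loc[merged["condition"].isna(),
                         ["array_id", "channel"]].iloc[0]
        raise ValueError(
            f"spot table references ({bad['array_id']}, {bad['channel']}) "
            "absent from the design table"
        )
    if "spot" not in merged.columns:
        merged["spot"] = merged.groupby(
            ["array_id", "channel", "gene"]).cumcount().astype(str)

    grp = merged.groupby(["gene", "condition", "replicate"])["value"]
    agg = grp.agg(["mean", "var", "count"]).reset_index()
    agg["sem2"] = (agg["var"].fillna(0.0) / agg["count"]).where(
        agg["count"] > 1, 0.0)

    cond_order = list(dict.fromkeys(design["condition"]))
    reps = sorted(design["replicate"].unique())
    cols = pd.MultiIndex.from_product([cond_order, reps],
                                      names=["condition", "replicate"])
    genes = pd.Index(sorted(merged["gene"].unique()), name="gene")

    def pivot(col: str, fill: float) -> pd.DataFrame:
        p = agg.pivot_table(index="gene", columns=["condition", "replicate"],
                            values=col, aggfunc="first")
        return p.reindex(index=genes, columns=cols).fillna(fill)

    values = pivot("mean", np.nan)
    mask = values.notna()
    values = values.fillna(0.0)
    sem2 = pivot("sem2", 0.0)
    n_spots = pivot("count", 0.0).astype(int)

    spot_long = merged[["gene", "spot", "condition", "replicate", "value"]].copy()
    return ExpressionMatrix(values, mask, sem2, n_spots, spot_long)


def _condition_ratios(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene expression ratios for every unordered condition pair."""
    conds = em.conditions
    means = {c: em.condition_values(c).mean(axis=1) for c in conds}
    cols = {}
    for a, b in itertools.combinations(conds, 2):
        cols[f"{a}/{b}"] = means[a] / means[b]
    return pd.DataFrame(cols, index=em.genes)


def iterative_renormalize(
    em: ExpressionMatrix, tol: float = 0.05, max_iter: int = 100
) -> tuple[ExpressionMatrix, int, float]:
    """Renormalize all samples across labels and conditions.

    Each pass rescales every sample by the median of its per-gene ratios
    to the across-sample geometric-mean reference (recomputed each pass),
    then measures the mean absolute relative change of all per-gene
    cross-condition expression ratios against the previous pass; the loop
    stops when that average change drops below ``tol``.

    Returns ``(matrix, n_iterations, final_delta)``; raises after
    ``max_iter`` passes without convergence, naming the last delta.
    """
    if em.values.shape[1] < 2:
        raise ValueError("iterative renormalization needs at least 2 samples")
    if max_iter < 1:
        raise ValueError("iterative renormalization needs max_iter >= 1")
    delta = np.inf
    old_ratios = _condition_ratios(em)
    for it in range(1, max_iter + 1):
        vals = em.values.where(em.mask)
        logref = np.log(vals).mean(axis=1)          # geometric-mean reference
        ref = np.exp(logref)
        usable = np.isfinite(ref) & (ref > 0)
        factors = (vals.loc[usable].div(ref[usable], axis=0)).median(axis=0)
        em.scale_samples(factors)
        new_ratios = _condition_ratios(em)
        rel = (new_ratios / old_ratios - 1.0).abs()
        delta = float(rel.stack().replace([np.inf, -np.inf], np.nan).dropna().mean())
        if np.isnan(delta):
            delta = 0.0
        log.info("iterative_renormalize: pass %d, delta=%.4g", it, delta)
        old_ratios = new_ratios
        if delta < tol:
            return em, it, delta
    raise RuntimeError(
        f"iterative renormalization did not converge in {max_iter} passes "
        f"(last average ratio change {delta:.4g})"
    )


def normalize_experiment(
    spots: pd.DataFrame,
    design: pd.DataFrame,
    tol: float = 0.05,
    max_iter: int = 100,
) -> tuple[ExpressionMatrix, int, float]:
    """Full chain: validity filter -> within-label median normalization ->
    redundancy collapse -> iterative cross-condition renormalization."""
    valid = validate_spots(spots)
    norm = normalize_within_label(valid)
    em = collapse_redundancy(norm, design)
    return iterative_renormalize(em, tol=tol, max_iter=max_iter)
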