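"""Pathway-level regulation and protection quantifiers.

Beyond the percentage of up-/down-regulated member genes, two cut-off-free
scores summarize how strongly a pathway is perturbed and how well a
treatment protects it:

* WPR (Weighted Pathway Regulation): the mean over quantified member genes
  of the contribution ``c_i = (|x_i| - 1) * (1 - p_i)``, which weights each
  gene by both the magnitude and the significance of its regulation and
  involves no fold-change or p-value threshold.  A gene at 2x, p = 0.01
  contributes more than twice a gene at 1.5x, p = 0.05 (0.99 vs 0.475).
* PPR (Pathway Protection): the percent reduction of WPR in the protected
  comparison relative to the unprotected one.
* TPR (Transcriptomic Protection): the percent reduction of the fraction
  of regulated genes, optionally debiting the treatment's own side effects
  (the percentage regulated by the treatment alone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from protectomics.regulation import CALL_DOWN, CALL_UP

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named pathway membership list (unique, nonempty symbols)."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.members)


def _quantified(reg: pd.DataFrame, members: tuple[str, ...]) -> pd.DataFrame:
    sub = reg.loc[reg.index.intersection(members)]
    return sub[sub["x"].notna() & sub["p"].notna()]


def percent_regulated(
    gene_set: GeneSet, reg: pd.DataFrame
) -> tuple[float, float, float]:
    """(pct_up, pct_down, pct_regulated) over *quantified* member genes.

    Unquantified members are excluded from the denominator; an empty
    intersection with the quantified genes is rejected.
    """
    sub = _quantified(reg, gene_set.members)
    if sub.empty:
        raise ValueError(
            f"pathway {gene_set.name!r}: no member gene was quantified"
        )
    n = len(sub)
    up = 100.0 * (sub["call"] == CALL_UP).sum() / n
    down = 100.0 * (sub["call"] == CALL_DOWN).sum() / n
    return float(up), float(down), float(up + down)


def wpr(gene_set: GeneSet, reg: pd.DataFrame, aggregation: str = "mean") -> float:
    """Weighted Pathway Regulation over quantified member genes."""
    sub = _quantified(reg, gene_set.members)
    if sub.empty:
        raise ValueError(
            f"pathway {gene_set.name!r}: no member gene was quantified"
        )
    contrib = (sub["x"].abs() - 1.0) * (1.0 - sub["p"])
    if aggregation == "mean":
        return float(contrib.mean())
    if aggregation == "sum":
        return float(contrib.sum())
    raise ValueError(f"wpr: unknown aggregation {aggregation!r}")


def ppr(wpr_unprotected: float, wpr_protected: float) -> float | None:
    """Percent reduction of WPR; None (missing) when the unprotected WPR
    is zero.  Negative values mean the 'protected' arm fared worse."""
    if wpr_unprotected == 0:
        return None
    return 100.0 * (wpr_unprotected - wpr_protected) / wpr_unprotected


def tpr(
    pct_unprotected: float,
    pct_protected: float,
    pct_side_effect: float = 0.0,
    side_effect_mode: bool = False,
) -> float | None:
    """Percent reduction of the regulated-gene fraction.

    With ``side_effect_mode`` the percentage regulated by the treatment
    alone is debited from the protected arm's credit.  None when the
    unprotected percentage is zero.
    """
    if pct_unprotected == 0:
        return None
    if side_effect_mode:
        return 100.0 * (pct_unprotected - pct_protected - pct_side_effect) \
            / pct_unprotected
    return 100.0 * (pct_unprotected - pct_protected) / pct_unprotected


def score_pathways(
    gene_sets: list[GeneSet],
    regulation: dict[str, pd.DataFrame],
    protection_pair: tuple[str, str] | None = None,
    side_effect_comparison: str | None = None,
    aggregation: str = "mean",
    side_effect_mode: bool = False,
) -> pd.DataFrame:
    """One row per (pathway, comparison) with percentages and WPR; when a
    (unprotected, protected) comparison pair is given the unprotected rows
    also carry TPR and PPR.

    Pathways with no quantified member in a comparison are skipped with a
    log line rather than aborting the whole panel.
    """
    rows = []
    for gs in gene_sets:
        per_cmp: dict[str, tuple[float, float, float, float, int]] = {}
        for cmp_name, reg in regulation.items():
            try:
                up, down, tot = percent_regulated(gs, reg)
                w = wpr(gs, reg, aggregation=aggregation)
            except ValueError as exc:
                log.warning("score_pathways: %s", exc)
                continue
            n_q = len(_quantified(reg, gs.members))
            per_cmp[cmp_name] = (up, down, tot, w, n_q)
        for cmp_name, (up, down, tot, w, n_q) in per_cmp.items():
            t = p = np.nan
            if protection_pair is not None and cmp_name == protection_pair[0]:
                unprot, prot = protection_pair
                if prot in per_cmp:
                    side = 0.0
                    if side_effect_mode and side_effect_comparison in regulation:
                        try:
                            _, _, side = percent_regulated(
                                gs, regulation[side_effect_comparison])
                        except ValueError:
                            side = 0.0
                    t_ = tpr(tot, per_cmp[prot][2], side,
                             side_effect_mode=side_effect_mode)
                    p_ = ppr(w, per_cmp[prot][3])
                    t = np.nan if t_ is None else t_
                    p = np.nan if p_ is None else p_
            rows.append(
                (gs.name, cmp_name, len(gs), n_q, up, down, tot, w, t, p)
            )
    return pd.DataFrame(
        rows,
        columns=["pathway", "comparison", "n_members", "n_quantified",
                 "pct_up", "pct_down", "pct_regulated", "WPR", "TPR", "PPR"],
    )
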