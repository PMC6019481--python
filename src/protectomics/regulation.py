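"""Per-gene regulation calls with a flexible fold-change cut-off.

Instead of a uniform 1.5x fold-change threshold, each gene gets its own
cut-off CUT combining the technical noise and biological variability of
its own measurements in the two compared conditions:

    CUT = 1 + sqrt(CV_A^2 + CV_B^2)

A gene is called regulated when its signed expression ratio x (negative
for down-regulation, |x| >= 1 by construction) satisfies |x| >= CUT *and*
the heteroscedastic (Welch) t-test of equal mean expression — applied per
distinct redundant spot group and combined with a Bonferroni-type
correction, p = min(1, k * min_j p_j) — is significant.  This per-gene
cut-off recovers stably expressed genes with modest ratios that a uniform
1.5x rule misses ("false negatives") and rejects noisy genes with large
ratios that it wrongly accepts ("false positives").
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from protectomics.normalize import ExpressionMatrix

log = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NONE = "none"

TURNED_ON = "turned_on"
TURNED_OFF = "turned_off"
EXPRESSED_BOTH = "expressed_both"
ABSENT_BOTH = "absent_both"


def expression_ratio(mu_a: float, mu_b: float) -> float:
    """Signed expression ratio of condition B over condition A.

    x = mu_B/mu_A when B is the larger mean, else -mu_A/mu_B; down-regulation
    is negative and |x| >= 1 always.  Equal means give x = 1 (up orientation
    by convention).
    """
    if mu_a <= 0 or mu_b <= 0:
        raise ValueError("expression_ratio: means must be positive")
    if mu_b >= mu_a:
        return mu_b / mu_a
    return -mu_a / mu_b


def chi2_corrected_cv(cv: float, n: int) -> float:
    """Median-unbiased CV rescaling via the chi-square mid-interval.

    The sample standard deviation from n replicates underestimates sigma
    at its median; dividing by sqrt(chi2_median(n-1)/(n-1)) centers it.
    """
    if n < 2:
        return cv
    return cv * np.sqrt((n - 1) / stats.chi2.ppf(0.5, n - 1))


def compute_cut(
    cv_a: float, cv_b: float, estimator: str = "plain",
    n_a: int | None = None, n_b: int | None = None,
) -> float:
    """Per-gene absolute fold-change cut-off from the two pooled CVs.

    ``estimator='chi2'`` applies the median-unbiased chi-square correction
    to each CV first (requires the replicate counts).
    """
    if cv_a < 0 or cv_b < 0:
        raise ValueError("compute_cut: CVs must be >= 0")
    if estimator == "chi2":
        if n_a is None or n_b is None:
            raise ValueError("compute_cut: chi2 estimator needs n_a and n_b")
        cv_a = chi2_corrected_cv(cv_a, n_a)
        cv_b = chi2_corrected_cv(cv_b, n_b)
    elif estimator != "plain":
        raise ValueError(f"compute_cut: unknown estimator {estimator!r}")
    return 1.0 + float(np.sqrt(cv_a * cv_a + cv_b * cv_b))


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate zero-variance samples: identical -> no evidence,
        # different -> arbitrarily strong evidence
        return 1.0 if a[0] == b[0] else 0.0
    t = stats.ttest_ind(a, b, equal_var=False)
    p = float(t.pvalue)
    return 1.0 if np.isnan(p) else p


def gene_p_value(
    groups_a: Mapping[str, Sequence[float]],
    groups_b: Mapping[str, Sequence[float]],
    log_scale: bool = True,
    min_replicates: int = 3,
) -> float | None:
    """Gene-level p-value across redundant spot groups.

    A Welch two-sample two-tailed t-test is run per distinct spot group
    (values of the group's replicates in conditions A and B, log scale by
    default); the gene p-value is ``min(1, k * min_j p_j)`` over the k
    testable groups (Bonferroni-type correction for redundant spots).
    Returns None when no spot group has ``min_replicates`` valid values
    on both sides (gene excluded, logged by the caller).
    """
    ps = []
    for spot in groups_a.keys() & groups_b.keys():
        a = np.asarray(groups_a[spot], dtype=float)
        b = np.asarray(groups_b[spot], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < min_replicates or len(b) < min_replicates:
            continue
        if log_scale:
            if np.any(a <= 0) or np.any(b <= 0):
                raise ValueError("gene_p_value: log scale needs positive values")
            a, b = np.log(a), np.log(b)
        ps.append(_welch_p(a, b))
    if not ps:
        return None
    return min(1.0, len(ps) * min(ps))


def call_regulation(x: float, cut: float, p: float, alpha: float = 0.05) -> str:
    """Regulation call from the signed ratio, the per-gene cut-off and p.

    Ties at |x| = CUT are called regulated (inclusive comparisons).
    """
    if p < alpha:
        if x >= cut:
            return CALL_UP
        if x <= -cut:
            return CALL_DOWN
    return CALL_NONE


def call_on_off(
    n_valid_a: int, n_valid_b: int, n_a: int, n_b: int
) -> str:
    """ON/OFF status from per-condition validity counts.

    A gene is quantifiable in a condition when valid in at least n-1
    replicates, and absent when valid in at most 1; turned ON means
    quantifiable in B but absent in A, turned OFF the mirror case.
    """
    quant_a = n_valid_a >= n_a - 1
    quant_b = n_valid_b >= n_b - 1
    absent_a = n_valid_a <= 1
    absent_b = n_valid_b <= 1
    if quant_b and absent_a:
        return TURNED_ON
    if quant_a and absent_b:
        return TURNED_OFF
    if quant_a and quant_b:
        return EXPRESSED_BOTH
    return ABSENT_BOTH


def _spot_groups(
    spot_long: pd.DataFrame, condition: str
) -> dict[str, dict[str, np.ndarray]]:
    """gene -> spot -> replicate values, for one condition."""
    sub = spot_long[spot_long["condition"] == condition]
    out: dict[str, dict[str, np.ndarray]] = {}
    for (gene, spot), vals in sub.groupby(["gene", "spot"])["value"]:
        out.setdefault(gene, {})[spot] = vals.to_numpy()
    return out


def regulate(
    em: ExpressionMatrix,
    comparison: str,
    alpha: float = 0.05,
    cut_estimator: str = "plain",
    test_scale: str = "log",
) -> pd.DataFrame:
    """Regulation table for one comparison ``"B:A"`` (condition B vs A).

    Rows cover every gene of the matrix: genes quantifiable (valid in at
    least n-1 replicates) in both conditions get x, CUT, p and a call;
    the rest carry only their ON/OFF status.
    """
    cond_b, cond_a = comparison.split(":")
    stats_a = em.condition_stats(cond_a)
    stats_b = em.condition_stats(cond_b)
    quant = em.quantifiable(cond_a) & em.quantifiable(cond_b)
    n_a, n_b = em.n_replicates(cond_a), em.n_replicates(cond_b)
    groups_a = _spot_groups(em.spot_long, cond_a)
    groups_b = _spot_groups(em.spot_long, cond_b)
    log_scale = test_scale == "log"

    rows = []
    n_excluded = 0
    for gene in em.genes:
        onoff = call_on_off(
            int(em.n_valid(cond_a)[gene]), int(em.n_valid(cond_b)[gene]),
            n_a, n_b,
        )
        x = cut = p = np.nan
        call = CALL_NONE
        if quant[gene]:
            mu_a, mu_b = stats_a.loc[gene, "mu"], stats_b.loc[gene, "mu"]
            if mu_a > 0 and mu_b > 0:
                x = expression_ratio(mu_a, mu_b)
                cut = compute_cut(
                    float(stats_a.loc[gene, "cv"]), float(stats_b.loc[gene, "cv"]),
                    estimator=cut_estimator,
                    n_a=int(stats_a.loc[gene, "n_valid"]),
                    n_b=int(stats_b.loc[gene, "n_valid"]),
                )
                pv = gene_p_value(
                    groups_a.get(gene, {}), groups_b.get(gene, {}),
                    log_scale=log_scale,
                )
                if pv is None:
                    n_excluded += 1
                else:
                    p = pv
                    call = call_regulation(x, cut, p, alpha=alpha)
        rows.append((gene, comparison, x, cut, p, call, onoff))
    if n_excluded:
        log.info("regulate %s: %d genes lacked a testable spot group",
                 comparison, n_excluded)
    return pd.DataFrame(
        rows, columns=["gene", "comparison", "x", "CUT", "p", "call", "onoff"]
    ).set_index("gene")
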