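"""Expression-coordination analysis across biological replicates.

For each condition, the Pearson correlation between two genes' expression
levels among the biological replicates measures whether the pair is
coordinately expressed.  With n replicates the exact two-tailed
significance threshold comes from the t-transform
``t = r * sqrt((n - 2) / (1 - r^2))``; at n = 4 and alpha = 0.05 the
critical |r| is exactly 0.95, so only near-perfect correlations are
called.  Classes:

* S (synergistic):   r >=  r_crit
* A (antagonistic):  r <= -r_crit
* I (independent):   |r| <= r_ind  (a declared near-zero band; with n = 4
  no rigorous test of independence exists)
* U (undetermined):  everything in between — not enough evidence.

A *switch* is a pair whose class changes between two conditions; the
synergistic-to-antagonistic direction is the signature of a perturbation
rewiring a pathway's coordination structure.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from protectomics.normalize import ExpressionMatrix
from protectomics.pathway import GeneSet

log = logging.getLogger(__name__)

CLASSES = ("S", "A", "I", "U")


def pair_count(n_genes: int) -> int:
    """Number of unordered gene pairs: G(G-1)/2."""
    if n_genes < 0:
        raise ValueError("pair_count: n_genes must be >= 0")
    return n_genes * (n_genes - 1) // 2


def r_critical(alpha: float = 0.05, n: int = 4) -> float:
    """Exact two-tailed critical |r| at significance alpha with n samples.

    Uses the t-transform with n-2 degrees of freedom rather than the
    Fisher z approximation, which is inaccurate at tiny n.
    """
    if n < 3:
        raise ValueError("r_critical: need n >= 3")
    t = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(t / np.sqrt(t * t + n - 2))


def correlation_p_value(r: float, n: int) -> float:
    """Two-tailed p of the t-transformed Pearson coefficient."""
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


def _log_condition_matrix(
    em: ExpressionMatrix, condition: str, use_log: bool
) -> pd.DataFrame:
    v = em.condition_values(condition)
    full = v.notna().all(axis=1)
    v = v.loc[full]
    return np.log(v) if use_log else v


def pairwise_correlation(
    values: pd.DataFrame,
    genes_a: Sequence[str] | None = None,
    genes_b: Sequence[str] | None = None,
    block_size: int = 512,
) -> pd.DataFrame:
    """Pearson r for gene pairs of a (genes x replicates) value matrix.

    With only ``genes_a`` (or neither), all unordered pairs within the
    list are enumerated once — G(G-1)/2 rows.  With both lists, the cross
    pairs a x b are produced (shared genes are the caller's concern).
    Zero-variance genes yield NaN r (uncomputable, logged).  Computation
    is blocked so memory stays proportional to ``block_size`` rows.
    """
    if genes_a is None:
        genes_a = list(values.index)
    missing = [g for g in genes_a if g not in values.index]
    if genes_b is not None:
        missing += [g for g in genes_b if g not in values.index]
    if missing:
        raise KeyError(f"genes absent from the matrix: {missing[:5]}")

    n = values.shape[1]

    def standardized(genes: Sequence[str]) -> np.ndarray:
        x = values.loc[list(genes)].to_numpy(dtype=float)
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0)
        bad = sd == 0
        if bad.any():
            log.info("pairwise_correlation: %d zero-variance genes", bad.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            x = x / sd[:, None]
        x[bad] = np.nan
        return x

    rows: list[pd.DataFrame] = []
    if genes_b is None:
        za = standardized(genes_a)
        g = list(genes_a)
        for i0 in range(0, len(g), block_size):
            i1 = min(i0 + block_size, len(g))
            r = za[i0:i1] @ za.T / n
            for i in range(i0, i1):
                j = np.arange(i + 1, len(g))
                if j.size:
                    rows.append(pd.DataFrame({
                        "gene_a": g[i],
                        "gene_b": [g[k] for k in j],
                        "r": np.clip(r[i - i0, j], -1.0, 1.0),
                    }))
    else:
        za, zb = standardized(genes_a), standardized(genes_b)
        ga, gb = list(genes_a), list(genes_b)
        for i0 in range(0, len(ga), block_size):
            i1 = min(i0 + block_size, len(ga))
            r = za[i0:i1] @ zb.T / n
            for i in range(i0, i1):
                rows.append(pd.DataFrame({
                    "gene_a": ga[i],
                    "gene_b": gb,
                    "r": np.clip(r[i - i0], -1.0, 1.0),
                }))
    if not rows:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "n"])
    out = pd.concat(rows, ignore_index=True)
    out["n"] = n
    return out


def classify_coordination(
    r: float | np.ndarray | pd.Series,
    n: int,
    alpha: float = 0.05,
    r_ind: float = 0.25,
) -> np.ndarray:
    """Vectorized S/A/I/U classification (NaN r stays NaN -> 'U' is *not*
    assigned; uncomputable pairs are the caller's to exclude)."""
    rc = r_critical(alpha, n)
    arr = np.asarray(r, dtype=float)
    out = np.full(arr.shape, "U", dtype=object)
    out[arr >= rc] = "S"
    out[arr <= -rc] = "A"
    out[np.abs(arr) <= r_ind] = "I"
    out[~np.isfinite(arr)] = None
    return out


def condition_edges(
    em: ExpressionMatrix,
    condition: str,
    genes_a: Sequence[str] | None = None,
    genes_b: Sequence[str] | None = None,
    alpha: float = 0.05,
    r_ind: float = 0.25,
    use_log: bool = True,
) -> pd.DataFrame:
    """Coordination edge table for one condition.

    Only genes quantified in *all* replicates of the condition enter; the
    table carries r, the correlation-test p-value and the S/A/I/U class.
    """
    vals = _log_condition_matrix(em, condition, use_log)
    if vals.shape[1] < 3:
        raise ValueError("condition_edges: need at least 3 replicates")
    avail = set(vals.index)
    ga = [g for g in (genes_a or vals.index) if g in avail]
    gb = None if genes_b is None else [g for g in genes_b if g in avail]
    edges = pairwise_correlation(vals, ga, gb)
    edges.insert(2, "condition", condition)
    n = vals.shape[1]
    edges["p_sig"] = [correlation_p_value(r, n) if np.isfinite(r) else np.nan
                      for r in edges["r"]]
    edges["class"] = classify_coordination(edges["r"], n, alpha, r_ind)
    return edges


def _pair_key(df: pd.DataFrame) -> pd.Series:
    a, b = df["gene_a"], df["gene_b"]
    return pd.Series(np.where(a < b, a + "|" + b, b + "|" + a), index=df.index)


def cross_set_percentages(
    set_a: GeneSet | Iterable[str],
    set_b: GeneSet | Iterable[str],
    edges: pd.DataFrame,
) -> tuple[float, float, float]:
    """(S%, A%, I%) over computable cross-set pairs; the remainder is U.

    Genes common to both sets are dropped from both (they belong to the
    common-gene layer of the three-layer networks, counted once there).
    """
    a = set(set_a.members if isinstance(set_a, GeneSet) else set_a)
    b = set(set_b.members if isinstance(set_b, GeneSet) else set_b)
    common = a & b
    a, b = a - common, b - common
    key = _pair_key(edges)
    cross = edges.loc[
        (edges["gene_a"].isin(a) & edges["gene_b"].isin(b))
        | (edges["gene_a"].isin(b) & edges["gene_b"].isin(a))
    ]
    cross = cross.loc[~key.loc[cross.index].duplicated()]
    cross = cross[cross["class"].notna()]
    if cross.empty:
        raise ValueError("cross_set_percentages: no computable cross-set pair")
    n = len(cross)
    pct = {c: 100.0 * (cross["class"] == c).sum() / n for c in ("S", "A", "I")}
    return pct["S"], pct["A"], pct["I"]


def detect_switches(
    edges_1: pd.DataFrame, edges_2: pd.DataFrame
) -> pd.DataFrame:
    """Pairs whose coordination class changed between two conditions.

    Both edge tables must cover the same pair universe; pairs uncomputable
    in either condition are excluded (logged).  ``switch_type`` separates
    the S->A and A->S directions from all other changes.
    """
    k1, k2 = _pair_key(edges_1), _pair_key(edges_2)
    if set(k1) != set(k2):
        raise ValueError("detect_switches: pair universes differ")
    e1 = edges_1.assign(key=k1).set_index("key")
    e2 = edges_2.assign(key=k2).set_index("key")
    merged = e1[["gene_a", "gene_b", "class"]].join(
        e2[["class"]], lsuffix="_from", rsuffix="_to"
    )
    computable = merged["class_from"].notna() & merged["class_to"].notna()
    if (~computable).any():
        log.info("detect_switches: %d pairs uncomputable in a condition",
                 int((~computable).sum()))
    merged = merged[computable]
    changed = merged[merged["class_from"] != merged["class_to"]].copy()
    changed["switch_type"] = "other"
    changed.loc[(changed["class_from"] == "S") &
                (changed["class_to"] == "A"), "switch_type"] = "S->A"
    changed.loc[(changed["class_from"] == "A") &
                (changed["class_to"] == "S"), "switch_type"] = "A->S"
    return changed.rename(
        columns={"class_from": "from_class", "class_to": "to_class"}
    ).reset_index(drop=True)


def switch_census(switches: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of S->A and A->S switches (hub-gene census)."""
    long = pd.concat([
        switches[["gene_a", "switch_type"]].rename(columns={"gene_a": "gene"}),
        switches[["gene_b", "switch_type"]].rename(columns={"gene_b": "gene"}),
    ])
    tab = long.pivot_table(index="gene", columns="switch_type",
                           aggfunc="size", fill_value=0)
    return tab.reindex(columns=["S->A", "A->S", "other"], fill_value=0)


def build_network(
    esg_set: GeneSet,
    nt_set: GeneSet,
    common_genes: Iterable[str],
    edges: pd.DataFrame,
    regulation: pd.DataFrame | None = None,
) -> nx.Graph:
    """Three-layer coordination network ESG <-> CG <-> neurotransmission.

    Edges are emitted for ESG-CG and CG-NT pairs whose class is S, A or I
    (U means not enough evidence and draws no line).  Node attributes
    carry the layer and, when a regulation table is supplied, the call
    (up/down/none/unquantified) for the chosen comparison.
    """
    cg = set(common_genes)
    union = set(esg_set.members) | set(nt_set.members)
    stray = sorted(cg - union)
    if stray:
        log.warning("build_network: common genes not in either pathway: %s",
                    stray)
    esg_only = set(esg_set.members) - cg
    nt_only = set(nt_set.members) - cg

    g = nx.Graph()
    for gene in esg_only | cg | nt_only:
        layer = "CG" if gene in cg else ("ESG" if gene in esg_only else "NT")
        call = "unquantified"
        if regulation is not None and gene in regulation.index:
            rec = regulation.loc[gene]
            call = rec["call"] if pd.notna(rec["x"]) else "unquantified"
        g.add_node(gene, layer=layer, regulation=call)

    informative = edges[edges["class"].isin(["S", "A", "I"])]
    for _, row in informative.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        pair_layers = {g.nodes[a]["layer"] if a in g else None,
                       g.nodes[b]["layer"] if b in g else None}
        if pair_layers in ({"ESG", "CG"}, {"CG", "NT"}):
            g.add_edge(a, b, r=float(row.get("r", np.nan)),
                       coordination=row["class"],
                       condition=row.get("condition", ""))
    return g


def all_within_pairs(genes: Sequence[str]) -> Iterable[tuple[str, str]]:
    """Unordered pair enumeration helper (each pair exactly once)."""
    return itertools.combinations(genes, 2)
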