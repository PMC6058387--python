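"""Fisher's-method combination of the per-cell-type association results.

For a probe tested in k cell types with p-values p_1..p_k, the combined
statistic is ``chi_sq = -2 * sum(ln p_i)``, distributed as chi-square with
``2k`` degrees of freedom under the joint null; the combined p is its
upper-tail probability, evaluated in log space so that extreme inputs do
not underflow.  Benjamini-Hochberg q-values are attached over all probes
entering the meta-analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ContractError, ValidationError

log = logging.getLogger(__name__)

#: floor applied to component p-values of zero (flagged with a warning)
P_FLOOR = 1e-300


class FisherResult(NamedTuple):
    chi_sq: float
    df: int
    p_combined: float


def fisher_combine(p_values: Sequence[float], floor: float = P_FLOOR) -> FisherResult:
    """Combine k p-values by Fisher's method (chi-square, 2k df)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ContractError("need at least one p-value")
    if np.any(p > 1) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    if np.any(p <= 0):
        warnings.warn(f"p-value(s) <= 0 clamped to floor {floor:g}", stacklevel=2)
        p = np.maximum(p, floor)
    chi_sq = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    p_combined = float(np.exp(stats.chi2.logsf(chi_sq, df)))
    return FisherResult(chi_sq, df, max(p_combined, np.finfo(float).tiny))


def bh_fdr(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``m`` overrides the number of tests, for q-values of a top-k slice of
    a larger ranked family (the slice must hold the smallest p-values);
    by default m = len(p_values).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ContractError("empty p-value vector")
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    n = p.size
    m = n if m is None else int(m)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_from_ranked(p_values: Sequence[float], ranks: Sequence[int], m: int) -> np.ndarray:
    """BH q-values for rows excerpted from a ranked family of m tests.

    ``ranks`` are the rows' 1-based ranks within the full family (need not
    be contiguous); q_i = min over listed rows j with rank >= rank_i of
    p_j * m / rank_j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    r = np.asarray(ranks, dtype=int)
    order = np.argsort(r, kind="stable")
    vals = p[order] * m / r[order]
    q_sorted = np.minimum.accumulate(vals[::-1])[::-1]
    q = np.empty(p.size)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def combine_cell_types(neuron: pd.DataFrame, glia: pd.DataFrame) -> pd.DataFrame:
    """Per-probe Fisher combination of the neuron and glia EWAS tables.

    Both tables must carry a ``p`` column indexed by probe; probes present
    in only one table are excluded (logged).  Returns a ranked table with
    p_neuron, p_glia, chi_sq, df, p_combined, fdr_q, rank.
    """
    shared = neuron.index.intersection(glia.index)
    dropped = len(neuron.index.union(glia.index)) - len(shared)
    if dropped:
        log.info("excluding %d probes present in only one cell type", dropped)
    if len(shared) == 0:
        raise ContractError("no shared probes between the two tables")
    pn = neuron.loc[shared, "p"].to_numpy(dtype=float)
    pg = glia.loc[shared, "p"].to_numpy(dtype=float)
    for arr in (pn, pg):
        if np.any((arr <= 0) | (arr > 1)):
            raise ValidationError("component p-values must lie in (0, 1]")
    chi = -2.0 * (np.log(pn) + np.log(pg))
    p_comb = np.exp(stats.chi2.logsf(chi, 4))
    p_comb = np.clip(p_comb, np.finfo(float).tiny, 1.0)
    table = pd.DataFrame(
        {
            "p_neuron": pn,
            "p_glia": pg,
            "chi_sq": chi,
            "df": 4,
            "p_combined": p_comb,
            "fdr_q": bh_fdr(p_comb),
        },
        index=shared,
    )
    order = np.lexsort((table.index.to_numpy(), p_comb))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return table


def top_k_overlap(table_a: pd.DataFrame, table_b: pd.DataFrame, k: int = 1000):
    """Overlap of the top-k probes (by rank) of two ranked tables.

    Returns ``(n_common, n_only_a, n_only_b)``.
    """
    for t in (table_a, table_b):
        if "rank" not in t.columns:
            raise ContractError("tables must be ranked")
        if k > len(t):
            raise ContractError(f"k={k} exceeds table size {len(t)}")
    top_a = set(table_a.index[table_a["rank"] <= k])
    top_b = set(table_b.index[table_b["rank"] <= k])
    return len(top_a & top_b), len(top_a - top_b), len(top_b - top_a)


@dataclass(frozen=True)
class BraakGrouping:
    """Partition of Braak stages into low/mid/high groups."""

    low: tuple = (0, 1, 2)
    mid: tuple = (3, 4)
    high: tuple = (5, 6)

    def __post_init__(self):
        if sorted(self.low + self.mid + self.high) != list(range(7)):
            raise ContractError("groups must partition Braak stages 0-6")


def braak_group_deltas(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    probes,
    grouping: BraakGrouping = BraakGrouping(),
) -> pd.DataFrame:
    """Mean beta per Braak group and pairwise deltas, per probe."""
    sub = sheet.loc[sheet.index.intersection(beta.columns)]
    probes = pd.Index(probes)
    out = {}
    for name in ("low", "mid", "high"):
        ids = sub.index[sub["braak"].isin(getattr(grouping, name))]
        if len(ids) == 0:
            raise ContractError(f"Braak group {name!r} is empty")
        out[f"mean_{name}"] = beta.loc[probes, ids].mean(axis=1)
    table = pd.DataFrame(out, index=probes)
    table["delta_high_low"] = table["mean_high"] - table["mean_low"]
    table["delta_mid_low"] = table["mean_mid"] - table["mean_low"]
    return table


@dataclass
class ClusterCheck:
    """Average-linkage dendrogram of samples over a probe subset."""

    linkage_matrix: np.ndarray
    labels: pd.Series  # two-cluster assignment per sample
    perfect_split: bool | None  # None = inconclusive (degenerate tree)


def hierarchical_cluster_check(
    beta: pd.DataFrame, sheet: pd.DataFrame | None = None
) -> ClusterCheck:
    """Cluster samples (Euclidean, average linkage) on the given probes and
    report whether the two-cluster cut separates the cell fractions.

    With a degenerate tree (all merge heights ~0, e.g. identical samples)
    the split is reported as inconclusive (``perfect_split=None``).
    """
    if beta.shape[0] < 2:
        raise ContractError("need at least 2 probes to cluster on")
    if beta.shape[1] < 4:
        raise ContractError("need at least 4 samples")
    X = beta.to_numpy(dtype=float).T
    Z = linkage(X, method="average", metric="euclidean")
    labels = pd.Series(fcluster(Z, 2, criterion="maxclust"), index=beta.columns)
    if Z[:, 2].max() <= 1e-12 or labels.nunique() < 2:
        return ClusterCheck(Z, labels, None)
    perfect = None
    if sheet is not None:
        fractions = sheet.reindex(beta.columns)["cell_fraction"]
        tab = pd.crosstab(labels, fractions)
        # perfect: each cluster holds exactly one cell fraction
        perfect = bool((tab.astype(bool).sum(axis=1) == 1).all() and tab.shape[0] == 2)
    return ClusterCheck(Z, labels, perfect)
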