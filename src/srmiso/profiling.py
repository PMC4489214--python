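"""Shotgun NSAF profiling, expression clustering, and binding arithmetic.

NSAF (normalized spectral abundance factor): spectral counts are
length-normalized and scaled so each sample column sums to one.  An
optional pseudo-count keeps zero-count proteins representable on a log
scale.

Expression profiles across regions or conditions are compared by exact
Spearman correlation (full permutation enumeration of the null for small
profiles — eight brain regions enumerate in 8! = 40320 permutations) and
organized by agglomerative clustering with Ward's objective on either
the correlation distance (1 − Pearson r between row profiles) or the
Euclidean distance.

Binding-specificity profiling compares variant recovery on two affinity
matrices as log10 of parent-normalized ratios; the cell-adhesion readout
is background-subtracted bound/input absorbance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

#: which parent species a variant recovery is normalized to
DEFAULT_BINDING_PARENT_RULES = {
    "alpha": "pan",
    "beta": "pan",
    "AS4": "pan",
    "AS3": "alpha",
    "AS6": "alpha",
}


class ProfilingError(ValueError):
    pass


@dataclass
class SpectralCountTable:
    """Integer spectral counts (rows = proteins/groups, cols = samples)
    plus per-row residue lengths for NSAF normalization."""

    counts: pd.DataFrame
    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = [r for r in self.counts.index if r not in self.lengths]
        if missing:
            raise ProfilingError(f"lengths missing for row(s) {missing}")
        arr = self.counts.to_numpy()
        if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
            raise ProfilingError("spectral counts must be non-negative integers")


def nsaf(counts: SpectralCountTable | pd.DataFrame,
         lengths: Mapping[str, int] | None = None,
         pseudo_count: int = 0) -> pd.DataFrame:
    """Per-sample NSAF: ((SpC_i + pseudo)/L_i) / Σ_j ((SpC_j + pseudo)/L_j).

    Each sample column of the result sums to 1.
    """
    if isinstance(counts, SpectralCountTable):
        table, lengths = counts.counts, counts.lengths
    else:
        table = counts
        if lengths is None:
            raise ProfilingError("lengths required when passing a bare DataFrame")
    lens = pd.Series({r: lengths[r] for r in table.index}, dtype=float)
    if (lens <= 0).any():
        raise ProfilingError("lengths must be > 0")
    saf = table.add(pseudo_count).div(lens, axis=0)
    totals = saf.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ProfilingError(f"zero total abundance in sample(s) {list(zero.index)}")
    return saf.div(totals, axis=1)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def hier_cluster(matrix: pd.DataFrame, metric: str = "correlation",
                 linkage: str = "ward"):
    """Ward clustering of row profiles.

    ``metric='correlation'`` uses 1 − Pearson r between rows;
    ``metric='euclidean'`` uses raw distances.  Rows are pre-sorted by
    label so merge order is deterministic under row permutations.
    Returns ``(Z, leaf_labels, newick)`` where Z is the scipy linkage
    matrix over the sorted row order.
    """
    if matrix.shape[0] < 2:
        raise ProfilingError("need >= 2 rows to cluster")
    if matrix.isna().any().any():
        raise ProfilingError("matrix contains missing cells")
    matrix = matrix.loc[sorted(matrix.index.astype(str))]
    X = matrix.to_numpy(dtype=float)
    if metric == "correlation":
        const = matrix.index[X.std(axis=1) == 0]
        if len(const):
            raise ProfilingError(
                f"constant row(s) under correlation metric: {list(const)}"
            )
        dist = pdist(X, metric="correlation")
    elif metric == "euclidean":
        dist = pdist(X, metric="euclidean")
    else:
        raise ProfilingError(f"unsupported metric {metric!r}")
    if linkage != "ward":
        raise ProfilingError("only Ward linkage is supported")
    Z = hierarchy.linkage(dist, method="ward")
    labels = list(matrix.index.astype(str))
    order = hierarchy.leaves_list(Z)
    leaf_labels = [labels[i] for i in order]
    newick = _to_newick(Z, labels)
    return Z, leaf_labels, newick


def _to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = render(node.left), render(node.right)
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return render(tree) + ";"


# ---------------------------------------------------------------------------
# Spearman with exact small-n p-values
# ---------------------------------------------------------------------------

def spearman_profile(x: Sequence[float], y: Sequence[float],
                     exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    For n ≤ ``exact_max_n`` the p-value is exact: the proportion of the
    n! rank permutations of one profile whose |rho| is at least the
    observed |rho|.  Larger profiles use the t approximation.  Ties get
    midranks; a constant profile has no defined rank correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ProfilingError("profiles must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ProfilingError("need length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ProfilingError("constant profile: rank correlation undefined")
    rx = stats.rankdata(x)  # midranks
    ry = stats.rankdata(y)
    rho = float(stats.pearsonr(rx, ry).statistic)
    if n > exact_max_n:
        return rho, float(stats.spearmanr(x, y).pvalue)
    # exact null: permute the ranks of y
    cx = rx - rx.mean()
    denom_x = math.sqrt(float(cx @ cx))
    count = 0
    total = 0
    tol = 1e-12
    for perm in itertools.permutations(ry):
        py = np.asarray(perm) - ry.mean()
        r = float(cx @ py) / (denom_x * math.sqrt(float(py @ py)))
        if abs(r) >= abs(rho) - tol:
            count += 1
        total += 1
    return rho, count / total


# ---------------------------------------------------------------------------
# binding arithmetic
# ---------------------------------------------------------------------------

def _parent_label(variant_label: str, rules: Mapping[str, str]) -> str:
    gene, _, variant = variant_label.rpartition("-")
    key = variant.rstrip("+")
    if key not in rules:
        raise ProfilingError(f"no parent rule for variant {variant_label!r}")
    return f"{gene}-{rules[key]}"


def binding_ratio(recovery_a: Mapping[str, float], recovery_b: Mapping[str, float],
                  parent_rules: Mapping[str, str] | None = None,
                  variants: Sequence[str] | None = None) -> dict:
    """log10 of parent-normalized recovery ratios between two baits.

    For each variant v: log10( (v/parent)_a / (v/parent)_b ), with the
    parent chosen per rule (alpha/beta/AS4 -> pan; AS3/AS6 -> alpha).
    Labels are ``gene-variant`` (e.g. ``NRX1-AS3+``).  Antisymmetric in
    (a, b) by construction.
    """
    rules = parent_rules or DEFAULT_BINDING_PARENT_RULES
    if variants is None:
        variants = [
            lab for lab in recovery_a
            if lab.rpartition("-")[2].rstrip("+") in rules
        ]
    out = {}
    for lab in variants:
        parent = _parent_label(lab, rules)
        for cond, rec in (("a", recovery_a), ("b", recovery_b)):
            if rec.get(lab, 0) <= 0:
                raise ProfilingError(f"condition {cond}: variant {lab} not quantified (> 0)")
            if rec.get(parent, 0) <= 0:
                raise ProfilingError(f"condition {cond}: parent {parent} not quantified (> 0)")
        ra = recovery_a[lab] / recovery_a[parent]
        rb = recovery_b[lab] / recovery_b[parent]
        out[lab] = math.log10(ra / rb)
    return out


def adhesion_relative_binding(bound_a415: Sequence[float],
                              input_a415: Sequence[float],
                              background: float) -> float:
    """Background-subtracted bound/input absorbance ratio (triplicate
    means) from the bead-based cell-adhesion assay."""
    bound = float(np.mean(bound_a415))
    inp = float(np.mean(input_a415))
    if inp <= background:
        raise ProfilingError("input signal must exceed background")
    return (bound - background) / (inp - background)
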