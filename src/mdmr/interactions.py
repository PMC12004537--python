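"""Cluster-distinguishing residue–residue interactions via nSMD.

For each residue pair (i, j), the standardized mean difference between two
conformational clusters x and y,

    SMD_ij^{x|y} = (d̄_ij^x − d̄_ij^y) / σ_pooled,

with the Cohen's-d pooled sample standard deviation, quantifies the effect
size of that distance pair. To bias toward pairs that can actually form an
interaction, the SMD is normalized by the gap between the pair's minimum
distance over the compared structures and a normalization offset α:

    nSMD_ij = SMD_ij / (min(d_ij) − α).

α defaults to 1.5 Å, allowing for hydrogens that X-ray models usually lack;
set α = 0 for NMR ensembles or hydrogen-complete models. Pairs are selected
into R3 (formed in cluster y, nSMD > cutoff) or R1 (formed in cluster x,
nSMD < −cutoff) when their minimum distance also falls strictly inside an
interaction window (default 1.8–3.5 Å). Summing each structure's R1 and R3
distances places it on a two-axis conformational coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .representation import FeatureMatrix, MinDistanceMatrix

__all__ = [
    "NSMDTable",
    "InteractionSet",
    "smd",
    "nsmd",
    "nsmd_table",
    "select_interactions",
    "interaction_sums",
    "pair_distance_histogram",
    "NearCovalentError",
]

#: pairs with min distance within this margin of α are flagged near-covalent
DENOMINATOR_GUARD = 0.1


class NearCovalentError(ValueError):
    """Denominator min(d) − α is at or below the guard; nSMD undefined."""


def smd(dist_x: np.ndarray, dist_y: np.ndarray, pooling: str = "cohen") -> float:
    """Standardized mean difference (d̄x − d̄y) / σ_pooled.

    ``pooling="cohen"`` uses the (N−1)-weighted pooled sample SD;
    ``pooling="average"`` uses the unweighted mean of the two variances.
    A zero pooled SD returns 0 for equal means and a signed infinity
    otherwise (callers flag and exclude such pairs).
    """
    x = np.asarray(dist_x, dtype=float)
    y = np.asarray(dist_y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"need at least 2 samples per cluster, got {nx}, {ny}")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if pooling == "cohen":
        pooled = math.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    elif pooling == "average":
        pooled = math.sqrt((vx + vy) / 2.0)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    if pooled == 0.0:
        if mx == my:
            return 0.0
        return math.inf if mx > my else -math.inf
    return (mx - my) / pooled


def nsmd(smd_value: float, min_distance: float, alpha: float = 1.5,
         guard: float = DENOMINATOR_GUARD) -> float:
    """Normalize an SMD by (min pair distance − α).

    Raises :class:`NearCovalentError` when the denominator is at or below
    the guard (e.g. sequence-adjacent residues joined by the ~1.33 Å
    peptide bond), where the statistic is undefined or sign-flipped.
    """
    denom = min_distance - alpha
    if denom <= guard:
        raise NearCovalentError(
            f"min distance {min_distance:.3f} Å within guard of α={alpha}")
    return smd_value / denom


@dataclass
class NSMDTable:
    """Per-pair SMD/nSMD between two clusters, as a tidy DataFrame.

    Columns: pair, mean_x, sd_x, n_x, mean_y, sd_y, n_y, smd, min_dist,
    nsmd, near_covalent. The (x|y) orientation is recorded so downstream
    selection knows which cluster positive values point to.
    """

    table: pd.DataFrame
    cluster_x: int
    cluster_y: int
    alpha: float
    pooling: str = "cohen"


@dataclass
class InteractionSet:
    """Selected residue pairs with the thresholds that selected them."""

    label: str  # "R1" or "R3"
    pairs: list[str] = field(default_factory=list)
    nsmd_cutoff: float = 5.0
    window: tuple[float, float] = (1.8, 3.5)

    def __contains__(self, pair: str) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def nsmd_table(features: FeatureMatrix, labels: np.ndarray,
               cluster_x: int, cluster_y: int, alpha: float = 1.5,
               pooling: str = "cohen") -> NSMDTable:
    """Compute SMD and nSMD for every pair feature between two clusters.

    ``labels`` aligns with ``features.ids``. The minimum pair distance is
    taken over the union of the two compared clusters' structures. Pairs
    whose denominator falls inside the near-covalent guard get
    ``nsmd = NaN`` and ``near_covalent = True``; selection skips them.
    """
    labels = np.asarray(labels)
    ix = np.flatnonzero(labels == cluster_x)
    iy = np.flatnonzero(labels == cluster_y)
    if len(ix) < 2 or len(iy) < 2:
        raise ValueError("each compared cluster needs at least 2 structures")
    X = features.X
    rows = []
    for j, pair in enumerate(features.labels):
        dx, dy = X[ix, j], X[iy, j]
        s = smd(dx, dy, pooling=pooling)
        mind = float(min(dx.min(), dy.min()))
        try:
            val = nsmd(s, mind, alpha=alpha) if math.isfinite(s) else math.nan
            near = False
        except NearCovalentError:
            val, near = math.nan, True
        rows.append({
            "pair": pair,
            "mean_x": dx.mean(), "sd_x": dx.std(ddof=1), "n_x": len(dx),
            "mean_y": dy.mean(), "sd_y": dy.std(ddof=1), "n_y": len(dy),
            "smd": s, "min_dist": mind, "nsmd": val, "near_covalent": near,
        })
    return NSMDTable(table=pd.DataFrame(rows), cluster_x=cluster_x,
                     cluster_y=cluster_y, alpha=alpha, pooling=pooling)


def select_interactions(table: NSMDTable, nsmd_cutoff: float = 5.0,
                        window: tuple[float, float] = (1.8, 3.5),
                        ) -> tuple[InteractionSet, InteractionSet]:
    """Select the R1 and R3 interaction sets from an nSMD table.

    With the table oriented x = inactive-like, y = active-like: pairs with
    nSMD > cutoff and minimum distance strictly inside the window form in
    cluster y (R3); pairs with nSMD < −cutoff form in cluster x (R1). All
    inequalities are strict. Near-covalent and infinite-SMD pairs are never
    selected.
    """
    lo, hi = window
    t = table.table
    ok = (~t["near_covalent"]) & np.isfinite(t["nsmd"]) \
        & (t["min_dist"] > lo) & (t["min_dist"] < hi)
    r3 = t.loc[ok & (t["nsmd"] > nsmd_cutoff), "pair"].tolist()
    r1 = t.loc[ok & (t["nsmd"] < -nsmd_cutoff), "pair"].tolist()
    return (InteractionSet("R1", r1, nsmd_cutoff, window),
            InteractionSet("R3", r3, nsmd_cutoff, window))


def interaction_sums(matrix: MinDistanceMatrix, r1: InteractionSet,
                     r3: InteractionSet) -> tuple[float, float]:
    """Sum a structure's distances over the R1 and R3 pair sets (Å)."""
    from .representation import pair_labels

    labels = pair_labels(matrix.keys)
    n = len(matrix.keys)
    iu = np.triu_indices(n, k=1)
    flat = dict(zip(labels, matrix.D[iu]))
    sums = []
    for s in (r1, r3):
        total = 0.0
        for p in s.pairs:
            if p not in flat:
                raise KeyError(f"pair {p} absent from matrix {matrix.structure_id}")
            total += float(flat[p])
        sums.append(total)
    return sums[0], sums[1]


def pair_distance_histogram(distances: np.ndarray, labels: np.ndarray,
                            bin_width: float = 0.25,
                            ) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Histogram one pair's distances per cluster over shared bins.

    Returns (bin edges, {cluster label: counts}). Noise (−1) structures are
    excluded. Counts per cluster sum to that cluster's structure count.
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    keep = labels >= 0
    d, l = distances[keep], labels[keep]
    if d.size == 0:
        raise ValueError("no clustered structures to histogram")
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts = {int(c): np.histogram(d[l == c], bins=edges)[0]
              for c in sorted(set(l.tolist()))}
    return edges, counts
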