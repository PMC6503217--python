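"""The continuum-vs-cluster analysis.

Pairs of genomes carry three numbers — ANI (%), genome coverage (%), and
genetic distance (substitutions/site) — and this module asks whether those
pairs form discrete genomic clusters or a continuum: rank correlations
between the measures, threshold-based cluster calling (ANI > ani_min AND
Gcov > gcov_min, strict inequalities, single-linkage components), and a
sliding-window smoothed ANI-vs-distance profile with saturation detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .io_core import DistanceMatrix, get_logger

_log = get_logger("cluster_diagnostics")


@dataclass
class PairRecord:
    genome_a: str
    genome_b: str
    ani_pct: float
    gcov_pct: float
    genetic_distance: float
    same_clade: bool | None = None


def pair_table(
    ani: pd.DataFrame, gcov: pd.DataFrame, distance: DistanceMatrix, clade_of: dict[str, str] | None = None
) -> list[PairRecord]:
    """One record per unordered genome pair, joining the three measures."""
    labels = sorted(ani.index)
    if sorted(gcov.index) != labels or sorted(distance.labels) != labels:
        raise ValueError("matrices are not aligned on the same labels")
    out = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            out.append(
                PairRecord(
                    a,
                    b,
                    float(ani.loc[a, b]),
                    float(gcov.loc[a, b]),
                    distance.get(a, b),
                    (clade_of[a] == clade_of[b]) if clade_of else None,
                )
            )
    return out


def spearman(x, y, exact_permutation: bool = False) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with its p-value.

    The p-value comes from the t approximation on n-2 df; with
    ``exact_permutation`` (n <= 10) it is the exact two-sided permutation
    probability instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    rho, p = scipy.stats.spearmanr(x, y)
    if exact_permutation:
        n = len(x)
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        ry = scipy.stats.rankdata(y)
        obs = abs(rho)
        count = 0
        total = 0
        rx = scipy.stats.rankdata(x)
        for perm in permutations(range(n)):
            r, _ = scipy.stats.pearsonr(rx, ry[list(perm)])
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        p = count / total
    return float(rho), float(p)


@dataclass
class ClusterCall:
    clusters: dict[str, frozenset]  # cluster_id -> genome ids (singletons included)
    ani_min: float
    gcov_min: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def n_multi(self) -> int:
        return sum(1 for c in self.clusters.values() if len(c) > 1)

    def assignment(self) -> dict[str, str]:
        return {g: cid for cid, members in self.clusters.items() for g in members}


def call_clusters(
    ani: pd.DataFrame, gcov: pd.DataFrame, ani_min: float = 96.0, gcov_min: float = 90.0
) -> ClusterCall:
    """Genomic clusters: connected components of the graph with an edge for
    every pair with ANI > ani_min AND Gcov > gcov_min (strict)."""
    for t in (ani_min, gcov_min):
        if not 0 <= t <= 100:
            raise ValueError("thresholds must be within [0, 100]")
    labels = list(ani.index)
    if list(gcov.index) != labels:
        raise ValueError("ANI and Gcov matrices are not aligned")
    g = nx.Graph()
    g.add_nodes_from(labels)
    a = ani.to_numpy()
    c = gcov.to_numpy()
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if a[i, j] > ani_min and c[i, j] > gcov_min:
                g.add_edge(labels[i], labels[j])
    comps = sorted((frozenset(c) for c in nx.connected_components(g)), key=lambda s: min(s))
    width = max(2, len(str(len(comps))))
    clusters = {f"GC{i + 1:0{width}d}": comp for i, comp in enumerate(comps)}
    _log.info(
        "call_clusters: ANI>%.1f & Gcov>%.1f -> %d clusters (%d multi-genome)",
        ani_min, gcov_min, len(clusters), sum(1 for x in comps if len(x) > 1),
    )
    return ClusterCall(clusters, ani_min, gcov_min)


@dataclass
class ContinuumProfile:
    window_centers: np.ndarray
    mean_ani: np.ndarray
    n_pairs: np.ndarray
    slopes: np.ndarray
    saturated: np.ndarray  # |local slope| < 10% of the initial slope magnitude

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance": self.window_centers,
                "mean_ani": self.mean_ani,
                "n_pairs": self.n_pairs,
                "slope": self.slopes,
                "saturated": self.saturated,
            }
        )


def continuum_profile(pairs: list[PairRecord], window: float = 0.005) -> ContinuumProfile:
    """Sliding-window mean ANI along genetic distance.

    Windows of the stated width step by half a window; the local slope is a
    finite difference of the smoothed curve, and windows where its
    magnitude falls below 10% of the initial slope magnitude are flagged
    saturated (the correlation's asymptote).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs")
    d = np.array([p.genetic_distance for p in pairs])
    a = np.array([p.ani_pct for p in pairs])
    lo, hi = float(d.min()), float(d.max())
    step = window / 2.0
    starts = np.arange(lo, max(hi - window, lo) + step / 2, step)
    centers, means, counts = [], [], []
    for s in starts:
        mask = (d >= s) & (d < s + window)
        if s + window >= hi:  # last window closed on the right
            mask = (d >= s) & (d <= s + window)
        if mask.any():
            centers.append(s + window / 2.0)
            means.append(float(a[mask].mean()))
            counts.append(int(mask.sum()))
    centers = np.array(centers)
    means = np.array(means)
    counts = np.array(counts, dtype=int)
    if len(centers) > 1:
        slopes = np.gradient(means, centers)
    else:
        slopes = np.zeros(len(centers))
    initial = abs(slopes[0]) if len(slopes) else 0.0
    saturated = np.abs(slopes) < 0.1 * initial if initial > 0 else np.ones(len(slopes), dtype=bool)
    return ContinuumProfile(centers, means, counts, slopes, saturated)
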