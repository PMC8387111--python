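"""Second-level (across-subject) nonparametric inference.

Decoding and encoding analyses yield one effect estimate per subject (a
score timecourse, a TG matrix...), tested against chance level 0 across
subjects with a Wilcoxon signed-rank test (single estimates) or a
cluster-based sign-flip permutation test (repeated measurements over
time or time x time grids).

The cluster test forms a one-sample t statistic at every point,
thresholds it at the two-tailed cluster-forming quantile, groups
suprathreshold points into contiguous clusters (1-D runs or 4-connected
2-D patches), and summarizes each cluster by its mass (sum of t).  The
null distribution of the maximum absolute cluster mass is built by
randomly sign-flipping whole subjects, which is exchangeable under the
null of a symmetric effect distribution centred on 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps

__all__ = [
    "wilcoxon_vs_chance",
    "Cluster",
    "ClusterResult",
    "cluster_permutation",
    "score_vs_distance_slope",
]


def wilcoxon_vs_chance(effects: np.ndarray) -> float:
    """Two-tailed Wilcoxon signed-rank p-value of subject effects vs 0.

    Requires at least five nonzero subject differences; all-zero input is
    undefined.
    """
    eff = np.asarray(effects, dtype=float).ravel()
    nz = eff[eff != 0]
    if nz.size < 5:
        raise ValueError("need >= 5 nonzero subject effects")
    return float(sps.wilcoxon(eff[eff != 0], alternative="two-sided").pvalue)


@dataclass(frozen=True)
class Cluster:
    """One suprathreshold cluster: member indices, mass, p-value."""

    indices: tuple[np.ndarray, ...]
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_obs: np.ndarray
    threshold: float
    n_permutations: int
    seed: int
    excluded: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_jsonable(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "clusters": [
                {
                    "mass": c.mass,
                    "p_value": c.p_value,
                    "n_points": int(len(c.indices[0])),
                }
                for c in self.clusters
            ],
        }


def _t_map(effects: np.ndarray) -> np.ndarray:
    n = effects.shape[0]
    mean = effects.mean(axis=0)
    sd = effects.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return mean / (sd / np.sqrt(n))


def _cluster_masses(t: np.ndarray, threshold: float) -> tuple[list, np.ndarray]:
    """Positive and negative clusters of a thresholded map."""
    clusters = []
    masses = []
    structure = ndimage.generate_binary_structure(t.ndim, 1)
    for sign in (1.0, -1.0):
        mask = (sign * t) > threshold
        labels, n = ndimage.label(mask, structure=structure)
        for lab in range(1, n + 1):
            idx = np.nonzero(labels == lab)
            mass = float(t[idx].sum())
            clusters.append(idx)
            masses.append(mass)
    return clusters, np.asarray(masses)


def cluster_permutation(
    effects: np.ndarray,
    adjacency: str = "time",
    alpha_cluster: float = 0.05,
    n_perm: int = 1024,
    seed: int = 0,
) -> ClusterResult:
    """One-sample spatiotemporal cluster test by subject sign flips.

    ``effects`` is subjects x time (``adjacency="time"``) or subjects x
    train-time x test-time (``adjacency="grid"``, 4-connected).  The
    cluster-forming threshold is the two-tailed t quantile at
    ``alpha_cluster``; cluster mass is the sum of t inside the cluster;
    the two-tailed family-wise p-value of each cluster is
    ``(1 + #{null max |mass| >= |observed mass|}) / (1 + n_perm)`` with
    the null built from random whole-subject sign flips.

    Points with degenerate (zero) variance across subjects are excluded
    with a warning.
    """
    effects = np.asarray(effects, dtype=float)
    if adjacency not in ("time", "grid"):
        raise ValueError("adjacency must be 'time' or 'grid'")
    want_dim = 2 if adjacency == "time" else 3
    if effects.ndim != want_dim:
        raise ValueError(f"effects must be {want_dim}-dimensional for {adjacency!r}")
    n_sub = effects.shape[0]
    if n_sub < 5:
        raise ValueError("need >= 5 subjects for permutation inference")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    degenerate = effects.std(axis=0) == 0
    if degenerate.any():
        warnings.warn(
            f"excluding {int(degenerate.sum())} degenerate-variance points",
            RuntimeWarning,
            stacklevel=2,
        )
        effects = effects.copy()
        # neutralize: zero effect, cannot exceed threshold
        effects[:, degenerate] = 0.0
        effects[0, degenerate] = np.finfo(float).tiny

    threshold = float(sps.t.ppf(1 - alpha_cluster / 2, df=n_sub - 1))
    t_obs = _t_map(effects)
    t_obs = np.nan_to_num(t_obs, nan=0.0)
    idx_list, masses = _cluster_masses(t_obs, threshold)

    rng = np.random.default_rng(seed)
    flat = effects.reshape(n_sub, -1)
    shape = effects.shape[1:]
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        t_p = np.nan_to_num(_t_map(flat * signs[:, None]).reshape(shape), nan=0.0)
        _, m = _cluster_masses(t_p, threshold)
        null_max[p] = np.abs(m).max() if m.size else 0.0

    clusters = [
        Cluster(
            indices=idx,
            mass=float(mass),
            p_value=float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm)),
        )
        for idx, mass in zip(idx_list, masses)
    ]
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(
        clusters=clusters,
        t_obs=t_obs,
        threshold=threshold,
        n_permutations=n_perm,
        seed=seed,
        excluded=degenerate,
    )


def score_vs_distance_slope(scores: np.ndarray, distances: np.ndarray):
    """Per-subject OLS slope of decoding score on stimulus distance.

    ``scores`` is (subjects, positions) — e.g. the per-position peak
    decoding scores — and ``distances`` the stimulus distance (number of
    intervening items) per position.  Returns the subject slopes and the
    Wilcoxon p-value of the slopes against 0 (NaN when fewer than five
    subjects).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    d = np.asarray(distances, dtype=float)
    if d.size < 3:
        raise ValueError("need >= 3 positions")
    if np.ptp(d) == 0:
        raise ValueError("distances are constant")
    dc = d - d.mean()
    slopes = (scores - scores.mean(axis=1, keepdims=True)) @ dc / (dc @ dc)
    try:
        p = wilcoxon_vs_chance(slopes)
    except ValueError:
        p = float("nan")
    return slopes, p
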