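"""k-means clustering of sub-transcripts and cluster-number selection.

Each dyad's standardized profile matrix is partitioned with k-means
(Lloyd's algorithm, k-means++ initialization, best of ``n_restarts``
random restarts).  *Distortion* is the k-means objective: the total
squared Euclidean distance between rows and their assigned cluster
centers (it reaches zero when k equals the number of rows).  The
number of clusters is chosen from an elbow scan: distortion is
computed for k = k_min..k_max and the elbow is operationalized as the
k with the largest discrete second difference d(k-1) - 2 d(k) + d(k+1)
(maximum curvature of the distortion curve).  Published analyses often
pick the elbow visually; where visual judgment disagrees, the chosen k
can be overridden explicitly, and an exhaustive partition-enumeration
oracle is provided to verify optimality on small instances.

A 2-D principal-component projection supports visual validation of a
clustering solution.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import DegeneracyError
from .profiles import ProfileMatrix, RowLabel, format_label

logger = logging.getLogger(__name__)

DEFAULT_N_RESTARTS = 50
DEFAULT_SEED = 0
MAX_LLOYD_ITER = 300

#: Relative curvature below which an elbow scan is considered flat
#: (no clear elbow): max second difference under 5% of the total
#: distortion drop across the scan.
FLAT_CURVATURE_FRACTION = 0.05


@dataclass(frozen=True)
class ClusteringSolution:
    """One fitted k-means solution on a dyad's profile matrix."""

    dyad_id: str
    k: int
    assignments: dict[RowLabel, int]
    centers: np.ndarray  # (k, 4) in the matrix's units
    distortion: float
    seed: int
    n_restarts: int

    def cluster_of(self, role: str, session_index: int) -> int:
        return self.assignments[(role, session_index)]


@dataclass(frozen=True)
class ElbowScan:
    """Distortion across a range of k with the elbow-selected k."""

    k_values: tuple[int, ...]
    distortions: tuple[float, ...]
    chosen_k: int
    flat: bool = False  # no clear elbow (low curvature everywhere)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "distortion": self.distortions})


@dataclass(frozen=True)
class ProjectionResult:
    """Top-2 principal-component coordinates of the matrix rows."""

    labels: tuple[RowLabel, ...]
    coordinates: np.ndarray  # (n_rows, 2)
    explained_variance_fractions: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [format_label(r, s) for r, s in self.labels],
                "pc1": self.coordinates[:, 0],
                "pc2": self.coordinates[:, 1],
            }
        )


def kmeans_fit(
    matrix: ProfileMatrix,
    k: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = DEFAULT_SEED,
) -> ClusteringSolution:
    """Best-of-restarts k-means on the matrix rows.

    Deterministic given ``seed``.  Lloyd iterations run to the
    assignment fixpoint or 300 iterations per restart.
    """
    n = matrix.n_rows
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        init="k-means++",
        max_iter=MAX_LLOYD_ITER,
        tol=0.0,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # duplicate rows can make fewer distinct optima than restarts
        warnings.filterwarnings("ignore", message=".*distinct clusters.*")
        km.fit(matrix.values)
    assignments = {lab: int(c) for lab, c in zip(matrix.labels, km.labels_)}
    return ClusteringSolution(
        dyad_id=matrix.dyad_id,
        k=k,
        assignments=assignments,
        centers=km.cluster_centers_.copy(),
        distortion=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def _partitions_into_k(n: int, k: int):
    """All set partitions of range(n) into exactly k non-empty blocks.

    Restricted-growth-string enumeration; first point is always in
    block 0, so label permutations are not revisited.
    """
    codes = [0] * n

    def rec(i: int, max_used: int):
        if i == n:
            if max_used + 1 == k:
                yield tuple(codes)
            return
        for c in range(min(max_used + 1, k - 1) + 1):
            codes[i] = c
            yield from rec(i + 1, max(max_used, c))

    yield from rec(1, 0) if n > 1 else iter([(0,)] if k == 1 else [])


def brute_force_kmeans(
    matrix: ProfileMatrix, k: int
) -> tuple[dict[RowLabel, int], float]:
    """Exact global k-means optimum by exhaustive partition enumeration.

    Scores every partition of the rows into k non-empty groups by its
    within-group sum of squares about group means.  Test oracle only:
    refuses instances above 10 rows or k above 3.
    """
    n = matrix.n_rows
    if n > 10 or k > 3:
        raise ValueError(f"brute force capped at 10 rows / k<=3, got n={n}, k={k}")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    X = matrix.values
    best_codes: tuple[int, ...] | None = None
    best_ss = np.inf
    for codes in _partitions_into_k(n, k):
        ss = 0.0
        arr = np.asarray(codes)
        for c in range(k):
            block = X[arr == c]
            ss += float(((block - block.mean(axis=0)) ** 2).sum())
        if ss < best_ss:
            best_ss = ss
            best_codes = codes
    assert best_codes is not None
    return (
        {lab: c for lab, c in zip(matrix.labels, best_codes)},
        best_ss,
    )


def choose_elbow(
    k_values: Sequence[int], distortions: Sequence[float]
) -> tuple[int, bool]:
    """Select the elbow k from a distortion scan.

    Returns ``(chosen_k, flat)``: the interior k maximizing the discrete
    second difference of the distortion curve (ties to the smallest k),
    and whether the scan is flat — max curvature at or below
    :data:`FLAT_CURVATURE_FRACTION` of the total distortion drop, as
    happens with a linear (elbow-less) decay.
    """
    if len(k_values) < 3:
        raise ValueError("need at least 3 k values for an elbow")
    d = np.asarray(distortions, dtype=float)
    curvature = d[:-2] - 2 * d[1:-1] + d[2:]
    chosen_k = int(k_values[int(np.argmax(curvature)) + 1])
    total_drop = d[0] - d[-1]
    flat = bool(curvature.max() <= FLAT_CURVATURE_FRACTION * max(total_drop, 1e-12))
    return chosen_k, flat


def elbow_scan(
    matrix: ProfileMatrix,
    k_min: int = 1,
    k_max: int = 10,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = DEFAULT_SEED,
) -> ElbowScan:
    """Distortion scan over k with elbow selection by maximum curvature.

    ``k_max`` is capped at n_rows - 1.  The chosen k is the interior k
    maximizing the second forward difference of the distortion curve;
    ties go to the smallest k.  A flat scan (max curvature below 5% of
    the total distortion drop) is flagged and triggers a warning, since
    the co-membership measure is then poorly identified.
    """
    n = matrix.n_rows
    k_max = min(k_max, n - 1)
    if k_max < k_min + 2:
        raise ValueError(
            f"need at least 3 k values for an elbow, got {k_min}..{k_max}"
        )
    k_values = list(range(k_min, k_max + 1))
    distortions = [
        kmeans_fit(matrix, k, n_restarts, seed).distortion for k in k_values
    ]

    # restart underspend can produce a non-monotone sequence; repair by
    # re-running the offending k with 5x restarts
    for i in range(1, len(k_values)):
        if distortions[i] > distortions[i - 1] + 1e-12:
            warnings.warn(
                f"distortion increased at k={k_values[i]}; "
                f"re-running with {5 * n_restarts} restarts",
                stacklevel=2,
            )
            distortions[i] = min(
                distortions[i - 1],
                kmeans_fit(matrix, k_values[i], 5 * n_restarts, seed).distortion,
            )

    chosen_k, flat = choose_elbow(k_values, distortions)
    if flat:
        warnings.warn(
            "no clear elbow (flat curvature); inspect the elbow plot and "
            "consider overriding k",
            stacklevel=2,
        )
    return ElbowScan(tuple(k_values), tuple(distortions), chosen_k, flat)


def cluster_centers_table(
    solution: ClusteringSolution, matrix: ProfileMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster variable means plus pairwise center distances.

    Returns ``(centers, separations)``: a k x 4 table of the mean score
    of each variable among cluster members (in the matrix's units), and
    the k x k Euclidean distances between centers as a separation
    diagnostic.
    """
    lab_to_cluster = solution.assignments
    clusters = np.array([lab_to_cluster[lab] for lab in matrix.labels])
    means = np.vstack(
        [matrix.values[clusters == c].mean(axis=0) for c in range(solution.k)]
    )
    centers = pd.DataFrame(
        means,
        columns=list(matrix.variables),
        index=[f"cluster_{c}" for c in range(solution.k)],
    )
    diff = means[:, None, :] - means[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    separations = pd.DataFrame(dist, index=centers.index, columns=centers.index)
    return centers, separations


def pca_project(matrix: ProfileMatrix) -> ProjectionResult:
    """Project rows onto the top-2 principal components.

    Sign convention: within each component, the largest-magnitude
    loading is made positive, so projections are reproducible across
    numerical backends.
    """
    if matrix.n_rows < 3:
        raise ValueError("PCA projection needs at least 3 rows")
    centered = matrix.values - matrix.values.mean(axis=0)
    if np.linalg.matrix_rank(centered) < 2:
        raise DegeneracyError("profile matrix has rank < 2; cannot project to 2-D")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(matrix.values)
    for j in range(2):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, j] = -coords[:, j]
    evf = pca.explained_variance_ratio_
    return ProjectionResult(
        labels=matrix.labels,
        coordinates=coords,
        explained_variance_fractions=(float(evf[0]), float(evf[1])),
    )


def save_elbow_plot(scan: ElbowScan, path: str | Path) -> None:
    """Write the elbow plot (distortion vs k) as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(scan.k_values, scan.distortions, marker="o")
    ax.axvline(scan.chosen_k, color="crimson", linestyle="--", label=f"k = {scan.chosen_k}")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("distortion")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_projection_plot(
    projection: ProjectionResult,
    solution: ClusteringSolution,
    path: str | Path,
) -> None:
    """Scatter the 2-D projection, colored by cluster, annotated by label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    clusters = np.array([solution.assignments[lab] for lab in projection.labels])
    cmap = plt.get_cmap("tab10")
    for c in sorted(set(clusters)):
        mask = clusters == c
        ax.scatter(
            projection.coordinates[mask, 0],
            projection.coordinates[mask, 1],
            color=cmap(c % 10),
            label=f"cluster {c}",
            s=25,
        )
    for (role, s), (x, y) in zip(projection.labels, projection.coordinates):
        ax.annotate(format_label(role, s), (x, y), fontsize=7, alpha=0.8)
    evf = projection.explained_variance_fractions
    ax.set_xlabel(f"PC1 ({100 * evf[0]:.1f}% var)")
    ax.set_ylabel(f"PC2 ({100 * evf[1]:.1f}% var)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
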