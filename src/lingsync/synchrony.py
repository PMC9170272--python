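"""Session-level synchrony outcomes from a clustering solution.

The co-membership rule: session x is *synchronized* iff the therapist
sub-transcript T_x and the client sub-transcript C_x fall into the same
cluster — their language that session is more alike than either is to
the dyad's other sessions.  A dyad's outcomes are (i) which sessions
are (a)synchronized, (ii) the percentage of synchronized sessions, and
(iii) the temporal distribution (run structure) of synchrony across the
treatment span.  All outcomes are invariant under relabelling clusters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .clustering import (
    DEFAULT_N_RESTARTS,
    DEFAULT_SEED,
    ClusteringSolution,
    ElbowScan,
    ProjectionResult,
    cluster_centers_table,
    elbow_scan,
    kmeans_fit,
    pca_project,
)
from .errors import ConsistencyError
from .profiles import ProfileMatrix, mean_center_by_speaker, zscore
from .transcripts import CLIENT, THERAPIST


@dataclass(frozen=True)
class SynchronyOutcome:
    """Per-session synchrony flags and summary measures for one dyad."""

    dyad_id: str
    session_flags: tuple[bool, ...]  # index 0 = session 1
    k: int
    degenerate: bool = False  # k == 1: co-membership is uninformative

    @property
    def n_sessions(self) -> int:
        return len(self.session_flags)

    @property
    def synchronized_sessions(self) -> list[int]:
        return [i + 1 for i, f in enumerate(self.session_flags) if f]

    @property
    def percentage(self) -> float:
        return 100.0 * sum(self.session_flags) / self.n_sessions

    @property
    def runs(self) -> list[tuple[int, int, bool]]:
        """Run-length encoding of the flags: (start_session, length, flag)."""
        runs: list[tuple[int, int, bool]] = []
        start = 0
        for i in range(1, self.n_sessions + 1):
            if i == self.n_sessions or self.session_flags[i] != self.session_flags[start]:
                runs.append((start + 1, i - start, self.session_flags[start]))
                start = i
        return runs


def session_synchrony(
    solution: ClusteringSolution, n_sessions: int
) -> SynchronyOutcome:
    """Apply the co-membership rule session by session."""
    missing = [
        x
        for x in range(1, n_sessions + 1)
        if (THERAPIST, x) not in solution.assignments
        or (CLIENT, x) not in solution.assignments
    ]
    if missing:
        raise ConsistencyError(
            f"clustering solution lacks both roles for sessions {missing}"
        )
    flags = tuple(
        solution.assignments[(THERAPIST, x)] == solution.assignments[(CLIENT, x)]
        for x in range(1, n_sessions + 1)
    )
    degenerate = solution.k == 1
    if degenerate:
        warnings.warn(
            "k = 1: every session is trivially synchronized; the synchrony "
            "percentage is uninformative — inspect the elbow plot",
            stacklevel=2,
        )
    return SynchronyOutcome(
        dyad_id=solution.dyad_id,
        session_flags=flags,
        k=solution.k,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class DistributionSummary:
    """Temporal structure of (a)synchrony across the treatment span."""

    runs: list[tuple[int, int, bool]]
    longest_synchronized_block: int
    first_synchronized: int | None
    last_synchronized: int | None
    text: str


def distribution_summary(outcome: SynchronyOutcome) -> DistributionSummary:
    """Run-length view of the synchrony flags plus a human-readable line."""
    runs = outcome.runs
    sync_sessions = outcome.synchronized_sessions
    longest = max((length for _, length, f in runs if f), default=0)
    first = sync_sessions[0] if sync_sessions else None
    last = sync_sessions[-1] if sync_sessions else None
    pieces = [
        f"{'sync' if f else 'async'} x{length} from session {start}"
        for start, length, f in runs
    ]
    text = (
        f"dyad {outcome.dyad_id}: {len(sync_sessions)}/{outcome.n_sessions} "
        f"sessions synchronized ({outcome.percentage:.1f}%); " + "; ".join(pieces)
    )
    return DistributionSummary(runs, longest, first, last, text)


@dataclass(frozen=True)
class DyadAnalysis:
    """All artifacts of the session-synchrony pipeline for one dyad."""

    matrix: ProfileMatrix  # preprocessed matrix the clustering ran on
    elbow: ElbowScan
    solution: ClusteringSolution
    outcome: SynchronyOutcome
    projection: ProjectionResult | None
    config: dict[str, Any] = field(default_factory=dict)


def analyze_dyad(
    matrix: ProfileMatrix,
    k: int | None = None,
    k_min: int = 1,
    k_max: int = 10,
    n_restarts: int = DEFAULT_N_RESTARTS,
    seed: int = DEFAULT_SEED,
    standardize: bool = True,
    mean_center: bool = False,
) -> DyadAnalysis:
    """Run the full pipeline on a raw profile matrix.

    Preprocess (optional per-speaker mean-centering, then z-scoring),
    scan for the elbow k (unless ``k`` overrides it), cluster with
    best-of-restarts k-means, and apply the co-membership rule.
    """
    work = matrix
    if mean_center and not work.centered:
        work = mean_center_by_speaker(work)
    if standardize and not work.standardized:
        work = zscore(work)

    scan = elbow_scan(work, k_min=k_min, k_max=k_max, n_restarts=n_restarts, seed=seed)
    chosen_k = k if k is not None else scan.chosen_k
    solution = kmeans_fit(work, chosen_k, n_restarts=n_restarts, seed=seed)
    outcome = session_synchrony(solution, work.n_sessions)
    projection = pca_project(work) if work.n_rows >= 3 else None

    config = {
        "k_override": k,
        "k": chosen_k,
        "k_min": k_min,
        "k_max": k_max,
        "n_restarts": n_restarts,
        "seed": seed,
        "standardize": standardize,
        "mean_center": mean_center,
    }
    return DyadAnalysis(work, scan, solution, outcome, projection, config)


def _round(x: float, nd: int = 10) -> float:
    return round(float(x), nd)


def build_report(
    outcome: SynchronyOutcome,
    centers: "Sequence[Sequence[float]] | np.ndarray | None" = None,
    elbow: ElbowScan | None = None,
    projection: ProjectionResult | None = None,
    config: dict[str, Any] | None = None,
    dyad_id: str | None = None,
) -> dict[str, Any]:
    """Assemble the machine-readable synchrony report for one dyad.

    All floats are rounded to 10 decimals so that identical inputs and
    configuration produce byte-identical serialized reports.
    """
    if dyad_id is not None and dyad_id != outcome.dyad_id:
        raise ConsistencyError(
            f"report parts disagree on dyad: {dyad_id!r} vs {outcome.dyad_id!r}"
        )
    report: dict[str, Any] = {
        "dyad_id": outcome.dyad_id,
        "n_sessions": outcome.n_sessions,
        "k": outcome.k,
        "degenerate_k1": outcome.degenerate,
        "flags": [bool(f) for f in outcome.session_flags],
        "synchronized_sessions": outcome.synchronized_sessions,
        "percentage": _round(outcome.percentage, 1),
        "runs": [
            {"start_session": s, "length": n, "synchronized": bool(f)}
            for s, n, f in outcome.runs
        ],
        "distribution": distribution_summary(outcome).text,
    }
    if centers is not None:
        report["centers"] = [[_round(v) for v in row] for row in np.asarray(centers)]
    if elbow is not None:
        report["elbow"] = {
            "k": list(elbow.k_values),
            "distortion": [_round(d) for d in elbow.distortions],
            "chosen_k": elbow.chosen_k,
            "flat": elbow.flat,
        }
    if projection is not None:
        report["projection"] = {
            "labels": [f"{'T' if r == THERAPIST else 'C'}{s}" for r, s in projection.labels],
            "coordinates": [[_round(v) for v in row] for row in projection.coordinates],
            "explained_variance_fractions": [
                _round(v) for v in projection.explained_variance_fractions
            ],
        }
    if config is not None:
        report["config"] = dict(sorted(config.items()))
    return report


def report_from_analysis(analysis: DyadAnalysis) -> dict[str, Any]:
    """Report with centers/elbow/projection taken from a pipeline run."""
    centers, _ = cluster_centers_table(analysis.solution, analysis.matrix)
    return build_report(
        analysis.outcome,
        centers=centers.to_numpy(),
        elbow=analysis.elbow,
        projection=analysis.projection,
        config=analysis.config,
    )


def serialize_report(report: dict[str, Any]) -> str:
    """Deterministic JSON serialization (sorted keys, fixed layout)."""
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
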