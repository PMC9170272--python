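"""Per-dyad profile matrices and preprocessing.

The clustering input for one dyad is a (2n × 4) matrix of summary
variable scores: one row per sub-transcript, ordered C1..Cn then
T1..Tn.  Before clustering, each variable is converted to a z-score
over the dyad's pooled 2n rows, so that cluster centers read as
"standard deviations above/below this dyad's average".  Optional
per-speaker mean-centering removes each speaker's own baseline to
disentangle within- from between-person variation; it is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AssemblyError, DegeneracyError
from .lexicon import VARIABLES, SummaryProfile
from .transcripts import CLIENT, THERAPIST

RowLabel = tuple[str, int]  # (role, session_index)


def format_label(role: str, session_index: int) -> str:
    return ("T" if role == THERAPIST else "C") + str(session_index)


@dataclass(frozen=True)
class ProfileMatrix:
    """Labelled sub-transcript × summary-variable matrix for one dyad."""

    dyad_id: str
    labels: tuple[RowLabel, ...]
    values: np.ndarray  # (n_rows, 4), float
    variables: tuple[str, ...] = VARIABLES
    standardized: bool = False
    centered: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape != (len(self.labels), len(self.variables)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.labels)} labels x {len(self.variables)} variables"
            )
        if np.isnan(values).any():
            raise ValueError("profile matrix contains missing values")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate row labels")

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    @property
    def n_sessions(self) -> int:
        client_sessions = {s for r, s in self.labels if r == CLIENT}
        return len(client_sessions) if client_sessions else len(
            {s for _, s in self.labels}
        )

    def sessions(self, role: str) -> list[int]:
        return sorted(s for r, s in self.labels if r == role)

    def row(self, role: str, session_index: int) -> np.ndarray:
        idx = self.labels.index((role, session_index))
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.variables))
        df.insert(0, "dyad_id", self.dyad_id)
        df.insert(1, "role", [r for r, _ in self.labels])
        df.insert(2, "session_index", [s for _, s in self.labels])
        return df

    def write_csv(self, path: str | Path) -> None:
        # 10-decimal formatting: round-trips the fixtures bit-exactly
        self.to_frame().to_csv(path, index=False, float_format="%.10f")


def matrix_from_frame(
    df: pd.DataFrame, standardized: bool = False, centered: bool = False
) -> ProfileMatrix:
    """Build a ProfileMatrix from a profile table (CSV layout)."""
    dyads = df["dyad_id"].unique()
    if len(dyads) != 1:
        raise AssemblyError(f"expected a single dyad, got {list(dyads)}")
    labels = tuple(
        (str(role), int(session))
        for role, session in zip(df["role"], df["session_index"])
    )
    values = df[list(VARIABLES)].to_numpy(dtype=float)
    return ProfileMatrix(
        str(dyads[0]), labels, values, standardized=standardized, centered=centered
    )


def read_matrix_csv(path: str | Path) -> ProfileMatrix:
    return matrix_from_frame(pd.read_csv(path))


def assemble_matrix(
    profiles: Sequence[SummaryProfile], exclude_degenerate: bool = False
) -> ProfileMatrix:
    """Assemble per-sub-transcript profiles into one dyad matrix.

    Rows are ordered C1..Cn then T1..Tn.  Every session must have both
    roles unless degenerate (empty) profiles are being excluded.
    """
    if not profiles:
        raise AssemblyError("no profiles to assemble")
    dyads = {p.dyad_id for p in profiles}
    if len(dyads) != 1:
        raise AssemblyError(f"profiles span multiple dyads: {sorted(dyads)}")
    dyad_id = profiles[0].dyad_id

    kept = [p for p in profiles if not (exclude_degenerate and p.degenerate)]
    by_key = {(p.role, p.session_index): p for p in kept}
    if len(by_key) != len(kept):
        raise AssemblyError("duplicate (role, session) profiles")

    sessions = sorted({s for _, s in by_key})
    missing = [
        s
        for s in sessions
        if (CLIENT, s) not in by_key or (THERAPIST, s) not in by_key
    ]
    if missing:
        raise AssemblyError(
            f"dyad {dyad_id}: sessions missing a role: {missing}"
        )

    labels: list[RowLabel] = [(CLIENT, s) for s in sessions] + [
        (THERAPIST, s) for s in sessions
    ]
    values = np.array([by_key[lab].values() for lab in labels], dtype=float)
    return ProfileMatrix(dyad_id, tuple(labels), values)


def zscore(matrix: ProfileMatrix, ddof: int = 1) -> ProfileMatrix:
    """Standardize each variable to mean 0, SD 1 over the dyad's pooled rows.

    Sample SD (``ddof=1``) by default; population SD (``ddof=0``) only
    rescales each column by the same factor, so clustering outcomes are
    unaffected by the choice.
    """
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [matrix.variables[i] for i in zero]
        raise DegeneracyError(f"zero-variance variable(s): {names}")
    return replace(matrix, values=(matrix.values - mean) / sd, standardized=True)


def mean_center_by_speaker(matrix: ProfileMatrix) -> ProfileMatrix:
    """Subtract each speaker's own per-variable mean (within-role centering)."""
    if matrix.standardized:
        raise ValueError("mean-center before z-scoring, not after")
    values = matrix.values.copy()
    roles = np.array([r for r, _ in matrix.labels])
    for role in (CLIENT, THERAPIST):
        mask = roles == role
        if mask.any():
            values[mask] -= values[mask].mean(axis=0)
    return replace(matrix, values=values, centered=True)
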