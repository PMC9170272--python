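"""Synthetic inputs with known ground truth, plus packaged study fixtures.

Two layers are generated so every pipeline stage is testable without
licensed transcripts or a proprietary dictionary:

* **Token streams** with planted category rates: each token is a
  multinomial draw among category representative words and filler words,
  so scored category percentages converge to the planted rates.

* **Profile matrices** with planted synchrony: each session is
  synchronized with probability ``planted_rate``.  A synchronized
  session has a single shared linguistic profile — one draw from an
  isotropic Gaussian around the *sync center* used for both the
  therapist and the client row — capturing the idea that synchrony is a
  shared per-session style.  An asynchronized session draws the two
  rows independently around role-specific centers.  By default the
  sync center sits midway between the therapist and client centers at
  Euclidean distance ``separation x noise_sd`` (6 noise-SDs) from each,
  so the three latent styles are well separated and the true flags are
  recoverable by the pipeline.

The published demonstration data (summary variable scores for three
dyads: 15-session psychoanalysis, 14-session CBT, 20-session humanistic
therapy, scored with LIWC) is packaged as checksummed CSV fixtures,
together with the reported synchrony outcomes, so the clustering and
synchrony stages can be validated against the published analysis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .lexicon import VARIABLES, CategoryDictionary
from .profiles import ProfileMatrix, RowLabel, matrix_from_frame
from .transcripts import CLIENT, THERAPIST

# --------------------------------------------------------------------
# planted profile matrices

#: Unit direction along which therapist and client styles differ by
#: default: therapists score higher on analytic, clout and tone and
#: lower on authenticity (the pattern seen in real dyads).
_ROLE_DIRECTION = np.array([0.5, 0.5, -0.5, 0.5])


@dataclass(frozen=True)
class PlantedDesign:
    """Design of a synthetic dyad with known per-session synchrony.

    ``separation`` is the Euclidean distance, in units of ``noise_sd``,
    from the sync center to each role center (role centers are twice
    that apart).  Centers may be overridden; defaults put the sync
    center at the scale midpoint (50 on each variable) with the role
    centers offset along :data:`_ROLE_DIRECTION`.
    """

    n_sessions: int = 50
    planted_rate: float = 0.5
    noise_sd: float = 4.0
    separation: float = 6.0
    seed: int = 0
    sync_center: np.ndarray = field(default=None)  # type: ignore[assignment]
    therapist_center: np.ndarray = field(default=None)  # type: ignore[assignment]
    client_center: np.ndarray = field(default=None)  # type: ignore[assignment]
    covariance: np.ndarray | None = None  # 4x4; default isotropic noise_sd^2 I
    dyad_id: str = "SIM"

    def __post_init__(self) -> None:
        if not 0.0 <= self.planted_rate <= 1.0:
            raise ValueError("planted_rate must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        offset = self.separation * self.noise_sd * _ROLE_DIRECTION
        sync = (
            np.full(4, 50.0) if self.sync_center is None
            else np.asarray(self.sync_center, float)
        )
        ther = (
            sync + offset if self.therapist_center is None
            else np.asarray(self.therapist_center, float)
        )
        client = (
            sync - offset if self.client_center is None
            else np.asarray(self.client_center, float)
        )
        for name, c in (("sync", sync), ("therapist", ther), ("client", client)):
            if c.shape != (4,):
                raise ValueError(f"{name}_center must be a 4-vector")
        if (
            np.allclose(sync, ther)
            or np.allclose(sync, client)
            or np.allclose(ther, client)
        ):
            raise ValueError("centers must be pairwise distinct")
        object.__setattr__(self, "sync_center", sync)
        object.__setattr__(self, "therapist_center", ther)
        object.__setattr__(self, "client_center", client)
        if self.covariance is not None:
            cov = np.asarray(self.covariance, float)
            if cov.shape != (4, 4):
                raise ValueError("covariance must be 4x4")
            object.__setattr__(self, "covariance", cov)


def simulate_profiles(design: PlantedDesign) -> tuple[ProfileMatrix, np.ndarray]:
    """Draw a profile matrix with planted synchrony; return it with truth flags.

    Deterministic given ``design.seed``.  Rows are ordered C1..Cn then
    T1..Tn like an assembled dyad matrix.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_sessions
    cov = (
        design.covariance
        if design.covariance is not None
        else design.noise_sd**2 * np.eye(4)
    )
    flags = rng.random(n) < design.planted_rate

    client_rows = np.empty((n, 4))
    therapist_rows = np.empty((n, 4))
    for i in range(n):
        if flags[i]:
            shared = rng.multivariate_normal(design.sync_center, cov)
            client_rows[i] = shared
            therapist_rows[i] = shared
        else:
            therapist_rows[i] = rng.multivariate_normal(design.therapist_center, cov)
            client_rows[i] = rng.multivariate_normal(design.client_center, cov)

    labels: list[RowLabel] = [(CLIENT, s) for s in range(1, n + 1)] + [
        (THERAPIST, s) for s in range(1, n + 1)
    ]
    matrix = ProfileMatrix(
        design.dyad_id,
        tuple(labels),
        np.vstack([client_rows, therapist_rows]),
    )
    return matrix, flags


# --------------------------------------------------------------------
# planted token streams

@dataclass(frozen=True)
class TokenStreamDesign:
    """Planted per-category token rates; the remainder is filler words."""

    category_rates: dict[str, float]
    n_tokens: int
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_rates.values())
        if total > 1.0 + 1e-12:
            raise ValueError(f"category rates sum to {total} > 1")
        if any(r < 0 for r in self.category_rates.values()):
            raise ValueError("rates must be non-negative")
        if self.n_tokens < 0:
            raise ValueError("n_tokens must be >= 0")


#: Filler word shapes; combined with an index to stay out of any
#: sensible dictionary ("qoz1", "vrek2", ...).
_FILLER_STEMS = ("qoz", "vrek", "zlun", "jyx", "wumph")


def _filler_words(dictionary: CategoryDictionary, n: int = 20) -> list[str]:
    words = []
    i = 0
    while len(words) < n:
        w = _FILLER_STEMS[i % len(_FILLER_STEMS)] + str(i)
        if not dictionary.matches(w):
            words.append(w)
        i += 1
    return words


def simulate_token_stream(
    design: TokenStreamDesign, dictionary: CategoryDictionary
) -> str:
    """Generate text whose scored category percentages converge to the rates.

    Each token is a multinomial draw: with probability ``rate(c)`` a
    uniformly chosen literal representative of category c, otherwise a
    filler word matching no dictionary pattern.
    """
    reps: dict[str, list[str]] = {}
    for cat in design.category_rates:
        if cat not in dictionary.category_names:
            raise ValueError(f"category {cat!r} not in dictionary")
        literals = [
            p for p, cats in dictionary.entries.items()
            if cat in cats and not p.endswith("*")
        ]
        if not literals:
            raise ValueError(f"category {cat!r} has no literal pattern")
        reps[cat] = sorted(literals)

    rng = np.random.default_rng(design.seed)
    cats = sorted(design.category_rates)
    probs = np.array([design.category_rates[c] for c in cats])
    filler_prob = max(0.0, 1.0 - probs.sum())
    fillers = _filler_words(dictionary)

    choices = rng.choice(
        len(cats) + 1, size=design.n_tokens, p=np.append(probs, filler_prob)
    )
    words = []
    for c in choices:
        pool = reps[cats[c]] if c < len(cats) else fillers
        words.append(pool[rng.integers(len(pool))])
    return " ".join(words)


# --------------------------------------------------------------------
# packaged fixtures: the three demonstration dyads

_FIXTURE_FILES = {
    "A": "table2_dyad_a.csv",
    "B": "table2_dyad_b.csv",
    "C": "table2_dyad_c.csv",
}

_FIXTURE_SHA256 = {
    "A": "8825657994484a7f8df44dabcac70c50ecf51eee67c580ce459c9d2a370dc627",
    "B": "c4e78fbead3692108b020d6d9e1d99f068cfccc0751c0510fea02af030313059",
    "C": "0dfe92db72cbaec305388f90a05d668f72951bfc0a4bfba95e24d76dd60d11bd",
}

#: Published synchrony outcomes for the three demonstration dyads:
#: the visually chosen cluster count, the synchronized sessions, and
#: the percentage, as reported in the source analysis.
_REPORTED_OUTCOMES = {
    "A": {
        "n_sessions": 15,
        "reported_k": 3,
        "synchronized_sessions": [2, 8, 10, 11, 12],
        "percentage": 33.3,
    },
    "B": {
        "n_sessions": 14,
        "reported_k": 2,
        "synchronized_sessions": [],
        "percentage": 0.0,
    },
    "C": {
        "n_sessions": 20,
        "reported_k": 2,
        "synchronized_sessions": [9, 11, 12, 14, 17],
        "percentage": 25.0,
    },
}

DYAD_IDS = tuple(_FIXTURE_FILES)


def fixture_path(dyad: str) -> Path:
    if dyad not in _FIXTURE_FILES:
        raise KeyError(f"unknown dyad {dyad!r}; have {list(_FIXTURE_FILES)}")
    return Path(str(resources.files("lingsync.data") / _FIXTURE_FILES[dyad]))


def load_fixture_dyad(dyad: str) -> ProfileMatrix:
    """Load one demonstration dyad's summary-variable scores (checksummed)."""
    path = fixture_path(dyad)
    data = path.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[dyad]:
        raise RuntimeError(
            f"fixture {path.name} checksum mismatch ({digest}); "
            "the packaged data has been altered"
        )
    return matrix_from_frame(pd.read_csv(path))


def fixture_table2() -> dict[str, ProfileMatrix]:
    """The three demonstration dyads' profile matrices (A: 30, B: 28, C: 40 rows)."""
    return {d: load_fixture_dyad(d) for d in DYAD_IDS}


def fixture_table3() -> dict[str, dict]:
    """Expected synchrony outcomes for the demonstration dyads."""
    return {d: dict(v) for d, v in _REPORTED_OUTCOMES.items()}
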