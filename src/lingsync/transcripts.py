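"""Speaker-turn transcripts and per-session role splitting.

A session transcript is plain text in which a new conversational turn
starts with a line-initial uppercase speaker label followed by a colon
(``THERAPIST: ...``).  Lines without a label continue the current turn.
Each session is split into two *sub-transcripts* — all of the
therapist's language and all of the client's language — which are the
objects scored and clustered downstream.  For a 10-session dyad this
yields 20 sub-transcripts, conventionally labelled T1–T10 and C1–C10.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import TranscriptFormatError, TranscriptParseError
from .lexicon import tokenize

logger = logging.getLogger(__name__)

THERAPIST = "therapist"
CLIENT = "client"
ROLES = (THERAPIST, CLIENT)

#: Default mapping from transcript labels to roles.
DEFAULT_SPEAKER_MAP: dict[str, str] = {
    "THERAPIST": THERAPIST,
    "CLIENT": CLIENT,
    "T": THERAPIST,
    "C": CLIENT,
}

# Line-initial uppercase label (letters/digits/underscore/space) + colon.
_PREFIX_RE = re.compile(r"^([A-Z][A-Z0-9_ ]*?)\s*:\s?(.*)$")

# Bracketed transcription annotations: "[...]", "(not in extract)", etc.
_ANNOTATION_RE = re.compile(r"\[[^\[\]]*\]|\([^()]*\)")


def strip_annotations(text: str) -> str:
    """Remove bracketed/parenthesized transcription annotations."""
    return _ANNOTATION_RE.sub(" ", text)


@dataclass(frozen=True)
class Turn:
    """One speaker turn within a session."""

    session_index: int
    speaker: str  # therapist | client
    text: str

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise ValueError("session_index must be >= 1")
        if self.speaker not in ROLES:
            raise ValueError(f"unknown speaker role {self.speaker!r}")
        if not self.text.strip():
            raise ValueError("turn text is empty")


@dataclass(frozen=True)
class SubTranscript:
    """One speaker's pooled language for one session (a T_x or C_x)."""

    dyad_id: str
    role: str
    session_index: int
    text: str
    token_count: int = field(init=False)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.session_index < 1:
            raise ValueError("session_index must be >= 1")
        object.__setattr__(self, "token_count", len(tokenize(self.text)))

    @property
    def label(self) -> str:
        """Short row label, e.g. ``T3`` / ``C3``."""
        return ("T" if self.role == THERAPIST else "C") + str(self.session_index)


def parse_transcript(
    raw_text: str,
    speaker_map: Mapping[str, str] | None = None,
    session_index: int = 1,
) -> list[Turn]:
    """Parse labelled transcript text into an ordered list of turns.

    Parameters
    ----------
    raw_text:
        Transcript with line-initial ``LABEL:`` speaker prefixes.
        Unprefixed lines continue the previous turn.  Line endings may
        be LF or CRLF.
    speaker_map:
        Mapping from transcript label to role (``therapist``/``client``).
        Defaults to :data:`DEFAULT_SPEAKER_MAP`.
    session_index:
        1-based session number attached to every turn.

    Raises
    ------
    TranscriptParseError
        A labelled line uses a label absent from ``speaker_map``.
    TranscriptFormatError
        No recognizable speaker prefix anywhere in the text.
    """
    if speaker_map is None:
        speaker_map = DEFAULT_SPEAKER_MAP
    lines = raw_text.replace("\r\n", "\n").replace("\r", "\n").split("\n")

    turns: list[Turn] = []
    current_role: str | None = None
    current_parts: list[str] = []

    def flush() -> None:
        nonlocal current_parts
        if current_role is None:
            return
        text = strip_annotations(" ".join(current_parts)).strip()
        text = re.sub(r"\s+", " ", text)
        if text:  # annotation-only turns are dropped
            turns.append(Turn(session_index, current_role, text))
        current_parts = []

    saw_prefix = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        m = _PREFIX_RE.match(line)
        if m:
            label, rest = m.group(1), m.group(2)
            if label not in speaker_map:
                raise TranscriptParseError(
                    f"unknown speaker label {label!r} on line {lineno}"
                )
            saw_prefix = True
            flush()
            current_role = speaker_map[label]
            current_parts = [rest]
        else:
            if not saw_prefix:
                raise TranscriptFormatError(
                    "no recognizable speaker prefixes found "
                    f"(first content on line {lineno})"
                )
            current_parts.append(line.strip())
    flush()

    if not saw_prefix:
        raise TranscriptFormatError("no recognizable speaker prefixes found")
    return turns


def split_by_role(
    turns: Sequence[Turn], dyad_id: str, session_index: int
) -> tuple[SubTranscript, SubTranscript]:
    """Split one session's turns into (therapist, client) sub-transcripts.

    A role with no turns yields an empty sub-transcript (token_count 0);
    emptiness is flagged downstream, not here.
    """
    for t in turns:
        if t.session_index != session_index:
            raise ValueError(
                f"turn session_index {t.session_index} != {session_index}"
            )
    parts = {role: [t.text for t in turns if t.speaker == role] for role in ROLES}
    return tuple(
        SubTranscript(dyad_id, role, session_index, " ".join(parts[role]))
        for role in ROLES
    )  # type: ignore[return-value]


def load_dyad(
    paths: Sequence[str | Path],
    dyad_id: str,
    speaker_map: Mapping[str, str] | None = None,
) -> list[SubTranscript]:
    """Load one file per session (order = session 1..n) into sub-transcripts.

    Returns 2n sub-transcripts (therapist and client per session).
    """
    subs: list[SubTranscript] = []
    for session_index, path in enumerate(paths, start=1):
        path = Path(path)
        try:
            raw = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise OSError(f"cannot read transcript file {path}: {exc}") from exc
        if raw.strip():
            turns = parse_transcript(raw, speaker_map, session_index)
        else:
            turns = []
        pair = split_by_role(turns, dyad_id, session_index)
        for sub in pair:
            logger.info(
                "dyad %s session %d %s: %d tokens",
                dyad_id, session_index, sub.role, sub.token_count,
            )
        subs.extend(pair)
    return subs


def read_manifest(path: str | Path) -> list[Path]:
    """Read a session manifest CSV (columns session_index, path).

    Returns transcript paths ordered by session_index; relative paths
    are resolved against the manifest's directory.
    """
    path = Path(path)
    rows: list[tuple[int, Path]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            p = Path(rec["path"])
            if not p.is_absolute():
                p = path.parent / p
            rows.append((int(rec["session_index"]), p))
    rows.sort(key=lambda r: r[0])
    return [p for _, p in rows]


def write_subtranscripts_csv(
    subs: Iterable[SubTranscript], path: str | Path
) -> None:
    """Serialize sub-transcripts to CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dyad_id", "role", "session_index", "token_count", "text"])
        for s in subs:
            writer.writerow([s.dyad_id, s.role, s.session_index, s.token_count, s.text])
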