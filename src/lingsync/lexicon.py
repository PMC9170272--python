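"""Dictionary-based word-category scoring and 0–100 summary variables.

A category dictionary in the de-facto ``.dic`` format maps words (or
``stem*`` prefix patterns) to word categories such as articles,
pronouns, or tentative words.  A text is scored as the percentage of
its tokens matching each category, and categories are combined into
four summary variables — *analytic* thinking, *clout*, *authenticity*,
and emotional *tone* — by a signed composition

    score = offset + sum(positive category %) - sum(negative category %)

clamped to [0, 100].  The sign structure follows the published
composition of each variable (e.g. analytic thinking rises with
articles and prepositions and falls with pronouns, auxiliary verbs,
conjunctions, adverbs, and negations).  The proprietary norming that
commercial tools apply on top of this composition is not reproduced,
so absolute scores are comparable only within this implementation;
the clustering stages also accept externally scored tables.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import DictionaryFormatError, MissingCategoryError

logger = logging.getLogger(__name__)

VARIABLES = ("analytic", "clout", "authentic", "tone")

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens: runs of letters/digits with internal apostrophes.

    Punctuation is discarded; contractions stay whole (``it's`` is one
    token).  Curly apostrophes are normalized to ASCII first.
    """
    return _TOKEN_RE.findall(text.replace("’", "'").lower())


@dataclass
class CategoryDictionary:
    """LIWC-style category dictionary.

    ``entries`` maps a lowercase pattern — a literal word or a stem with
    a single trailing ``*`` wildcard — to the set of category names it
    counts toward.
    """

    categories: dict[int, str]
    entries: dict[str, frozenset[str]]
    _literals: dict[str, frozenset[str]] = field(init=False, repr=False)
    _stems: list[tuple[str, frozenset[str]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._literals = {}
        self._stems = []
        for pattern, cats in self.entries.items():
            if pattern.endswith("*"):
                self._stems.append((pattern[:-1], cats))
            else:
                self._literals[pattern] = cats
        # longest stems first so specific patterns are still all applied
        self._stems.sort(key=lambda s: -len(s[0]))

    @property
    def category_names(self) -> frozenset[str]:
        return frozenset(self.categories.values())

    def lookup(self, token: str) -> frozenset[str]:
        """All categories the token counts toward (literal + stem matches)."""
        cats: set[str] = set(self._literals.get(token, ()))
        for stem, stem_cats in self._stems:
            if token.startswith(stem):
                cats.update(stem_cats)
        return frozenset(cats)

    def matches(self, token: str) -> bool:
        return bool(self.lookup(token))


def load_dictionary(path: str | Path) -> CategoryDictionary:
    """Parse a ``.dic`` file.

    Layout: a header block delimited by lines containing only ``%``,
    with ``id<TAB>name`` category declarations, followed by entry lines
    ``pattern<TAB>id [id ...]``.  Wildcards are a single trailing ``*``.

    Raises
    ------
    DictionaryFormatError
        Missing header, undeclared category id, or malformed line.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()

    categories: dict[int, str] = {}
    entries: dict[str, frozenset[str]] = {}
    in_header = False
    header_done = False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line == "%":
            if not header_done:
                if in_header:
                    header_done = True
                in_header = not in_header
            continue
        fields = line.split()
        if in_header:
            try:
                cat_id = int(fields[0])
            except ValueError as exc:
                raise DictionaryFormatError(
                    f"{path}:{lineno}: category id {fields[0]!r} is not an integer"
                ) from exc
            if len(fields) < 2:
                raise DictionaryFormatError(
                    f"{path}:{lineno}: category {cat_id} has no name"
                )
            categories[cat_id] = fields[1]
        else:
            if not header_done:
                raise DictionaryFormatError(
                    f"{path}:{lineno}: entry line before '%'-delimited header"
                )
            pattern = fields[0].lower()
            if "*" in pattern[:-1] or pattern.count("*") > 1:
                raise DictionaryFormatError(
                    f"{path}:{lineno}: wildcard only allowed in final position"
                )
            cats: set[str] = set()
            for f in fields[1:]:
                try:
                    cat_id = int(f)
                except ValueError as exc:
                    raise DictionaryFormatError(
                        f"{path}:{lineno}: bad category id {f!r}"
                    ) from exc
                if cat_id not in categories:
                    raise DictionaryFormatError(
                        f"{path}:{lineno}: undeclared category id {cat_id}"
                    )
                cats.add(categories[cat_id])
            if pattern in entries:
                logger.warning(
                    "%s:%d: duplicate pattern %r, last wins", path, lineno, pattern
                )
            entries[pattern] = frozenset(cats)

    if not header_done:
        raise DictionaryFormatError(f"{path}: no '%'-delimited category header")
    logger.info(
        "loaded dictionary %s: %d categories, %d entries",
        path, len(categories), len(entries),
    )
    return CategoryDictionary(categories, entries)


@dataclass(frozen=True)
class CategoryProfile:
    """Per-category token percentages for one text."""

    percentages: Mapping[str, float]
    token_count: int

    @property
    def degenerate(self) -> bool:
        return self.token_count == 0


def score_categories(
    tokens: Sequence[str], dictionary: CategoryDictionary
) -> CategoryProfile:
    """Percentage of tokens matching each dictionary category.

    A token may count toward several categories but at most once per
    category.  An empty token list yields an all-zero, degenerate
    profile.
    """
    counts = {name: 0 for name in dictionary.category_names}
    for token in tokens:
        for cat in dictionary.lookup(token):
            counts[cat] += 1
    n = len(tokens)
    if n == 0:
        return CategoryProfile({name: 0.0 for name in counts}, 0)
    return CategoryProfile({name: 100.0 * c / n for name, c in counts.items()}, n)


@dataclass(frozen=True)
class SummaryVariableSpec:
    """Signed composition of categories into one 0–100 summary variable."""

    name: str
    positive_categories: tuple[str, ...]
    negative_categories: tuple[str, ...]
    offset: float = 50.0

    def __post_init__(self) -> None:
        pos, neg = set(self.positive_categories), set(self.negative_categories)
        if pos & neg:
            raise ValueError(f"{self.name}: categories on both sides: {pos & neg}")
        if not (pos or neg):
            raise ValueError(f"{self.name}: no categories at all")


#: Default compositions of the four summary variables.  Category names
#: must exist in the user-supplied dictionary.
DEFAULT_SUMMARY_SPECS: tuple[SummaryVariableSpec, ...] = (
    SummaryVariableSpec(
        "analytic",
        positive_categories=("article", "preposition"),
        negative_categories=("pronoun", "auxverb", "conjunction", "adverb", "negation"),
    ),
    SummaryVariableSpec(
        "clout",
        positive_categories=("we", "you"),
        negative_categories=("tentative",),
    ),
    SummaryVariableSpec(
        "authentic",
        positive_categories=("i", "third_person", "exclusive"),
        negative_categories=("negemo", "motion"),
    ),
    SummaryVariableSpec(
        "tone",
        positive_categories=("posemo",),
        negative_categories=("negemo",),
    ),
)


def summary_variable(profile: CategoryProfile, spec: SummaryVariableSpec) -> float:
    """Evaluate one summary variable: offset + Σ pos% − Σ neg%, clamped to [0, 100]."""
    for cat in (*spec.positive_categories, *spec.negative_categories):
        if cat not in profile.percentages:
            raise MissingCategoryError(
                f"summary variable {spec.name!r} needs category {cat!r}, "
                "absent from the dictionary"
            )
    raw = (
        spec.offset
        + sum(profile.percentages[c] for c in spec.positive_categories)
        - sum(profile.percentages[c] for c in spec.negative_categories)
    )
    return min(100.0, max(0.0, raw))


@dataclass(frozen=True)
class SummaryProfile:
    """The 4-vector of summary variables for one sub-transcript."""

    dyad_id: str
    role: str
    session_index: int
    analytic: float
    clout: float
    authentic: float
    tone: float
    degenerate: bool = False

    def values(self) -> tuple[float, float, float, float]:
        return (self.analytic, self.clout, self.authentic, self.tone)


def profile_subtranscript(
    sub,
    dictionary: CategoryDictionary,
    specs: Sequence[SummaryVariableSpec] = DEFAULT_SUMMARY_SPECS,
) -> SummaryProfile:
    """Score one sub-transcript on the four summary variables.

    Empty sub-transcripts get the flagged midpoint profile (50 on every
    variable); downstream stages may exclude flagged rows.
    """
    names = tuple(s.name for s in specs)
    if sorted(names) != sorted(VARIABLES):
        raise ValueError(f"need exactly the four specs {VARIABLES}, got {names}")
    tokens = tokenize(sub.text)
    if not tokens:
        return SummaryProfile(
            sub.dyad_id, sub.role, sub.session_index, 50.0, 50.0, 50.0, 50.0,
            degenerate=True,
        )
    cat_profile = score_categories(tokens, dictionary)
    scores = {spec.name: summary_variable(cat_profile, spec) for spec in specs}
    return SummaryProfile(sub.dyad_id, sub.role, sub.session_index, **scores)


def write_profiles_csv(profiles: Iterable[SummaryProfile], path: str | Path) -> None:
    """Write summary profiles as CSV (one row per sub-transcript)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dyad_id", "role", "session_index", *VARIABLES])
        for p in profiles:
            writer.writerow(
                [p.dyad_id, p.role, p.session_index, *(f"{v:.10g}" for v in p.values())]
            )
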