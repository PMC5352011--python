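"""Grouping mazes into disfluent intervals and classifying them by type.

The schema distinguishes four disfluency types:

* **repetition (REP)** — the maze and its repair are identical, including
  mid-word interruptions where a fragment (``do-``) is resolved by the
  repair (``dog``);
* **revision (REV)** — maze and repair differ; when the repair is formed
  purely by deleting maze words the subtype is DEL, purely by inserting
  new words INS, otherwise NONE;
* **false start (FS)** — a content maze with no corresponding repair;
* **filler (F)** — a filled pause or discourse marker (*um*, *uh*,
  *I mean*, ...).

A *disfluent interval* is one or more consecutive mazes optionally
followed by a repair; it is the unit of classification.  A content maze
counts as *cued* when a filler is adjacent to it: between the maze and
its repair, or immediately before or after the maze.  Mazes smaller than
a prosodic word (unresolved fragments, "stutters") are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .transcript_io import Activity, SpanKind, Token, Transcript, Utterance

__all__ = [
    "DEFAULT_FILLER_LEXICON",
    "FillerLexicon",
    "ElementKind",
    "DisfluentInterval",
    "EditOp",
    "EditScript",
    "DType",
    "Subtype",
    "DisfluencyEvent",
    "OrphanRepairError",
    "CueOnFillerError",
    "is_filler",
    "group_intervals",
    "align_words",
    "classify_interval",
    "detect_cue",
    "extract_events",
]

#: Default filler inventory: filled pauses and discourse markers.
DEFAULT_FILLER_LEXICON = frozenset(
    {"like", "um", "uh", "mm", "hmm", "i mean", "ah"}
)


class FillerLexicon:
    """Normalized filler word/phrase set with multiword matching."""

    def __init__(self, entries: Iterable[str] = DEFAULT_FILLER_LEXICON):
        self._phrases: dict[tuple[str, ...], int] = {}
        for entry in entries:
            words = tuple(entry.lower().split())
            if not words:
                raise ValueError("empty filler entry")
            self._phrases[words] = len(words)
        self._max_len = max(self._phrases.values())

    def match_at(self, norms: Sequence[str], i: int) -> int:
        """Length of the longest filler phrase starting at ``norms[i]`` (0 if none)."""
        for n in range(min(self._max_len, len(norms) - i), 0, -1):
            if tuple(norms[i : i + n]) in self._phrases:
                return n
        return 0

    def covers(self, norms: Sequence[str]) -> bool:
        """True when the whole sequence is a concatenation of filler phrases."""
        i = 0
        while i < len(norms):
            n = self.match_at(norms, i)
            if n == 0:
                return False
            i += n
        return len(norms) > 0

    def __contains__(self, word: str) -> bool:
        return (word.lower(),) in self._phrases


def is_filler(token: Token | str, lexicon: FillerLexicon | Iterable[str] = DEFAULT_FILLER_LEXICON) -> bool:
    """True when the (single) token is a filler after normalization."""
    if not isinstance(lexicon, FillerLexicon):
        lexicon = FillerLexicon(lexicon)
    norm = token.norm if isinstance(token, Token) else token.lower()
    return norm in lexicon


class ElementKind(str, Enum):
    CONTENT_MAZE = "CONTENT_MAZE"
    FILLER_MAZE = "FILLER_MAZE"
    REPAIR = "REPAIR"


@dataclass
class DisfluentInterval:
    """A maximal run of consecutive mazes plus an optional trailing repair."""

    elements: list[tuple[ElementKind, list[Token]]]
    utterance_index: int = 0
    position: int = 0

    @property
    def has_repair(self) -> bool:
        return bool(self.elements) and self.elements[-1][0] is ElementKind.REPAIR


class OrphanRepairError(ValueError):
    pass


class CueOnFillerError(ValueError):
    pass


def group_intervals(
    u: Utterance,
    lexicon: FillerLexicon | Iterable[str] = DEFAULT_FILLER_LEXICON,
    utterance_index: int = 0,
) -> list[DisfluentInterval]:
    """Group the utterance's maze/repair spans into disfluent intervals.

    Consecutive maze spans (no fluent token between them) belong to one
    interval; a repair span immediately after closes it.  Every maze and
    repair token ends up in exactly one interval.
    """
    if not isinstance(lexicon, FillerLexicon):
        lexicon = FillerLexicon(lexicon)
    intervals: list[DisfluentInterval] = []
    current: DisfluentInterval | None = None
    for kind, _mid, toks in u.spans():
        if kind is SpanKind.FLUENT:
            current = None
            continue
        if kind is SpanKind.MAZE:
            ekind = (
                ElementKind.FILLER_MAZE
                if lexicon.covers([t.norm for t in toks])
                else ElementKind.CONTENT_MAZE
            )
            if current is None or current.has_repair:
                current = DisfluentInterval(
                    elements=[], utterance_index=utterance_index, position=toks[0].index
                )
                intervals.append(current)
            current.elements.append((ekind, list(toks)))
        else:  # REPAIR
            if current is None or current.has_repair:
                raise OrphanRepairError(
                    f"repair at token {toks[0].index} has no maze in its interval"
                )
            current.elements.append((ElementKind.REPAIR, list(toks)))
            current = None
    return intervals


# ---------------------------------------------------------------------------
# word-level minimum-edit-distance alignment


class EditOp(str, Enum):
    MATCH = "MATCH"
    SUB = "SUB"
    DEL = "DEL"
    INS = "INS"


@dataclass(frozen=True)
class EditScript:
    ops: tuple[EditOp, ...]
    cost: int

    def op_kinds(self) -> set[EditOp]:
        return set(self.ops)


def _word_view(w: Token | str) -> tuple[str, bool]:
    if isinstance(w, Token):
        return w.norm, w.is_fragment
    w = w.lower()
    if w.endswith("-") and len(w) > 1:
        return w[:-1], True
    return w, False


def _words_match(a: tuple[str, bool], b: tuple[str, bool]) -> bool:
    # equal normalized words, or a fragment matching a word it prefixes
    if a[0] == b[0]:
        return True
    if a[1] and b[0].startswith(a[0]):
        return True
    if b[1] and a[0].startswith(b[0]):
        return True
    return False


def align_words(a: Sequence[Token | str], b: Sequence[Token | str]) -> EditScript:
    """Minimum-edit alignment of word sequence ``a`` onto ``b``.

    Unit costs for SUB/DEL/INS; MATCH requires equal normalized words,
    with a fragment matching any word it prefixes.  Ties are broken
    deterministically, preferring MATCH, then SUB, then DEL, then INS
    during backtrace (so a substitution is never split into DEL+INS).
    """
    av = [_word_view(w) for w in a]
    bv = [_word_view(w) for w in b]
    m, n = len(av), len(bv)
    # dp[i][j] = min cost to transform a[:i] into b[:j]
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        dp[i][0] = i
    for j in range(1, n + 1):
        dp[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            diag = dp[i - 1][j - 1] + (0 if _words_match(av[i - 1], bv[j - 1]) else 1)
            dp[i][j] = min(diag, dp[i - 1][j] + 1, dp[i][j - 1] + 1)
    ops: list[EditOp] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            matched = _words_match(av[i - 1], bv[j - 1])
            if dp[i][j] == dp[i - 1][j - 1] + (0 if matched else 1):
                ops.append(EditOp.MATCH if matched else EditOp.SUB)
                i -= 1
                j -= 1
                continue
        if i > 0 and dp[i][j] == dp[i - 1][j] + 1:
            ops.append(EditOp.DEL)
            i -= 1
            continue
        ops.append(EditOp.INS)
        j -= 1
    ops.reverse()
    return EditScript(ops=tuple(ops), cost=dp[m][n])


# ---------------------------------------------------------------------------
# classification


class DType(str, Enum):
    REP = "REP"
    REV = "REV"
    FS = "FS"
    F = "F"


class Subtype(str, Enum):
    DEL = "DEL"
    INS = "INS"
    NONE = "NONE"


@dataclass
class DisfluencyEvent:
    dtype: DType
    subtype: Subtype = Subtype.NONE
    cued: bool = False
    child_id: str = ""
    activity: Activity | None = None
    utterance_index: int = 0
    interval_index: int = 0
    element_index: int = 0  # position of the event's maze within its interval

    def __post_init__(self) -> None:
        if self.dtype is not DType.REV and self.subtype is not Subtype.NONE:
            raise ValueError("subtype only applies to revisions")


def _is_stutter(tokens: list[Token], target: list[Token] | None) -> bool:
    """Unresolvable all-fragment maze: less than a prosodic word, ignored."""
    if not all(t.is_fragment for t in tokens):
        return False
    if target is None or not target:
        return True
    return not target[0].norm.startswith(tokens[0].norm)


def classify_interval(
    iv: DisfluentInterval,
    lexicon: FillerLexicon | Iterable[str] = DEFAULT_FILLER_LEXICON,
) -> list[DisfluencyEvent]:
    """Classify one disfluent interval into zero or more events.

    Each filler maze contributes one F event per filler phrase.  Each
    content maze is paired with a repair target: the right-most content
    maze pairs with the interval's repair (if any); an earlier content
    maze pairs with the next content maze, which acts as its repair in a
    stacked self-correction like ``(I) (I want) {I need}``.  Zero edit
    cost against the target makes a repetition, non-zero a revision; a
    content maze without a target is a false start.  Unresolved
    all-fragment mazes (stutters) yield no event.
    """
    if not isinstance(lexicon, FillerLexicon):
        lexicon = FillerLexicon(lexicon)
    events: list[DisfluencyEvent] = []
    content_idx = [
        i for i, (k, _) in enumerate(iv.elements) if k is ElementKind.CONTENT_MAZE
    ]
    repair = iv.elements[-1][1] if iv.has_repair else None

    for ei, (kind, toks) in enumerate(iv.elements):
        if kind is ElementKind.FILLER_MAZE:
            norms = [t.norm for t in toks]
            i = 0
            while i < len(norms):
                n = lexicon.match_at(norms, i)
                events.append(DisfluencyEvent(dtype=DType.F, element_index=ei))
                i += max(n, 1)
        elif kind is ElementKind.CONTENT_MAZE:
            later = [c for c in content_idx if c > ei]
            target = iv.elements[later[0]][1] if later else repair
            if _is_stutter(toks, target):
                continue
            if target is None:
                events.append(DisfluencyEvent(dtype=DType.FS, element_index=ei))
                continue
            script = align_words(toks, target)
            if script.cost == 0:
                events.append(DisfluencyEvent(dtype=DType.REP, element_index=ei))
            else:
                kinds = script.op_kinds() - {EditOp.MATCH}
                if kinds == {EditOp.DEL}:
                    sub = Subtype.DEL
                elif kinds == {EditOp.INS}:
                    sub = Subtype.INS
                else:
                    sub = Subtype.NONE
                events.append(
                    DisfluencyEvent(dtype=DType.REV, subtype=sub, element_index=ei)
                )
    return events


def detect_cue(
    iv: DisfluentInterval, event: DisfluencyEvent, u: Utterance | None = None
) -> bool:
    """True when a filler is adjacent to the event's content maze.

    Adjacent means no fluent token intervenes: the filler sits between
    the maze and its repair, or immediately before/after the maze within
    the interval (consecutive mazes are by construction contiguous).
    """
    if event.dtype is DType.F:
        raise CueOnFillerError("fillers cue; they are not themselves cued")
    ei = event.element_index
    for nb in (ei - 1, ei + 1):
        if 0 <= nb < len(iv.elements) and iv.elements[nb][0] is ElementKind.FILLER_MAZE:
            return True
    return False


def extract_events(
    t: Transcript,
    lexicon: FillerLexicon | Iterable[str] = DEFAULT_FILLER_LEXICON,
) -> list[DisfluencyEvent]:
    """Classify every disfluent interval in the child's utterances."""
    if not isinstance(lexicon, FillerLexicon):
        lexicon = FillerLexicon(lexicon)
    events: list[DisfluencyEvent] = []
    for ui, u in enumerate(t.utterances):
        if u.speaker.name != "CHILD":
            continue
        for ii, iv in enumerate(group_intervals(u, lexicon, utterance_index=ui)):
            for ev in classify_interval(iv, lexicon):
                ev.child_id = t.child_id
                ev.activity = u.activity
                ev.utterance_index = ui
                ev.interval_index = ii
                if ev.dtype is not DType.F:
                    ev.cued = detect_cue(iv, ev, u)
                events.append(ev)
    return events
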