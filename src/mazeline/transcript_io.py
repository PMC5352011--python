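"""Reading and writing maze/repair-annotated language-sample transcripts.

The on-disk format is a small SALT-style dialect, one C-unit (utterance)
per line:

* the first whitespace-delimited field is the speaker code, ``C`` (child)
  or ``E`` (examiner);
* mazes — stretches of disfluent speech the listener must excise — are
  wrapped in parentheses, ``(pool)``;
* repairs — the fluent material replacing a maze — are wrapped in curly
  braces, ``{park}``;
* bound morphemes are marked with ``/`` inside a word (``dog/s`` counts
  as two morphemes);
* word fragments carry a trailing hyphen (``do-``);
* a trailing ``>`` marks an incomplete or abandoned utterance;
* activity sections are introduced by header lines ``+Activity: Play``
  (also ``Picture``, ``Story``, ``Conversation``) and apply to every
  utterance until the next header.

Example::

    +Activity: Play
    C I like going to the (pool) {park}.
    E where do you like to go?

Nested brackets are not part of the dialect and are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator

__all__ = [
    "Speaker",
    "Activity",
    "SpanKind",
    "Token",
    "SpanLabel",
    "Utterance",
    "Transcript",
    "ParseError",
    "UnbalancedBrackets",
    "UnknownSpeakerCode",
    "MissingActivityHeader",
    "Issue",
    "parse_transcript",
    "serialize_transcript",
    "validate",
]


class Speaker(str, Enum):
    CHILD = "C"
    EXAMINER = "E"


class Activity(str, Enum):
    """ADOS activity a stretch of transcript belongs to."""

    PLAY = "Play"
    PICTURE = "Picture"
    STORY = "Story"
    CONVERSATION = "Conversation"


class SpanKind(str, Enum):
    FLUENT = "FLUENT"
    MAZE = "MAZE"
    REPAIR = "REPAIR"


_TERMINAL_PUNCT = ".?!,"


@dataclass(frozen=True)
class Token:
    """One word of an utterance.

    ``norm`` is the lowercased form with terminal punctuation and any
    fragment hyphen stripped; all word comparisons (alignment, filler
    lookup) operate on it.  ``morpheme_count`` is 1 plus the number of
    ``/`` bound-morpheme markers; fragments always count one morpheme.
    """

    raw: str
    norm: str
    is_fragment: bool
    morpheme_count: int
    index: int

    @staticmethod
    def from_raw(raw: str, index: int) -> "Token":
        core = raw.rstrip(_TERMINAL_PUNCT)
        is_fragment = core.endswith("-") and len(core) > 1
        norm = (core[:-1] if is_fragment else core).lower()
        morphemes = 1 if is_fragment else 1 + core.count("/")
        return Token(
            raw=raw,
            norm=norm,
            is_fragment=is_fragment,
            morpheme_count=morphemes,
            index=index,
        )


@dataclass(frozen=True)
class SpanLabel:
    """Span membership of one token: FLUENT, or a bracketed MAZE/REPAIR.

    ``maze_id`` groups the consecutive tokens of one bracketed span; ids
    increase in reading order within an utterance and are -1 for FLUENT.
    """

    kind: SpanKind
    maze_id: int = -1


@dataclass
class Utterance:
    speaker: Speaker
    activity: Activity
    tokens: list[Token]
    labels: list[SpanLabel]
    complete: bool = True
    terminator: str = "."
    empty_spans: int = 0  # "( )" / "{ }" in the source; reported by validate()

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError("tokens and labels must have equal length")

    def spans(self) -> list[tuple[SpanKind, int, list[Token]]]:
        """Contiguous (kind, maze_id, tokens) runs, in token order."""
        out: list[tuple[SpanKind, int, list[Token]]] = []
        for tok, lab in zip(self.tokens, self.labels):
            if out and out[-1][0] is lab.kind and out[-1][1] == lab.maze_id:
                out[-1][2].append(tok)
            else:
                out.append((lab.kind, lab.maze_id, [tok]))
        return out


@dataclass
class Transcript:
    child_id: str
    utterances: list[Utterance] = field(default_factory=list)
    ados_module: int = 3

    def child_utterances(self) -> Iterator[Utterance]:
        return (u for u in self.utterances if u.speaker is Speaker.CHILD)


class ParseError(ValueError):
    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.column = column


class UnbalancedBrackets(ParseError):
    pass


class UnknownSpeakerCode(ParseError):
    pass


class MissingActivityHeader(ParseError):
    pass


@dataclass(frozen=True)
class Issue:
    """A machine-readable validation finding."""

    code: str  # OrphanRepair | EmptyMaze | FragmentOutsideMaze | ...
    message: str
    utterance_index: int | None = None


_LEXER = re.compile(r"[(){}]|[^\s(){}]+")
_ACTIVITY_HEADER = re.compile(r"^\+\s*Activity\s*:\s*(\w+)\s*$", re.IGNORECASE)
_ACTIVITY_BY_NAME = {a.value.lower(): a for a in Activity}
_SPEAKERS = {s.value: s for s in Speaker}


def _parse_line(line: str, lineno: int, activity: Activity) -> Utterance:
    fields = line.split(None, 1)
    code = fields[0]
    if code not in _SPEAKERS:
        raise UnknownSpeakerCode(f"unknown speaker code {code!r}", line=lineno, column=1)
    body = fields[1] if len(fields) > 1 else ""

    tokens: list[Token] = []
    labels: list[SpanLabel] = []
    complete = True
    terminator = ""
    state: SpanKind = SpanKind.FLUENT
    span_tokens = 0  # tokens seen inside the currently open span
    maze_id = -1
    empty_spans = 0
    open_col = 0

    for m in _LEXER.finditer(body):
        sym = m.group(0)
        col = m.start() + len(code) + 2
        if sym in "({":
            if state is not SpanKind.FLUENT:
                raise UnbalancedBrackets("nested or unclosed bracket", line=lineno, column=col)
            state = SpanKind.MAZE if sym == "(" else SpanKind.REPAIR
            maze_id += 1
            span_tokens = 0
            open_col = col
        elif sym in ")}":
            want = SpanKind.MAZE if sym == ")" else SpanKind.REPAIR
            if state is not want:
                raise UnbalancedBrackets(f"unmatched {sym!r}", line=lineno, column=col)
            if span_tokens == 0:
                empty_spans += 1
            state = SpanKind.FLUENT
        elif sym == ">":
            complete = False
        elif all(c in _TERMINAL_PUNCT for c in sym):
            # bare punctuation token, e.g. the "." after "{park}."
            terminator = sym
        else:
            tokens.append(Token.from_raw(sym, len(tokens)))
            labels.append(
                SpanLabel(kind=state, maze_id=maze_id if state is not SpanKind.FLUENT else -1)
            )
            span_tokens += 1

    if state is not SpanKind.FLUENT:
        raise UnbalancedBrackets("unclosed bracket", line=lineno, column=open_col)

    # sentence punctuation attached to a final fluent word becomes the terminator
    if tokens and labels[-1].kind is SpanKind.FLUENT and tokens[-1].raw[-1:] in ".?!":
        punct = tokens[-1].raw[-1]
        tokens[-1] = replace(tokens[-1], raw=tokens[-1].raw[:-1])
        terminator = punct
    if not complete:
        terminator = ""
    return Utterance(
        speaker=_SPEAKERS[code],
        activity=activity,
        tokens=tokens,
        labels=labels,
        complete=complete,
        terminator=terminator,
        empty_spans=empty_spans,
    )


def parse_transcript(text: str, child_id: str, ados_module: int = 3) -> Transcript:
    """Parse dialect text into a :class:`Transcript`.

    Raises :class:`UnbalancedBrackets`, :class:`UnknownSpeakerCode` or
    :class:`MissingActivityHeader` on malformed input; structural issues
    that do not prevent parsing (e.g. a repair with no preceding maze)
    are left for :func:`validate`.
    """
    utterances: list[Utterance] = []
    activity: Activity | None = None
    for lineno, rawline in enumerate(text.splitlines(), start=1):
        line = rawline.strip()
        if not line or line.startswith(";"):
            continue
        header = _ACTIVITY_HEADER.match(line)
        if header:
            name = header.group(1).lower()
            if name not in _ACTIVITY_BY_NAME:
                raise ParseError(f"unknown activity {header.group(1)!r}", line=lineno)
            activity = _ACTIVITY_BY_NAME[name]
            continue
        if activity is None:
            raise MissingActivityHeader("utterance before first activity header", line=lineno)
        utterances.append(_parse_line(line, lineno, activity))
    return Transcript(child_id=child_id, utterances=utterances, ados_module=ados_module)


def _serialize_utterance(u: Utterance) -> str:
    parts: list[str] = [u.speaker.value]
    for kind, _mid, toks in u.spans():
        words = " ".join(t.raw for t in toks)
        if kind is SpanKind.MAZE:
            parts.append(f"({words})")
        elif kind is SpanKind.REPAIR:
            parts.append(f"{{{words}}}")
        else:
            parts.append(words)
    line = " ".join(parts)
    if not u.complete:
        return line + " >"
    return line + u.terminator


def serialize_transcript(t: Transcript) -> str:
    """Emit canonical dialect text; inverse of :func:`parse_transcript`."""
    lines: list[str] = []
    current: Activity | None = None
    for u in t.utterances:
        if u.activity is not current:
            current = u.activity
            lines.append(f"+Activity: {current.value}")
        lines.append(_serialize_utterance(u))
    return "\n".join(lines) + ("\n" if lines else "")


def validate(t: Transcript) -> list[Issue]:
    """Check module invariants; returns issues instead of raising."""
    issues: list[Issue] = []
    if not t.child_id:
        issues.append(Issue("EmptyChildId", "transcript has no child_id"))
    for i, u in enumerate(t.utterances):
        spans = u.spans()
        seen_ids: set[int] = set()
        prev_kind: SpanKind | None = None
        last_id = -1
        for kind, mid, toks in spans:
            if kind is SpanKind.REPAIR and prev_kind is not SpanKind.MAZE:
                issues.append(Issue("OrphanRepair", "repair span without preceding maze", i))
            if kind is not SpanKind.FLUENT:
                if mid in seen_ids or mid <= last_id:
                    issues.append(Issue("SpanOrder", "maze_ids not increasing", i))
                seen_ids.add(mid)
                last_id = mid
            prev_kind = kind
        for _ in range(u.empty_spans):
            issues.append(Issue("EmptyMaze", "bracketed span contains no tokens", i))
        for tok, lab in zip(u.tokens, u.labels):
            if not tok.norm:
                issues.append(Issue("EmptyToken", f"token {tok.raw!r} normalizes to nothing", i))
            if tok.is_fragment and lab.kind is SpanKind.FLUENT:
                issues.append(Issue("FragmentOutsideMaze", f"fragment {tok.raw!r} outside maze", i))
    return issues


def read_transcript(path: str, child_id: str | None = None, ados_module: int = 3) -> Transcript:
    """Read a ``.slt`` file; the child id defaults to the file stem."""
    import pathlib

    p = pathlib.Path(path)
    return parse_transcript(
        p.read_text(encoding="utf-8"),
        child_id=child_id or p.stem,
        ados_module=ados_module,
    )


def write_transcript(t: Transcript, path: str) -> None:
    import pathlib

    pathlib.Path(path).write_text(serialize_transcript(t), encoding="utf-8")
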