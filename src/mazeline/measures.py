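"""Transcript-level language-sample measures and inter-annotator agreement.

Covers mean length of utterance in morphemes (MLUM), per-child and
per-activity tallies of utterances, fluent words, disfluent intervals
and disfluency types, and the agreement procedure used to audit manual
maze annotation: a stratified sample of disfluent utterances, repair-span
agreement, and Cohen's kappa over disfluency-type labels.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .disfluency_core import (
    DisfluencyEvent,
    DisfluentInterval,
    DType,
    FillerLexicon,
    DEFAULT_FILLER_LEXICON,
    group_intervals,
)
from .transcript_io import SpanKind, Speaker, Transcript, Utterance

__all__ = [
    "CountsRow",
    "AgreementResult",
    "SampleItem",
    "NoEligibleUtterances",
    "ChildMismatch",
    "LengthMismatch",
    "DegenerateMarginals",
    "mlum",
    "counts_table",
    "counts_frame",
    "agreement_sample",
    "span_agreement",
    "cohen_kappa",
]

ALL = "ALL"


class NoEligibleUtterances(ValueError):
    pass


class ChildMismatch(ValueError):
    pass


class LengthMismatch(ValueError):
    pass


class DegenerateMarginals(ValueError):
    pass


def mlum(t: Transcript) -> float:
    """Mean length of utterance in morphemes over complete child utterances.

    Maze tokens are excluded: only fluent material (repairs included, as
    they sit outside the parentheses) contributes morphemes.  Morphemes
    are read off the explicit ``/`` bound-morpheme markers.
    """
    lengths: list[int] = []
    for u in t.child_utterances():
        if not u.complete or not u.tokens:
            continue
        lengths.append(
            sum(
                tok.morpheme_count
                for tok, lab in zip(u.tokens, u.labels)
                if lab.kind is not SpanKind.MAZE
            )
        )
    if not lengths:
        raise NoEligibleUtterances(f"{t.child_id}: no complete child utterance")
    return float(np.mean(lengths))


@dataclass
class CountsRow:
    """Per child x activity tallies (activity ``ALL`` pools the four)."""

    child_id: str
    activity: str
    n_utterances: int = 0
    n_fluent_words: int = 0
    n_intervals: int = 0
    counts: dict[str, int] = field(default_factory=lambda: {d.value: 0 for d in DType})

    @property
    def total_events(self) -> int:
        return sum(self.counts.values())


def counts_table(
    events: Sequence[DisfluencyEvent],
    transcripts: Sequence[Transcript],
    lexicon: FillerLexicon | Iterable[str] = DEFAULT_FILLER_LEXICON,
) -> list[CountsRow]:
    """One row per child x activity, plus an ALL row per child.

    Fluent words are child tokens outside any maze (repair tokens are
    fluent speech); intervals are counted directly from the transcripts
    so that stutter-only intervals, which yield no event, still appear
    in ``n_intervals``.
    """
    known = {t.child_id for t in transcripts}
    for ev in events:
        if ev.child_id not in known:
            raise ChildMismatch(f"event references unknown child {ev.child_id!r}")

    rows: dict[tuple[str, str], CountsRow] = {}

    def row(child: str, act: str) -> CountsRow:
        if (child, act) not in rows:
            rows[(child, act)] = CountsRow(child_id=child, activity=act)
        return rows[(child, act)]

    for t in transcripts:
        for u in t.utterances:
            if u.speaker is not Speaker.CHILD:
                continue
            act = u.activity.name
            r = row(t.child_id, act)
            r.n_utterances += 1
            r.n_fluent_words += sum(
                1 for lab in u.labels if lab.kind is not SpanKind.MAZE
            )
            r.n_intervals += len(group_intervals(u, lexicon))
    for ev in events:
        r = row(ev.child_id, ev.activity.name)
        r.counts[ev.dtype.value] += 1

    out: list[CountsRow] = []
    for child in sorted({c for c, _ in rows}):
        total = CountsRow(child_id=child, activity=ALL)
        for (c, act), r in sorted(rows.items()):
            if c != child:
                continue
            out.append(r)
            total.n_utterances += r.n_utterances
            total.n_fluent_words += r.n_fluent_words
            total.n_intervals += r.n_intervals
            for k, v in r.counts.items():
                total.counts[k] += v
        out.append(total)
    return out


def counts_frame(rows: Sequence[CountsRow]) -> pd.DataFrame:
    """Counts rows as a tidy DataFrame (one column per disfluency type)."""
    return pd.DataFrame(
        {
            "child_id": r.child_id,
            "activity": r.activity,
            "n_utterances": r.n_utterances,
            "n_fluent_words": r.n_fluent_words,
            "n_intervals": r.n_intervals,
            **r.counts,
            "total_events": r.total_events,
        }
        for r in rows
    )


@dataclass(frozen=True)
class SampleItem:
    child_id: str
    utterance_index: int
    first_interval: DisfluentInterval


def agreement_sample(
    transcripts: Sequence[Transcript],
    per_child: int = 4,
    seed: int | np.random.Generator = 0,
    lexicon: FillerLexicon | Iterable[str] = DEFAULT_FILLER_LEXICON,
) -> list[SampleItem]:
    """Stratified sample of disfluent utterances for an agreement audit.

    Draws ``per_child`` disfluent utterances from each child (all of
    them, with a warning, when a child has fewer); only the first
    disfluent interval of each sampled utterance is referenced, matching
    the unit of analysis of the audit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    items: list[SampleItem] = []
    for t in transcripts:
        candidates: list[tuple[int, DisfluentInterval]] = []
        for ui, u in enumerate(t.utterances):
            if u.speaker is not Speaker.CHILD:
                continue
            ivs = group_intervals(u, lexicon, utterance_index=ui)
            if ivs:
                candidates.append((ui, ivs[0]))
        if len(candidates) < per_child:
            warnings.warn(
                f"{t.child_id}: only {len(candidates)} disfluent utterances "
                f"(requested {per_child}); taking all",
                stacklevel=2,
            )
            chosen = range(len(candidates))
        else:
            chosen = rng.choice(len(candidates), size=per_child, replace=False)
            chosen = sorted(int(i) for i in chosen)
        for i in chosen:
            ui, iv = candidates[i]
            items.append(SampleItem(t.child_id, ui, iv))
    return items


def span_agreement(
    ann_a: Sequence[tuple[int, int] | None], ann_b: Sequence[tuple[int, int] | None]
) -> float:
    """Fraction of paired items whose repair token-index spans coincide."""
    if len(ann_a) != len(ann_b):
        raise LengthMismatch(f"{len(ann_a)} vs {len(ann_b)} items")
    if not ann_a:
        raise LengthMismatch("no items")
    return sum(a == b for a, b in zip(ann_a, ann_b)) / len(ann_a)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa: chance-corrected agreement between two label sequences."""
    if len(labels_a) != len(labels_b) or not labels_a:
        raise LengthMismatch("label sequences must be paired and non-empty")
    n = len(labels_a)
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    labels = set(ca) | set(cb)
    p_e = sum(ca[l] * cb[l] for l in labels) / n**2
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0:
            return 1.0
        raise DegenerateMarginals("chance agreement is 1 with imperfect observed agreement")
    return (p_o - p_e) / (1 - p_e)


@dataclass
class AgreementResult:
    span_agreement: float
    type_agreement: float
    kappa: float
    n_items: int


def agreement_result(
    spans_a: Sequence[tuple[int, int] | None],
    spans_b: Sequence[tuple[int, int] | None],
    types_a: Sequence[str],
    types_b: Sequence[str],
) -> AgreementResult:
    """Bundle span agreement, raw type agreement, and kappa for an audit."""
    if not (len(spans_a) == len(spans_b) == len(types_a) == len(types_b)):
        raise LengthMismatch("all four sequences must be paired")
    n = len(types_a)
    return AgreementResult(
        span_agreement=span_agreement(spans_a, spans_b),
        type_agreement=sum(a == b for a, b in zip(types_a, types_b)) / n,
        kappa=cohen_kappa(types_a, types_b),
        n_items=n,
    )
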