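"""Synthetic cohorts with known disfluency ground truth.

Every stage of the pipeline — parsing, interval grouping, type
classification, cue detection, counting, regression — is testable
against this generator: it emits dialect transcripts together with the
gold event list the classifier must reproduce exactly, plus subject
records (group, verbal IQ, age) for the cohort statistics.

The default configuration mirrors the study population the schema was
developed on: three diagnostic groups (ASD n=47, SLI n=18, TD n=32)
whose verbal-IQ distributions, disfluency type mixes (about 72% of the
ASD group's disfluencies are content mazes versus about 51% for TD) and
cue probabilities (0.29 ASD, 0.41 TD) follow the published group-level
figures, with per-activity log-odds offsets modulating both the
content-vs-filler balance and cueing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .disfluency_core import DisfluencyEvent, DType, Subtype
from .transcript_io import Activity, Transcript, parse_transcript

__all__ = [
    "GroupSpec",
    "SynthConfig",
    "TokenTableConfig",
    "InvalidConfig",
    "default_cohort_config",
    "simulate_cohort",
    "simulate_token_table",
]


class InvalidConfig(ValueError):
    pass


# closed vocabulary, disjoint from the filler lexicon; nouns may take "/s"
_VOCAB = (
    "my the a dog cat ball park pool big red we they go want see play "
    "nice house tree car boy girl jump run good little"
).split()
_NOUNS = {"dog", "cat", "ball", "park", "pool", "house", "tree", "car", "boy", "girl"}
_FILLERS = ("um", "uh", "hmm", "ah")
_PLURAL_PROB = 0.12


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_subjects: int
    viq_mean: float
    viq_sd: float
    ca_mean: float = 6.8
    ca_sd: float = 1.0
    rate: float = 0.15  # disfluent intervals per fluent word
    #: unconditional type mix over REP / REV / FS / F; sums to 1
    type_mix: dict[str, float] = field(
        default_factory=lambda: {"REP": 0.25, "REV": 0.15, "FS": 0.20, "F": 0.40}
    )
    cue_prob: float = 0.35


@dataclass(frozen=True)
class SynthConfig:
    groups: tuple[GroupSpec, ...]
    utterances_per_activity: int = 25
    words_per_utterance: tuple[int, int] = (4, 9)
    #: log-odds offsets on the content-vs-filler balance per activity
    content_offsets: dict[str, float] = field(
        default_factory=lambda: {"PLAY": 0.074, "PICTURE": -0.088, "STORY": 0.360, "CONVERSATION": -0.347}
    )
    #: log-odds offsets on cue probability per activity
    cue_offsets: dict[str, float] = field(
        default_factory=lambda: {"PLAY": -0.071, "PICTURE": 0.061, "STORY": -0.164, "CONVERSATION": 0.174}
    )
    stutter_prob: float = 0.02
    fragment_rep_prob: float = 0.15
    incomplete_prob: float = 0.05
    examiner_turn_prob: float = 0.25
    module2_prob: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise InvalidConfig("no groups")
        for g in self.groups:
            if abs(sum(g.type_mix.values()) - 1.0) > 1e-9:
                raise InvalidConfig(f"{g.name}: type mix must sum to 1")
            if g.rate < 0:
                raise InvalidConfig(f"{g.name}: negative disfluency rate")
            if not 0 <= g.cue_prob <= 1:
                raise InvalidConfig(f"{g.name}: cue probability outside [0,1]")
            if any(p < 0 for p in g.type_mix.values()):
                raise InvalidConfig(f"{g.name}: negative mix entry")
        lo, hi = self.words_per_utterance
        if lo < 1 or hi < lo:
            raise InvalidConfig("words_per_utterance must be 1 <= lo <= hi")


def _mix(rep: int, rev: int, fs: int, f: int, cue_prob: float) -> dict[str, float]:
    """Interval-level type mix whose *realized* event mix hits the targets.

    The target proportions (from per-group event counts) include cue
    fillers among F.  The generator emits one extra F event per cued
    content interval, so the interval-level content probability q must
    satisfy  q / (1 + q * cue_prob) = m, where m is the target marginal
    content share; the remainder goes to plain filler intervals.
    """
    total = rep + rev + fs + f
    content = rep + rev + fs
    m = content / total
    q = m / (1.0 - m * cue_prob)
    return {
        "REP": q * rep / content,
        "REV": q * rev / content,
        "FS": q * fs / content,
        "F": 1.0 - q,
    }


def default_cohort_config(seed: int = 0) -> SynthConfig:
    """Study-scale defaults: group sizes, VIQ/age distributions, per-group
    disfluency type mixes (from the published per-group type counts) and
    cue probabilities."""
    return SynthConfig(
        groups=(
            GroupSpec("ASD", 47, 94.8, 17.8, ca_mean=6.7, ca_sd=1.1,
                      type_mix=_mix(rep=1315, rev=695, fs=1180, f=1269, cue_prob=0.29),
                      cue_prob=0.29),
            GroupSpec("SLI", 18, 86.1, 6.1, ca_mean=7.1, ca_sd=1.0,
                      type_mix=_mix(rep=352, rev=202, fs=410, f=588, cue_prob=0.35),
                      cue_prob=0.35),
            GroupSpec("TD", 32, 116.9, 12.9, ca_mean=6.8, ca_sd=1.0,
                      type_mix=_mix(rep=659, rev=503, fs=754, f=1867, cue_prob=0.41),
                      cue_prob=0.41),
        ),
        seed=seed,
    )


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _sample_word(rng: np.random.Generator) -> str:
    w = _VOCAB[rng.integers(len(_VOCAB))]
    if w in _NOUNS and rng.random() < _PLURAL_PROB:
        return w + "/s"
    return w


def _sample_phrase(rng: np.random.Generator, lo: int, hi: int) -> list[str]:
    return [_sample_word(rng) for _ in range(int(rng.integers(lo, hi + 1)))]


def _norm(w: str) -> str:
    return w.lower()


def _make_interval(
    rng: np.random.Generator, cfg: SynthConfig, g: GroupSpec, activity: str
) -> tuple[list[str], list[DisfluencyEvent], int]:
    """One disfluent interval: (dialect chunks, gold events, n planted mazes).

    Chunks are already-bracketed strings like ``(my dog)`` or ``{my cat}``.
    Gold events are in element order, matching the classifier's output
    order; ``element_index`` is filled in relative to the interval.
    """
    if rng.random() < cfg.stutter_prob:
        # unresolved fragment: excluded from counting
        word = _VOCAB[rng.integers(len(_VOCAB))]
        frag = word[: max(2, len(word) - 1)] + "-"
        return [f"({frag})"], [], 1

    p_content = _sigmoid(
        _logit(g.type_mix["REP"] + g.type_mix["REV"] + g.type_mix["FS"])
        + cfg.content_offsets.get(activity, 0.0)
    )
    if rng.random() >= p_content:
        if rng.random() < 0.1:
            return ["(I mean)"], [DisfluencyEvent(dtype=DType.F, element_index=0)], 1
        filler = _FILLERS[rng.integers(len(_FILLERS))]
        return [f"({filler})"], [DisfluencyEvent(dtype=DType.F, element_index=0)], 1

    content_mix = {k: g.type_mix[k] for k in ("REP", "REV", "FS")}
    total = sum(content_mix.values())
    r = rng.random() * total
    dtype = DType.FS
    for k in ("REP", "REV", "FS"):
        if r < content_mix[k]:
            dtype = DType(k)
            break
        r -= content_mix[k]

    subtype = Subtype.NONE
    if dtype is DType.REP:
        repair = _sample_phrase(rng, 1, 2)
        if len(repair) == 1 and len(repair[0]) > 2 and "/" not in repair[0] and rng.random() < cfg.fragment_rep_prob:
            cut = int(rng.integers(2, len(repair[0])))
            maze = [repair[0][:cut] + "-"]
        else:
            maze = list(repair)
    elif dtype is DType.REV:
        kind = ("DEL", "INS", "SUB")[rng.integers(3)]
        if kind == "DEL":
            maze = _sample_phrase(rng, 2, 3)
            drop = int(rng.integers(len(maze)))
            repair = maze[:drop] + maze[drop + 1 :]
            subtype = Subtype.DEL
        elif kind == "INS":
            maze = _sample_phrase(rng, 1, 2)
            at = int(rng.integers(len(maze) + 1))
            repair = maze[:at] + [_sample_word(rng)] + maze[at:]
            subtype = Subtype.INS
        else:
            maze = _sample_phrase(rng, 1, 3)
            at = int(rng.integers(len(maze)))
            new = _sample_word(rng)
            while _norm(new) == _norm(maze[at]):
                new = _sample_word(rng)
            repair = list(maze)
            repair[at] = new
    else:  # FS
        maze = _sample_phrase(rng, 1, 3)
        repair = None

    cued = rng.random() < _sigmoid(_logit(g.cue_prob) + cfg.cue_offsets.get(activity, 0.0))
    chunks: list[str] = []
    events: list[DisfluencyEvent] = []
    n_mazes = 1
    filler_first = bool(cued and rng.random() < 0.5)
    if cued and filler_first:
        chunks.append(f"({_FILLERS[rng.integers(len(_FILLERS))]})")
        events.append(DisfluencyEvent(dtype=DType.F, element_index=0))
        n_mazes += 1
    ei = len(events)
    chunks.append("(" + " ".join(maze) + ")")
    events.append(DisfluencyEvent(dtype=dtype, subtype=subtype, cued=cued, element_index=ei))
    if cued and not filler_first:
        chunks.append(f"({_FILLERS[rng.integers(len(_FILLERS))]})")
        events.append(DisfluencyEvent(dtype=DType.F, element_index=ei + 1))
        n_mazes += 1
    if repair is not None:
        chunks.append("{" + " ".join(repair) + "}")
    return chunks, events, n_mazes


@dataclass
class GoldBook:
    """Generator-side bookkeeping returned alongside the gold events."""

    n_planted_mazes: int = 0
    n_stutter_mazes: int = 0


def simulate_cohort(
    cfg: SynthConfig,
) -> tuple[list[Transcript], list["SubjectRecord"], list[DisfluencyEvent], GoldBook]:
    """Generate transcripts, subject records, and gold-labelled events.

    The emitted transcripts are produced by serializing and re-parsing
    the generated dialect text, so they are guaranteed to parse cleanly;
    gold events carry exactly the labels the classifier should recover.
    """
    from .cohort_stats import SubjectRecord  # local import: avoid cycle at import time

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    transcripts: list[Transcript] = []
    subjects: list[SubjectRecord] = []
    gold: list[DisfluencyEvent] = []
    book = GoldBook()

    child_no = 0
    for g in cfg.groups:
        for _ in range(g.n_subjects):
            child_no += 1
            child_id = f"{g.name.lower()}{child_no:03d}"
            module = 2 if rng.random() < cfg.module2_prob else 3
            subjects.append(
                SubjectRecord(
                    child_id=child_id,
                    group=g.name,
                    viq=float(rng.normal(g.viq_mean, g.viq_sd)),
                    ados_module=module,
                    covariates={"CA": float(rng.normal(g.ca_mean, g.ca_sd))},
                )
            )
            lines: list[str] = []
            utt_index = 0
            child_gold: list[DisfluencyEvent] = []
            for activity in Activity:
                lines.append(f"+Activity: {activity.value}")
                for _ in range(cfg.utterances_per_activity):
                    if rng.random() < cfg.examiner_turn_prob:
                        words = _sample_phrase(rng, *cfg.words_per_utterance)
                        lines.append("E " + " ".join(words) + "?")
                        utt_index += 1
                    lo, hi = cfg.words_per_utterance
                    n_words = int(rng.integers(lo, hi + 1))
                    words = [_sample_word(rng) for _ in range(n_words)]
                    incomplete = rng.random() < cfg.incomplete_prob
                    n_disf = 0 if incomplete else int(rng.binomial(n_words, g.rate))
                    positions = sorted(
                        int(p) for p in rng.choice(n_words, size=min(n_disf, n_words), replace=False)
                    )
                    chunks: list[str] = []
                    interval_index = 0
                    for wi, w in enumerate(words):
                        if wi in positions:
                            ivc, evs, n_mazes = _make_interval(rng, cfg, g, activity.name)
                            chunks.extend(ivc)
                            book.n_planted_mazes += n_mazes
                            if not evs:
                                book.n_stutter_mazes += 1
                            for ev in evs:
                                ev.child_id = child_id
                                ev.activity = activity
                                ev.utterance_index = utt_index
                                ev.interval_index = interval_index
                                child_gold.append(ev)
                            interval_index += 1
                        chunks.append(w)
                    line = "C " + " ".join(chunks) + (" >" if incomplete else ".")
                    lines.append(line)
                    utt_index += 1
            t = parse_transcript("\n".join(lines) + "\n", child_id=child_id, ados_module=module)
            transcripts.append(t)
            gold.extend(child_gold)
    return transcripts, subjects, gold, book


# ---------------------------------------------------------------------------
# direct token-table generator for regression tests


@dataclass(frozen=True)
class TokenTableConfig:
    """Logistic-model generator with planted effects.

    ``group_logodds`` maps each group to its sum-coded effect (values
    should sum to 0); subjects are split evenly across groups, each with
    ``tokens_per_subject`` Bernoulli outcomes and a normal random
    intercept of sd ``random_intercept_sd``.
    """

    n_subjects: int = 100
    tokens_per_subject: int = 100
    intercept: float = 0.0
    group_logodds: dict[str, float] = field(
        default_factory=lambda: {"ASD": 0.4, "SLI": 0.0, "TD": -0.4}
    )
    viq_logodds: float = 0.0
    activity_logodds: dict[str, float] = field(
        default_factory=lambda: {"PLAY": 0.0, "PICTURE": 0.0, "STORY": 0.0, "CONVERSATION": 0.0}
    )
    random_intercept_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < len(self.group_logodds):
            raise InvalidConfig("fewer subjects than groups")
        if self.tokens_per_subject < 1:
            raise InvalidConfig("tokens_per_subject must be >= 1")
        if self.random_intercept_sd < 0:
            raise InvalidConfig("negative random-intercept sd")


def simulate_token_table(cfg: TokenTableConfig) -> list["TokenRow"]:
    """Draw token rows from the planted mixed-logit model."""
    from .cohort_stats import TokenRow

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_logodds)
    activities = list(cfg.activity_logodds)
    rows: list[TokenRow] = []
    viqs = rng.standard_normal(cfg.n_subjects)
    viqs = (viqs - viqs.mean()) / viqs.std(ddof=1)
    for s in range(cfg.n_subjects):
        grp = groups[s % len(groups)]
        b = float(rng.normal(0.0, cfg.random_intercept_sd))
        viq_z = float(viqs[s])
        acts = rng.integers(len(activities), size=cfg.tokens_per_subject)
        for a in acts:
            act = activities[int(a)]
            eta = (
                cfg.intercept
                + cfg.group_logodds[grp]
                + cfg.viq_logodds * viq_z
                + cfg.activity_logodds[act]
                + b
            )
            rows.append(
                TokenRow(
                    child_id=f"s{s:04d}",
                    outcome=int(rng.random() < _sigmoid(eta)),
                    group=grp,
                    viq_z=viq_z,
                    activity=act,
                )
            )
    return rows
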