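# mazeline

Disfluency coding and analysis for maze/repair-annotated child-language
transcripts.

Speech-language researchers studying children with autism spectrum
disorder (ASD) or specific language impairment (SLI) quantify *disfluency*
— repetitions, revisions, false starts, and fillers — from language
samples such as ADOS session transcripts. Transcribers mark *mazes*
(stretches of disfluent speech a listener must mentally excise) in
parentheses and the *repairs* that replace them in curly braces:

    I like going to the (pool) {park}.

`mazeline` turns such transcripts into quantitative results: it parses a
precisely defined SALT-style dialect, groups mazes and repairs into
disfluent intervals, classifies every interval automatically, derives
per-child measures, and runs the group-comparison statistics.

## The classification schema

A disfluent interval is one or more consecutive mazes optionally followed
by a repair. Each content maze is compared with its repair by
minimum-edit-distance alignment at the word level (a fragment `do-`
matches a word it prefixes, like `dog`):

| type | definition | example |
|---|---|---|
| repetition (REP) | maze = repair (edit cost 0) | `(My) {My} dog is nice.` |
| revision (REV) | maze ≠ repair; subtypes deletion / insertion | `(My old dog) {My dog} is nice.` |
| false start (FS) | content maze with no repair | `(But what if) My friend likes dogs.` |
| filler (F) | filled pauses & discourse markers | `um, uh, like, I mean, …` |

Mazes smaller than a prosodic word (unresolved fragments, "stutters") are
ignored. A content maze is *cued* when a filler is adjacent to it —
between maze and repair, or immediately before/after the maze, as in
`(cat) (um) {dog}`.

Group inference uses mixed-effects logistic regression with a per-subject
random intercept: for tokens *t* of subject *s*,

    logit P(y_st = 1) = β₀ + β_group(s) + β_viq · VIQ_s(z) + β_activity(t) + b_s,
    b_s ~ N(0, σ²)

with sum-coded factors, likelihood-ratio tests per factor, and Tukey-style
single-step all-pairs group contrasts. Maximum likelihood is computed by
adaptive Gauss–Hermite quadrature (verified against lme4's `glmer`,
nAGQ=25, in the test suite). Exploratory correlations use Kendall's τ_b
with Benjamini–Hochberg FDR adjustment; cohort matching uses Welch's
unequal-variance t and the two-sample Anderson–Darling test with a greedy
trimming search (groups match when all p ≥ .2).

## Worked example

```python
from mazeline import transcript_io as tio, disfluency_core as dc, measures

text = """\
+Activity: Play
C I like going to the (pool) (um) {park}.
C (My) {My} dog/s are nice.
E what else do you like?
C (But what if) we go home.
"""
t = tio.parse_transcript(text, child_id="demo")
for ev in dc.extract_events(t):
    print(f"{ev.activity.name:<5} utt {ev.utterance_index} -> {ev.dtype.value:<3} "
          f"subtype={ev.subtype.value:<4} cued={ev.cued}")
print(f"MLUM = {measures.mlum(t):.2f}")
```

prints

```
PLAY  utt 0 -> REV subtype=NONE cued=True
PLAY  utt 0 -> F   subtype=NONE cued=False
PLAY  utt 1 -> REP subtype=NONE cued=False
PLAY  utt 3 -> FS  subtype=NONE cued=False
MLUM = 4.67
```

The first utterance is one disfluent interval holding a content maze
(`pool`), a filler (`um`), and a repair (`park`): the maze differs from
its repair, so it is a revision, and the filler between them makes it
cued; the filler itself also counts as an F event. `(My) {My}` aligns at
cost zero (repetition), and `(But what if)` has no repair (false start).
MLUM is the mean length of utterance in morphemes over complete child
utterances, excluding maze material: (6 + 5 + 3) / 3 ≈ 4.67 morphemes
(`dog/s` carries an explicit bound-morpheme marker and counts 2; the
examiner line and maze tokens are excluded).

## Command line

```sh
mazeline simulate --seed 3 --out-dir cohort/          # synthetic study cohort
mazeline parse    --in cohort/asd001.slt --json       # dialect -> JSON
mazeline classify --in cohort/asd001.slt --events-out events.csv
mazeline counts   --in cohort/ --out counts.csv       # per child x activity
mazeline agree    --a cohort/ --b cohort/ --per-child 4 --seed 1 --out agree.json
mazeline analyze  --events events.csv --subjects cohort/subjects.csv \
                  --contrast content_vs_filler --out result.json
```

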