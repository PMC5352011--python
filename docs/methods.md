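# Methods

## The coding schema and its operationalization

The package classifies *disfluent intervals*: maximal runs of consecutive
mazes (no fluent token between them) plus an immediately following repair
span, if any. Every maze and repair token belongs to exactly one
interval.

**Maze kinds.** A maze whose tokens are entirely consumed by filler
lexicon matches (longest-match, left to right; multiword entries such as
*I mean* allowed) is a filler maze; anything else is a content maze. The
default lexicon is *like, um, uh, mm, hmm, I mean, ah*, overridable via
configuration. *like* counts as a filler only when it appears inside a
maze — annotators only bracket disfluent material, so an unbracketed
*like* is an ordinary word.

**Repair pairing.** When an interval holds several content mazes (stacked
self-corrections such as `(I) (I want) {I need}`), the right-most content
maze pairs with the repair and each earlier content maze pairs with the
next content maze, which acts as its repair. This handles stacked repairs
while reproducing every single-maze worked example exactly. Whether the
original annotation tool compared the repair against the nearest maze or
a concatenation of all of them is not documented anywhere we could find;
nearest-maze pairing is this package's documented choice.

**Classification.** A content maze with a repair target is a repetition
when word-level minimum-edit alignment costs 0 and a revision otherwise;
revision subtype is DEL when the optimal script contains only
MATCH and DEL operations, INS when only MATCH and INS, otherwise NONE
(these conditions are provably equivalent to the repair being a proper
subsequence of the maze, and vice versa — property-tested). A content
maze with no target is a false start. Alignment treats a word fragment
(`do-`) as matching any word it prefixes, so `(do-) {dog}` is a
repetition (a mid-word interruption). Tie-breaking prefers MATCH, then
SUB, then DEL, then INS during backtrace, so a substitution is never
split into DEL+INS and classification is deterministic.

**Stutters.** A content maze consisting solely of fragments that is not
resolved by its target's first word (or has no target) is below the
prosodic-word threshold and yields no event. A fragment that prefixes
its repair's first word is a repetition, per the worked mid-word example.

**Cues.** A content-maze event is cued when a filler maze is adjacent to
it within the interval (no fluent token intervenes): between maze and
repair, or immediately before/after the maze. Fillers in a content
interval are counted as F events *and* serve as cues — type tallies count
fillers as a type, and the cue definition independently references them.

**Incomplete utterances.** The `>`-marked incomplete utterances are
excluded from MLUM (complete child utterances only, the SALT convention)
but still contribute disfluency events; the source methodology is silent
on the latter point, so this is the package's choice.

## Transcript dialect

One C-unit per line; first field is the speaker code (`C`/`E`); mazes in
`( )`, repairs in `{ }`; `/` marks bound morphemes (`dog/s` = 2
morphemes); a trailing `-` marks a fragment; `>` marks an incomplete
utterance; `+Activity:` headers assign the four ADOS activities (Play,
Picture, Story, Conversation) to all following utterances. Nested
brackets are rejected. Token comparison is case-insensitive with terminal
`.,?!` stripped. Utterance-final sentence punctuation is stored as a
terminator attribute so that parse∘serialize is an exact identity; this
round-trip holds by property test for every generated transcript.
Structural problems that do not prevent parsing (orphan repairs, empty
brackets, fragments outside mazes) are reported by `validate` as issue
records rather than raised.

## Measures

MLUM is the mean, over complete child utterances, of the summed morpheme
counts of non-maze tokens (repairs are outside parentheses and count as
fluent speech; morphemes come from explicit `/` markers, not from
morphological analysis). Fluent-word counts cover child speech only.
Count tables carry one row per child × activity plus an ALL row; the
interval count is recomputed from the transcript so stutter-only
intervals, which produce no event, are still counted.

The agreement audit draws a stratified sample (default four disfluent
utterances per child, seeded; all of them with a warning when a child has
fewer) and uses only the first interval of each sampled utterance. Span
agreement is the fraction of identical repair token-index spans; type
agreement is raw label agreement; κ is Cohen's kappa over the four type
labels. With identical annotations all three are exactly 1 (tested).

## Regression model

Each disfluency event is a Bernoulli token. Four contrasts define the
outcome: content maze vs filler (all events), repetition vs revision,
false start vs repair-based (content events), and cued vs uncued (content
events — false starts are content mazes and are included). Fixed effects
are diagnostic group and ADOS activity (sum-coded: level effects sum to
zero, the last level reported as minus the sum with its SE from the full
covariance) and verbal IQ z-scored over the included subjects (unbiased
SD); the model has a per-subject random intercept b ~ N(0, σ²).

Likelihood is maximized by adaptive Gauss–Hermite quadrature with 20
nodes: for every evaluation, each subject's nodes are recentred at the
posterior mode of its intercept (found by a vectorized Newton iteration)
and scaled by the Laplace width. Non-adaptive quadrature is inadequate
here — with ~100 tokens per subject the integrand is far narrower than
the prior and a 25-node non-adaptive rule inflates the log-likelihood by
several units. The adaptive implementation reproduces `glmer`
(lme4, nAGQ=25) log-likelihood, estimates, and standard errors to four
decimals on a 100-subject × 100-token dataset; that cross-check is part
of the test suite. Optimization is L-BFGS-B with an analytic gradient
and σ ≥ 0; convergence requires the gradient inf-norm below 1e-4 scaled
per 1000 observations, otherwise a warning with optimizer diagnostics is
attached to the result. Standard errors come from the observed
information (central finite differences of the analytic gradient).
With a single observation per subject σ is not identified (a β–σ ridge);
`fix_sigma=0` pins the model to a plain logistic fit for that degenerate
design, and the reduction is verified against `statsmodels.Logit` to
1e-3.

Per-factor significance uses likelihood-ratio tests refitting the model
without the whole factor (df = levels − 1, or 1 for VIQ). Post hoc group
comparisons are all-pairs contrasts with single-step max-|Z| familywise
adjustment; because all pairwise contrasts of one factor are linearly
dependent, the joint null distribution is evaluated by seeded Monte Carlo
sampling (200k draws) of the underlying normal, the multcomp idiom.

## Supporting statistics

Kendall's τ_b and its two-sided p come from `scipy.stats.kendalltau`
(exact enumeration for small untied samples, tie-corrected normal
approximation otherwise). FDR adjustment is Benjamini–Hochberg step-up
(`statsmodels`). Welch's t uses Satterthwaite degrees of freedom
(`scipy`). The two-sample Anderson–Darling test is the midrank k-sample
version (`scipy.stats.anderson_ksamp`); its asymptotic p is interpolated
and clipped to [0.001, 0.25], which is sufficient for the matching
threshold of 0.2, and a seeded permutation p is available for very small
samples. τ_b, κ, BH, Welch, and the AD statistic are all tested against
independent direct-formula or enumeration oracles on hundreds of random
small inputs.

**Matching.** Constraints name a variable and a set of groups; a
constraint passes when every pairwise Welch p and the Anderson–Darling p
are at least the threshold (default .2). The search greedily removes the
single subject whose exclusion most increases the worst constraint p,
never shrinking a group below a floor (default 3), and raises
`Unsatisfiable` when no removal makes progress. This is a deliberately
simple search — acceptance is defined by the final test battery, which
the result re-reports, not by reproducing any particular published
matching algorithm's subsets.

## Synthetic data

`simulate_cohort` writes dialect text and parses it back, so emitted
transcripts round-trip by construction, and it returns gold event labels
that the classifier must reproduce exactly — the end-to-end gate of the
test suite (five seeds, 100% agreement required). Defaults mirror the
study population: groups ASD n=47 (VIQ 94.8 ± 17.8, age 6.7 ± 1.1),
SLI n=18 (86.1 ± 6.1, 7.1 ± 1.0), TD n=32 (116.9 ± 12.9, 6.8 ± 1.0);
type mixes derived from the published per-group event counts (content
shares ≈ 72% / 62% / 51%); cue probabilities .29 / .35 / .41;
per-activity log-odds offsets on both the content-vs-filler balance and
cueing taken from the published activity effects. Because a cued content
interval emits an extra filler event, the interval-level content
probability q is back-computed from the target marginal share m via
q/(1 + q·cue) = m, so the realized corpus reproduces the published
marginal proportions. The disfluency rate is 0.15 intervals per fluent
word with 25 utterances per activity of 4–9 words, giving roughly 100–115
events per child, the scale of the original corpus. Revisions are
generated by perturbing a sampled phrase (delete/insert/substitute one
word), so subtype gold labels are known; repetitions occasionally use a
fragment maze (mid-word interruption); 2% of planted mazes are
unresolvable-fragment stutters; 5% of utterances are incomplete;
examiner turns are interleaved. The vocabulary is a small closed word
list, disjoint from the filler lexicon, with occasional `/s` plurals so
MLUM is exercised.

What the cohort generator does **not** emulate: per-child heterogeneity
in type mix or cue rate within a group (children in a group share the
same propensities, so regression σ estimates on cohort output are near
zero and standard errors are smaller than in real data), lexical or
syntactic realism, prosody and timing, annotator disagreement or
annotation noise. Passing the end-to-end tests therefore demonstrates
the correctness of parsing, grouping, classification, and counting on
well-formed annotations — not robustness to noisy human transcription.

`simulate_token_table` generates regression tokens directly from the
logistic model with planted group / VIQ / activity log-odds and a
per-subject random intercept (default SD 0.5 on the log-odds scale,
a between-child spread of roughly 30–75% around a 50% mean proportion).
It is the ground truth for fitter validation: planted ±0.4 group effects
at 100 subjects × 100 tokens are recovered within 2 SE for ≥80% of level
estimates with the group LRT rejecting in ≥80% of 20 replicates, and
under a planted null the LRT rejection rate over 500 replicates of 60
subjects × 16 tokens lies in 0.05 ± 0.02. The 60 × 16 size keeps 500
replicates cheap while the χ² reference for a between-subject factor is
still trustworthy; rejection rates at this size run slightly above
nominal (~0.06–0.07), a known finite-sample property of the LRT here,
shared with lme4.

## Numerical and degenerate-input conventions

Brackets must balance per line (reported with line and column); a repair
with no preceding maze parses but is flagged. κ with both annotators
constant on the same label returns 1. τ_b on a fully tied variable,
Welch/AD on samples of fewer than two points (or both constant), and
z-transformation of a constant vector raise typed errors. In token
tables with a single included subject (or identical VIQs) the VIQ
z-score is set to 0 rather than failing. A constant regression outcome
raises a separation error. All stochastic components — generators,
agreement sampling, the permutation AD option, and the post hoc Monte
Carlo — take explicit seeds; fixed inputs give bit-identical results.
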