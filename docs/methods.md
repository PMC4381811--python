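# Methods

This note documents the models implemented in `searchseq`, the
assumptions behind them, the calibration of the synthetic generator,
and the numerical choices that matter for reproducing results.

## Data model

The unit of analysis is the *search activity*: one coded action from a
closed 18-symbol alphabet partitioned into five stages (querying,
accessing, evaluating, using, discarding). A *session* is one
participant's ordered activity sequence for one health topic; a corpus
partitions labeled sessions into familiarity groups L1/L2/L3. Codes
are stored as canonical strings exactly as defined by the coding scheme
(stage prefix, colon, mixed case); readers reject near-misses instead
of normalizing them so that corpora stay auditable. Sessions that fail
validation (unknown codes, non-consecutive step indices, empty
sequences) are excluded from all statistics and reported, so analyses
run only on qualified sessions.

## Familiarity scoring

Each topic is probed by six questionnaire items: two surface-recognition
items (0.15 points each when correct) and four conceptual items (0.175
each), for a per-topic score in [0, 1]. Labels: L1 iff points ≤ 0.3,
L2 iff 0.3 < points ≤ 0.65, L3 otherwise. Scores are computed in
integer milli-points (150/175 per item; thresholds 300/650), so the
inclusive boundaries at 0.3 and 0.65 classify exactly — floating-point
accumulation of 0.15 + 0.175 + … can land on either side of the
threshold, and the boundary cases are precisely the ones the thresholds
are about. "Unknown" answers score 0, identically to incorrect
answers: respondents are instructed to mark "Unknown" rather than
guess, and only correct answers earn points. Incomplete or duplicated
questionnaires are rejected with the offending (section, item) slots
named; no imputation is attempted.

## Transition matrices and their comparison

First-order transition counts f_ij are tallied over consecutive pairs
within sessions only — a session of length L contributes L − 1
transitions, and no pair crosses a session boundary. Probabilities are
row-normalized; rows never observed as a source keep all-zero
probability rows rather than uniform ones, and the comparison handles
the resulting structural zeros explicitly. Ranked transition reports
break frequency ties lexicographically on (from, to) code strings, so
reports are deterministic. The descriptive mean/SD of per-pair counts
uses the population denominator (ddof = 0) over cells observed at least
once; the convention is noted in the API documentation because either
choice is defensible.

The two-sample comparison follows the Chen–Cooper Markov-chain
procedure. With sample A as reference and sample B tested, expected
counts are E_ij = (B's row-i total) × p_ij^A, and

    C = Σ_{E_ij > 0} (f_ij^B − E_ij)² / E_ij

is referred to a chi-square distribution with df = K² − N1 − N2, where
K is the number of states in the state space, N1 the number of states
actually appearing in B (as source or target), and N2 the number of
impossible transitions — operationalized as the number of cells with
zero expectation, which covers both cells A never realizes and whole
rows B never occupies. Equivalently df = (cells used) − N1. A
degenerate df (≤ 0, possible for near-deterministic toy chains whose
usable cells are fewer than their states) raises an error rather than
producing a meaningless decision.

Two deliberate choices:

- **Direction.** The procedure is asymmetric and the natural reporting
  direction is unspecified in general, so `compare_groups` computes
  both directions and reports the maximum-C direction by default; both
  are retained on the result object.
- **Significance level.** The default is α = 0.001. The critical
  values this pipeline is checked against (104.716 at df 64, 99.607 at
  df 60) are exactly the 0.001 upper-tail chi-square quantiles, so that
  tail is the default; α is a parameter everywhere it appears.

**Reference-size sensitivity.** The chi-square approximation treats
A's kernel as known. When A is estimated from a sample of comparable
size to B, the statistic's variance is inflated by roughly
(1 + n_B/n_A) and the test becomes anticonservative — with equal-size
samples E[C] ≈ 2·df and false rejections are common even under a shared
kernel. The implementation is faithful to the procedure; the
calibration tests therefore draw the tested sample from the reference's
(effectively exact) kernel, and users comparing similar-sized groups
should read small C excesses over the critical value with this in
mind. For strongly separated groups (the regime the pipeline targets,
where C exceeds the critical value by an order of magnitude) the
inflation is immaterial.

## n-gram models and order selection

Sessions are sentences over the closed vocabulary of 18 activity codes
plus boundary markers: n − 1 start markers are prepended (conditioned
on, never predicted) and one end marker appended (predicted and counted
in the token total). Conditionals use *interpolated* Witten-Bell
discounting

    p(w | h) = (c(h, w) + T(h) · p(w | h')) / (c(h) + T(h)),

with c(h) the continuation total of history h, T(h) its number of
distinct observed continuations, and h' the history minus its oldest
symbol; the order-0 base is uniform over the 19 predictable symbols
(18 codes + end marker). Unseen histories fall through to the next
lower order. Interpolated (rather than backoff) Witten-Bell is the
implemented variant and is recorded in model metadata; with a closed
vocabulary there is no unknown-word state. The interpolated model
flattens exactly into ARPA backoff form — seen n-grams carry their
interpolated probability and history h carries backoff weight
T(h)/(c(h) + T(h)) — which is what `write_arpa` emits; a JSON dump of
raw counts round-trips the model exactly.

Perplexity is pooled over a test corpus, PP = exp(−Σ log p / Σ t),
with t counting session tokens plus end markers. The train/test split
is a seeded session-level random split (a session is the natural
sentence unit); the train side receives round(fraction · n) sessions.
Order selection sweeps orders 2–7 by default on one shared split and
returns the argmin of held-out perplexity, ties resolved to the
smaller order. On data generated by a first-order chain the sweep
correctly prefers order 2; recovering an optimum at order 5 requires
genuine lag-4 dependence in the data (the test suite constructs such a
generator).

## Pattern mining and categories

Pattern tables count every contiguous, **unpadded** window of n
activities within sessions (the language model pads; listed behavioral
patterns consist solely of activity codes, so windows do not). Ranking
is by frequency with the same lexicographic tie-break as transition
reports. Both token-window totals and distinct-pattern-type counts are
reported, and shares use token windows as the denominator.

The four behavioral categories are narrative descriptions formalized as
explicit, versioned rules (ruleset "1"), each anchored on a *querying
prefix* — a search-engine or health-website access immediately followed
by a new/modified query:

1. querying prefix followed in the window by exactly one health-item
   selection (`A:SelHI`) and an item evaluation (`E:EvalI`);
2. querying prefix followed by two or more consecutive accessing-stage
   activities;
3. `E:EvalI` immediately followed by a use or discard judgement
   (`U:UseHI`, `U:UseGI`, `D:DisHI`, `D:DisGI`);
4. an information use followed later in the window by any querying
   activity or by re-examining results (`E:ExamSR`).

A pattern may match several categories (reported in category order);
`none` means no rule fired. Alternative readings of the narrative
definitions can be configured by editing the rule table without
touching the mining code.

## Synthetic generator and its calibration

Raw transcripts are unavailable, so the generator emulates the study's
group-level structure from its published summaries. It is the
package's test bed: it defines what the property suite can and cannot
demonstrate about real data.

**Kernels.** Each group's 18×18 kernel is built from a transition-flow
table. The ten published top-10 transition cells per group carry their
published counts verbatim. Remaining cells are calibration fill chosen
by bounded least squares to (a) respect per-state flow balance
(inflow = outflow, with session starts crediting the two start states
and session stops debiting the use states), (b) stay strictly below
each group's rank-10 anchor so the anchored cells keep their published
ranking, and (c) stay close to a hand-specified prior encoding the
published per-activity frequencies (health-vs-general selection splits,
information-use totals) and the narrative session structure (discards
lead back to querying or re-examination; the familiar group sometimes
starts directly at a consumer health website and revisits it).
Near-unvisited states are given a single plausible successor so their
rows are exactly recoverable. The fill is calibration, not ground
truth: simulated corpora reproduce the published top-10 *sets* and
close-to-published rankings (adjacent swaps of nearly-tied cells
occur), the modal unfamiliar-group 5-gram
`Q:AccSE–Q:ModQ–E:ExamSR–A:SelHI–E:EvalI`, and the published ordering
of search efficiency across groups (L1 lowest). Efficiency magnitudes
land near but not exactly on the published percentages (simulated L1 ≈
0.24 vs 0.294 published) because the published anchors are not exactly
consistent with a stationary first-order chain.

**Lengths and session counts.** Group session counts 61/51/48 follow
from published arithmetic: each group's activity total minus its
transition total (2424 − 2363, 1204 − 1153, 967 − 919). Hence
per-group mean lengths 2424/61 ≈ 39.7, 1204/51 ≈ 23.6, 967/48 ≈ 20.1,
whose weighted mean reproduces the published corpus-level 28.7
activities per session. A session stops, with per-group probability
(0.399/0.441/0.505, tuned by bisection against 120k-session runs),
after each information-use activity once the minimum length 6 is
reached; at the cap of 221 (the published range) the session is
truncated back to its last use activity, so terminal states are
use-stage activities — every analyzed session "found its answer". The
stop probabilities were calibrated once against the mean-length targets
and frozen.

**Questionnaires.** Each label has a base answer pattern (L1: none
correct; L2: sections 1–2 correct, the inclusive 0.65 boundary; L3: all
correct); items flip independently with error rate 0.01. Scoring the
output recovers the requested label for ≥ 95% of simulated
participants (closed loop through the scoring module).

**Determinism.** All randomness flows through one
`numpy.random.default_rng` (PCG64) generator per run; a fixed seed
yields byte-identical corpora, and simulation manifests record the
seed and per-profile kernel checksums.

**What passing tests do not show.** The generator is a first-order
chain with a length-dependent stop rule: it has no query text, dwell
times, participant heterogeneity beyond the group kernels, or
higher-order sequential structure (except the purpose-built lagged
generator used for order-selection tests). Properties verified on it —
estimator consistency, test calibration, order recovery — are
properties of the methods, not evidence about real search behavior.

## Problem sizes in the test suite

The property suite uses 1000 replicates of 2000-transition 3-state
chains for type-I calibration (reference chain of 400k transitions, so
the reference kernel is effectively exact), 50,000 sessions for kernel
recovery (max-abs-deviation < 0.01), 3000 lag-4 sessions (~100k tokens)
for order selection, and 30-seed batches of 500-session group corpora
for the discrimination checks. These sizes keep the full suite under a
minute of simulation time while leaving comfortable statistical
margins.

## Known limitations

- The chi-square comparison's df bookkeeping treats every
  zero-expectation cell as an impossible transition; cells that are
  merely unobserved in a small reference sample are excluded with it.
  This matches the published bookkeeping but makes df depend on
  reference sample size.
- Witten-Bell is the only smoothing family; no Kneser-Ney or
  Good-Turing comparison is implemented.
- Pattern mining is contiguous fixed-length windows only; no
  gap-allowing or closed/maximal sequential-pattern mining.
- The generator cannot reproduce exact published group totals (they
  derive from 160 specific sessions); it targets their expectations.
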