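# Methods

## The problem

Qualitative GMO screening by real-time PCR asks, for every known GM
transformation event and every validated detection assay, whether the
assay is expected to detect the event.  When the event's DNA sequence and
the assay's primer/probe sequences are known, that question can be
answered *in silico* by simulating primer annealing and probe
hybridisation, and the answers can be tabulated once into a screening
matrix.  `gmoscreen` implements that simulation, the 0/1/2 scoring of
every event × method pair, matrix construction and export, and the
inverse problem: given observed positive/negative screening results,
which events — singly or as mixes of up to three — could explain them.

Because real event sequences are Confidential Business Information, the
package ships a synthetic-panel generator that plants primer/probe
cassettes with known ground truth into random backbones; all validation
runs against such panels and against brute-force reference
implementations.

## Primer annealing model

A primer anneals to a template window when the *canonical alignment* of
the full primer against that window stays within per-primer budgets of
**at most 2 mismatches and at most 2 gap bases** (gap bases = total
inserted + deleted bases, not gap openings).  Candidate amplicons must
span **20–500 bp** end-to-end, primer footprints included.  These four
thresholds are the package defaults and are recorded in every score
store; a store cannot be queried under different thresholds.

The model is purely edit-count based: no melting-temperature or ΔG
modelling, and no 3'-terminal-match requirement (none is standard for
electronic-PCR site searches, and imposing one would be an extra
assumption).

### The canonical alignment

The alignment objective is **match +1, mismatch −1, gap base −2**,
optimised over all semi-global alignments (full primer against a local
template window) that use at most the gap budget, with ties broken by
fewer gap bases and then by the smaller window end.  Two deliberate
choices:

* *Optimising before counting* prevents re-coding a substitution as an
  insertion+deletion pair to smuggle a third mismatch under the gap
  budget: the mismatch version scores strictly higher (−2 net vs −4), so
  the optimum always reports the honest decomposition.
* *Restricting the search space to the gap budget* (rather than taking
  the unconstrained optimum and then rejecting it if it used too many gap
  bases) makes the objective bandable and identical for the production
  aligner and the reference oracle.  The two definitions differ only on
  windows whose unconstrained optimum needs more gap bases than the
  budget — windows that are rejected either way in every case we could
  construct.

Degenerate IUPAC codes match by base-set intersection and count as
matches (a degenerate primer base is a wildcard over its set, which is
how degenerate primers behave chemically); `N` in a template matches
everything.

### Site search and reduction

The production aligner is a banded dynamic program over diagonal offset
(|d| ≤ gap budget) with the exact gap-base count as part of the state,
vectorised with numpy across all template start positions at once; minus
strand sites are found by searching the reverse complement of the primer
and reported in plus-strand coordinates.

Every start position yields one canonical alignment, so an exact planted
site is surrounded by shifted echoes (one leading deletion, score −2,
etc.).  These are suppressed by a local-optimum rule: **a candidate is
dropped iff a strictly better-scoring retained candidate overlaps its
interval**.  Because candidates are only ever compared against strictly
better scores, the retained set is well defined by induction on score,
independent of tie order, and exactly mirror-symmetric — which is what
makes end-to-end strand symmetry of scores an invariant rather than an
accident.  Equal-scoring overlapping sites are all retained.

A consequence worth knowing: a substitution at a primer *terminus* can
sometimes be absorbed by a one-base frame shift at a neighbouring start
position (at the cost of gap bases), so a "3-substitution" window can
still admit a within-budget site when one substitution is terminal or
when substitutions are clustered.  Tests that assert rejection therefore
plant *interior, scattered* substitutions.

### The reference oracle

The independent check (`gmoscreen.reference`) enumerates every explicit
gap layout — a multiset of deletion boundaries plus a set of inserted
primer positions, up to 2 gap bases — and scores each layout at every
start position from diagonal prefix-sum tables.  Same mathematical
definition, structurally different computation; the acceptance suite
requires exact site-set equality on 200 random instances.

## Amplicon enumeration

All three primer pairings are simulated: primer1 + primer2 (on either
template orientation), primer1 + primer1, primer2 + primer2.  Every
convergent (plus-strand site, minus-strand site) pair within the length
bounds is a hit; budgets apply per primer site, not per amplicon.
Same-primer hits are genuine amplicons but outside the assay's intent:
they count toward the score and set a warning flag that the matrix
renders as a `!` suffix.  A footprint pairing with itself (identical
interval) is excluded for the same-primer pairings; for the intended
pairing coincident footprints are allowed — primers that are reverse
complements of one another legitimately produce the minimal 20 bp
amplicon that way.

## Probe binding

A TaqMan probe can hybridise to either strand, so the probe is aligned
against both the extracted amplicon and its reverse complement and the
better alignment (by score, then fewer gap bases, then fewer mismatches)
decides; the result is exactly invariant to amplicon orientation.  The
probe must be covered end-to-end: a partial local alignment cannot report
meaningful mismatch budgets, so full-coverage semi-global alignment is
used even though a local aligner would be the more traditional tool here.
Classification: `perfect` (0 mismatches, 0 gap bases), `imperfect`
(within the same 2/2 budgets as primers — chosen for symmetry with the
primer thresholds), else `none`.

## Scoring

Hits are pooled over all template sequences of an event (retransformed
and stacked events carry several sequences under one identifier) and all
pairings.  For probe-bearing methods, hits whose probe classification is
`none` are discarded — TaqMan reporting requires probe hydrolysis, so an
amplicon the probe cannot bind produces no signal.  Then:

* **2** — some retained hit has both primer footprints exact and the
  probe (if any) perfect;
* **1** — a retained hit exists but every one is imperfect somewhere
  (including the case of perfect primers with an imperfectly binding
  probe, which is still an "imperfect probe" match);
* **0** — nothing retained.

Score 1 is deliberately its own category: with a few mismatches or gaps
in a binding site, whether the assay still fires is empirically
unpredictable, so downstream interpretation treats it as ambiguous.  The
best hit (for reporting) is chosen by quality, then fewest total edits,
then lowest sequence index, then leftmost amplicon start — an invented
but deterministic tie-break.

## Score store and matrices

Scores are pre-computed once (`gmoscreen build-db`) into a single-file
tabular store: a TSV with a two-line `#` header recording the format
version and the four thresholds, rows sorted by (event_id, method_id),
unique per pair with upsert semantics.  A text store was chosen over an
embedded database file because the format round-trips byte-identically
and diffs cleanly.  Matrix CSV export writes `event_id` plus one column
per method, cells `0`/`1`/`2` with a `!` suffix for self-pair warnings,
LF line endings; an optional static HTML rendering carries no extra
semantics.

## Pattern inversion

Detection per event × method is derived from the score; the ambiguous
score 1 is governed by a policy: `wildcard` (default; counts as detected
when checking positive calls, as not-detected when checking negative
calls), `as_positive`, or `as_negative`.  A combination fits a pattern
iff every positive method detects ≥ 1 member and no negative method
detects any member.  Events violating a negative call are excluded
up-front; the remaining search ORs per-method detection bit-vectors over
subsets of size 1–3, ascending, skipping supersets of accepted
combinations.  Since fitting is monotone once violators are excluded,
this returns exactly the minimal fitting sets — minimality filtering is
essential because any fitting singleton otherwise spawns O(n²) fitting
supersets.  Results are cross-checked against full subset enumeration.

## Synthetic panels

The generator emulates a curated event-sequence repository and a
validated-methods registry:

* random 20-mer primers, 24-mer probes (half the methods probe-bearing),
  2 kb event backbones;
* spacer lengths 30–160 bp, keeping amplicons in the 50–200 bp band
  typical of validated TaqMan assays;
* score-2 cells: exact `primer1 + spacer (+ probe copy) + rc(primer2)`
  cassette; score-1 cells: one substitution in a primer footprint (a
  probe-substitution variant is available to exercise the other score-1
  branch); score-0 cells: no cassette;
* self-pair cells: an additional `primer1 … rc(primer1)` cassette,
  probe copy included and degraded to match the planted score — a
  retained self-pair hit always contributes to the score, so self-pair
  cells require a planted score ≥ 1 (score-0 self-pair specs are
  rejected as infeasible);
* default planted-score frequencies 0.5 / 0.1 / 0.4 for 0/1/2 — score 1
  is rare in practice against real sequences.

Every generated event is verified by re-scoring all its cells with the
production scorer; any disagreement (a chance binding site in the random
backbone, a spurious self-pair) triggers rejection and a resample under a
fresh deterministic sub-seed.  This verification deliberately uses the
production aligner rather than the brute-force oracle — the oracle at
backbone scale would be far slower, and the aligner itself is validated
independently against the oracle — so panel-recovery results primarily
certify the pooling, probe-filtering, scoring, store and export layers.
All randomness derives from the spec seed; outputs are byte-identical
across runs.

What the panels do *not* emulate: real sequence composition (GC bias,
repeats, homopolymers), vector backbones shared between constructs,
partially homologous element variants across events, or sequencing
error.  Passing on planted panels therefore demonstrates correctness of
the simulation machinery, not concordance with wet-lab results on real
events, which requires the confidential sequences.

## Problem sizes and numerics

The standard validation panel is 48 events × 6 methods (288 cells, 3
self-pair cells, one two-sequence event) — the shape of a realistic
laboratory verification exercise; property tests use 8×4 and smaller.
Oracle equivalence uses 200 instances with primers of 15–25 nt and
templates up to 300 nt; finder equivalence uses a 20-event panel, 50
random patterns, all three policies (1350 subsets each).  All scores in
the DP are small integers (no floating point anywhere in the alignment),
so there are no tolerance questions: every comparison in the test suite
is exact.

Degenerate inputs: templates shorter than the primer minus the gap
budget yield no sites; an amplicon shorter than the probe minus the gap
budget classifies as `none` with `covered = False`; empty method or
event selections produce degenerate (n×0) matrices without error.

## Known limitations

* Annealing is edit-count based; thermodynamic effects (terminal
  mismatches, GC content, secondary structure) are out of scope.
* The per-start canonical alignment with local-optimum reduction can, in
  adversarial repeat-rich templates, report sites a seed-and-extend
  electronic-PCR implementation would miss or merge; this implementation
  is exhaustive, so disagreement with heuristic tools is conservative
  (extra candidate sites, never missed ones).
* Mixes are sets of distinct events; relative quantities, likelihood
  ranking of candidate mixes, and copy-number modelling are out of scope.
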