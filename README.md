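# gmoscreen

In-silico qPCR screening matrices for GMO detection.

GMO control laboratories screen food and feed samples with a first-pass
panel of element- and construct-specific real-time PCR assays (e.g. for
the CaMV 35S promoter or the nopaline synthase terminator), then confirm
positives with event-specific methods.  Planning a screening strategy and
interpreting its result pattern both require knowing, for every known GM
event and every assay, whether the assay detects the event.  When event
and assay sequences are available, that question is answerable purely
in silico — and sequence-level simulation catches cases annotation-based
matrices miss, because elements sharing a name can differ at the DNA
level between constructs.

`gmoscreen` simulates the detection of each event by each method and
condenses it to a score:

* **2** — perfect annealing of both primers and, if present, the TaqMan
  probe;
* **1** — an amplicon is predicted, but with imperfect primer and/or
  probe binding (detection empirically unpredictable);
* **0** — no amplicon within the thresholds.

The simulation searches each primer on both strands of every template
under per-primer budgets of ≤ 2 mismatches and ≤ 2 gap bases (canonical
semi-global alignment: match +1, mismatch −1, gap base −2), enumerates
candidate amplicons of 20–500 bp for all three primer pairings —
including the same-primer pairings, which are flagged as warnings (`!`)
when they amplify — and requires full-length probe hybridisation on
either amplicon strand for probe-bearing assays.  Pre-computed scores
feed two front-ends: an events × methods **screening matrix** (CSV/HTML)
and an **event finder** that inverts an observed pattern of
positive/negative screening results into the minimal single events or
mixes of up to 3 events that explain it.

Real GM event sequences are confidential, so the package includes a
deterministic synthetic-panel generator (`simulate-panel`) that plants
primer/probe cassettes with known ground truth into random backbones;
see `docs/methods.md` for the model and its limits.

## Worked example

```bash
# 1. a synthetic panel: 8 events x 4 methods, one self-pair cell
gmoscreen simulate-panel --out-dir panel --n-events 8 --n-methods 4 \
    --self-pairs 1 --seed 11

# 2. pre-compute all 32 pair scores
gmoscreen build-db --events panel/events.fasta --methods panel/methods.tsv \
    --store panel/scores.tsv
# stderr: scored 8 events x 4 methods: 17 zero, 3 imperfect, 12 perfect,
#         1 self-pair warnings -> panel/scores.tsv

# 3. the screening matrix
gmoscreen matrix --store panel/scores.tsv --out panel/matrix.csv
head -3 panel/matrix.csv
# event_id,QT-SYN-00-001,QT-SYN-00-002,QT-SYN-00-003,QT-SYN-00-004
# SYN-EV001,2,2,0,0
# SYN-EV002,2,1,0,2

# 4. invert a screening pattern: which events fit "method 1 positive,
#    method 3 negative"?
gmoscreen find --store panel/scores.tsv \
    --positive QT-SYN-00-001 --negative QT-SYN-00-003
# SYN-EV001
# SYN-EV002
# SYN-EV004
# SYN-EV008
# 4 minimal combination(s) fit the pattern
```

Cell values are the 0/1/2 scores above; a `!` suffix (e.g. `2!`) marks a
pair where a same-primer amplicon was also predicted — outside the
assay's intent, shown for warning purposes.  The finder lists minimal
explanations only: a mix is never reported when one of its subsets
already fits.  Ambiguous score-1 cells are treated as wildcards by
default (`--policy wildcard|as_positive|as_negative`).

The same functionality is available as a library:

```python
from gmoscreen import read_events_fasta, read_methods_table, score_pair

events = read_events_fasta("panel/events.fasta")
methods = read_methods_table("panel/methods.tsv")
ps = score_pair(methods[0], events[0])
print(ps.score, ps.self_pair_warning, ps.best_hit.amplicon_length)
# 2 False 153
```

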