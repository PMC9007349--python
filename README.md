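# pathcall

Annotate the uptake and catabolism of carbon sources in bacterial and
archaeal genomes. Given a predicted proteome, a database of experimentally
characterized proteins, and pathway definitions (steps plus alternate
rules), `pathcall` finds candidate proteins for every step by sequence and
profile-HMM homology, classifies each candidate into three confidence
tiers, and selects the best path for each compound. It is aimed at
comparative genomics of catabolic capability: asking which compounds a
genome can plausibly use, and where the gaps in its pathways are.

## The model

A pathway for a compound is an entry **rule**: an OR-of-alternatives, each
alternative an AND-list of **steps** (enzymes, transporters, or individual
subunits) and sub-rules. A **path** is one full expansion of the entry
rule into a set of steps.

Candidates for a step are scored against characterized proteins. A
sequence candidate is **high** confidence when identity ≥ 40% with ≥ 80%
coverage of the characterized protein and it is more similar (bit score)
to proteins performing the step than to characterized proteins with other
functions; **medium** when identity ≥ 30% with 80% coverage and not
out-scored by an other-function protein, or identity ≥ 40% with 70%
coverage; otherwise **low**. An HMM candidate is high when the alignment
covers ≥ 80% of the model and no other-function protein aligns at 40%
identity and 80% coverage. Similarity to a step's *ignore list* (close
paralogs with slightly different substrates) is never counted against a
candidate. A step with no candidates is low confidence.

Each path is then scored: +1 per high step, −0.1 per medium step, −2 per
low step. The solver maximizes, lexicographically: (all-high, then
low-free, then total score, then number of steps, then definition order).
It is exact — equal to brute-force enumeration over all paths — without
expanding the rule tree, using a Pareto front of candidate step-sets per
rule.

Supporting analyses: single-linkage clustering of characterized proteins
(30% identity, 75% coverage of both sequences, by default) with heteromer
flagging for curation work; Fisher exact 2×2 trait association with sample
odds ratios; profile-HMM family presence calls at the model's trusted
cutoff with competing-model exclusion; and a leave-one-out benchmark of
the high-confidence thresholds (does a protein's best hit share its
step?), binned by identity.

## Worked example

Generate a small synthetic world (3 compounds, 3 genomes, with planted
candidates at controlled identities) and annotate one genome:

```sh
pathcall fixture --seed 7 --compounds 3 --out world
pathcall run --genome world/genomes/g0.faa --db world \
    --pathways world/pathways --out out
cat out/summary.tsv
```

```text
genome	compound	category	score	n_high	n_medium	n_low	path
g0	c0	high	3	3	0	0	c0_s0,c0_s1,c0_s2
g0	c1	medium	2.9	3	1	0	c1_s0,c1_s1,c1_s2,c1_s3
g0	c2	low	-1	1	0	1	c2_s0,c2_s1
```

For genome g0, compound c0's three steps all have high-confidence
candidates (category *high*, score 3 = 3×(+1)); c1 has one step whose best
candidate sits in the 30–40% identity band (one medium step, 3×1 − 0.1 =
2.9); c2 is missing a step entirely (one low step, 1 − 2 = −1), i.e. a
pathway gap. `out/candidates.tsv` lists every candidate with its identity,
coverage, bit scores against same-step and other-function proteins, and
confidence; this matches the planted ground truth in `world/truth.tsv`.

Other subcommands: `pathcall cluster` (curation clustering), `pathcall
assoc` (Fisher tests from a counts TSV), `pathcall benchmark`
(leave-one-out threshold accuracy).

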