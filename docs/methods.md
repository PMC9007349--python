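# Methods

## Pathway model

A compound's definition is a set of named steps and rules. Rules are
OR-of-alternatives; alternatives are AND-lists of step ids and rule ids;
the designated entry rule defines utilization. The rule graph must be
acyclic. Steps or rules may be imported from another compound's
definition; imports are materialized *by reference*, so a correction to a
shared step definition is recorded once and is visible to every importer.
After import resolution the registry is validated and frozen.

Paths are step **sets**: when an alternative or a pair of sub-rules
mentions the same step twice, it is counted once — scoring it twice would
double-count one gene product. `enumerate_paths` expands the entry rule
depth-first in definition order (duplicates collapsed within each path)
and refuses to expand beyond a configurable bound (default 10,000); it
exists as the reference semantics and as the solver's test oracle, not as
the production path.

## Homology contract

All identity/coverage quantities in the package come from one alignment
contract: best local alignment under BLOSUM62 with affine gaps (open 11,
extend 1), Karlin–Altschul bit scores with the standard gapped parameters
(λ = 0.267, K = 0.041), and E-values normalized to the searched database
size. Identity is identical columns over aligned columns (gap columns
included); coverage of a sequence is its aligned span over its length.
"Coverage" unqualified in the confidence rules means coverage of the
characterized (subject) protein: the point of the threshold is that the
candidate spans the known protein's functional length. The engine (the
Biopython pairwise aligner) is behind a narrow surface and can be swapped
for an external search tool that honours the same definitions.

Two numerical details. The dynamic program is run on a canonical
orientation of each pair so that identity and bit score are exactly
symmetric (traceback tie-breaks cannot differ between (a,b) and (b,a)).
Ties in bit score are broken by subject id, lexicographically, for
determinism.

Candidate limiting follows the tool's published behavior: per step, only
the four top candidates by bit score, at most two of them below 40%
identity (with higher-identity hits back-filling displaced slots); when
weighing a candidate against other functions, only its top eight
characterized hits by bit score are examined, skipping proteins associated
with the step and proteins on the step's ignore list.

Profile-HMM search runs through pyhmmer (HMMER3). Model coverage is the
best-scoring domain's span over match states divided by model length;
trusted cutoffs are honoured when the model carries them. Steps without
available models degrade to sequence evidence alone.

## Confidence classification

The three-tier rules are implemented exactly as stated in the model
section of the README. Two points were genuinely open and were decided as
follows:

* "More similar to proteins known to perform this step" is read as
  *strictly greater* bit score; an exact tie demotes. This is the
  conservative reading — fewer false highs.
* The published rules define only the *high* case for HMM evidence. Hits
  that pass the reporting threshold but miss the high criteria are
  classified medium: a reported domain hit is positive evidence for the
  family, but an incomplete model alignment should not certify a step.

A step with zero candidates is low confidence and still participates in
scoring (−2), so every path through the rule tree has a defined score.

## Best-path solver

The objective is lexicographic: category (2 = all steps high, 1 = no low
steps, 0 otherwise), then total score (+1 / −0.1 / −2 per step by class),
then number of steps (two equally good pathways are distinguished by
preferring the one with more steps), then definition order (pure
determinism; the selection among exact ties is otherwise arbitrary).

A greedy bottom-up recursion — pick each sub-rule's best alternative in
isolation — is **not** exact under set semantics. Counterexample: entry
`X Y` with `X: a | b` and `Y: a c`; if `a` is low and `b` is medium, `X`
locally prefers `b`, but `a` is already forced into the path by `Y`, so
choosing `a` in `X` is free and avoids `b`'s penalty. The solver therefore
propagates, per rule, a *front* of candidate step-sets, combining
AND-lists by unions over the cross product and pruning with two rules that
are safe under union with any enclosing context:

* drop S if a retained superset T adds only high-confidence steps — in any
  context T's category equals S's and its score and step count are at
  least S's (extra high steps contribute +1 or, if already present in the
  context, 0);
* drop T if T is a superset of a retained S and every extra step is medium
  or low — the extras can only reduce category and score; in a context
  that already contains all of them, T and S collapse to the same set.

Sets differing by a mix of high and non-high steps are incomparable and
both survive. Equal sets are deduplicated keeping the first (definition
order) occurrence, which realizes the final tie-break. Equality with
brute-force enumeration is property-tested on 1,000 random rule trees.
Fronts stay small for realistic pathways; a safety valve errors out past
100,000 sets per rule.

## Curated database and clustering

Characterized proteins load from FASTA + TSV (id, source, description,
comma-separated step ids, complex flag); sequences are validated against
the 20-letter alphabet plus X and upper-cased. An sqlite3 round-trip is
provided for repeated runs against larger databases. Curation clustering
builds a graph with edges at ≥ 30% identity and ≥ 75% coverage *of both
sequences* (defaults) and takes connected components — i.e. single
linkage. The linkage is not stated explicitly by the tool this reimplements;
single linkage is our reading of its merge behavior (similar permease
subunits chain together at 30% and are separated by re-clustering at 40%),
and it is what the published defaults reproduce here. Heteromer flagging
is keyword-based ("subunit", "component", case-insensitive) plus explicit
complex annotations.

## Association and benchmark computations

`fisher_exact_2x2` reports the sample odds ratio (a/b)/(c/d) and the exact
two-sided p (sum of hypergeometric probabilities ≤ the observed table's),
delegating the p computation to scipy; tests keep an independent
full-enumeration oracle. Sample (unconditional) odds ratios are used
throughout rather than the conditional MLE — the printed odds ratios of
the analyses this reproduces match sample ORs. `trait_association` puts
the trait-positive group in row 1 and reports prevalences as integer
percentages. Family presence calls use hmmsearch at the model's trusted
cutoff with competing-model exclusion: a protein scoring higher against a
named competitor model than against the target is ignored.

One caveat on exact-test calibration: Fisher p-values are discrete and
conservative, so at a few hundred genomes their null distribution is
visibly super-uniform. The uniformity property test therefore simulates
5,000 genomes per draw, where the discreteness is negligible; at smaller n
the deviation from uniformity is a property of the exact test itself, not
of this implementation.

The leave-one-out benchmark compares every step-associated characterized
protein to all other characterized proteins; proteins whose best hit fails
the high-confidence thresholds (40% identity, 80% subject coverage) are
excluded from the denominator, and accuracy is the fraction whose best hit
shares a step, reported overall and per best-hit identity bin (the
40–50% bin is where the thresholds are stress-tested). Step kind
(enzyme/transporter) lives on step definitions, so the enzyme/transporter
split takes an explicit step→kind mapping.

## Synthetic worlds

The fixture generator emulates the inputs end to end: a characterized
database, pathway files in the text dialect, and proteomes with planted
candidates. Defaults: 5 compounds with 2–4 steps each (plus occasional
never-planted alternative branches), 3 genomes, 250-residue proteins,
proteomes padded to 25 proteins with random sequences, identity levels
0.90 (high band) and 0.35 (medium band), and 2 other-function decoy
families at ~50% identity to a planted exemplar. Per (genome, compound)
one scenario is planted — complete (expected high), one step in the
medium band (expected medium), one step deleted (expected low), or a
candidate identical to a decoy so the other-function comparison demotes it
(expected medium). Planted identities are kept ≥ 0.05 from every
classification threshold so expected categories are unambiguous;
substitution-only mutation keeps coverage near 1.0 (an indel mode exists
to exercise the 70–80% coverage clauses). Sequences are i.i.d. uniform
over the 20 amino acids.

What passing these tests shows: the pipeline's thresholds, limiting,
demotion, and path selection behave exactly as specified on sequences
whose divergence is controlled. What it does not show: performance on real
proteomes, where domain architecture, compositional bias, indels, and
families straddling the thresholds make annotation transfer genuinely
uncertain — the published accuracy of the 40% identity threshold near the
boundary is far from perfect, especially for transporters, and nothing in
the synthetic worlds captures that.

## Problem sizes and determinism

The shipped tests and the acceptance script run at desk scale by design:
toy worlds as above (ten seeds in the end-to-end recovery test), 1,000
random rule trees for solver equivalence, enumeration-oracle Fisher checks
with margins ≤ 300. Every random draw is seeded; identical specs produce
byte-identical world files. The CLI surfaces all thresholds as flags with
the standard values as defaults, so the zero-flag run is the canonical
configuration.

## Known limitations

* No compartment modeling: a periplasmic and a cytoplasmic hydrolase are
  interchangeable to the solver.
* One protein may serve several steps of the chosen path; this is allowed
  with a warning rather than modeled (fusions are real, but so are
  over-merged step definitions).
* E-values use fixed Karlin–Altschul parameters without edge-effect
  corrections; they are slightly permissive for short sequences. The
  confidence rules deliberately do not consume E-values beyond the lax
  reporting threshold.
* The bundled aligner is exact Smith–Waterman; it is fast enough for
  desk-scale databases but a heuristic search tool should back the same
  contract for genome-scale curated databases.
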