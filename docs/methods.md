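# Methods

## Switch architecture and conformational targets

A gRNA switch is laid out 5'->3' as `toehold | clamp | loop | linker |
repeat | guide`, with 0-based half-open coordinates throughout. The clamp is
the reverse complement of the repeat's 5' prefix; by default clamp position
`k` pairs repeat position `clamp_len - 1 - k`, so the OFF-state stem encloses
the loop (plus any linker) as its hairpin loop. This prefix register is a
design choice — the innermost clamp pair sits on repeat position 0 — and an
explicit pair-map override is accepted wherever the register matters, because
other registers (e.g. centred on the handle stem) are equally coherent.

The OFF target is the single-strand structure with exactly that clamp:handle
stem and every other position unpaired. The ON target is a two-strand
structure (switch & trigger) in which the toehold pairs the trigger's 3'
segment and the loop the trigger's 5' segment, both antiparallel; the clamp
and the trigger's middle segment face each other unpaired as a symmetric
internal loop (an option pairs them instead, for sensor domains with clamp
complementarity); the linker is unpaired in both states; and the repeat
adopts the handle hairpin, defined operationally as the pair map of the
repeat folded alone by the engine. For the bundled 19-nt FnCas12a processed
repeat (`AAUUUCUACUGUUGUAGAU` — configuration data, not an assumption) this
is the canonical 5-bp stem with a 4-nt loop, plus one enclosing A-U pair that
the additive model considers favorable. The repeat's natural pseudoknot is
outside the nested-structure model and is approximated by this hairpin,
consistent with the two-state picture of switch function.

Default sub-domain lengths are 15 nt toehold, 13 nt clamp, 15 nt loop, no
linker (86-nt switch, 43-nt trigger); all lengths are free parameters, with
the constraints `clamp_len <= len(repeat)` and `loop_len + linker_len >=
min_loop` so the OFF hairpin loop is realizable.

## The ensemble engine

The engine scores a nested (pseudoknot-free) structure as the sum of its
pair scores — GC = 3, AU = 2, GU = 1 by default, i.e. hydrogen-bond counts
read as binding free energies of roughly 1 kcal/mol per bond — and weights it
`exp(beta * score)`. Hairpin loops must span at least `min_loop = 3` unpaired
bases; two strands are folded over their concatenation, pairs spanning the
nick are exempt from the loop minimum, and an optional duplex-initiation
penalty (default 0) is charged once to any bimolecular structure containing
an inter-strand pair.

`beta` defaults to 1/RT at 37 degrees C (1.6225 mol/kcal), making the weight
scale consistent with the kcal/mol reading of the scores. This scale is what
makes designed cognate switch:trigger pairs essentially fully complexed at
1 uM — the behavior the architecture is built around; a flatter scale (e.g.
`beta = 1`) leaves even a 30-bp sensor duplex measurably dissociated at
micromolar concentrations.

Inside recursion (half-open intervals, leftmost-position conditioning, so
each structure is parsed exactly once):

```
Q[i, j] = Q[i+1, j] + sum_k W[i, k] * Q[i+1, k] * Q[k+1, j]
```

with the matching outside recursion for exact base-pair probabilities;
both are O(n^3) and JIT-compiled. The maximum-score structure uses the same
decomposition with deterministic tie-breaking: highest score, then fewest
pairs, then the lexicographically smallest pair table (unpaired encoded as
-1) — so identical inputs always yield identical structures. Partition
functions, pair probabilities, MFE scores and ensemble defects are validated
against exhaustive enumeration of all nested structures for lengths up to 12
(hundreds of randomized single-strand and nicked-duplex cases, agreement to
1e-9).

The normalized ensemble defect of a target is the mean over positions of the
probability of *not* being in the target state (the target partner's pair
probability, or the unpaired probability). Heterodimer equilibria use
`K = Q_ab / (Q_a * Q_b) / c_ref` with `c_ref = 1 M` and solve the mass-action
quadratic at its physical root in a numerically stable form; mass is
conserved by construction.

Any engine implementing the `FoldEngine` contract (MFE fold, partition
function with normalized pair probabilities) can replace the reference
engine; a ViennaRNA-backed adapter ships with the package. The contract is
structural only — nearest-neighbor numbers are not expected to agree with
the additive model, and the adapter is the route to publication-grade
thermodynamics.

## Sequence design

Free regions (toehold, loop, trigger middle, linker; in natural-trigger mode
only the linker, since toehold/loop are complements of the chosen trigger
window) are initialized uniformly at random from a seeded generator, then
optimized by greedy stochastic descent on the summed OFF+ON ensemble defect:
a position is sampled with probability proportional to its positional
defect, a different residue is proposed (complementarity propagated to the
trigger), and the move is accepted iff the objective does not increase and
no prevented pattern is introduced. The run stops when both stop conditions
(OFF <= 1%, ON <= 5% by default) hold or a proposal budget (default 20,000)
is exhausted; results record the final defects, iteration count and seed
either way, and identical seeds reproduce results bitwise.

Prevented patterns (`AAAA, CCCC, GGGG, UUUU, KKKKKK, MMMMMM, RRRRRR, SSSSSS,
WWWWWW, YYYYYY`, IUPAC classes) are enforced only where a match overlaps at
least one designable position: the fixed repeat itself contains a K-run
(`UGUUGU`), so constraining fixed domains would make every design infeasible.
The standalone scanner reports all occurrences anywhere, overlapping ones
included.

**Known limitation — the stop conditions under the additive model.** Because
the model has no helix-initiation or stacking penalty, an isolated
complementary pair is as stable per-pair as a long stem, and a random 24-nt
guide virtually always offers several such pairs to the rest of the switch.
These contribute position defects the designer cannot remove (the guide and
repeat are fixed), so the OFF defect of an 86-nt switch plateaus far above
1% at every `beta`; the 1%/5% stop conditions are effectively reachable only
through a nearest-neighbor adapter engine, which destabilizes isolated pairs.
The design loop, stop-condition bookkeeping and convergence flags are exact
regardless; `scripts/acceptance.py` reports the measured convergence rate
and median defects of a 10-guide experiment rather than assuming them. The
same missing penalty means a non-cognate trigger can occasionally peel a
single terminal clamp pair off the OFF stem in the pair MFE at zero cost, so
clamp sequestration over a designed panel is typically, not universally,
complete.

## Trigger scouting

Natural RNAs are scanned in fixed windows (default 71 nt) folded in
isolation — no flanking context, matching per-window folding semantics.
"Low structure" is scored as mean unpaired probability over the window
(1.0 = fully accessible); the window MFE score is reported alongside as a
diagnostic. Selection is greedy on accessibility with non-overlap
constraints, ties to the smaller start; a forced 5'-proximal pick (zone
default 100 nt, operationalizing "close to the 5' end") is added when it is
not already among the selections. Both the scoring statistic and the zone
are configuration-exposed, since reasonable alternatives exist (MFE per
nucleotide, larger zones).

## Cross-talk

Panels are evaluated pairwise only: monomer partition functions per switch
and trigger, one heterodimer co-fold per pair at equal totals (default 1 uM),
fraction complexed = heterodimer concentration over total switch
concentration. Pairs above a 5% reporting threshold are flagged. Homodimers
and higher-order complexes are deliberately out of scope. Clamp
sequestration is the fraction of OFF-state clamp pairs present in the pair's
maximum-score structure; 1.0 means the handle stays blocked with that
trigger.

## Assay analysis

Normalized fluorescence anchors the targeting control at 0% and the
non-targeting control at 100%; it is invariant to shifting all three
readings or rescaling them by a positive factor. Flow-cytometry means are
background-subtracted (a blank-strain control) before the same
normalization. For growth assays, the exponential phase is the earliest
contiguous span of fixed length (default 210 min) maximizing the R^2 of a
straight-line fit to log OD600; differentials `(F[t+w] - F[t]) / (OD[t+w] -
OD[t])` use windows of 4 sampling intervals (20 min at 5-min sampling — the
window is specified in intervals so the time span, not the point count, is
fixed) and exclude the first and last 20 min of the span. Normalized GFP
expression applies the anchor formula to differentials at a single
representative time point, by default the one nearest the span midpoint
(configurable, since any pseudo-steady-state point is defensible). Welch's
two-tailed t-test (unequal variances, Welch-Satterthwaite degrees of
freedom) handles group comparisons; the degenerate all-equal case returns
t = 0, p = 1 with the convention flagged in the docstring.

## Synthetic fixtures

The fixture generator reproduces the workflow's study conditions: random
24-nt guides; 43-nt triggers with GC content uniform over 30-53%; a 90-nt
sRNA stand-in built from two stem-loops flanking two A/C-rich accessible
segments (A/C alphabets cannot pair internally, giving known accessibility
ground truth); a 1.7-kb mRNA stand-in with three designed low-structure
71-nt windows (5'-proximal, mid-ORF, 3'-proximal); plate-reader series with
exactly exponential growth to 250 min followed by a plateau and fluorescence
`offset + rate * OD`, rates chosen so each experiment sample's normalized
GFP expression equals an injected truth value; and flow-cytometry means
constructed the same way around a background level. One seeded generator
drives everything, so bundles are bitwise reproducible.

What passing the closed-loop tests shows — and what it does not: recovery of
injected normalization values demonstrates the window/differential/
normalization algebra is exact for data generated under the pipeline's own
assumptions (uniform sampling, clean exponential phase, affine
fluorescence). Real plate data add measurement noise, drift and imperfect
exponential phases, which the pipeline tolerates only insofar as the R^2
window search and differencing average them out; no noise robustness claim
is made or tested. Likewise the sRNA/mRNA stand-ins make accessibility
ground truth unambiguous, which real transcripts never are.

## Problem sizes

Default test and acceptance runs use: enumeration cross-checks at lengths
<= 12 (hundreds of cases); design experiments of 10 guides at 500 proposals
and panels of 4 at 1,500 proposals (objective trajectories plateau within a
few hundred proposals on the default architecture, so longer budgets change
defects only marginally); 10x10 cross-talk panels; and full 1,630-window
scans of the 1.7-kb mRNA stand-in.
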