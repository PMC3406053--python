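# Methods

## The pair model

A residue enters the analysis only when it is fully characterized: Cα and
functional-atom coordinates, residue type, secondary structure, solvent
accessibility and chain membership. Residues missing any of these are
discarded individually; the rest of the chain is kept, and the chain length
used downstream (CL) is the count of residues *after* discarding. The
sequence index used for sequence distance (SD) is the 1-based ordinal among
the validated residues of the chain, not the author's PDB numbering —
author numbering carries gaps and insertion codes and would make SD depend
on bookkeeping rather than on chain topology.

Two residues of the same chain form a pair when

1. they occupy the same solvent-accessibility bin, and
2. the minimum Euclidean distance over all combinations of their functional
   atoms is strictly below 8.25 Å.

The minimum over functional atoms (types have one or two) is the natural
contact criterion and keeps the relation symmetric. Each pair is binned
along eight axes into a sparse tensor of shape 20·20·12·14·4·4·12·6 =
77,414,400 cells. Bin intervals follow the half-open convention
(lower, upper]; the extreme bins absorb out-of-range values (SA ≤ 0,
SA > 100, CL > 1000, SD > 4). The strict `< 8.25` distance criterion is the
open lower edge of "beyond the last bin": the last distance bin is
7.75 < D ≤ 8.25.

**Insertion modes.** In the default *symmetric* mode every observation
increments both its cell and the AA/SS-swapped cell, so swapped pair orders
(Phe–Ile vs Ile–Phe) always carry equal counts and the tensor total is twice
the number of observations. A *canonical* mode (one increment into the cell
with AA1 ≤ AA2, ties broken by SS1 ≤ SS2) is provided for analyses that want
totals equal to observation counts. Both modes are recorded in the tensor
header and checked when tensors are combined.

**Provenance.** Every insertion can be logged as a compact string —
structure id, then zero-padded 4-digit author residue number + chain id for
each partner (e.g. `1ABC0102A1030B`). Residue numbers beyond 9999 cannot be
represented in that fixed width and are emitted unpadded with a warning.

**Secondary-structure mapping.** The four categories (helix, strand, turn,
coil) do not uniquely partition the DSSP/HSSP code alphabet, so the mapping
is a configurable table with default H→helix, E→strand, T→turn and
everything else (G, I, B, S, blank) →coil.

**Annotation conflicts.** When the coordinate file and the annotation
disagree on a residue's type, the annotation wins (logged); annotations are
the authority for type, SS and SA, coordinates for geometry. Alternate
locations resolve to the first conformer; only the first model of
multi-model files is read. Relative solvent accessibility is accepted as any
finite percentage — values above 100 occur in practice and land in the
SA > 100 bin.

## The permutation null

The reference tensor is built by shuffling the residue-type labels within
each chain — a uniform random permutation — while every positional attribute
(coordinates, SA, SS, sequence index) stays put, re-running the full pair
pipeline, and averaging the resulting tensors over repetitions (default 10).
Keeping geometry positional is the only choice that needs no rebuilt
coordinates: a position keeps its spatial signature and only its label
moves. A consequence worth noting is that after relabeling, a position's
functional-atom count may not match its new label; distances are computed
from the original atoms at each position, which is exactly the intended
null — "which types sit in which environments" is randomized, the
environments themselves are not.

Because label shuffling never changes which *position* pairs qualify, every
repetition has the same total as the observed tensor; only the distribution
over cells changes. Averaged counts are kept as unrounded floats and ratios
use the unrounded mean. Cells observed but never seen in the reference have
an infinite ratio and are reported separately rather than folded into a
numeric value.

Determinism: one master seed spawns an independent substream per
(repetition, chain) via `numpy.random.SeedSequence`, so results are
reproducible regardless of iteration order.

## Rank-frequency fitting

The rank table maps each population R to ω(R), the number of cells with
exactly that population; by construction Σω = occupied cells and
ΣR·ω = tensor total. The power-law exponent is estimated by ordinary least
squares of log₂ω on log₂R, one point per distinct rank, unweighted —
matching the plotted construction of such log–log diagnostics. Reported per
fit: slope (= −λ), intercept, t-based 95% CI on the slope, |Pearson r| (the
"closer to 1 is better" goodness used to order subspace fits) and the
residual RMSE in log₂ units. Base-2 logarithms are used throughout.

**Tail truncation.** An empirical rank-frequency histogram has a sparse
tail: ranks expected to hold fractional cell counts appear with ω ∈ {0, 1},
and since ω = 0 points cannot enter a log fit, the surviving tail points are
biased upward and flatten the slope. Simulation (10⁵ populations drawn from
P(R) ∝ R^−λ on [1, 1000]) shows full-range OLS recovers λ = 1.5 well but is
biased by ~0.7 at λ = 2.3. The estimator therefore exposes
`tail="contiguous"`, which restricts the fit to the maximal run of
consecutive integer ranks starting at the smallest observed rank — the
well-populated head of the histogram. With it, the generating exponent is
recovered within |Δλ| ≤ 0.15 across λ ∈ {1.5, 2.3, 3.0} in 20/20 simulation
seeds. The default remains `tail="all"` (all observed ranks), with the
fitting range additionally exposed via `r_min`/`r_max`; maximum-likelihood
power-law estimation is deliberately out of scope — the log–log OLS *is*
the statistic of interest here.

## The synthetic corpus

The generator emulates the features of a culled experimental chain set that
drive the pair statistics; defaults in parentheses.

- **Chain lengths** uniform on [40, 300] by default (minimum 40 residues,
  matching the culling convention for such corpora; lengths up to 1000+ are
  supported).
- **Composition**: a standard database background profile (Leu most
  frequent at 9.1%, Trp rarest at 1.4%), boosted ×2.0 for the hydrophobic
  set {Ala, Ile, Leu, Val, Phe, Met} inside helix/strand segments, then
  renormalized.
- **Secondary structure**: segments drawn with category weights
  (helix .32, strand .22, turn .12, coil .34) and geometric lengths (means
  10/5/3/6), adjacent segments never sharing a category.
- **Geometry**: a self-avoiding Cα trace (3.0 Å exclusion, checked at Cα
  level only) with 3.8 Å virtual bonds. Helix segments follow ideal α-helix
  geometry (2.3 Å radius, 1.5 Å rise, 100°/residue — which reproduces the
  characteristic i,i+3/i,i+4 contacts), strands are extended zigzags, and
  coil/turn steps are a correlated walk. Segment directions acquire an
  inward bias once the trace leaves a target radius ≈ 3.3·n^{1/3} + 2 Å, so
  chains stay globular and sequence-distant residues make contacts (the
  SD > 4 bin is populated, as in real folds). Functional atoms are
  pseudo-atoms at fixed per-type offsets from Cα (0 Å for Gly up to 6.7 Å
  for Arg), randomly oriented, two atoms 65° apart for the two-atom types.
- **Solvent accessibility**: a buried/exposed mixture; hydrophobic types are
  buried (SA ≤ 10) with probability 0.75, others 0.30, with small masses at
  SA = 0 and SA > 100 so the extreme bins are exercised.

These choices give the corpus a buried hydrophobic core, so cells with high
populations concentrate on buried Ala/Ile/Leu/Val pairs — the qualitative
structure the descriptive summaries are designed to read out.

What the generator does **not** emulate: real rotamers and side-chain
packing, backbone dihedral statistics, hydrogen-bond-driven sheet topology,
SA/SS correlations beyond the buried-hydrophobic bias, or homology structure
between chains. Passing tests on synthetic corpora therefore validate the
*machinery* — counting identities, oracle equivalence of pair detection,
null-model calibration, estimator recovery — not the empirical exponents of
real proteomes; synthetic exponents at desk scale (λ ≈ 4 on 30–60 chains)
are steeper than those of large experimental corpora, and quantities that
depend on corpus scale (maximum cell populations, per-type maximum ranks)
only emerge with thousands of chains.

## Problem sizes and tolerances

The shipped test suite and the acceptance script run on: 20–100 synthetic
chains of 40–300 residues (pair-finding oracle equivalence uses 100 chains
≤ 200 residues), reference tensors with 2–10 repetitions, and
exponent-recovery studies at 10⁵ cells per tensor with 5–20 seeds per
exponent. Exact identities (counting conservation, oracle equivalence,
unit ratios under the identity shuffle) are asserted exactly; Monte-Carlo
quantities use ~4σ bounds; exponent recovery uses the |Δλ| ≤ 0.15 band in
≥ 90% of seeds.

## Known limitations

- Inter-chain pairs are out of scope by definition (pairs are same-chain).
- HSSP parsing targets the residue block of classic HSSP layouts, guided by
  the header line; exotic HSSP variants may need the TSV dialect instead.
- The SD = 0 bin exists for format fidelity but is empty by construction
  (self-pairs are excluded).
- The dense tensor is never materialized; all operations are sparse, so
  memory scales with occupied cells (~1.8 M for corpus-scale runs), not with
  the 77.4 M-cell index space.
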