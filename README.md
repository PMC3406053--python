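# pairspace

Statistics of amino-acid pair interactions in folded proteins, organized as
an 8-dimensional count tensor.

A folded protein can be read as the cumulative result of pairwise residue
interactions. `pairspace` quantifies each interaction by eight observables:
the two residue types (AA1, AA2), the shared solvent-accessibility shell
(SA), the Euclidean distance between the residues' functional atoms (D), the
secondary-structure element of each partner (SS1, SS2), the length of the
chain (CL) and the sequence separation of the pair (SD). Two residues of the
same chain count as a pair when they fall in the same SA bin and their
functional atoms — the designated side-chain tip atoms, e.g. Lys NZ, Phe CZ,
Gly Cα — approach within 8.25 Å. Every pair increments one cell of a sparse
count tensor of shape 20 × 20 × 12 × 14 × 4 × 4 × 12 × 6 (77,414,400 cells;
stored sparsely, never densely).

Three analyses sit on top of the tensor:

- **Rank-frequency power laws.** With R a cell population ("rank") and ω(R)
  the number of cells holding exactly that population, scale-free
  organization means ω(R) ∝ R^−λ — a straight line of slope −λ in a
  log₂ω vs log₂R plot. `fit_powerlaw` estimates λ by OLS on those points,
  with a t-based 95% CI, |Pearson r| as the goodness-of-fit ordering
  criterion, and an optional truncation of the sparse histogram tail;
  `subspace_scan` repeats the fit over projections onto dimension subsets.
- **A composition-preserving permutation null.** `shuffle_labels` permutes
  residue-type labels within each chain while geometry, SA and secondary
  structure stay positional; re-running the pair pipeline over shuffled
  corpora and averaging (default 10 repetitions) gives a reference tensor,
  and `ratio_map` the per-cell observed/expected significance ratios
  (cells observed but absent from the reference are flagged infinite).
- **Descriptive summaries.** Pair matrices above a rank threshold,
  SA × distance histograms, per-residue-type and per-secondary-structure
  rank curves, cumulative pair counts, and the comparison of each type's
  natural occurrence with its pair participation.

Inputs are PDB-format coordinate files plus per-residue annotations
(secondary structure and relative solvent accessibility in percent),
supplied either as HSSP files or as a plain tab-separated table. A
first-class synthetic-data module generates self-avoiding, globular chains
with realistic composition, secondary-structure segments and a
buried-hydrophobic core, so the entire pipeline is testable without any
external downloads.

## Worked example

```python
import numpy as np
import pairspace as ps

params = ps.CorpusParams(seed=1, n_chains=30, min_length=40, max_length=200)
corpus = [s.chain for s in ps.generate_corpus(params)]

observations = []
for chain in corpus:
    observations.extend(ps.find_pairs(chain))
tensor = ps.accumulate(observations, mode="symmetric")
print(f"{len(corpus)} chains, {len(observations)} pair observations, "
      f"{tensor.nnz} occupied cells (total {tensor.total():.0f})")

fit = ps.fit_powerlaw(ps.rank_frequency(tensor), tail="contiguous")
print(fit.summary())

ref = ps.build_reference(corpus, n_reps=10, seed=1)
ratios = ps.ratio_map(tensor, ref)
print(f"{len(ratios.infinite_cells)} cells observed but never seen in the reference")

hyd = [ps.DEFAULT_SCHEME.aa_bin(aa) for aa in ("ALA", "ILE", "LEU", "VAL")]
for name, thr in (("all ranks", 1), ("rank >= 4", 4)):
    m = ps.pair_matrix(tensor, ps.at_least(thr))
    share = m.counts[np.ix_(hyd, hyd)].sum() / m.total
    print(f"AILV-AILV share, {name}: {share:.2f}")
```

prints

```
30 chains, 3422 pair observations, 6088 occupied cells (total 6844)
Rank-frequency power-law fit (log2-log2 OLS)
  points:        6 distinct ranks in [1, 6]
  slope:         -4.0158  (lambda = 4.0158)
  95% CI:        (-4.4855, -3.5461)
  intercept:     12.5707 (log2 units)
  |Pearson r|:   0.9965
  RMSE:          0.2953 (log2 units)

3639 cells observed but never seen in the reference
AILV-AILV share, all ranks: 0.33
AILV-AILV share, rank >= 4: 1.00
```

In symmetric insertion mode each observation also increments the
AA/SS-swapped cell, so the tensor total is twice the observation count and
Phe–Ile and Ile–Phe cells always agree. The rank-frequency plot of this
small corpus is already close to linear in log–log coordinates, and the
highly populated cells concentrate almost entirely on pairs among Ala, Ile,
Leu and Val — buried (SA ≤ 10), as the SA × distance histogram shows. A
corpus of thousands of real chains sharpens both readouts; see
`docs/methods.md` for what the synthetic corpus does and does not emulate.

The same workflow is available from a shell:

```sh
pairspace simulate --out corpus --n-chains 30 --seed 1
pairspace build --corpus corpus --out tensor.tsv
pairspace reference --corpus corpus --out ref.tsv --n-reps 10 --seed 1
pairspace ratios --observed tensor.tsv --reference ref.tsv --out ratios.tsv
pairspace fit --tensor tensor.tsv --out fit.tsv --tail contiguous
pairspace scan --tensor tensor.tsv --out scan.tsv
pairspace summaries --tensor tensor.tsv --corpus corpus --out-dir summaries
```

All outputs are plain tab-separated text; reruns from the same seed and
configuration are byte-identical.

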