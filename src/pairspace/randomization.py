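"""Composition-preserving permutation null and observed/expected ratios.

The null model permutes the residue-type labels within each chain while
leaving everything positional — Cα and functional-atom coordinates, solvent
accessibility, secondary structure, sequence index — at its position.  Each
chain's amino-acid composition is therefore conserved exactly, while the
assignment of types to spatial environments is randomized.  The pair pipeline
is re-run on the relabeled chains; averaging the resulting tensors over
repetitions yields the reference tensor, the denominator of the per-cell
observed/expected significance ratios.

After relabeling, functional-atom distances are computed from the original
atoms at each position: a position keeps its spatial signature, only its
type label moves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .pair_tensor import (
    BinScheme,
    DEFAULT_SCHEME,
    SparseCountTensor,
    accumulate,
    find_pairs,
    new_tensor8d,
)
from .structure_io import ValidatedChain


def shuffle_labels(chain: ValidatedChain, rng: np.random.Generator | int) -> ValidatedChain:
    """Return a copy of the chain with residue-type labels uniformly permuted.

    Positional attributes (coordinates, SA, SS, seq_index, provenance) stay at
    their positions; the multiset of residue types is unchanged.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(chain.residues)
    perm = rng.permutation(n)
    residues = [
        replace(chain.residues[pos], aa=chain.residues[int(src)].aa)
        for pos, src in enumerate(perm)
    ]
    return ValidatedChain(chain.structure_id, chain.chain_id, residues)


def identity_shuffle(chain: ValidatedChain, rng: np.random.Generator | int) -> ValidatedChain:
    """Test hook: a 'shuffle' that returns the chain unchanged."""
    return chain


@dataclass
class ReferenceTensor:
    """Cell-wise mean of shuffled-corpus tensors over `n_reps` repetitions."""

    tensor: SparseCountTensor
    n_reps: int
    seed: int

    def write(self, path) -> None:
        self.tensor.meta.update(
            {"reference": "true", "n_reps": str(self.n_reps), "seed": str(self.seed)}
        )
        self.tensor.write(path)

    @classmethod
    def read(cls, path) -> "ReferenceTensor":
        t = SparseCountTensor.read(path)
        if t.meta.get("reference") != "true":
            raise ValueError(f"{path}: not a reference tensor file")
        return cls(tensor=t, n_reps=int(t.meta["n_reps"]), seed=int(t.meta["seed"]))


def build_reference(
    corpus: Sequence[ValidatedChain],
    n_reps: int = 10,
    seed: int = 0,
    scheme: BinScheme = DEFAULT_SCHEME,
    mode: str = "symmetric",
    shuffler: Callable[[ValidatedChain, np.random.Generator], ValidatedChain] = shuffle_labels,
) -> ReferenceTensor:
    """Shuffle every chain, re-run the pair pipeline, and average over repetitions.

    A master seed spawns an independent substream per (repetition, chain), so
    the result is deterministic given the seed regardless of iteration order.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_reps)
    acc = new_tensor8d(scheme, meta={"mode": mode})
    for rep in range(n_reps):
        chain_streams = streams[rep].spawn(len(corpus))
        observations = []
        for chain, ss in zip(corpus, chain_streams):
            shuffled = shuffler(chain, np.random.default_rng(ss))
            observations.extend(find_pairs(shuffled, scheme))
        rep_tensor = accumulate(observations, scheme, mode=mode)
        for idx, v in rep_tensor.items():
            acc.add(idx, v)
    mean = acc.scale(1.0 / n_reps)
    mean.meta["mode"] = mode
    return ReferenceTensor(tensor=mean, n_reps=n_reps, seed=seed)


@dataclass
class RatioMap:
    """Per-cell observed/reference ratios.

    Cells observed but never seen in the reference have an infinite ratio and
    are listed separately in `infinite_cells`.
    """

    cells: dict[tuple[int, ...], float]
    infinite_cells: set[tuple[int, ...]]
    observed: dict[tuple[int, ...], float]
    reference: dict[tuple[int, ...], float]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# idx8\tobserved\texpected\tratio\n")
            for idx in sorted(set(self.cells) | self.infinite_cells):
                obs = self.observed[idx]
                ref = self.reference.get(idx, 0.0)
                ratio = "inf" if idx in self.infinite_cells else repr(self.cells[idx])
                fh.write("\t".join(str(i) for i in idx)
                         + f"\t{obs!r}\t{ref!r}\t{ratio}\n")


def ratio_map(observed: SparseCountTensor,
              reference: ReferenceTensor | SparseCountTensor) -> RatioMap:
    """Observed/reference ratio for every cell with observed > 0."""
    ref_tensor = reference.tensor if isinstance(reference, ReferenceTensor) else reference
    if ref_tensor.shape != observed.shape:
        raise ValueError(
            f"shape mismatch: observed {observed.shape} vs reference {ref_tensor.shape}")
    if observed.meta.get("mode") and ref_tensor.meta.get("mode") and \
            observed.meta["mode"] != ref_tensor.meta["mode"]:
        raise ValueError("observed and reference tensors use different insertion modes")

    cells: dict[tuple[int, ...], float] = {}
    infinite: set[tuple[int, ...]] = set()
    obs_map: dict[tuple[int, ...], float] = {}
    for idx, count in observed.items():
        obs_map[idx] = count
        ref = ref_tensor[idx]
        if ref == 0.0:
            infinite.add(idx)
        else:
            cells[idx] = count / ref
    return RatioMap(cells=cells, infinite_cells=infinite,
                    observed=obs_map, reference=dict(ref_tensor.cells))
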