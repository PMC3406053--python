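"""Descriptive summaries of the 8-D pair tensor.

Everything here is a read-out of the tensor (plus, for composition, the
corpus): which amino-acid pairs populate the high-count cells, where those
pairs sit in the solvent-accessibility x distance plane, how secondary
structure changes with rank, and how pair participation compares with the
natural occurrence of each residue type.

"Rank" is a cell's population.  Predicates select cells either with exactly
a given population (kind="equal") or at least it (kind="at_least"); the
threshold of interest for the hydrophobic-core readout is rank >= 50.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pair_tensor import SparseCountTensor
from .residues import AA3, SS_CATEGORIES
from .scalefree import RankTable
from .structure_io import ValidatedChain


@dataclass(frozen=True)
class RankPredicate:
    kind: str            # "equal" or "at_least"
    threshold: float

    def __post_init__(self):
        if self.kind not in ("equal", "at_least"):
            raise ValueError(f"unknown predicate kind: {self.kind!r}")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")

    def __call__(self, population: float) -> bool:
        if self.kind == "equal":
            return population == self.threshold
        return population >= self.threshold


def at_least(threshold: float) -> RankPredicate:
    return RankPredicate("at_least", threshold)


def equal(threshold: float) -> RankPredicate:
    return RankPredicate("equal", threshold)


def _dim(tensor: SparseCountTensor, name: str) -> int:
    try:
        return tensor.dim_names.index(name)
    except ValueError:
        raise ValueError(f"tensor lacks dimension {name!r}") from None


# ---------------------------------------------------------------------------
# Pair matrix
# ---------------------------------------------------------------------------

@dataclass
class PairMatrix:
    """20x20 pair counts restricted to a rank predicate.

    counts[i, j] sums the populations of predicate-satisfying cells with
    AA1 = i, AA2 = j.  The per-residue marginal counts each cell once per
    distinct member type: row + column sums with the diagonal counted once.
    """

    counts: np.ndarray
    predicate: RankPredicate
    aa_order: tuple[str, ...] = AA3

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def marginals(self) -> pd.Series:
        m = self.counts.sum(axis=0) + self.counts.sum(axis=1) - np.diag(self.counts)
        return pd.Series(m, index=list(self.aa_order), name="pairs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.aa_order),
                            columns=list(self.aa_order))


def pair_matrix(tensor: SparseCountTensor, pred: RankPredicate) -> PairMatrix:
    """Sum populations of predicate-satisfying cells into their (AA1, AA2) entry."""
    a1, a2 = _dim(tensor, "AA1"), _dim(tensor, "AA2")
    n = tensor.shape[a1]
    counts = np.zeros((n, n))
    for idx, pop in tensor.items():
        if pred(pop):
            counts[idx[a1], idx[a2]] += pop
    return PairMatrix(counts=counts, predicate=pred)


# ---------------------------------------------------------------------------
# Per-residue rank curves
# ---------------------------------------------------------------------------

def per_residue_rank_curves(
    tensor: SparseCountTensor,
    r_max: float = np.inf,
) -> tuple[dict[str, RankTable], dict[str, float]]:
    """Rank-frequency curve and maximum rank per residue type.

    omega_X(R) counts cells of population R whose AA1 or AA2 is X; a cell with
    AA1 = AA2 = X is counted once.  Returns ({aa: RankTable}, {aa: max rank}),
    with max rank 0 for types appearing in no cell.
    """
    a1, a2 = _dim(tensor, "AA1"), _dim(tensor, "AA2")
    counters: dict[str, Counter] = {aa: Counter() for aa in AA3}
    for idx, pop in tensor.items():
        if pop > r_max:
            continue
        members = {idx[a1], idx[a2]}
        for m in members:
            counters[AA3[m]][float(pop)] += 1
    tables = {aa: RankTable(dict(c)) for aa, c in counters.items()}
    max_rank = {aa: (max(c) if c else 0.0) for aa, c in counters.items()}
    return tables, max_rank


# ---------------------------------------------------------------------------
# SA x distance histogram
# ---------------------------------------------------------------------------

@dataclass
class Histogram2D:
    """Pair counts over the (solvent accessibility, distance) bin plane."""

    counts: np.ndarray            # (n_sa_bins, n_dist_bins)
    predicate: RankPredicate

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self, sa_labels=None, dist_labels=None) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=sa_labels, columns=dist_labels)


def sa_distance_histogram(tensor: SparseCountTensor, pred: RankPredicate) -> Histogram2D:
    sa, d = _dim(tensor, "SA"), _dim(tensor, "D")
    counts = np.zeros((tensor.shape[sa], tensor.shape[d]))
    for idx, pop in tensor.items():
        if pred(pop):
            counts[idx[sa], idx[d]] += pop
    return Histogram2D(counts=counts, predicate=pred)


# ---------------------------------------------------------------------------
# Secondary structure vs rank
# ---------------------------------------------------------------------------

def ss_vs_rank(tensor: SparseCountTensor) -> dict[str, RankTable]:
    """omega_c(R): cells of population R whose SS1 or SS2 is category c
    (cells with SS1 = SS2 = c counted once)."""
    s1, s2 = _dim(tensor, "SS1"), _dim(tensor, "SS2")
    counters: dict[str, Counter] = {c: Counter() for c in SS_CATEGORIES}
    for idx, pop in tensor.items():
        for m in {idx[s1], idx[s2]}:
            counters[SS_CATEGORIES[m]][float(pop)] += 1
    return {c: RankTable(dict(cnt)) for c, cnt in counters.items()}


# ---------------------------------------------------------------------------
# Cumulative pairs above rank
# ---------------------------------------------------------------------------

def cumulative_pairs_above_rank(tensor: SparseCountTensor) -> dict[int, float]:
    """C(R) = sum over ranks R' >= R of R' * omega(R').

    Monotone non-increasing, anchored at C(1) = tensor total; defined for
    every integer rank from 1 to one past the maximum observed rank.
    """
    counter: Counter = Counter()
    for _, pop in tensor.items():
        counter[float(pop)] += 1
    if not counter:
        return {1: 0.0}
    max_rank = int(max(counter))
    out: dict[int, float] = {}
    running = 0.0
    ranks_desc = sorted(counter, reverse=True)
    k = 0
    for r in range(max_rank + 1, 0, -1):
        while k < len(ranks_desc) and ranks_desc[k] >= r:
            running += ranks_desc[k] * counter[ranks_desc[k]]
            k += 1
        out[r] = running
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# Natural occurrence vs pair participation
# ---------------------------------------------------------------------------

def occurrence_comparison(
    corpus: Sequence[ValidatedChain],
    tensor: SparseCountTensor,
) -> pd.DataFrame:
    """Per-residue composition fraction vs pair-participation fraction.

    Composition is the normalized residue count over the corpus; participation
    is the normalized per-residue marginal of the pair matrix over all
    occupied cells.  Both columns sum to 1 (participation is NaN when the
    tensor holds no pairs).
    """
    comp = Counter()
    for chain in corpus:
        for r in chain.residues:
            comp[r.aa] += 1
    n_res = sum(comp.values())
    if n_res == 0:
        raise ValueError("empty corpus")
    composition = pd.Series({aa: comp.get(aa, 0) / n_res for aa in AA3},
                            name="composition")

    marg = pair_matrix(tensor, at_least(1)).marginals()
    if marg.sum() == 0:
        import logging
        logging.getLogger(__name__).warning(
            "tensor holds no pairs; participation fractions undefined")
        participation = pd.Series(np.nan, index=list(AA3), name="pair_participation")
    else:
        participation = (marg / marg.sum()).rename("pair_participation")
    return pd.concat([composition, participation], axis=1)
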