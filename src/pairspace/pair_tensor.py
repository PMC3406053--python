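"""The 8-dimensional bin scheme, pair detection and the sparse count tensor.

Two residues of the same chain form a pair when they sit in the same
solvent-accessibility bin and the minimum Euclidean distance between their
functional atoms is below 8.25 Å.  Each pair is binned along eight axes —
(AA1, AA2, SA, D, SS1, SS2, CL, SD) — and counted in a sparse tensor of shape
20 x 20 x 12 x 14 x 4 x 4 x 12 x 6 (77,414,400 cells).  The tensor is stored
sparsely; the dense array is never materialized.

Bin intervals follow the half-open convention (lower, upper]: e.g. the
solvent-accessibility bins are SA<=0, 0<SA<=10, ..., 90<SA<=100, SA>100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial import cKDTree

from .residues import AA3, AA_INDEX, FUNCTIONAL_ATOMS, SS_CATEGORIES, SS_INDEX
from .structure_io import ResidueRecord, ValidatedChain

DIM_NAMES = ("AA1", "AA2", "SA", "D", "SS1", "SS2", "CL", "SD")

#: strict upper cutoff on the functional-atom distance for a pair
DISTANCE_CUTOFF = 8.25

# Bin edges (multiples of 0.5, 10 and 100) are exactly representable and
# float division is monotone, so ceil-based bin arithmetic is exact.


# ---------------------------------------------------------------------------
# Bin scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    """Binning of the eight tensor axes.

    Defaults give the canonical scheme: 20 amino-acid bins per AA axis
    (alphabetical by 3-letter code), 12 solvent-accessibility bins
    (SA<=0, width-10 bins to 100, SA>100), 14 distance bins (D<=1.75,
    width-0.5 bins to 8.25), 4 secondary-structure bins per SS axis,
    12 chain-length bins (CL<=0, width-100 bins to 1000, CL>1000) and
    6 sequence-distance bins (0, 1, 2, 3, 4, >4).
    """

    aa_order: tuple[str, ...] = AA3
    ss_categories: tuple[str, ...] = SS_CATEGORIES
    n_sa_bins: int = 12
    n_dist_bins: int = 14
    n_cl_bins: int = 12
    n_sd_bins: int = 6

    @property
    def shape(self) -> tuple[int, ...]:
        n_aa = len(self.aa_order)
        n_ss = len(self.ss_categories)
        return (n_aa, n_aa, self.n_sa_bins, self.n_dist_bins,
                n_ss, n_ss, self.n_cl_bins, self.n_sd_bins)

    # --- per-dimension binning -------------------------------------------
    def aa_bin(self, aa: str) -> int:
        return AA_INDEX[aa] if self.aa_order is AA3 else self.aa_order.index(aa)

    def ss_bin(self, ss: str) -> int:
        return SS_INDEX[ss] if self.ss_categories is SS_CATEGORIES else self.ss_categories.index(ss)

    def sa_bin(self, sa: float) -> int:
        if math.isnan(sa):
            raise ValueError("SA is NaN")
        if sa <= 0:
            return 0
        if sa > 100:
            return self.n_sa_bins - 1
        return min(int(math.ceil(sa / 10.0)), self.n_sa_bins - 2)

    def dist_bin(self, d: float) -> int:
        if math.isnan(d):
            raise ValueError("distance is NaN")
        if d <= 1.75:
            return 0
        if d > 8.25:
            return self.n_dist_bins - 1
        return min(int(math.ceil((d - 1.75) / 0.5)), self.n_dist_bins - 1)

    def cl_bin(self, cl: float) -> int:
        if math.isnan(cl):
            raise ValueError("chain length is NaN")
        if cl <= 0:
            return 0
        if cl > 1000:
            return self.n_cl_bins - 1
        return min(int(math.ceil(cl / 100.0)), self.n_cl_bins - 2)

    def sd_bin(self, sd: float) -> int:
        if math.isnan(sd):
            raise ValueError("sequence distance is NaN")
        sd = int(sd)
        return sd if 0 <= sd <= 4 else self.n_sd_bins - 1

    def sa_bin_labels(self) -> list[str]:
        labels = ["SA<=0"] + [f"{10*i}<SA<={10*(i+1)}" for i in range(10)] + ["SA>100"]
        return labels

    def dist_bin_labels(self) -> list[str]:
        labels = ["D<=1.75"]
        lo = 1.75
        for _ in range(self.n_dist_bins - 1):
            labels.append(f"{lo:.2f}<D<={lo + 0.5:.2f}")
            lo += 0.5
        return labels


DEFAULT_SCHEME = BinScheme()


def assign_bin(value: float, dimension: str, scheme: BinScheme = DEFAULT_SCHEME) -> int:
    """Bin a scalar along one of the numeric dimensions ('sa', 'dist', 'cl', 'sd')."""
    dim = dimension.lower()
    if dim == "sa":
        return scheme.sa_bin(value)
    if dim in ("dist", "d"):
        return scheme.dist_bin(value)
    if dim == "cl":
        return scheme.cl_bin(value)
    if dim == "sd":
        return scheme.sd_bin(value)
    raise ValueError(f"unknown binnable dimension: {dimension!r}")


def tensor_size(scheme: BinScheme = DEFAULT_SCHEME) -> int:
    """Total number of cells of the (dense) tensor the scheme defines."""
    return int(np.prod(scheme.shape))


# ---------------------------------------------------------------------------
# Pair detection
# ---------------------------------------------------------------------------

@dataclass
class PairObservation:
    idx8: tuple[int, ...]          # (AA1, AA2, SA, D, SS1, SS2, CL, SD)
    euclid: float                  # min functional-atom distance, Å
    provenance: str                # "1ABC0102A1030B"-style string
    scheme: BinScheme = field(default=DEFAULT_SCHEME, repr=False, compare=False)


def pair_distance(r1: ResidueRecord, r2: ResidueRecord) -> float:
    """Minimum Euclidean distance over all functional-atom combinations."""
    diff = r1.functional_xyz[:, None, :] - r2.functional_xyz[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=-1)).min())


def _provenance_number(seq_key: str) -> str:
    """Zero-pad the numeric part of an author residue key to 4 digits."""
    digits = "".join(ch for ch in seq_key if ch.isdigit() or ch == "-")
    icode = "".join(ch for ch in seq_key if ch.isalpha())
    try:
        num = int(digits)
    except ValueError:
        return seq_key
    if num > 9999 or num < -999:
        import logging
        logging.getLogger(__name__).warning(
            "residue number %d cannot be zero-padded to 4 digits", num)
        return f"{num}{icode}"
    return f"{num:04d}{icode}"


def pair_provenance(structure_id: str, r1: ResidueRecord, r2: ResidueRecord) -> str:
    return (structure_id
            + _provenance_number(r1.provenance[1]) + (r1.provenance[2] or r1.chain_id)
            + _provenance_number(r2.provenance[1]) + (r2.provenance[2] or r2.chain_id))


def find_pairs(
    chain: ValidatedChain,
    scheme: BinScheme = DEFAULT_SCHEME,
) -> list[PairObservation]:
    """Detect all qualifying residue pairs of one chain.

    All unordered pairs (i < j by seq_index) are tested against the three
    criteria: same chain (by construction), same SA bin, and minimum
    functional-atom distance strictly below 8.25 Å.  Candidate pairs are
    pre-screened with a k-d tree over all functional atoms so long chains
    avoid the full quadratic distance scan.
    """
    n = len(chain.residues)
    if n < 2:
        return []

    sa_bins = [scheme.sa_bin(r.sa) for r in chain.residues]
    cl = scheme.cl_bin(chain.chain_length)

    # stack all functional atoms with a map back to their residue
    coords = []
    owner = []
    for i, r in enumerate(chain.residues):
        for xyz in r.functional_xyz:
            coords.append(xyz)
            owner.append(i)
    coords = np.asarray(coords)
    owner = np.asarray(owner)

    tree = cKDTree(coords)
    atom_pairs = tree.query_pairs(r=DISTANCE_CUTOFF, output_type="ndarray")

    # minimum distance per residue pair among candidate atom pairs
    best: dict[tuple[int, int], float] = {}
    if len(atom_pairs):
        ii = owner[atom_pairs[:, 0]]
        jj = owner[atom_pairs[:, 1]]
        d = np.sqrt(((coords[atom_pairs[:, 0]] - coords[atom_pairs[:, 1]]) ** 2).sum(axis=1))
        for a, b, dist in zip(ii, jj, d):
            if a == b:
                continue
            key = (int(a), int(b)) if a < b else (int(b), int(a))
            if dist < best.get(key, np.inf):
                best[key] = float(dist)

    out: list[PairObservation] = []
    for (i, j), dist in sorted(best.items()):
        if dist >= DISTANCE_CUTOFF:
            continue
        if sa_bins[i] != sa_bins[j]:
            continue
        r1, r2 = chain.residues[i], chain.residues[j]
        idx8 = (
            scheme.aa_bin(r1.aa),
            scheme.aa_bin(r2.aa),
            sa_bins[i],
            scheme.dist_bin(dist),
            scheme.ss_bin(r1.ss),
            scheme.ss_bin(r2.ss),
            cl,
            scheme.sd_bin(abs(r1.seq_index - r2.seq_index)),
        )
        out.append(PairObservation(
            idx8=idx8,
            euclid=dist,
            provenance=pair_provenance(chain.structure_id, r1, r2),
            scheme=scheme,
        ))
    return out


# ---------------------------------------------------------------------------
# Sparse count tensor
# ---------------------------------------------------------------------------

class SparseCountTensor:
    """Sparse non-negative count tensor over binned dimensions.

    Cells are stored as a dict mapping index tuples to counts; counts may be
    fractional (averaged reference tensors).  Zero cells are never stored.
    """

    def __init__(
        self,
        shape: tuple[int, ...],
        dim_names: tuple[str, ...] | None = None,
        meta: dict[str, str] | None = None,
    ):
        self.shape = tuple(int(s) for s in shape)
        self.dim_names = tuple(dim_names) if dim_names else tuple(
            f"dim{i}" for i in range(len(shape)))
        if len(self.dim_names) != len(self.shape):
            raise ValueError("dim_names length must match shape length")
        self.cells: dict[tuple[int, ...], float] = {}
        self.meta: dict[str, str] = dict(meta or {})

    # --- basic container behaviour ---------------------------------------
    def __len__(self) -> int:
        return len(self.cells)

    @property
    def nnz(self) -> int:
        return len(self.cells)

    def __getitem__(self, idx: tuple[int, ...]) -> float:
        return self.cells.get(tuple(idx), 0.0)

    def items(self) -> Iterator[tuple[tuple[int, ...], float]]:
        return iter(self.cells.items())

    def total(self) -> float:
        return sum(self.cells.values())

    def add(self, idx: Iterable[int], weight: float = 1.0) -> None:
        idx = tuple(int(i) for i in idx)
        if len(idx) != len(self.shape):
            raise ValueError(f"index length {len(idx)} != tensor ndim {len(self.shape)}")
        for k, (i, s) in enumerate(zip(idx, self.shape)):
            if not 0 <= i < s:
                raise IndexError(f"index {i} out of range for dimension {self.dim_names[k]}")
        new = self.cells.get(idx, 0.0) + weight
        if new == 0.0:
            self.cells.pop(idx, None)
        else:
            self.cells[idx] = new

    def copy(self) -> "SparseCountTensor":
        out = SparseCountTensor(self.shape, self.dim_names, self.meta)
        out.cells = dict(self.cells)
        return out

    def scale(self, factor: float) -> "SparseCountTensor":
        out = SparseCountTensor(self.shape, self.dim_names, self.meta)
        out.cells = {k: v * factor for k, v in self.cells.items()}
        return out

    # --- serialization -----------------------------------------------------
    def write(self, path: str | Path) -> None:
        """Write the tensor in the sparse tab-separated format (round-trip safe)."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("#pairspace-tensor\tv1\n")
            fh.write("#shape\t" + "\t".join(str(s) for s in self.shape) + "\n")
            fh.write("#dims\t" + "\t".join(self.dim_names) + "\n")
            fh.write(f"#nnz\t{self.nnz}\n")
            fh.write(f"#total\t{self.total()!r}\n")
            for key, value in sorted(self.meta.items()):
                fh.write(f"#{key}\t{value}\n")
            for idx in sorted(self.cells):
                count = self.cells[idx]
                count_str = str(int(count)) if count == int(count) else repr(count)
                fh.write("\t".join(str(i) for i in idx) + "\t" + count_str + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "SparseCountTensor":
        path = Path(path)
        shape: tuple[int, ...] | None = None
        dims: tuple[str, ...] | None = None
        meta: dict[str, str] = {}
        cells: dict[tuple[int, ...], float] = {}
        with path.open() as fh:
            first = fh.readline()
            if not first.startswith("#pairspace-tensor"):
                raise ValueError(f"{path}: not a pairspace sparse tensor file")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, rest = line[1:].partition("\t")
                    if key == "shape":
                        shape = tuple(int(x) for x in rest.split("\t"))
                    elif key == "dims":
                        dims = tuple(rest.split("\t"))
                    elif key in ("nnz", "total"):
                        pass   # recomputed
                    else:
                        meta[key] = rest
                    continue
                fields = line.split("\t")
                idx = tuple(int(x) for x in fields[:-1])
                cells[idx] = float(fields[-1])
        if shape is None:
            raise ValueError(f"{path}: missing #shape header")
        out = cls(shape, dims, meta)
        for idx, v in cells.items():
            out.add(idx, v)
        return out


#: Alias used throughout for the full 8-dimensional tensor.
Tensor8D = SparseCountTensor


def new_tensor8d(scheme: BinScheme = DEFAULT_SCHEME,
                 meta: dict[str, str] | None = None) -> SparseCountTensor:
    return SparseCountTensor(scheme.shape, DIM_NAMES, meta)


def accumulate(
    observations: Iterable[PairObservation],
    scheme: BinScheme = DEFAULT_SCHEME,
    mode: str = "symmetric",
    index_records: list[tuple[str, tuple[int, ...]]] | None = None,
) -> SparseCountTensor:
    """Accumulate pair observations into a sparse 8-D count tensor.

    mode="symmetric" (default): every observation increments both its cell
    and the AA/SS-swapped cell, so the tensor total is twice the number of
    observations and swapped amino-acid orders carry equal counts.
    mode="canonical": one increment into the cell with AA1 <= AA2 (ties broken
    by SS1 <= SS2); total equals the number of observations.

    If `index_records` is given, a (provenance, idx8) record is appended for
    every insertion.
    """
    if mode not in ("symmetric", "canonical"):
        raise ValueError(f"unknown insertion mode: {mode!r}")
    tensor = new_tensor8d(scheme, meta={"mode": mode})
    n_obs = 0
    for obs in observations:
        if obs.scheme is not scheme and obs.scheme != scheme:
            raise ValueError("observation binned under a different BinScheme")
        n_obs += 1
        a1, a2, sa, d, s1, s2, cl, sd = obs.idx8
        swapped = (a2, a1, sa, d, s2, s1, cl, sd)
        if mode == "symmetric":
            for idx in (obs.idx8, swapped):
                tensor.add(idx)
                if index_records is not None:
                    index_records.append((obs.provenance, idx))
        else:
            idx = obs.idx8 if (a1, s1) <= (a2, s2) else swapped
            tensor.add(idx)
            if index_records is not None:
                index_records.append((obs.provenance, idx))
    tensor.meta["observations"] = str(n_obs)
    return tensor


def write_index(records: list[tuple[str, tuple[int, ...]]], path: str | Path) -> None:
    """Write insertion provenance records: one '<provenance>\\t<8 indices>' line each."""
    with Path(path).open("w") as fh:
        for prov, idx in records:
            fh.write(prov + "\t" + "\t".join(str(i) for i in idx) + "\n")
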