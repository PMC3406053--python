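"""Rank-frequency analysis of tensor cell populations and power-law fitting.

The cell populations of the (possibly projected) tensor are summarized as a
rank-frequency table: R is a cell population ("rank") and omega(R) the number
of cells holding exactly that population.  Scale-free organization means
omega(R) ~ R^-lambda, i.e. a straight line of slope -lambda when plotting
log2(omega) against log2(R).  The fit is an ordinary least-squares regression
on the log2-log2 points, one point per distinct rank, with a standard t-based
95% confidence interval on the slope.

Two goodness measures are reported: |Pearson r| of the log-log points (the
"closer to 1 is better" figure of merit used to order subspace fits) and the
residual RMSE in log2 units.

The sparse tail of an empirical rank-frequency histogram — ranks observed
zero or one time — flattens the apparent slope, because ranks with omega = 0
cannot enter a log-log fit.  `fit_powerlaw(tail="contiguous")` therefore
restricts the fit to the maximal run of consecutive integer ranks starting at
the smallest observed rank, which is where the histogram is well populated;
the default uses every observed rank.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pair_tensor import SparseCountTensor


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def project(tensor: SparseCountTensor, keep_dims) -> SparseCountTensor:
    """Marginalize the tensor onto a subset of its dimensions.

    `keep_dims` is a sequence of dimension names or positions; counts are
    summed over the dropped dimensions, conserving the total.
    """
    keep = list(keep_dims)
    if not keep:
        raise ValueError("keep_dims must be non-empty")
    positions: list[int] = []
    for d in keep:
        if isinstance(d, str):
            try:
                positions.append(tensor.dim_names.index(d))
            except ValueError:
                raise ValueError(f"unknown dimension name: {d!r}") from None
        else:
            if not 0 <= int(d) < len(tensor.shape):
                raise ValueError(f"dimension position out of range: {d}")
            positions.append(int(d))
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate dimensions in keep_dims")

    out = SparseCountTensor(
        shape=tuple(tensor.shape[p] for p in positions),
        dim_names=tuple(tensor.dim_names[p] for p in positions),
        meta=dict(tensor.meta),
    )
    for idx, v in tensor.items():
        out.add(tuple(idx[p] for p in positions), v)
    return out


# ---------------------------------------------------------------------------
# Rank-frequency table
# ---------------------------------------------------------------------------

@dataclass
class RankTable:
    """Map from rank R (cell population) to omega(R) (cells with that population)."""

    entries: dict[float, int]

    def ranks(self) -> np.ndarray:
        return np.array(sorted(self.entries), dtype=float)

    @property
    def n_cells(self) -> int:
        """Total number of non-zero cells: sum of omega over all ranks."""
        return sum(self.entries.values())

    @property
    def total_count(self) -> float:
        """Total tensor count: sum of R * omega(R)."""
        return float(sum(r * w for r, w in self.entries.items()))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tomega\n")
            for r in sorted(self.entries):
                r_str = str(int(r)) if float(r) == int(r) else repr(r)
                fh.write(f"{r_str}\t{self.entries[r]}\n")

    @classmethod
    def read(cls, path) -> "RankTable":
        entries: dict[float, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("rank", "#")):
                    continue
                r, w = line.split("\t")
                entries[float(r)] = int(w)
        return cls(entries)


def rank_frequency(cells: SparseCountTensor) -> RankTable:
    """Exact histogram of non-zero cell populations (zero cells never counted)."""
    counter: Counter[float] = Counter()
    for _, v in cells.items():
        if v != 0:
            counter[float(v)] += 1
    return RankTable(entries=dict(counter))


# ---------------------------------------------------------------------------
# Power-law fit
# ---------------------------------------------------------------------------

@dataclass
class PowerLawFit:
    """OLS fit of log2(omega) on log2(R).  slope = -lambda."""

    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    pearson_r_abs: float
    rmse: float
    n_points: int
    r_range: tuple[float, float]

    @property
    def lambda_(self) -> float:
        return -self.slope

    def summary(self) -> str:
        lo, hi = self.slope_ci95
        return (
            "Rank-frequency power-law fit (log2-log2 OLS)\n"
            f"  points:        {self.n_points} distinct ranks in "
            f"[{self.r_range[0]:g}, {self.r_range[1]:g}]\n"
            f"  slope:         {self.slope:.4f}  (lambda = {self.lambda_:.4f})\n"
            f"  95% CI:        ({lo:.4f}, {hi:.4f})\n"
            f"  intercept:     {self.intercept:.4f} (log2 units)\n"
            f"  |Pearson r|:   {self.pearson_r_abs:.4f}\n"
            f"  RMSE:          {self.rmse:.4f} (log2 units)\n"
        )


FitResult = PowerLawFit


def fit_powerlaw(
    table: RankTable,
    r_min: float = 1.0,
    r_max: float = math.inf,
    tail: str = "all",
) -> PowerLawFit:
    """Fit omega(R) = c * R^slope by OLS on the log2-log2 points.

    One point per distinct stored rank; ranks with omega = 0 never enter.
    tail="contiguous" truncates to the maximal run of consecutive integer
    ranks starting at the smallest selected rank (drops the sparse tail).
    """
    ranks = sorted(r for r in table.entries if r_min <= r <= r_max and r > 0)
    if tail == "contiguous":
        kept = ranks[:1]
        for r in ranks[1:]:
            if r - kept[-1] <= 1.0 + 1e-9:
                kept.append(r)
            else:
                break
        ranks = kept
    elif tail != "all":
        raise ValueError(f"unknown tail rule: {tail!r}")

    if len(ranks) < 3:
        raise ValueError(
            f"power-law fit needs >= 3 distinct ranks in range, got {len(ranks)}")

    x = np.log2(np.array(ranks, dtype=float))
    y = np.log2(np.array([table.entries[r] for r in ranks], dtype=float))
    res = stats.linregress(x, y)
    n = len(x)
    tcrit = stats.t.ppf(0.975, n - 2) if n > 2 else math.nan
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    resid = y - (res.intercept + res.slope * x)
    return PowerLawFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci95=(float(ci[0]), float(ci[1])),
        pearson_r_abs=float(abs(res.rvalue)),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        n_points=n,
        r_range=(float(ranks[0]), float(ranks[-1])),
    )


# ---------------------------------------------------------------------------
# Subspace scan
# ---------------------------------------------------------------------------

@dataclass
class SubspaceReport:
    """Per-subset power-law fits, sorted by goodness (|Pearson r|), best first."""

    rows: list[tuple[tuple[str, ...], PowerLawFit]]
    skipped: list[tuple[tuple[str, ...], str]]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("dimensions\tslope\tci_low\tci_high\tgoodness\trmse\tn_points\n")
            for dims, fit in self.rows:
                fh.write(" ".join(dims)
                         + f"\t{fit.slope:.4f}\t{fit.slope_ci95[0]:.4f}"
                         + f"\t{fit.slope_ci95[1]:.4f}\t{fit.pearson_r_abs:.4f}"
                         + f"\t{fit.rmse:.4f}\t{fit.n_points}\n")
            for dims, reason in self.skipped:
                fh.write("# skipped " + " ".join(dims) + ": " + reason + "\n")


def subspace_scan(
    tensor: SparseCountTensor,
    subsets,
    goodness_floor: float = 0.0,
    **fit_kwargs,
) -> SubspaceReport:
    """project -> rank_frequency -> fit_powerlaw over each dimension subset.

    Rows with |Pearson r| >= goodness_floor are kept, sorted descending by
    goodness; subsets whose fit fails (too few points) are reported in
    `skipped` with the reason.
    """
    rows: list[tuple[tuple[str, ...], PowerLawFit]] = []
    skipped: list[tuple[tuple[str, ...], str]] = []
    for subset in subsets:
        names = tuple(
            tensor.dim_names[d] if not isinstance(d, str) else d for d in subset)
        try:
            fit = fit_powerlaw(rank_frequency(project(tensor, subset)), **fit_kwargs)
        except ValueError as exc:
            skipped.append((names, str(exc)))
            continue
        if fit.pearson_r_abs >= goodness_floor:
            rows.append((names, fit))
    rows.sort(key=lambda row: row[1].pearson_r_abs, reverse=True)
    return SubspaceReport(rows=rows, skipped=skipped)


def aa_pair_subsets(extra_dims=("SA", "D", "SS1", "SS2", "CL", "SD")):
    """All 2^k dimension subsets that always contain AA1 and AA2."""
    out = []
    k = len(extra_dims)
    for mask in range(1 << k):
        subset = ["AA1", "AA2"]
        for b in range(k):
            if mask >> b & 1:
                subset.append(extra_dims[b])
        out.append(tuple(subset))
    return out
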