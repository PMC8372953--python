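"""Land-cover change accounting, Markov projection and CA allocation.

Works on categorical grids (class codes on a raster).  The canonical on-disk
format is a plain-text integer grid: one row of space-separated codes per
line, row-major from the top-left, nodata code -1.

The projection machinery follows the CA-Markov pattern: a first-order Markov
chain on class areas decides *how much* changes per period, and a
cellular-automata neighbourhood rule decides *where* — cells flip to a
growing class in order of neighbourhood suitability, which keeps allocated
change spatially contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

NODATA = -1

#: change-map codes
CHANGE_CODES = {
    "retained_nonforest": 0,
    "degraded": 1,
    "restored": 2,
    "retained": 3,
}


@dataclass
class LandCoverMap:
    """A categorical land-cover grid with a class legend."""

    grid: np.ndarray  # 2-D int array of class codes
    legend: dict[int, str]
    cell_area_ha: float
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_area_ha <= 0:
            raise ValueError("cell_area_ha must be positive")
        codes = set(np.unique(self.grid).tolist()) - {self.nodata}
        unknown = codes - set(self.legend)
        if unknown:
            raise ValueError(f"grid contains codes missing from the legend: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def class_counts(self) -> dict[int, int]:
        """Cell count per legend class (nodata excluded)."""
        return {
            c: int(np.sum(self.grid == c)) for c in sorted(self.legend)
        }

    def class_areas(self) -> dict[int, float]:
        """Area per legend class, ha."""
        return {c: n * self.cell_area_ha for c, n in self.class_counts().items()}


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic class-transition probabilities over one period."""

    classes: tuple[int, ...]
    probabilities: np.ndarray
    period_years: float = 11.0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        k = len(self.classes)
        if p.shape != (k, k):
            raise ValueError("probabilities must be square and match classes")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("every row must sum to 1")
        object.__setattr__(self, "probabilities", p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, index=list(self.classes), columns=list(self.classes))


@dataclass
class ChangeMap:
    """Cell-wise two-date change classes and their areas."""

    grid: np.ndarray  # CHANGE_CODES values, or nodata
    cell_area_ha: float
    areas_ha: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Text-grid I/O
# ---------------------------------------------------------------------------

def read_grid(path, legend: dict[int, str], cell_area_ha: float, nodata: int = NODATA) -> LandCoverMap:
    """Read a plain-text integer grid (one row per line, space-separated)."""
    grid = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return LandCoverMap(grid=grid, legend=legend, cell_area_ha=cell_area_ha, nodata=nodata)


def write_grid(lcmap: LandCoverMap, path) -> None:
    np.savetxt(path, lcmap.grid, fmt="%d")


# ---------------------------------------------------------------------------
# Spectral helper
# ---------------------------------------------------------------------------

def ndvi(nir, red):
    """Normalized Difference Vegetation Index, (NIR - red)/(NIR + red).

    Accepts scalars or arrays of non-negative reflectances; cells where both
    bands are zero yield NaN (nodata).  Values lie in [-1, 1].
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if np.any(nir < 0) or np.any(red < 0):
        raise ValueError("reflectances must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Change detection & transition estimation
# ---------------------------------------------------------------------------

def _check_pair(map_t1: LandCoverMap, map_t2: LandCoverMap) -> None:
    if map_t1.shape != map_t2.shape:
        raise ValueError(f"grid shapes differ: {map_t1.shape} vs {map_t2.shape}")
    if map_t1.legend != map_t2.legend:
        raise ValueError("legends differ between the two maps")


def classify_change(
    map_t1: LandCoverMap, map_t2: LandCoverMap, forest_classes: set[int]
) -> ChangeMap:
    """Cell-wise degraded / restored / retained classification.

    forest -> non-forest = degraded; non-forest -> forest = restored;
    forest -> forest = retained; non-forest -> non-forest is reported
    separately as retained_nonforest.
    """
    _check_pair(map_t1, map_t2)
    g1, g2 = map_t1.grid, map_t2.grid
    f1 = np.isin(g1, list(forest_classes))
    f2 = np.isin(g2, list(forest_classes))
    valid = (g1 != map_t1.nodata) & (g2 != map_t2.nodata)

    out = np.full(g1.shape, NODATA, dtype=np.int16)
    out[valid & f1 & ~f2] = CHANGE_CODES["degraded"]
    out[valid & ~f1 & f2] = CHANGE_CODES["restored"]
    out[valid & f1 & f2] = CHANGE_CODES["retained"]
    out[valid & ~f1 & ~f2] = CHANGE_CODES["retained_nonforest"]

    areas = {
        name: float(np.sum(out == code)) * map_t1.cell_area_ha
        for name, code in CHANGE_CODES.items()
    }
    return ChangeMap(grid=out, cell_area_ha=map_t1.cell_area_ha, areas_ha=areas)


def estimate_transition(
    map_t1: LandCoverMap,
    map_t2: LandCoverMap,
    period_years: float = 11.0,
    classes: tuple[int, ...] | None = None,
) -> TransitionMatrix:
    """Maximum-likelihood transition matrix from a two-date cross-tabulation.

    Rows are normalised by the t1 class counts; a class absent at t1 gets an
    identity row (it cannot be observed to leave, so it is assumed to stay).
    """
    _check_pair(map_t1, map_t2)
    if classes is None:
        classes = tuple(sorted(map_t1.legend))
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}

    valid = (map_t1.grid != map_t1.nodata) & (map_t2.grid != map_t2.nodata)
    g1 = map_t1.grid[valid].ravel()
    g2 = map_t2.grid[valid].ravel()

    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (np.vectorize(idx.get)(g1), np.vectorize(idx.get)(g2)), 1)

    probs = np.eye(k)
    row_totals = counts.sum(axis=1)
    nz = row_totals > 0
    probs[nz] = counts[nz] / row_totals[nz, np.newaxis]
    return TransitionMatrix(classes=classes, probabilities=probs, period_years=period_years)


# ---------------------------------------------------------------------------
# Markov projection & CA allocation
# ---------------------------------------------------------------------------

def markov_project(
    areas: dict[int, float] | np.ndarray,
    matrix: TransitionMatrix,
    n_periods: int = 1,
) -> dict[int, float]:
    """Project per-class areas forward: a_{t+k} = a_t @ P^k.

    Total area is conserved exactly (row-stochasticity of P).
    """
    if n_periods < 0:
        raise ValueError("n_periods must be >= 0")
    if isinstance(areas, dict):
        missing = set(matrix.classes) - set(areas)
        if missing:
            raise ValueError(f"areas missing classes {sorted(missing)}")
        vec = np.array([areas[c] for c in matrix.classes], dtype=float)
    else:
        vec = np.asarray(areas, dtype=float)
        if vec.shape != (len(matrix.classes),):
            raise ValueError("area vector length does not match matrix classes")
    if np.any(vec < 0):
        raise ValueError("areas must be non-negative")
    out = vec @ np.linalg.matrix_power(matrix.probabilities, n_periods)
    return {c: float(v) for c, v in zip(matrix.classes, out)}


def largest_remainder_round(targets: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers preserving their (integer) total."""
    t = np.asarray(targets, dtype=float)
    floors = np.floor(t).astype(np.int64)
    deficit = total - floors.sum()
    if deficit < 0:
        raise ValueError("floors already exceed the total")
    remainders = t - floors
    # largest remainders win; stable order on ties (lowest index first)
    order = np.argsort(-remainders, kind="stable")
    floors[order[:deficit]] += 1
    return floors


def _suitability(grid: np.ndarray, cls: int, filter_size: int) -> np.ndarray:
    """Fraction of class ``cls`` cells in the truncated filter neighbourhood."""
    member = (grid == cls).astype(np.float64)
    ones = np.ones_like(member)
    # separable box sums with truncated edges
    kernel = np.ones(filter_size)

    def box(a: np.ndarray) -> np.ndarray:
        a = convolve1d(a, kernel, axis=0, mode="constant", cval=0.0)
        return convolve1d(a, kernel, axis=1, mode="constant", cval=0.0)

    return box(member) / box(ones)


def ca_allocate(
    map_t: LandCoverMap,
    matrix: TransitionMatrix,
    n_periods: int = 1,
    filter_size: int = 5,
    seed: int | None = None,
) -> LandCoverMap:
    """Spatially allocate a Markov projection with a contiguity filter.

    Target per-class cell counts come from ``markov_project`` applied to the
    current cell counts and rounded by largest remainder (total conserved
    exactly).  Classes above target donate cells; classes below target claim
    them in descending neighbourhood suitability (fraction of same-class
    cells in the ``filter_size`` x ``filter_size`` window around the cell on
    the current map), ties broken by row-major cell order then class order.
    Cells keep their class unless claimed.  The rule is fully deterministic;
    ``seed`` is accepted for interface symmetry with the generators but has
    no effect.
    """
    if filter_size < 1 or filter_size % 2 == 0:
        raise ValueError("filter_size must be a positive odd integer")
    if np.any(map_t.grid == map_t.nodata):
        raise ValueError("ca_allocate requires a gap-free map (no nodata cells)")

    grid = map_t.grid.copy()
    classes = matrix.classes
    counts = np.array([np.sum(grid == c) for c in classes], dtype=float)
    total = int(counts.sum())
    projected = np.array(
        [markov_project(counts, matrix, n_periods)[c] for c in classes]
    )
    targets = largest_remainder_round(projected, total)

    current = np.array([np.sum(grid == c) for c in classes], dtype=np.int64)
    deficit = targets - current  # >0: class must grow; <0: class donates
    surplus = {c: int(-d) for c, d in zip(classes, deficit) if d < 0}
    growers = [c for c, d in zip(classes, deficit) if d > 0]
    need = {c: int(d) for c, d in zip(classes, deficit) if d > 0}
    if not growers:
        return LandCoverMap(
            grid=grid, legend=dict(map_t.legend), cell_area_ha=map_t.cell_area_ha,
            nodata=map_t.nodata,
        )

    # candidate claims: (neg suitability, row-major cell index, class order)
    nrows, ncols = grid.shape
    claims: list[tuple[float, int, int]] = []
    for ci, c in enumerate(classes):
        if c not in need:
            continue
        suit = _suitability(grid, c, filter_size)
        flat = suit.ravel()
        cells = np.flatnonzero(grid.ravel() != c)
        for cell in cells:
            claims.append((-flat[cell], int(cell), ci))
    claims.sort()

    flat_grid = grid.ravel()
    claimed = np.zeros(flat_grid.size, dtype=bool)
    for neg_s, cell, ci in claims:
        c = classes[ci]
        if need.get(c, 0) <= 0:
            continue
        if claimed[cell]:
            continue
        donor = int(flat_grid[cell])
        if surplus.get(donor, 0) <= 0:
            continue
        flat_grid[cell] = c
        claimed[cell] = True
        need[c] -= 1
        surplus[donor] -= 1
        if all(v <= 0 for v in need.values()):
            break

    out = flat_grid.reshape(nrows, ncols)
    return LandCoverMap(
        grid=out, legend=dict(map_t.legend), cell_area_ha=map_t.cell_area_ha,
        nodata=map_t.nodata,
    )


# ---------------------------------------------------------------------------
# Accuracy assessment
# ---------------------------------------------------------------------------

def confusion_matrix(reference: LandCoverMap, predicted: LandCoverMap) -> pd.DataFrame:
    """Cross-tabulation of reference (rows) vs predicted (columns) classes."""
    _check_pair(reference, predicted)
    valid = (reference.grid != reference.nodata) & (predicted.grid != predicted.nodata)
    classes = sorted(reference.legend)
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k), dtype=np.int64)
    r = np.vectorize(idx.get)(reference.grid[valid].ravel())
    p = np.vectorize(idx.get)(predicted.grid[valid].ravel())
    np.add.at(counts, (r, p), 1)
    return pd.DataFrame(counts, index=classes, columns=classes)


def accuracy_from_confusion(confusion: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Overall accuracy and Cohen's kappa from a square confusion matrix.

    OA = trace/total; kappa = (po - pe)/(1 - pe) with pe from the row/column
    marginals.  When pe = 1 (a single class on both maps) kappa is degenerate
    and reported as 1.0.
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = m.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    po = np.trace(m) / total
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if pe >= 1.0 - 1e-12:
        return float(po), 1.0
    return float(po), float((po - pe) / (1.0 - pe))


def accuracy_metrics(
    reference: LandCoverMap, predicted: LandCoverMap
) -> tuple[float, float, pd.DataFrame]:
    """Overall accuracy, kappa and the confusion matrix for a map pair."""
    conf = confusion_matrix(reference, predicted)
    oa, kappa = accuracy_from_confusion(conf)
    return oa, kappa, conf
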