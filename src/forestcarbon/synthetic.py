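"""Synthetic stands and land-cover map pairs with known ground truth.

Every downstream stage of the pipeline (structure statistics, clustering,
biomass, transition estimation, CA allocation) is validated against data
generated here, where the truth is known by construction:

* ``generate_stand`` draws a deciduous-stand census: plots of fixed area,
  species from a ranked abundance model, DBH as ``dbh_min + Exponential``
  (the simplest generator with the reverse-J size structure typical of
  continuously regenerating stands), and height from a power-law allometry
  ``H = a * DBH^b`` with multiplicative lognormal noise.

* ``generate_landscape_pair`` draws two categorical land-cover grids: the
  first from given class proportions, the second by pushing every cell
  through a known row-stochastic transition matrix, optionally followed by
  majority smoothing passes that add spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inventory import PlotInventory, TreeRecord
from .lulc import LandCoverMap

__all__ = ["StandSpec", "LandscapeSpec", "generate_stand", "generate_landscape_pair"]

ABUNDANCE_MODELS = ("log_series", "geometric")


@dataclass(frozen=True)
class StandSpec:
    """Parameters of a synthetic deciduous-stand census.

    Defaults emulate the study conditions this package targets: 25 plots of
    0.16 ha, ~150 stems per plot (≈940 trees ha-1), a pool of 110 species,
    mean DBH ≈ 12.7 cm (rate 0.13 above the 5 cm census threshold) and mean
    height ≈ 9 m at the mean DBH.
    """

    n_plots: int = 25
    plot_area_ha: float = 0.16
    species_pool: int = 110
    abundance_model: str = "log_series"
    stems_per_plot: int = 150
    dbh_rate: float = 0.13  # 1/cm; mean DBH = dbh_min + 1/rate
    dbh_min: float = 5.0
    height_allometry: tuple[float, float, float] = (2.0, 0.6, 0.15)  # (a, b, sigma)
    n_subplots: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.plot_area_ha <= 0:
            raise ValueError("plot_area_ha must be positive")
        if self.species_pool < 1:
            raise ValueError("species_pool must be >= 1")
        if self.abundance_model not in ABUNDANCE_MODELS:
            raise ValueError(
                f"abundance_model must be one of {ABUNDANCE_MODELS}, "
                f"got {self.abundance_model!r}"
            )
        if self.stems_per_plot < 1:
            raise ValueError("stems_per_plot must be >= 1")
        if self.dbh_rate <= 0:
            raise ValueError("dbh_rate must be positive")
        if self.dbh_min < 5.0:
            raise ValueError("dbh_min must be >= 5 (census threshold)")
        a, b, sigma = self.height_allometry
        if a <= 0 or b <= 0:
            raise ValueError("height_allometry a and b must be positive")
        if sigma < 0:
            raise ValueError("height_allometry sigma must be >= 0")
        if self.n_subplots < 1:
            raise ValueError("n_subplots must be >= 1")


def _abundance_probs(spec: StandSpec) -> np.ndarray:
    """Ranked relative abundances of the species pool (non-increasing)."""
    k = np.arange(1, spec.species_pool + 1, dtype=float)
    if spec.abundance_model == "log_series":
        x = 0.98  # shape of the log-series; long tail of rare species
        p = x**k / k
    else:  # geometric
        ratio = 0.95
        p = ratio ** (k - 1)
    return p / p.sum()


def generate_stand(spec: StandSpec) -> list[PlotInventory]:
    """Draw a reproducible synthetic census for ``spec``.

    Species labels are ``sp001 ...``, assigned so that label rank matches
    abundance rank.  All randomness comes from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    probs = _abundance_probs(spec)
    labels = np.array([f"sp{i + 1:03d}" for i in range(spec.species_pool)])
    a, b, sigma = spec.height_allometry

    plots: list[PlotInventory] = []
    for ip in range(spec.n_plots):
        n = spec.stems_per_plot
        sp_idx = rng.choice(spec.species_pool, size=n, p=probs)
        dbh = spec.dbh_min + rng.exponential(scale=1.0 / spec.dbh_rate, size=n)
        height = a * dbh**b * np.exp(rng.normal(0.0, sigma, size=n))
        subplot = rng.integers(1, spec.n_subplots + 1, size=n)
        plot_id = f"P{ip + 1:02d}"
        records = [
            TreeRecord(
                plot_id=plot_id,
                subplot_id=f"S{subplot[j]:02d}",
                species=str(labels[sp_idx[j]]),
                dbh=float(dbh[j]),
                height=float(height[j]),
            )
            for j in range(n)
        ]
        plots.append(
            PlotInventory(plot_id=plot_id, records=records, area_ha=spec.plot_area_ha)
        )
    return plots


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a synthetic two-date land-cover pair."""

    n_rows: int
    n_cols: int
    classes: tuple[str, ...]
    initial_proportions: tuple[float, ...]
    true_transition: tuple[tuple[float, ...], ...]
    cell_area_ha: float = 0.09  # 30 m Landsat-like pixel
    autocorr_passes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_area_ha <= 0:
            raise ValueError("cell_area_ha must be positive")
        k = len(self.classes)
        if k < 1:
            raise ValueError("need at least one class")
        p = np.asarray(self.initial_proportions, dtype=float)
        if p.shape != (k,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                "initial_proportions must be a length-matched simplex vector "
                "(non-negative, summing to 1)"
            )
        t = np.asarray(self.true_transition, dtype=float)
        if t.shape != (k, k) or np.any(t < 0):
            raise ValueError("true_transition must be a non-negative k x k matrix")
        if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("every row of true_transition must sum to 1")
        if self.autocorr_passes < 0:
            raise ValueError("autocorr_passes must be >= 0")


def _majority_smooth(grid: np.ndarray, n_classes: int, passes: int) -> np.ndarray:
    """Majority filter over the 3x3 neighbourhood (centre included).

    Ties keep the current class when it is among the modes, otherwise the
    lowest class code wins.  Edge cells use the truncated neighbourhood.
    """
    out = grid
    for _ in range(passes):
        padded = np.full((out.shape[0] + 2, out.shape[1] + 2), -1, dtype=out.dtype)
        padded[1:-1, 1:-1] = out
        counts = np.zeros((n_classes,) + out.shape, dtype=np.int32)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                window = padded[
                    1 + dr : 1 + dr + out.shape[0], 1 + dc : 1 + dc + out.shape[1]
                ]
                for c in range(n_classes):
                    counts[c] += window == c
        maxc = counts.max(axis=0)
        winner = counts.argmax(axis=0)  # lowest code among ties
        current_count = np.take_along_axis(
            counts, out[np.newaxis].astype(np.intp), axis=0
        )[0]
        out = np.where(current_count == maxc, out, winner).astype(grid.dtype)
    return out


def generate_landscape_pair(spec: LandscapeSpec) -> tuple[LandCoverMap, LandCoverMap]:
    """Draw a (t1, t2) pair of categorical maps from a known transition matrix.

    Raw t1 cells are iid from ``initial_proportions``; raw t2 cells are
    independent per-cell draws from the ``true_transition`` row of their raw
    t1 class.  Both raw grids then receive the same ``autocorr_passes``
    majority-smoothing passes, which introduces spatial autocorrelation (and,
    as on real classified imagery, biases a naive per-cell transition
    estimate — keep passes at 0 when exact matrix recovery is the point).
    Deriving t2 before smoothing keeps an identity matrix absorbing: the two
    raw grids are then equal and the deterministic smoothing preserves that.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.classes)
    shape = (spec.n_rows, spec.n_cols)

    p0 = np.asarray(spec.initial_proportions, dtype=float)
    raw1 = rng.choice(k, size=shape, p=p0).astype(np.int16)

    t = np.asarray(spec.true_transition, dtype=float)
    cum = np.cumsum(t, axis=1)
    u = rng.random(size=shape)
    raw2 = (u[..., np.newaxis] >= cum[raw1]).sum(axis=-1).astype(np.int16)

    grid1 = _majority_smooth(raw1, k, spec.autocorr_passes)
    grid2 = _majority_smooth(raw2, k, spec.autocorr_passes)

    legend = {i: name for i, name in enumerate(spec.classes)}
    return (
        LandCoverMap(grid=grid1, legend=legend, cell_area_ha=spec.cell_area_ha),
        LandCoverMap(grid=grid2, legend=legend, cell_area_ha=spec.cell_area_ha),
    )
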