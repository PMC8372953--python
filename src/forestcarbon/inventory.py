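"""Tree-inventory data model, I/O and stand-structure statistics.

The inventory is the plot-census backbone of the pipeline: one record per
measured stem (DBH >= 5 cm census threshold), grouped into fixed-area plots
(default 0.16 ha, i.e. 40 m x 40 m quadrats subdivided into 16 subplots of
10 m x 10 m).  On top of it this module computes the standard stand-structure
and diversity statistics of tropical forest inventories:

* stem density (trees ha-1) and basal area (m2 ha-1),
* Shannon-Wiener diversity (log base 2),
* Jaccard similarity between species sets,
* importance value index (IVI = relative density + relative frequency +
  relative dominance) per species,
* DBH / height class distributions,
* one-way ANOVA between plot groups,
* sampling-intensity design, n = ceil((Z*sigma/E)^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: census threshold: stems below this DBH (cm) are not part of the inventory
DBH_CENSUS_THRESHOLD_CM = 5.0

#: default plot area in hectares (40 m x 40 m)
DEFAULT_PLOT_AREA_HA = 0.16


class InventoryFormatError(ValueError):
    """Raised when an inventory file violates the expected layout."""


@dataclass(frozen=True)
class TreeRecord:
    """One measured stem."""

    plot_id: str
    species: str
    dbh: float  # cm
    height: float  # m
    subplot_id: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if self.dbh < DBH_CENSUS_THRESHOLD_CM:
            raise ValueError(
                f"dbh must be >= {DBH_CENSUS_THRESHOLD_CM} cm (census threshold), "
                f"got {self.dbh}"
            )
        if self.height <= 0:
            raise ValueError(f"height must be positive, got {self.height}")

    @property
    def basal_area_m2(self) -> float:
        """Cross-sectional stem area at breast height, m2 (DBH in cm)."""
        return math.pi * (self.dbh / 200.0) ** 2


@dataclass
class PlotInventory:
    """All stems of one sampling plot."""

    plot_id: str
    records: list[TreeRecord] = field(default_factory=list)
    area_ha: float = DEFAULT_PLOT_AREA_HA
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"area_ha must be positive, got {self.area_ha}")
        for r in self.records:
            if r.plot_id != self.plot_id:
                raise ValueError(
                    f"record plot_id {r.plot_id!r} does not match plot {self.plot_id!r}"
                )

    @property
    def n_trees(self) -> int:
        return len(self.records)

    def species_counts(self) -> pd.Series:
        return pd.Series(
            [r.species for r in self.records], dtype="object"
        ).value_counts().sort_index()


@dataclass(frozen=True)
class SamplingDesign:
    """Sampling-intensity design: n = ceil((Z*sigma/E)^2)."""

    z_value: float
    sigma: float
    required_precision_e: float
    n_required: int


@dataclass
class StructureSummary:
    """Stand-level structure and diversity summary.

    ``per_stratum`` maps stratum label -> {metric: (mean, sd, n_plots)} where
    metrics are per-plot values summarised with the sample SD (n-1).
    """

    n_species: int
    density: float  # trees ha-1
    basal_area: float  # m2 ha-1
    shannon: float  # bits
    n_trees: int
    total_area_ha: float
    per_stratum: dict[str, dict[str, tuple[float, float, int]]] = field(
        default_factory=dict
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "plot": "plot",
    "species": "species",
    "dbh": "dbh",
    "height": "height",
    "subplot": "subplot",
    "family": "family",
}


def read_inventory(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    plot_area_ha: float = DEFAULT_PLOT_AREA_HA,
    dbh_min: float = DBH_CENSUS_THRESHOLD_CM,
) -> list[PlotInventory]:
    """Read a delimited-text inventory into per-plot collections.

    The file must have a header naming at least the plot, species, dbh and
    height columns (names configurable through ``column_map``).  Rows with
    DBH below ``dbh_min`` are rejected and counted in a log message rather
    than silently dropped.  Comma and tab delimiters are auto-detected when
    ``delimiter`` is None.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    sep = delimiter
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","

    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]

    for key in ("plot", "species", "dbh", "height"):
        if cols[key] not in df.columns:
            raise InventoryFormatError(
                f"missing mandatory column {cols[key]!r} "
                f"(have: {', '.join(df.columns)})"
            )

    records: list[TreeRecord] = []
    n_rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row_d = dict(zip(df.columns, row))
        try:
            dbh = float(row_d[cols["dbh"]])
            height = float(row_d[cols["height"]])
        except (TypeError, ValueError) as exc:
            raise InventoryFormatError(
                f"line {i}: non-numeric dbh/height ({exc})"
            ) from exc
        if dbh < dbh_min:
            n_rejected += 1
            continue
        subplot = row_d.get(cols["subplot"])
        family = row_d.get(cols["family"])
        records.append(
            TreeRecord(
                plot_id=str(row_d[cols["plot"]]),
                species=str(row_d[cols["species"]]),
                dbh=dbh,
                height=height,
                subplot_id=None if subplot in (None, "") or pd.isna(subplot) else str(subplot),
                family=None if family in (None, "") or pd.isna(family) else str(family),
            )
        )
    if n_rejected:
        logger.info(
            "read_inventory: rejected %d row(s) below the %.1f cm DBH threshold",
            n_rejected,
            dbh_min,
        )

    plots: dict[str, list[TreeRecord]] = {}
    for r in records:
        plots.setdefault(r.plot_id, []).append(r)
    return [
        PlotInventory(plot_id=pid, records=recs, area_ha=plot_area_ha)
        for pid, recs in sorted(plots.items())
    ]


def write_inventory(plots: Iterable[PlotInventory], path, delimiter: str = ",") -> None:
    """Write plots back to the delimited inventory format (round-trips read_inventory)."""
    rows = []
    for p in plots:
        for r in p.records:
            rows.append(
                {
                    "plot": r.plot_id,
                    "subplot": r.subplot_id if r.subplot_id is not None else "",
                    "species": r.species,
                    "family": r.family if r.family is not None else "",
                    "dbh": r.dbh,
                    "height": r.height,
                }
            )
    pd.DataFrame(
        rows, columns=["plot", "subplot", "species", "family", "dbh", "height"]
    ).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Design & structure statistics
# ---------------------------------------------------------------------------

def sampling_intensity(z: float, sigma: float, e: float) -> SamplingDesign:
    """Number of plots needed for a target precision: n = ceil((Z*sigma/E)^2)."""
    if z <= 0 or sigma <= 0 or e <= 0:
        raise ValueError("z, sigma and e must all be positive")
    n = math.ceil((z * sigma / e) ** 2)
    return SamplingDesign(z_value=z, sigma=sigma, required_precision_e=e, n_required=max(n, 1))


def _per_plot_metrics(plot: PlotInventory) -> dict[str, float]:
    ba = sum(r.basal_area_m2 for r in plot.records)
    counts = plot.species_counts()
    return {
        "n_species": float(len(counts)),
        "density": plot.n_trees / plot.area_ha,
        "basal_area": ba / plot.area_ha,
        "shannon": shannon_index(counts.to_numpy()) if plot.n_trees else 0.0,
    }


def density_and_basal_area(plots: Sequence[PlotInventory]) -> StructureSummary:
    """Pooled density, basal area and diversity, with per-stratum plot summaries.

    Pooled values divide totals by the total surveyed area; per-stratum
    entries are means +/- sample SD of per-plot values, weighting each plot
    equally.
    """
    if not plots:
        raise ValueError("plots must be non-empty")
    total_area = sum(p.area_ha for p in plots)
    if total_area <= 0:
        raise ValueError("total plot area is zero")
    n_trees = sum(p.n_trees for p in plots)
    total_ba = sum(r.basal_area_m2 for p in plots for r in p.records)
    all_counts = pd.Series(
        [r.species for p in plots for r in p.records], dtype="object"
    ).value_counts()

    per_stratum: dict[str, dict[str, tuple[float, float, int]]] = {}
    strata: dict[str, list[dict[str, float]]] = {}
    for p in plots:
        strata.setdefault(p.stratum or "all", []).append(_per_plot_metrics(p))
    for label, metric_rows in strata.items():
        dfm = pd.DataFrame(metric_rows)
        per_stratum[label] = {
            m: (float(dfm[m].mean()), float(dfm[m].std(ddof=1)) if len(dfm) > 1 else 0.0, len(dfm))
            for m in dfm.columns
        }

    return StructureSummary(
        n_species=int(len(all_counts)),
        density=n_trees / total_area,
        basal_area=total_ba / total_area,
        shannon=shannon_index(all_counts.to_numpy()) if n_trees else 0.0,
        n_trees=n_trees,
        total_area_ha=total_area,
        per_stratum=per_stratum,
    )


def plot_weighted_mean(stratum_means: Sequence[float], n_plots: Sequence[int]) -> float:
    """Pool per-stratum means into an overall mean, weighting by plot counts."""
    if len(stratum_means) != len(n_plots) or not stratum_means:
        raise ValueError("stratum_means and n_plots must be non-empty and equal length")
    w = np.asarray(n_plots, dtype=float)
    if np.any(w <= 0):
        raise ValueError("plot counts must be positive")
    return float(np.average(np.asarray(stratum_means, dtype=float), weights=w))


def shannon_index(abundances: Sequence[float], base: float = 2.0) -> float:
    """Shannon-Wiener diversity H' = -sum p_i log_base p_i.

    Log base 2 by default, so the index is in bits and bounded above by
    log2(richness), with equality only for a uniform community.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size == 0 or np.any(a < 0):
        raise ValueError("abundances must be non-negative and non-empty")
    total = a.sum()
    if total <= 0:
        raise ValueError("at least one abundance must be positive")
    p = a[a > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def jaccard_similarity(
    species_a: set,
    species_b: set,
    convention: str = "standard",
    total_override: int | None = None,
) -> float:
    """Species-overlap similarity, as a percent.

    ``standard``    100 * |A & B| / |A | B|   (the Jaccard index proper)
    ``paper_total`` 100 * |A & B| / total_override, where the divisor is a
                    reported overall species count rather than the union.
                    Some field studies report overlap this way; both are kept
                    so either published figure can be reproduced.
    """
    shared = len(set(species_a) & set(species_b))
    if convention == "standard":
        union = len(set(species_a) | set(species_b))
        if union == 0:
            raise ValueError("both species sets are empty")
        return 100.0 * shared / union
    if convention == "paper_total":
        if total_override is None:
            raise ValueError("convention 'paper_total' requires total_override")
        if total_override < shared or total_override <= 0:
            raise ValueError("total_override must be >= the shared-species count and > 0")
        return 100.0 * shared / total_override
    raise ValueError(f"unknown convention {convention!r}; use 'standard' or 'paper_total'")


# ---------------------------------------------------------------------------
# Importance value index
# ---------------------------------------------------------------------------

IVI_CONVENTIONS = ("paper_100", "standard_300")


def importance_values(
    plots: Sequence[PlotInventory],
    quadrat: str = "auto",
    convention: str = "paper_100",
) -> pd.DataFrame:
    """Per-species importance value index table.

    Components (percent):

    * relative density    100 * stems_i / total stems
    * relative frequency  100 * quadrats containing i / sum over species of
      quadrats containing each species
    * relative dominance  100 * basal area_i / total basal area

    Under ``standard_300`` each component sums to 100 over species and the
    IVI column to 300.  Under ``paper_100`` every component is divided by 3
    before summing, so components sum to 100/3 each and IVI to 100 — the
    normalisation used in the published tables this package reproduces.

    ``quadrat`` selects the presence/absence unit for frequency: ``subplot``
    (requires subplot ids), ``plot``, or ``auto`` (subplot when every record
    carries one, else plot).  Rows are sorted by descending IVI, ties broken
    by species label.
    """
    if convention not in IVI_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; use one of {IVI_CONVENTIONS}")
    if not plots:
        raise ValueError("plots must be non-empty")
    records = [r for p in plots for r in p.records]
    if not records:
        raise ValueError("no tree records in the given plots")

    if quadrat == "auto":
        quadrat = "subplot" if all(r.subplot_id is not None for r in records) else "plot"
    if quadrat not in ("plot", "subplot"):
        raise ValueError(f"unknown quadrat level {quadrat!r}; use 'plot' or 'subplot'")
    if quadrat == "subplot" and any(r.subplot_id is None for r in records):
        raise ValueError("quadrat='subplot' but some records lack subplot ids")

    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "quadrat": [
                (r.plot_id, r.subplot_id) if quadrat == "subplot" else r.plot_id
                for r in records
            ],
            "ba": [r.basal_area_m2 for r in records],
        }
    )
    stems = df.groupby("species").size()
    freq = df.groupby("species")["quadrat"].nunique()
    dom = df.groupby("species")["ba"].sum()

    rd = 100.0 * stems / stems.sum()
    rf = 100.0 * freq / freq.sum()
    rdo = 100.0 * dom / dom.sum()

    table = pd.DataFrame(
        {
            "relative_density": rd,
            "relative_frequency": rf,
            "relative_dominance": rdo,
        }
    )
    if convention == "paper_100":
        table = table / 3.0
    table["ivi"] = table.sum(axis=1)
    table.index.name = "species"
    table = table.sort_values(
        ["ivi", "species"], ascending=[False, True], kind="mergesort"
    )
    table.attrs["convention"] = convention
    table.attrs["quadrat"] = quadrat
    return table


# ---------------------------------------------------------------------------
# Class distributions & ANOVA
# ---------------------------------------------------------------------------

DEFAULT_DBH_EDGES = (5.0, 10.0, 20.0, 30.0)
DEFAULT_HEIGHT_EDGES = (1.3, 5.0, 10.0, 15.0)


def class_distribution(
    records: Sequence[TreeRecord],
    variable: str = "dbh",
    edges: Sequence[float] | None = None,
    last_open: bool = True,
) -> pd.DataFrame:
    """Counts and percents per size class.

    Classes are half-open ``[lo, hi)``; with ``last_open`` the final class is
    ``[last_edge, inf)``.  Records below the first edge go to an explicit
    ``below-range`` bucket (excluded from the percent base) so nothing is
    silently dropped.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if variable not in ("dbh", "height"):
        raise ValueError(f"unknown variable {variable!r}; use 'dbh' or 'height'")
    if edges is None:
        edges = DEFAULT_DBH_EDGES if variable == "dbh" else DEFAULT_HEIGHT_EDGES
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")

    values = np.array([getattr(r, variable) for r in records], dtype=float)
    bounds = edges + [np.inf] if last_open else edges
    labels = []
    counts = []
    for lo, hi in zip(bounds, bounds[1:]):
        labels.append(f"[{lo:g}, {hi:g})" if np.isfinite(hi) else f">= {lo:g}")
        counts.append(int(np.sum((values >= lo) & (values < hi))))
    below = int(np.sum(values < edges[0]))
    in_range = sum(counts)

    out = pd.DataFrame({"class": labels, "count": counts})
    out["percent"] = 100.0 * out["count"] / in_range if in_range else 0.0
    out.attrs["below_range"] = below
    return out


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across plot groups.

    Returns (F, p).  F = (SSB/(k-1)) / (SSW/(N-k)).  When both the between-
    and within-group sums of squares vanish (all observations identical) the
    statistic is degenerate; F is reported as 0.0 with p = 1.0.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    if sum(a.size for a in arrays) - len(arrays) < 1:
        raise ValueError("at least one group needs two or more values")

    grand = np.concatenate(arrays)
    ssb = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0 and ssb == 0.0:
        return 0.0, 1.0
    f_stat, p = stats.f_oneway(*arrays)
    if not np.isfinite(f_stat):  # zero within-group variance, non-zero between
        return float("inf"), 0.0
    return float(f_stat), float(p)
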