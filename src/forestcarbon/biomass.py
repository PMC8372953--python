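"""Allometric above-ground biomass and carbon-stock estimation.

Per-tree biomass uses the Ogawa et al. allometry for Thai natural deciduous
forests, with D the DBH in cm and H the tree height in m:

    Ws = 0.0396 (D^2 H)^0.9326        stem, kg
    Wb = 0.003487 (D^2 H)^1.027       branch, kg
    Wl = 1 / (28.0/(Ws + Wb) + 0.025) leaf, kg  (asymptote 40 kg)

AGB = Ws + Wb + Wl, and carbon = AGB x 0.47 (IPCC default carbon fraction).
The allometry is applied per tree in kilograms and only then aggregated to
t ha-1, never to per-hectare totals directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .forest_typing import ForestTypeAssignment
from .inventory import PlotInventory

#: IPCC default carbon fraction of dry biomass
CARBON_FRACTION = 0.47

#: Ogawa deciduous-forest coefficients: (stem_a, stem_b, branch_a, branch_b,
#: leaf_c, leaf_d) with Wl = 1/(leaf_c/(Ws+Wb) + leaf_d)
OGAWA_COEFFS = {
    "stem_a": 0.0396,
    "stem_b": 0.9326,
    "branch_a": 0.003487,
    "branch_b": 1.027,
    "leaf_c": 28.0,
    "leaf_d": 0.025,
}


@dataclass(frozen=True)
class AllometricResult:
    """Per-tree biomass components (kg) and carbon (kg)."""

    ws: float
    wb: float
    wl: float
    total: float
    carbon: float


@dataclass
class BiomassSummary:
    """Per-stratum and overall biomass/carbon summary.

    ``per_stratum`` maps stratum -> {component: (mean, sd, n_plots)} of
    per-plot t ha-1 values (components: stem, branch, leaf, total, carbon);
    ``overall`` holds the plot-weighted pooled means; ``species_t_ha`` maps
    stratum -> per-species biomass contribution in t ha-1 over the stratum
    area; ``per_plot`` is the per-plot table the summaries are computed from.
    """

    per_stratum: dict[str, dict[str, tuple[float, float, int]]]
    overall: dict[str, float]
    species_t_ha: dict[str, pd.Series]
    per_plot: pd.DataFrame
    carbon_fraction: float = CARBON_FRACTION


def ogawa_biomass(
    dbh: float,
    height: float,
    coeffs: dict[str, float] | None = None,
    carbon_fraction: float = CARBON_FRACTION,
) -> AllometricResult:
    """Stem/branch/leaf biomass (kg) of one tree from DBH (cm) and height (m)."""
    if dbh <= 0 or height <= 0:
        raise ValueError(f"dbh and height must be positive, got D={dbh}, H={height}")
    c = OGAWA_COEFFS if coeffs is None else {**OGAWA_COEFFS, **coeffs}
    d2h = dbh * dbh * height
    ws = c["stem_a"] * d2h ** c["stem_b"]
    wb = c["branch_a"] * d2h ** c["branch_b"]
    wl = 1.0 / (c["leaf_c"] / (ws + wb) + c["leaf_d"])
    total = ws + wb + wl
    return AllometricResult(ws=ws, wb=wb, wl=wl, total=total, carbon=carbon_fraction * total)


def carbon_from_biomass(biomass: float, fraction: float = CARBON_FRACTION) -> float:
    """Carbon stock from dry biomass (any mass unit): carbon = fraction x biomass."""
    if biomass < 0:
        raise ValueError(f"biomass must be non-negative, got {biomass}")
    if fraction <= 0:
        raise ValueError(f"carbon fraction must be positive, got {fraction}")
    return fraction * biomass


def tree_biomass_table(
    plots: list[PlotInventory],
    coeffs: dict[str, float] | None = None,
    carbon_fraction: float = CARBON_FRACTION,
) -> pd.DataFrame:
    """Per-tree allometric results for every record (kg)."""
    rows = []
    for p in plots:
        for r in p.records:
            res = ogawa_biomass(r.dbh, r.height, coeffs, carbon_fraction)
            rows.append(
                {
                    "plot": p.plot_id,
                    "species": r.species,
                    "dbh": r.dbh,
                    "height": r.height,
                    "ws_kg": res.ws,
                    "wb_kg": res.wb,
                    "wl_kg": res.wl,
                    "total_kg": res.total,
                    "carbon_kg": res.carbon,
                }
            )
    return pd.DataFrame(rows)


def aggregate_biomass(
    plots: list[PlotInventory],
    assignment: ForestTypeAssignment | None = None,
    coeffs: dict[str, float] | None = None,
    carbon_fraction: float = CARBON_FRACTION,
) -> BiomassSummary:
    """Aggregate per-tree biomass to plot, stratum and landscape level.

    Per-plot values are sums of per-tree kg divided by 1000 and by the plot
    area (t ha-1).  Stratum summaries are mean +/- sample SD (n-1) over
    plots; the overall mean weights every plot equally.  When ``assignment``
    is None, plots fall back to their own ``stratum`` label (or "all").
    """
    if not plots:
        raise ValueError("plots must be non-empty")

    def stratum_of(p: PlotInventory) -> str:
        if assignment is not None:
            if p.plot_id not in assignment.assignment:
                raise ValueError(f"plot {p.plot_id!r} has no forest-type assignment")
            return assignment.assignment[p.plot_id]
        return p.stratum or "all"

    per_plot_rows = []
    species_kg: dict[str, dict[str, float]] = {}
    stratum_area: dict[str, float] = {}
    for p in plots:
        s = stratum_of(p)
        stratum_area[s] = stratum_area.get(s, 0.0) + p.area_ha
        comp = {"stem": 0.0, "branch": 0.0, "leaf": 0.0}
        for r in p.records:
            res = ogawa_biomass(r.dbh, r.height, coeffs, carbon_fraction)
            comp["stem"] += res.ws
            comp["branch"] += res.wb
            comp["leaf"] += res.wl
            sp = species_kg.setdefault(s, {})
            sp[r.species] = sp.get(r.species, 0.0) + res.total
        total = sum(comp.values())
        per_plot_rows.append(
            {
                "plot": p.plot_id,
                "stratum": s,
                "stem": comp["stem"] / 1000.0 / p.area_ha,
                "branch": comp["branch"] / 1000.0 / p.area_ha,
                "leaf": comp["leaf"] / 1000.0 / p.area_ha,
                "total": total / 1000.0 / p.area_ha,
                "carbon": carbon_fraction * total / 1000.0 / p.area_ha,
            }
        )
    per_plot = pd.DataFrame(per_plot_rows)

    components = ["stem", "branch", "leaf", "total", "carbon"]
    per_stratum: dict[str, dict[str, tuple[float, float, int]]] = {}
    for s, sub in per_plot.groupby("stratum"):
        per_stratum[s] = {
            c: (
                float(sub[c].mean()),
                float(sub[c].std(ddof=1)) if len(sub) > 1 else 0.0,
                len(sub),
            )
            for c in components
        }
    overall = {c: float(per_plot[c].mean()) for c in components}

    species_t_ha = {
        s: (pd.Series(kg) / 1000.0 / stratum_area[s]).sort_values(ascending=False)
        for s, kg in species_kg.items()
    }
    return BiomassSummary(
        per_stratum=per_stratum,
        overall=overall,
        species_t_ha=species_t_ha,
        per_plot=per_plot,
        carbon_fraction=carbon_fraction,
    )
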