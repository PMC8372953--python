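"""End-to-end orchestration: inventory -> typing -> biomass -> LULC -> ledger.

Every stage writes its outputs as delimited text under the configured output
directory, plus a run manifest (config hash, seed, stage record counts) so a
run is reproducible and auditable.  Paths left null in the config are filled
with synthetic data from the config seed, so the default pipeline is fully
self-contained.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import accounting, biomass, forest_typing, inventory, lulc, synthetic
from .config import config_hash, validate_config

logger = logging.getLogger(__name__)


def run_pipeline(cfg: dict, output_dir: str | Path | None = None) -> dict:
    """Run all stages; returns a report dict of the main quantities.

    Raises ValueError when the config is invalid; stage failures propagate
    with the stage name prefixed.
    """
    findings = validate_config(cfg)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        msgs = "; ".join(f"{f.field}: {f.message}" for f in errors)
        raise ValueError(f"invalid config: {msgs}")

    out_dir = Path(output_dir if output_dir is not None else cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"config_hash": config_hash(cfg), "seed": seed, "stages": {}}
    report: dict = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                manifest["stages"].setdefault(name, {})
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                # timings go to the log, not the manifest, so reruns under the
                # same config and seed are byte-identical
                logger.info("stage %s: %.3fs", name, time.perf_counter() - self_inner.t0)

        return _Timer()

    # --- inventory -------------------------------------------------------
    with stage("inventory"):
        inv_cfg = cfg["inventory"]
        if inv_cfg.get("path"):
            plots = inventory.read_inventory(
                inv_cfg["path"],
                plot_area_ha=inv_cfg["plot_area_ha"],
                dbh_min=inv_cfg["dbh_min"],
            )
        else:
            plots = synthetic.generate_stand(synthetic.StandSpec(seed=seed))
            inventory.write_inventory(plots, out_dir / "inventory.csv")
        manifest["stages"]["inventory"]["n_plots"] = len(plots)
        manifest["stages"]["inventory"]["n_trees"] = sum(p.n_trees for p in plots)

        summary = inventory.density_and_basal_area(plots)
        report["n_species"] = summary.n_species
        report["density_trees_ha"] = summary.density
        report["basal_area_m2_ha"] = summary.basal_area
        report["shannon_bits"] = summary.shannon

        records = [r for p in plots for r in p.records]
        conv = cfg["conventions"]
        dbh_classes = inventory.class_distribution(records, "dbh", conv["dbh_edges"])
        dbh_classes.to_csv(out_dir / "dbh_classes.csv", index=False)
        height_classes = inventory.class_distribution(records, "height", conv["height_edges"])
        height_classes.to_csv(out_dir / "height_classes.csv", index=False)

        ivi = inventory.importance_values(plots, convention=conv["ivi"])
        ivi.to_csv(out_dir / "ivi.csv")

    # --- forest typing ---------------------------------------------------
    with stage("typing"):
        matrix = forest_typing.build_ivi_matrix(plots)
        dend, assignment = forest_typing.cluster_plots(
            matrix, linkage=cfg["typing"]["linkage"], k=cfg["typing"]["k"]
        )
        pd.Series(assignment.assignment, name="forest_type").rename_axis("plot").to_csv(
            out_dir / "forest_types.csv"
        )
        np.savetxt(out_dir / "dendrogram_merges.txt", dend.linkage_matrix, fmt="%.6f")
        report["n_forest_types"] = assignment.n_types
        report["chaining_percent"] = dend.chaining_percent

    # --- biomass & carbon ------------------------------------------------
    with stage("biomass"):
        allo = dict(cfg["allometry"])
        fraction = allo.pop("carbon_fraction")
        bio = biomass.aggregate_biomass(
            plots, assignment, coeffs=allo, carbon_fraction=fraction
        )
        bio.per_plot.to_csv(out_dir / "biomass_per_plot.csv", index=False)
        report["agb_t_ha"] = bio.overall["total"]
        report["carbon_tC_ha"] = bio.overall["carbon"]

    # --- land cover ------------------------------------------------------
    with stage("lulc"):
        lc = cfg["lulc"]
        legend = {0: "DDF", 1: "MDF", 2: "nonforest"}
        if lc.get("map_t1") and lc.get("map_t2"):
            map1 = lulc.read_grid(lc["map_t1"], legend, lc["cell_area_ha"])
            map2 = lulc.read_grid(lc["map_t2"], legend, lc["cell_area_ha"])
        else:
            spec = synthetic.LandscapeSpec(
                n_rows=120,
                n_cols=120,
                classes=("DDF", "MDF", "nonforest"),
                initial_proportions=(0.55, 0.15, 0.30),
                true_transition=(
                    (0.92, 0.03, 0.05),
                    (0.02, 0.93, 0.05),
                    (0.10, 0.06, 0.84),
                ),
                cell_area_ha=lc["cell_area_ha"],
                autocorr_passes=1,
                seed=seed,
            )
            map1, map2 = synthetic.generate_landscape_pair(spec)
            lulc.write_grid(map1, out_dir / "map_t1.txt")
            lulc.write_grid(map2, out_dir / "map_t2.txt")

        forest = set(lc["forest_classes"])
        change = lulc.classify_change(map1, map2, forest)
        report["area_degraded_ha"] = change.areas_ha["degraded"]
        report["area_restored_ha"] = change.areas_ha["restored"]
        report["area_retained_ha"] = change.areas_ha["retained"]

        trans = lulc.estimate_transition(map1, map2, period_years=lc["period_years"])
        trans.to_frame().to_csv(out_dir / "transition_matrix.csv")

        projected_map = lulc.ca_allocate(
            map2, trans, n_periods=lc["n_periods"], filter_size=lc["filter_size"], seed=seed
        )
        lulc.write_grid(projected_map, out_dir / "map_projected.txt")
        areas_proj = lulc.markov_project(map2.class_areas(), trans, lc["n_periods"])
        manifest["stages"]["lulc"]["projected_areas_ha"] = {
            legend[c]: round(a, 3) for c, a in areas_proj.items()
        }

    # --- carbon ledger ---------------------------------------------------
    with stage("ledger"):
        market = cfg["market"]
        total_area = map1.grid.size * map1.cell_area_ha
        # forest classes carry the inventory carbon density; non-forest a
        # nominal residual density (shrub/agricultural cover)
        density = {
            c: (report["carbon_tC_ha"] if c in forest else 0.1 * report["carbon_tC_ha"])
            for c in legend
        }
        years = [2007, 2018, 2018 + 11 * lc["n_periods"]]
        areas_by_year = {
            years[0]: map1.class_areas(),
            years[1]: map2.class_areas(),
            years[2]: areas_proj,
        }
        dens_by_year = {y: dict(density) for y in years}
        params = accounting.MarketParams(
            co2e_factor=market["co2e_factor"],
            price=market["price_usd_per_tco2e"],
            area_ha=total_area,
            period_years=years[1] - years[0],
        )
        ledger = accounting.build_ledger(
            {y: {legend[c]: a for c, a in areas.items()} for y, areas in areas_by_year.items()},
            {y: {legend[c]: d for c, d in dens.items()} for y, dens in dens_by_year.items()},
            params,
        )
        ledger.stocks.to_csv(out_dir / "ledger_stocks.csv", index=False)
        ledger.changes.to_csv(out_dir / "ledger_changes.csv", index=False)
        totals = ledger.stocks[ledger.stocks["area_class"] == "Total"]
        report["carbon_stock_start_tC"] = float(totals["carbon_tC"].iloc[0])
        report["carbon_stock_end_tC"] = float(totals["carbon_tC"].iloc[-1])

    manifest["report"] = {
        k: (round(v, 6) if isinstance(v, float) else v) for k, v in report.items()
    }
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
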