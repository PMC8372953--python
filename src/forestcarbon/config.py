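"""Pipeline configuration: loading, defaults and validation."""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .forest_typing import LINKAGES
from .inventory import IVI_CONVENTIONS


@dataclass(frozen=True)
class Finding:
    """One validation finding."""

    severity: str  # "error" | "warning"
    field: str
    message: str


def default_config() -> dict:
    """The packaged default configuration (synthetic inputs, seed 1)."""
    with resources.files("forestcarbon.data").joinpath("default_config.yaml").open("r") as fh:
        return yaml.safe_load(fh)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, filling unset sections from the packaged default."""
    cfg = default_config()
    if path is not None:
        try:
            with open(path, "r", encoding="utf-8") as fh:
                user = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            loc = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
            raise ValueError(f"cannot parse config {path}{loc}: {exc}") from exc
        if user:
            cfg = _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, update: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in update.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config, for stamping outputs."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def validate_config(cfg: dict) -> list[Finding]:
    """Structural and value checks; returns findings, never mutates."""
    findings: list[Finding] = []

    def err(field: str, message: str) -> None:
        findings.append(Finding("error", field, message))

    inv = cfg.get("inventory", {})
    if inv.get("dbh_min", 5.0) < 5.0:
        err("inventory.dbh_min", "must be >= 5 (census threshold)")
    if inv.get("plot_area_ha", 0.16) <= 0:
        err("inventory.plot_area_ha", "must be positive")
    if inv.get("path") is not None and not Path(inv["path"]).exists():
        err("inventory.path", f"file not found: {inv['path']}")

    conv = cfg.get("conventions", {})
    if conv.get("ivi", "paper_100") not in IVI_CONVENTIONS:
        err("conventions.ivi", f"unknown IVI convention; allowed: {', '.join(IVI_CONVENTIONS)}")
    if conv.get("jaccard", "standard") not in ("standard", "paper_total"):
        err("conventions.jaccard", "unknown convention; allowed: standard, paper_total")
    for key in ("dbh_edges", "height_edges"):
        edges = conv.get(key, [])
        if any(b <= a for a, b in zip(edges, edges[1:])):
            err(f"conventions.{key}", "edges must be strictly increasing")

    typ = cfg.get("typing", {})
    if typ.get("linkage", "ward") not in LINKAGES:
        err("typing.linkage", f"unknown linkage; allowed: {', '.join(LINKAGES)}")
    if typ.get("k", 2) < 1:
        err("typing.k", "must be >= 1")

    allo = cfg.get("allometry", {})
    for key in ("stem_a", "stem_b", "branch_a", "branch_b", "leaf_c", "carbon_fraction"):
        if allo.get(key, 1.0) <= 0:
            err(f"allometry.{key}", "must be positive")

    lulc = cfg.get("lulc", {})
    if lulc.get("cell_area_ha", 0.09) <= 0:
        err("lulc.cell_area_ha", "must be positive")
    fs = lulc.get("filter_size", 5)
    if fs < 1 or fs % 2 == 0:
        err("lulc.filter_size", "must be a positive odd integer")
    if lulc.get("n_periods", 1) < 0:
        err("lulc.n_periods", "must be >= 0")
    for key in ("map_t1", "map_t2"):
        if lulc.get(key) is not None and not Path(lulc[key]).exists():
            err(f"lulc.{key}", f"file not found: {lulc[key]}")

    market = cfg.get("market", {})
    if market.get("co2e_factor", 3.67) <= 0:
        err("market.co2e_factor", "must be positive")
    if market.get("price_usd_per_tco2e", 3.20) < 0:
        err("market.price_usd_per_tco2e", "must be non-negative")

    if not isinstance(cfg.get("seed", 0), int):
        err("seed", "must be an integer")
    return findings
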