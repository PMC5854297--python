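"""Serialization of landscapes, configurations, weights and results.

A landscape directory holds three text files:

``sites.csv``
    ``site_id,cost,mu,perimeter,h_1,...,h_J[,h_nontarget]`` — one row per
    site; habitat columns beyond the targets are non-target filler.
``adjacency.csv``
    ``site_a,site_b,shared_length`` — sparse symmetric shared boundaries.
``config.json`` (or ``config.yaml``)
    ``targets``, ``blm``, ``spf``, ``alpha`` (optional), ``initial_reserve``,
    and optionally a ``budget`` model (``{"constant": x}`` or
    ``{"amounts": [...], "probs": [...]}``).

Reading is strict: missing columns, unknown ids, out-of-range values and
conflicting adjacency rows raise descriptive errors, and a written landscape
reads back as an identical instance.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .evaluation import BudgetModel, EECEstimate
from .landscape import Landscape, SharedBoundaries, Site
from .policies import WeightVector

__all__ = [
    "read_landscape",
    "write_landscape",
    "read_weights",
    "write_weights",
    "write_results",
    "write_geojson",
]

SCHEMA_VERSION = 1


def _budget_to_config(budget: BudgetModel) -> dict:
    if budget.is_constant:
        return {"constant": float(budget.amounts[0])}
    return {"amounts": budget.amounts.tolist(), "probs": budget.probs.tolist()}


def _budget_from_config(cfg: Mapping) -> BudgetModel:
    if "constant" in cfg:
        return BudgetModel.constant(float(cfg["constant"]))
    return BudgetModel.discrete(cfg["amounts"], cfg["probs"])


def write_landscape(
    landscape: Landscape,
    directory: str | Path,
    budget_model: BudgetModel | None = None,
) -> Path:
    """Write the three-file landscape bundle; returns the directory path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    J = landscape.n_targets
    n_hab = landscape.habitat_matrix.shape[1]
    hab_cols = [f"h_{j + 1}" for j in range(J)]
    if n_hab == J + 1:
        hab_cols.append("h_nontarget")
    else:
        hab_cols += [f"h_nontarget_{k + 1}" for k in range(n_hab - J)]
    rows = []
    for site in landscape.sites:
        row = {
            "site_id": site.id,
            "cost": site.cost,
            "mu": site.mu,
            "perimeter": site.perimeter,
        }
        row.update({col: site.habitat[k] for k, col in enumerate(hab_cols)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "sites.csv", index=False, float_format="%.17g")

    adj = [
        {"site_a": a, "site_b": b, "shared_length": length}
        for (a, b), length in sorted(landscape.boundaries.items())
    ]
    pd.DataFrame(adj, columns=["site_a", "site_b", "shared_length"]).to_csv(
        directory / "adjacency.csv", index=False, float_format="%.17g"
    )

    config = {
        "schema_version": SCHEMA_VERSION,
        "targets": landscape.targets.tolist(),
        "blm": landscape.blm,
        "spf": landscape.spf.tolist(),
        "alpha": landscape.alpha,
        "initial_reserve": sorted(landscape.initial_reserve),
    }
    if budget_model is not None:
        config["budget"] = _budget_to_config(budget_model)
    (directory / "config.json").write_text(json.dumps(config, indent=2))
    return directory


def _habitat_columns(columns: Iterable[str], n_targets: int) -> list[str]:
    target_cols = sorted(
        (c for c in columns if re.fullmatch(r"h_\d+", c)),
        key=lambda c: int(c.split("_")[1]),
    )
    expected = [f"h_{j + 1}" for j in range(n_targets)]
    if target_cols[: n_targets] != expected:
        raise ValueError(
            f"sites.csv must provide habitat columns {expected}, found {target_cols}"
        )
    extra = [c for c in columns if c.startswith("h_nontarget")]
    return expected + target_cols[n_targets:] + extra


def read_landscape(directory: str | Path) -> tuple[Landscape, BudgetModel | None]:
    """Load and validate a landscape bundle written by :func:`write_landscape`."""
    directory = Path(directory)
    sites_path = directory / "sites.csv"
    adj_path = directory / "adjacency.csv"
    if not sites_path.exists():
        raise FileNotFoundError(f"missing {sites_path}")
    config_path = directory / "config.json"
    if not config_path.exists():
        config_path = directory / "config.yaml"
    if not config_path.exists():
        raise FileNotFoundError(f"missing config.json/config.yaml in {directory}")
    if config_path.suffix == ".json":
        config = json.loads(config_path.read_text())
    else:
        config = yaml.safe_load(config_path.read_text())

    df = pd.read_csv(sites_path, float_precision="round_trip")
    required = ["site_id", "cost", "mu", "perimeter"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sites.csv is missing required columns {missing}")
    targets = list(config.get("targets", []))
    hab_cols = _habitat_columns(df.columns, len(targets))

    sites = []
    for rec in df.itertuples(index=False):
        rec = rec._asdict()
        if not 0.0 <= rec["mu"] <= 1.0:
            raise ValueError(f"site {rec['site_id']}: mu={rec['mu']} outside [0, 1]")
        if rec["cost"] < 0:
            raise ValueError(f"site {rec['site_id']}: negative cost {rec['cost']}")
        sites.append(
            Site(
                id=int(rec["site_id"]),
                cost=float(rec["cost"]),
                mu=float(rec["mu"]),
                perimeter=float(rec["perimeter"]),
                habitat=tuple(float(rec[c]) for c in hab_cols),
            )
        )
    known_ids = {s.id for s in sites}

    boundaries = SharedBoundaries()
    if adj_path.exists():
        adj = pd.read_csv(adj_path, float_precision="round_trip")
        missing = [c for c in ("site_a", "site_b", "shared_length") if c not in adj.columns]
        if missing:
            raise ValueError(f"adjacency.csv is missing required columns {missing}")
        for rec in adj.itertuples(index=False):
            a, b, length = int(rec.site_a), int(rec.site_b), float(rec.shared_length)
            for sid in (a, b):
                if sid not in known_ids:
                    raise ValueError(f"adjacency.csv references unknown site id {sid}")
            existing = boundaries.get(a, b)
            if existing and abs(existing - length) > 1e-9:
                raise ValueError(
                    f"conflicting shared lengths for pair ({a},{b}): "
                    f"{existing} vs {length}"
                )
            boundaries.set(a, b, length)

    landscape = Landscape(
        sites,
        boundaries=boundaries,
        targets=targets,
        blm=float(config.get("blm", 0.0)),
        spf=config.get("spf", 1e6),
        alpha=config.get("alpha"),
        initial_reserve=config.get("initial_reserve", ()),
    )
    budget = _budget_from_config(config["budget"]) if "budget" in config else None
    return landscape, budget


def write_weights(weights: WeightVector, path: str | Path) -> None:
    """Weights as a JSON list [lambda_1, ..., lambda_J, lambda_c]."""
    Path(path).write_text(json.dumps(list(weights.lambdas) + [weights.lambda_c]))


def read_weights(path: str | Path) -> WeightVector:
    vals = json.loads(Path(path).read_text())
    if not isinstance(vals, list) or len(vals) < 2:
        raise ValueError("weights file must be a JSON list [lambda_1..lambda_J, lambda_c]")
    return WeightVector(tuple(float(v) for v in vals[:-1]), float(vals[-1]))


def write_results(
    estimate: EECEstimate,
    rows: Iterable[Mapping],
    directory: str | Path,
) -> Path:
    """Per-scenario rows to ``results.csv``, summary stats to ``summary.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(list(rows)).to_csv(directory / "results.csv", index=False)
    summary = {
        "schema_version": SCHEMA_VERSION,
        "mean_eec": estimate.mean,
        "stderr": estimate.stderr,
        "n_scenarios": estimate.n_scenarios,
        "target_frequency": estimate.target_frequency,
        "mean_sites": estimate.mean_sites,
        "mean_boundary": estimate.mean_boundary,
        "mean_periods": estimate.mean_periods,
    }
    (directory / "summary.json").write_text(json.dumps(summary, indent=2))
    return directory


def write_geojson(landscape: Landscape, path: str | Path) -> None:
    """Optional polygon export (requires generator-attached geometry)."""
    from shapely.geometry import mapping

    geom = getattr(landscape, "geometry", None)
    if geom is None:
        raise ValueError("this landscape carries no polygon geometry")
    features = [
        {
            "type": "Feature",
            "geometry": mapping(geom.polygons[i]),
            "properties": {"site_id": landscape.ordered_ids[i]},
        }
        for i in range(geom.n)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
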