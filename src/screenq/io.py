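"""File formats: registry/life-table/population CSV, network and
scenario TOML, and run manifests.

CSV dialect is deliberately plain: UTF-8, comma separators, a required
header, ``.`` decimals.  Queue indices in network files are 1-based
(the convention used in display labels); they are converted to the
0-based internal indexing on read.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimation import LIFE_TABLE_COLUMNS, REGISTRY_COLUMNS
from .network import QueueNetwork, RoutingMatrix, ServiceSpec
from .screening import ScreeningScenario, SubgroupKey

__all__ = [
    "SchemaError",
    "read_registry",
    "write_registry",
    "read_life_table",
    "write_life_table",
    "read_population_table",
    "write_population_table",
    "read_network_toml",
    "read_scenario_toml",
    "write_manifest",
]


class SchemaError(ValueError):
    """A tabular input does not match its declared schema."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_registry(path) -> pd.DataFrame:
    """Read and type-check a registry CSV.

    Malformed rows are rejected with their (1-based, header-inclusive)
    line numbers; row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: empty registry")
    _check_columns(df, REGISTRY_COLUMNS, path)
    bad_lines = []
    surv = pd.to_numeric(df["survival_months"], errors="coerce")
    bad_lines += list(df.index[surv.isna() | (surv < 0)])
    bad_lines += list(df.index[~df["vital_status"].isin(["dead", "alive"])])
    treated = df["treated"].astype(bool)
    ttt = pd.to_numeric(df["months_to_treatment"], errors="coerce")
    bad_lines += list(df.index[~treated & ttt.notna()])
    if bad_lines:
        lines = sorted({int(i) + 2 for i in bad_lines})  # +2: header + 0-base
        raise SchemaError(f"{path}: malformed row(s) at line(s) {lines}")
    df["treated"] = treated
    df["survival_months"] = surv
    df["months_to_treatment"] = ttt
    return df


def write_registry(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_life_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, LIFE_TABLE_COLUMNS, path)
    if (df["expectancy_years"] <= 0).any():
        raise SchemaError(f"{path}: expectancies must be positive")
    return df


def write_life_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_population_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(
        df, ["cancer_type", "sex", "ancestry", "age_band", "population"], path
    )
    if (df["population"] <= 0).any():
        raise SchemaError(f"{path}: populations must be positive")
    return df


def write_population_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def population_lookup(df: pd.DataFrame, key: SubgroupKey) -> int:
    row = df[
        (df["cancer_type"] == key.cancer_type)
        & (df["sex"] == key.sex)
        & (df["ancestry"] == key.ancestry)
        & (df["age_band"] == key.age_band)
    ]
    if row.empty:
        raise KeyError(f"no population entry for {key}")
    return int(row["population"].iloc[0])


def _service_from_table(table: dict) -> ServiceSpec:
    family = table.get("family", "exponential")
    if family == "exponential":
        return ServiceSpec.exponential(table["mean"])
    if family == "deterministic":
        return ServiceSpec.deterministic(table.get("mean", table.get("value")))
    if family == "uniform":
        return ServiceSpec.uniform(table["low"], table["high"])
    if family == "lognormal":
        return ServiceSpec.lognormal(table["mean"], table["sigma_log"])
    if family == "empirical":
        return ServiceSpec.empirical(table["samples"])
    raise SchemaError(f"unsupported service family in network file: {family!r}")


def read_network_toml(path) -> QueueNetwork:
    """Load a network description file.

    Expected layout::

        eta = [10.0, 0.0]                 # arrivals per month
        [[queue]]
        label = "diagnosed, awaiting surgery"
        family = "lognormal"
        mean = 6.0
        sigma_log = 1.0
        [[route]]                          # 1-based queue indices
        from = 1
        to = 2
        p = 0.4
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    queues = doc.get("queue", [])
    if not queues:
        raise SchemaError(f"{path}: no [[queue]] tables")
    J = len(queues)
    eta = np.asarray(doc.get("eta", [0.0] * J), dtype=float)
    R = np.zeros((J, J))
    for route in doc.get("route", []):
        i, j = int(route["from"]) - 1, int(route["to"]) - 1
        if not (0 <= i < J and 0 <= j < J):
            raise SchemaError(f"{path}: route ({route['from']}->{route['to']}) out of range")
        R[i, j] = float(route["p"])
    services = tuple(_service_from_table(q) for q in queues)
    labels = tuple(q.get("label", f"queue {k + 1}") for k, q in enumerate(queues))
    return QueueNetwork(
        routing=RoutingMatrix(R), exogenous_rates=eta, services=services, labels=labels
    )


def read_scenario_toml(path) -> ScreeningScenario:
    """Load a screening-scenario file (flat key/value TOML)."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    known = {
        "detection_prob",
        "effectiveness",
        "qaly_factor",
        "mortality_prob",
        "mortality_survival",
        "false_positive_rate",
        "confirmatory_specificity",
        "fp_survival_reduction",
        "screens_per_person_year",
    }
    extra = set(doc) - known
    if extra:
        raise SchemaError(f"{path}: unknown scenario key(s) {sorted(extra)}")
    if "detection_prob" not in doc or "effectiveness" not in doc:
        raise SchemaError(f"{path}: detection_prob and effectiveness are required")
    return ScreeningScenario(**doc)


def write_manifest(out_dir, command: str, inputs: dict, config: dict, seed=None) -> Path:
    """Write a machine-readable run manifest enabling exact reruns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "tool": "screenq",
        "version": __version__,
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": seed,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
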