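"""File formats, run configuration and dispatch.

Family data travel as a tidy CSV with one row per family and an explicit
``structure`` column; an empty cell means the variable is not observed for
that structure (never imputed).  Covariance blocks travel as JSON at full
double precision.  Every dispatched run writes a manifest (config hash,
seed, package versions) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .family_simulator import SimulatedGroup, sample_covariance
from .ml_fitting import GroupData
from .path_model import ModelParams, structure_roster

__all__ = [
    "FAMILY_TABLE_COLUMNS",
    "ConfigError",
    "read_family_table",
    "write_family_table",
    "read_covblocks",
    "write_covblocks",
    "validate_config",
    "run",
]

logger = logging.getLogger("adoptsem")

#: Canonical family-table columns.  Zp_b and Zp_a are never observed in any
#: structure, so they only appear (as *_latent) in full oracle dumps.
FAMILY_TABLE_COLUMNS = (
    "family_id",
    "structure",
    "Zm",
    "Zp",
    "Zo",
    "Zm_b",
    "Zm_a",
    "Zp_b_latent",
    "Zp_a_latent",
    "Y",
)

_GENOTYPE_COLUMNS = ("Zm", "Zp", "Zo", "Zm_b", "Zm_a")


class ConfigError(ValueError):
    """Invalid run configuration."""


# ---------------------------------------------------------------------------
# Family tables (CSV)
# ---------------------------------------------------------------------------

def write_family_table(
    groups: Sequence[SimulatedGroup],
    path: str | Path,
    as_analyzed: bool = True,
) -> None:
    """Write simulated groups as one tidy CSV.

    With ``as_analyzed`` (the fit input dialect) only each structure's
    observed variables are filled.  Otherwise every generated variable is
    written (latent founders included, Zp_b/Zp_a under their *_latent
    columns) together with a sidecar ``<path>.latent.json`` mask.
    """
    path = Path(path)
    frames = []
    latent_mask: dict[str, list[str]] = {}
    offset = 0
    for group in groups:
        cols: dict[str, object] = {
            "family_id": np.arange(offset, offset + group.n),
            "structure": group.label,
        }
        for name in FAMILY_TABLE_COLUMNS[2:]:
            cols[name] = np.full(group.n, np.nan)
        out = pd.DataFrame(cols)
        offset += group.n
        observed = group.structure.observed_vars
        columns = observed if as_analyzed else [
            c for c in group.data.columns if c != "related"
        ]
        for col in columns:
            target = col + "_latent" if col in ("Zp_b", "Zp_a") else col
            out[target] = group.data[col].to_numpy()
        if not as_analyzed:
            latent_mask[group.label] = [
                c + "_latent" if c in ("Zp_b", "Zp_a") else c
                for c in group.latent_columns
                if c != "related"
            ]
        frames.append(out)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, index=False)
    if not as_analyzed:
        with open(f"{path}.latent.json", "w") as fh:
            json.dump(latent_mask, fh, indent=1)


def read_family_table(path: str | Path) -> tuple[list[GroupData], dict[str, int]]:
    """Read an as-analyzed family CSV into per-structure sample covariances.

    Validates that each structure's rows observe exactly the roster's
    variables; returns the group data and per-structure row counts.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    required = {"family_id", "structure", "Y"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"family table is missing required columns: {sorted(missing)}")
    groups: list[GroupData] = []
    counts: dict[str, int] = {}
    for code, rows in table.groupby("structure", sort=False):
        roster = structure_roster(str(code))  # raises on unknown code
        observed = roster.observed_vars
        for col in observed:
            if col not in rows.columns or rows[col].isna().any():
                raise ValueError(
                    f"{code}: column {col!r} must be observed for every row "
                    f"(roster: {observed})"
                )
        for col in _GENOTYPE_COLUMNS:
            if col not in observed and col in rows.columns and rows[col].notna().any():
                raise ValueError(
                    f"{code}: column {col!r} holds values but is not in the "
                    f"roster {observed}"
                )
        counts[str(code)] = len(rows)
        block = sample_covariance(rows[list(observed)], as_analyzed=False)
        groups.append(GroupData(str(code), block))
    if not groups:
        raise ValueError("family table holds no rows")
    return groups, counts


# ---------------------------------------------------------------------------
# Covariance blocks (JSON)
# ---------------------------------------------------------------------------

def write_covblocks(groups: Sequence[GroupData], path: str | Path) -> None:
    """Serialize group covariance blocks as JSON (full double precision)."""
    payload = [g.to_dict() for g in groups]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_covblocks(path: str | Path) -> list[GroupData]:
    with open(path) as fh:
        payload = json.load(fh)
    return [GroupData.from_dict(d) for d in payload]


# ---------------------------------------------------------------------------
# Run configuration and dispatch
# ---------------------------------------------------------------------------

_COMMON_KEYS = {"params", "sizes", "alpha", "seed", "verbosity"}
_SCHEMAS: dict[str, dict[str, set]] = {
    "power": {
        "required": {"params", "sizes", "constraint"},
        "optional": _COMMON_KEYS | {"grid", "unit_variance"},
    },
    "simulate": {
        "required": {"params", "sizes"},
        "optional": _COMMON_KEYS | {"as_analyzed"},
    },
    "study": {
        "required": {"kind", "params", "sizes"},
        "optional": _COMMON_KEYS
        | {
            "constraint",
            "reps",
            "scenario",
            "relationship",
            "fractions",
            "model_r",
            "full_scale",
            "wald",
        },
    },
    "fit": {
        "required": set(),
        "optional": _COMMON_KEYS | {"data", "cov", "reduced", "fixed"},
    },
}


def validate_config(config: Mapping, command: str) -> dict:
    """Schema-check a run configuration; unknown keys are rejected."""
    if command not in _SCHEMAS:
        raise ConfigError(f"unknown command {command!r}")
    if not isinstance(config, Mapping):
        raise ConfigError("configuration must be a mapping")
    schema = _SCHEMAS[command]
    keys = set(config)
    unknown = keys - schema["required"] - schema["optional"]
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    missing = schema["required"] - keys
    if missing:
        raise ConfigError(f"missing required configuration keys: {sorted(missing)}")
    cfg = dict(config)
    if "params" in cfg:
        try:
            cfg["params"] = ModelParams.from_dict(cfg["params"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid params block: {exc}") from exc
    if "sizes" in cfg:
        if not isinstance(cfg["sizes"], Mapping):
            raise ConfigError("sizes must map structure codes to counts")
        cfg["sizes"] = {str(k): int(v) for k, v in cfg["sizes"].items()}
    if "constraint" in cfg and isinstance(cfg["constraint"], str):
        cfg["constraint"] = [cfg["constraint"]]
    cfg.setdefault("alpha", 0.05)
    cfg.setdefault("seed", 0)
    return cfg


def _manifest(command: str, config: Mapping, seed: int) -> dict:
    canonical = json.dumps(
        {k: v.as_dict() if isinstance(v, ModelParams) else v for k, v in sorted(config.items())},
        sort_keys=True,
        default=str,
    )
    import pandas
    import scipy

    return {
        "command": command,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "adoptsem": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }


def _setup_logging(out_dir: Path, verbosity: int = 0) -> None:
    level = logging.DEBUG if verbosity else logging.INFO
    logger.setLevel(level)
    have = {type(h) for h in logger.handlers}
    if logging.StreamHandler not in have:
        logger.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def run(command: str, config: Mapping, out_dir: str | Path) -> dict:
    """Dispatch a validated configuration to the library and write artifacts.

    Returns a summary dict (also written as JSON in ``out_dir``).
    """
    from . import misspecification_studies as studies
    from . import power_analysis as pa
    from .family_simulator import simulate_dataset

    cfg = validate_config(config, command)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir, cfg.get("verbosity", 0))
    seed = int(cfg.get("seed", 0))
    manifest = _manifest(command, cfg, seed)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("run %s (config %s)", command, manifest["config_sha256"][:12])

    summary: dict
    if command == "power":
        params = cfg["params"]
        constraint = list(cfg["constraint"])
        if cfg.get("grid"):
            table = pa.power_grid(
                params, cfg["sizes"], cfg["grid"], constraint, cfg["alpha"],
                unit_variance=bool(cfg.get("unit_variance", True)), seed=seed,
            )
            table.to_csv(out_dir / "power_grid.csv", index=False)
            summary = {"rows": len(table), "table": "power_grid.csv"}
        else:
            res = pa.asymptotic_power(params, cfg["sizes"], constraint, cfg["alpha"], seed=seed)
            summary = {
                "ncp": res.ncp, "df": res.df, "alpha": res.alpha, "power": res.power,
            }
    elif command == "simulate":
        groups = simulate_dataset(cfg["params"], cfg["sizes"], seed=seed)
        write_family_table(groups, out_dir / "families.csv",
                           as_analyzed=bool(cfg.get("as_analyzed", True)))
        summary = {"groups": {g.label: g.n for g in groups}, "table": "families.csv"}
    elif command == "study":
        summary = _run_study(cfg, out_dir, seed, studies)
    else:
        raise ConfigError(f"command {command!r} is not dispatchable via run()")

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary


def _run_study(cfg: Mapping, out_dir: Path, seed: int, studies) -> dict:
    kind = cfg["kind"]
    params: ModelParams = cfg["params"]
    sizes = dict(cfg["sizes"])
    reps = int(cfg.get("reps", 200))
    if not cfg.get("full_scale", False):
        # scaled-down default: a tenth of each group, capped replicate count
        sizes = {c: max(int(round(n / 10)), 5) for c, n in sizes.items()}
        reps = min(reps, 200)
    constraint = tuple(cfg.get("constraint", ["gamma_m"]))
    alpha = float(cfg["alpha"])
    if kind == "type1":
        res = studies.type1_error_study(params, sizes, constraint, alpha, reps, seed,
                                        wald=bool(cfg.get("wald", True)))
    elif kind == "power":
        res = studies.empirical_power_study(params, sizes, constraint, alpha, reps, seed,
                                            wald=bool(cfg.get("wald", False)))
    elif kind == "misspec":
        res = studies.misspec_bias_study(
            params, sizes,
            scenario=cfg["scenario"],
            relationship=cfg.get("relationship", "sibling"),
            fractions=tuple(cfg.get("fractions", (0.0, 0.2, 0.4, 0.6, 0.8))),
            reps=reps, seed=seed,
            model_r=bool(cfg.get("model_r", False)),
            alpha=alpha, constraint=constraint,
        )
    else:
        raise ConfigError(f"unknown study kind {kind!r}")
    res.table.to_csv(out_dir / f"study_{kind}.csv", index=False)
    summary = {
        "kind": kind,
        "table": f"study_{kind}.csv",
        "flagged": res.flagged,
        "meta": {k: v for k, v in res.meta.items() if not isinstance(v, np.ndarray)},
    }
    return summary
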