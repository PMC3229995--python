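"""File formats and run configuration.

Point clouds travel as CSV with the mandatory header
``x_mm,y_mm,z_mm,label,scan_id`` (comma separated, period decimal,
UTF-8); results are written as JSON with deterministic key order,
full-precision floats plus display fields rounded the way wear results
are conventionally reported (mm to 2 decimal places, degrees to whole
degrees; ties round half-to-even).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from .geometry import VALID_LABELS, PointCloud
from .pipeline import DEFAULT_DENSITY_MG_MM3, ScanData, WearResult
from .stats import AgreementSummary

__all__ = [
    "RunConfig",
    "ParseError",
    "read_point_clouds",
    "write_point_clouds",
    "scan_data_from_clouds",
    "write_result",
    "read_result",
]

logger = logging.getLogger("cupwear")

_REQUIRED_COLUMNS = ("x_mm", "y_mm", "z_mm", "label", "scan_id")


class ParseError(ValueError):
    """Raised for malformed input files; message carries the line number."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Defaults shared across the pipelines.

    ``filter_threshold`` is the artifact-elimination distance (mm);
    ``density`` the cup material density (mg/mm^3) for gravimetric
    conversion; ``max_fit_iterations`` bounds the eliminate-and-refit
    loop; ``flip_worn_side`` swaps the worn-hemisphere convention for
    left-sided cups.
    """

    filter_threshold: float = 0.5
    density: float = DEFAULT_DENSITY_MG_MM3
    max_fit_iterations: int = 10
    flip_worn_side: bool = False
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.filter_threshold <= 0:
            raise ValueError("filter threshold must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.max_fit_iterations < 1:
            raise ValueError("need at least one fit iteration")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def read_point_clouds(path: str | Path) -> list[PointCloud]:
    """Read labelled point clouds from CSV, grouped by (scan_id, label).

    Row order within each cloud follows file order. Raises
    :class:`ParseError` naming the offending line for missing columns,
    non-numeric coordinates or unknown surface labels. An empty file
    (header only) yields an empty list with a logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise ParseError(f"{path}: cannot read CSV ({exc})") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}, line 1: missing columns {missing}")
    if len(df) == 0:
        logger.warning("%s: no data rows, returning empty collection", path)
        return []
    coords = np.empty((len(df), 3), dtype=float)
    for j, col in enumerate(("x_mm", "y_mm", "z_mm")):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # + header + 1-based
            raise ParseError(
                f"{path}, line {line}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col}"
            )
        # parse through numpy for correctly-rounded (bit-exact) floats
        coords[:, j] = df[col].to_numpy(dtype="U32").astype(float)
    labels = df["label"].astype(str)
    bad_label = ~labels.isin(VALID_LABELS)
    if bad_label.any():
        line = int(bad_label.idxmax()) + 2
        raise ParseError(
            f"{path}, line {line}: unknown label {labels[bad_label.idxmax()]!r}; "
            f"expected one of {sorted(VALID_LABELS)}"
        )
    clouds: list[PointCloud] = []
    keys = df[["scan_id", "label"]].astype(str)
    for (scan_id, label), idx in keys.groupby(
        ["scan_id", "label"], sort=False
    ).groups.items():
        order = np.sort(np.asarray(idx))
        clouds.append(PointCloud(coords[order], str(label), str(scan_id)))
    return clouds


def write_point_clouds(clouds: Iterable[PointCloud], path: str | Path) -> None:
    """Write clouds to CSV at full precision (round-trips bitwise)."""
    frames = []
    for cloud in clouds:
        frames.append(
            pd.DataFrame(
                {
                    "x_mm": cloud.points[:, 0],
                    "y_mm": cloud.points[:, 1],
                    "z_mm": cloud.points[:, 2],
                    "label": cloud.label,
                    "scan_id": cloud.scan_id,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(_REQUIRED_COLUMNS)
    )
    # repr-format floats: shortest string that round-trips binary64
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def scan_data_from_clouds(
    clouds: Iterable[PointCloud], scan_id: str
) -> ScanData:
    """Assemble one scan's ScanData from a cloud collection."""
    by_label = {c.label: c for c in clouds if c.scan_id == scan_id}
    required = ("cup_outer", "head", "plane1", "plane2")
    missing = [lab for lab in required if lab not in by_label]
    if missing:
        raise ParseError(
            f"scan {scan_id!r}: missing surface clouds {missing}"
        )
    return ScanData(
        cup_outer=by_label["cup_outer"],
        head=by_label["head"],
        plane1=by_label["plane1"],
        plane2=by_label["plane2"],
        cup_inner=by_label.get("cup_inner"),
        scan_id=scan_id,
    )


def _round_display(value: float, ndigits: int) -> float:
    """Round for display (banker's rounding, matching Python round)."""
    return round(float(value), ndigits)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def result_to_dict(result: WearResult | AgreementSummary) -> dict[str, Any]:
    """JSON-ready dictionary with full-precision and display fields."""
    if isinstance(result, WearResult):
        return {
            "kind": "wear",
            "method": result.method,
            "linear_wear_mm": float(result.linear_wear),
            "wear_vector_mm": result.wear_vector.tolist(),
            "theta_deg": float(result.theta),
            "phi_deg": float(result.phi),
            "angles_defined": bool(result.angles_defined),
            "display": {
                "linear_wear_mm": _round_display(result.linear_wear, 2),
                "theta_deg": int(_round_display(result.theta, 0)),
                "phi_deg": int(_round_display(result.phi, 0)),
            },
            "diagnostics": _jsonable(result.diagnostics),
        }
    if isinstance(result, AgreementSummary):
        return {
            "kind": "agreement",
            "n": result.n,
            "mean_difference": float(result.mean_difference),
            "sd_difference": float(result.sd_difference),
            "loa_low": float(result.loa_low),
            "loa_high": float(result.loa_high),
            "bias_ci_low": float(result.bias_ci_low),
            "bias_ci_high": float(result.bias_ci_high),
            "repeatability": result.repeatability,
            "accuracy": result.accuracy,
            "display": {
                "mean_difference": _round_display(result.mean_difference, 2),
                "loa_low": _round_display(result.loa_low, 2),
                "loa_high": _round_display(result.loa_high, 2),
            },
        }
    raise TypeError(f"cannot serialise {type(result).__name__}")


def write_result(result: WearResult | AgreementSummary, path: str | Path) -> None:
    """Write a result as JSON with deterministic key order."""
    payload = result_to_dict(result)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_result(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
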