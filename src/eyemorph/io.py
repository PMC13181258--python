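"""Readers and writers for the pipeline's CSV/TSV/JSON formats.

All tables are comma-separated UTF-8 with a mandatory header row (a two-column
header-less XY dialect is accepted for cast centers via ``no_header=True``).
Comma decimals are rejected with a pointed error.  Written tables carry a
provenance comment header (version, seed, config hash) that readers skip.
"""
from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .types import CurvatureRecord, EyeCast, SpecimenRecord


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


@dataclass
class RunConfig:
    """Settings shared across pipeline stages, loadable from a YAML file.

    All numeric settings must be positive and ``alpha`` must lie in (0, 1).
    """

    bin_width_um: float = 2.0
    delaunay_prune_factor: float = 1.5
    alpha: float = 0.05
    seed: int = 20180501
    out_dir: str = "results"
    log_level: str = "warning"

    def __post_init__(self) -> None:
        if not self.bin_width_um > 0:
            raise ValueError("bin_width_um must be > 0")
        if not self.delaunay_prune_factor > 0:
            raise ValueError("delaunay_prune_factor must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a YAML mapping")
        unknown = set(raw) - {f.name for f in fields(cls)}
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
        try:
            return cls(**raw)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


_CAST_CENTER_COLS = ["x_mm", "y_mm"]
_OUTLINE_COLS = ["x_mm", "y_mm"]
_SPECIMEN_REQUIRED = ["specimen_id", "group", "head_width_mm"]
_SPECIMEN_OPTIONAL = [
    "head_height_mm", "eye_height_mm", "it_span_mm", "mass_g",
    "n_ommatidia", "dphi_x_deg", "dphi_y_deg",
]
_CURVATURE_COLS = ["specimen_id", "group", "axis", "a_deg", "b_mm", "D_um"]


def provenance_header(seed: Optional[int] = None, config: Optional[dict] = None) -> str:
    cfg = json.dumps(config or {}, sort_keys=True)
    digest = hashlib.sha256(cfg.encode()).hexdigest()[:12]
    parts = [f"# eyemorph v{__version__}", f"# config_sha256={digest}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    return "\n".join(parts) + "\n"


def write_table(
    df: pd.DataFrame,
    path,
    sep: str = ",",
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    """Write a DataFrame with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(provenance_header(seed, config))
        df.to_csv(fh, sep=sep, index=False)


def _read_csv(path, sep: str = ",", header: bool = True) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep=sep, comment="#", header=0 if header else None,
            skip_blank_lines=True,
        )
    except Exception as exc:  # noqa: BLE001 - rewrap for the CLI
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    return df


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _require_numeric(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    for c in cols:
        if df[c].dtype == object:
            sample = df[c].astype(str).head(20).str.contains(",").any()
            if sample:
                raise SchemaError(
                    f"{path}: column {c!r} contains comma decimals; use '.' as the"
                    " decimal separator"
                )
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {c!r} is not numeric: {exc}") from exc
    return df


def read_cast(
    centers_path,
    outline_path,
    specimen_id: str = "",
    group: str = "",
    no_header: bool = False,
) -> EyeCast:
    """Read facet centers and an outline polygon into an :class:`EyeCast`.

    ``no_header=True`` accepts a bare two-column XY export for the centers.
    """
    if no_header:
        centers = _read_csv(centers_path, header=False)
        if centers.shape[1] < 2:
            raise SchemaError(f"{centers_path}: expected two columns of XY coordinates")
        centers = centers.iloc[:, :2]
        centers.columns = _CAST_CENTER_COLS
    else:
        centers = _read_csv(centers_path)
        _require_columns(centers, _CAST_CENTER_COLS, centers_path)
    centers = _require_numeric(centers, _CAST_CENTER_COLS, centers_path)

    outline = _read_csv(outline_path)
    _require_columns(outline, _OUTLINE_COLS, outline_path)
    outline = _require_numeric(outline, _OUTLINE_COLS, outline_path)
    if not specimen_id:
        specimen_id = Path(centers_path).stem
    return EyeCast(
        specimen_id=specimen_id,
        group=group or "unknown",
        centers=centers[_CAST_CENTER_COLS].to_numpy(),
        outline=outline[_OUTLINE_COLS].to_numpy(),
    )


def write_cast(
    cast: EyeCast,
    centers_path,
    outline_path,
    true_diam_um: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    params: Optional[dict] = None,
) -> None:
    """Write a cast as centers + outline CSVs (plus a JSON param sidecar)."""
    centers = pd.DataFrame(cast.centers, columns=_CAST_CENTER_COLS)
    if true_diam_um is not None:
        centers["true_diam_um"] = true_diam_um
    write_table(centers, centers_path, seed=seed, config=params)
    outline = pd.DataFrame(cast.outline, columns=_OUTLINE_COLS)
    write_table(outline, outline_path, seed=seed, config=params)
    if params is not None:
        sidecar = Path(str(centers_path)).with_suffix(".params.json")
        sidecar.write_text(json.dumps(params, indent=2, sort_keys=True) + "\n")


def read_specimens(path) -> pd.DataFrame:
    """Read a specimen morphometrics table; validates schema and types."""
    df = _read_csv(path)
    _require_columns(df, _SPECIMEN_REQUIRED, path)
    numeric = ["head_width_mm"] + [c for c in _SPECIMEN_OPTIONAL if c in df.columns]
    df = _require_numeric(df, numeric, path)
    bad = df["head_width_mm"] <= 0
    if bad.any():
        raise SchemaError(f"{path}: non-positive head_width_mm in rows {list(df.index[bad])}")
    return df


def specimen_records(df: pd.DataFrame) -> list[SpecimenRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                group=str(row["group"]),
                head_width_mm=float(row["head_width_mm"]),
                head_height_mm=float(row.get("head_height_mm", np.nan)),
                eye_height_mm=float(row.get("eye_height_mm", np.nan)),
                it_span_mm=float(row.get("it_span_mm", np.nan)),
                mass_g=float(row.get("mass_g", np.nan)),
                n_ommatidia=(
                    int(row["n_ommatidia"])
                    if "n_ommatidia" in row and np.isfinite(row["n_ommatidia"])
                    else None
                ),
                dphi_x_deg=float(row.get("dphi_x_deg", np.nan)),
                dphi_y_deg=float(row.get("dphi_y_deg", np.nan)),
            )
        )
    return records


def read_curvature(path) -> list[CurvatureRecord]:
    """Read local-curvature measurement records (one row per specimen x axis)."""
    df = _read_csv(path)
    _require_columns(df, _CURVATURE_COLS, path)
    df = _require_numeric(df, ["a_deg", "b_mm", "D_um"], path)
    records = []
    for _, row in df.iterrows():
        axis = str(row["axis"]).strip().lower()
        if axis not in ("x", "y"):
            raise SchemaError(f"{path}: axis must be 'x' or 'y', got {row['axis']!r}")
        records.append(
            CurvatureRecord(
                axis=axis,
                a_deg=float(row["a_deg"]),
                b_mm=float(row["b_mm"]),
                D_um=float(row["D_um"]),
                specimen_id=str(row["specimen_id"]),
                group=str(row["group"]),
                measurement_site=str(row.get("measurement_site", "")),
            )
        )
    return records


def curvature_table(records: Sequence[CurvatureRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])[
        ["specimen_id", "group", "axis", "a_deg", "b_mm", "D_um", "measurement_site"]
    ]
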