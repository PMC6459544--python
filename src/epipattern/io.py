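"""CSV/JSON readers and writers, pipeline configuration, and the run manifest.

All tables are RFC-4180 CSV, UTF-8, '.' decimal separator.  Boolean marker
flags are written as 0/1 but a tolerant set of spellings (``TRUE``/``FALSE``,
``True``/``False``, ``T``/``F``, ``yes``/``no``) is accepted on read and
normalized on rewrite.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geometry import EmbryoGeometry, make_geometry
from .patterns import AnalysisConfig
from .synthetic import (
    CELL_COLUMNS,
    GEOMETRY_COLUMNS,
    CohortConfig,
    ConditionPreset,
    default_presets,
)

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_geometry_table",
    "write_geometry_table",
    "PipelineConfig",
    "config_hash",
]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}

_FLOAT_COLUMNS = ("x_um", "y_um", "diameter_um")
_FLAG_COLUMNS = ("p63", "dlc", "brdu")


def _parse_flag(raw: str, column: str, line: int) -> bool:
    v = str(raw).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise SchemaError(f"line {line}: cannot parse {column}={raw!r} as a flag")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cell table CSV.

    Raises :class:`SchemaError` naming the offending column or line for a
    missing column, an unparsable coordinate/diameter or flag, or a
    duplicated (embryo_id, cell_id) pair.  Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    df = df[CELL_COLUMNS].copy()
    # data lines start at 2 (line 1 is the header)
    for col in _FLOAT_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if len(bad):
            i = int(bad[0])
            raise SchemaError(
                f"{path.name} line {i + 2}: non-numeric {col}={df[col].iloc[i]!r}"
            )
        df[col] = vals.astype(float)
    for col in _FLAG_COLUMNS:
        df[col] = [
            _parse_flag(v, col, i + 2) for i, v in enumerate(df[col].tolist())
        ]
        df[col] = df[col].astype(bool)
    dup = df.duplicated(subset=["embryo_id", "cell_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(
            f"{path.name} line {i + 2}: duplicate (embryo_id, cell_id) "
            f"({df['embryo_id'].iloc[i]!r}, {df['cell_id'].iloc[i]!r})"
        )
    try:
        df["cell_id"] = pd.to_numeric(df["cell_id"]).astype(int)
    except (ValueError, TypeError):
        pass  # non-numeric cell ids are allowed
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table with flags normalized to 0/1."""
    out = cells[CELL_COLUMNS].copy()
    for col in _FLAG_COLUMNS:
        out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, index=False, lineterminator="\n")


def read_geometry_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a geometry table CSV (one row per embryo)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in GEOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    df = df[GEOMETRY_COLUMNS].copy()
    if df["embryo_id"].duplicated().any():
        raise SchemaError(f"{path.name}: duplicate embryo_id")
    for col in GEOMETRY_COLUMNS[1:]:
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise SchemaError(f"{path.name}: non-numeric value in {col}")
    return df


def write_geometry_table(geometries: pd.DataFrame, path: str | Path) -> None:
    geometries[GEOMETRY_COLUMNS].to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for a full simulate -> analyze -> compare run.

    Round-trips losslessly through JSON; unknown keys are rejected.
    """

    presets: tuple[ConditionPreset, ...] = field(
        default_factory=lambda: tuple(default_presets())
    )
    n_embryos_per_condition: int = 20
    seed: int = 0
    radius_um: float = 400.0
    sector_center_rad: float = -math.pi / 2.0
    sector_halfwidth_rad: float = 1.6875
    central_fraction: float = 0.40
    pair_threshold: float = 1.25
    diameter_estimator: str = "recorded"
    diameter_scope: str = "dlc"
    reference: str = "wt"
    tests: tuple[str, ...] = ("het", "hom", "mo", "oe")
    log_level: str = "INFO"

    def geometry(self) -> EmbryoGeometry:
        return make_geometry(
            self.radius_um, self.sector_center_rad, self.sector_halfwidth_rad
        )

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            presets=list(self.presets),
            n_embryos_per_condition=self.n_embryos_per_condition,
            seed=self.seed,
            geometry=self.geometry(),
        )

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            central_fraction=self.central_fraction,
            pair_threshold=self.pair_threshold,
            diameter_estimator=self.diameter_estimator,
            diameter_scope=self.diameter_scope,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["presets"] = [p.to_dict() for p in self.presets]
        d["tests"] = list(self.tests)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "presets" in d:
            d["presets"] = tuple(
                ConditionPreset.from_dict(p) for p in d["presets"]
            )
        if "tests" in d:
            d["tests"] = tuple(d["tests"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = json.loads(Path(path).read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(data, dict):
            raise SchemaError(f"{path}: config must be a JSON object")
        return cls.from_dict(data)


def config_hash(config: PipelineConfig) -> str:
    """Stable SHA-256 over the canonical JSON form of the config."""
    canon = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()
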