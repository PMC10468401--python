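"""Reading, writing and validation of localization tables and configuration.

Localization tables are plain delimited text (comma by default) with a
header row.  Required columns: ``trace_id, x_nm, y_nm, z_nm``.  Optional
columns: per-axis uncertainties ``sigma_x_nm, sigma_y_nm, sigma_z_nm``, a
``truth_id`` provenance column (synthetic data) and a time index ``t``.
All coordinates are absolute nanometres in a right-handed frame with z up
from the coverslip.

The instrument's ``.mat`` export is a proprietary dialect and is
not read here; :func:`mat_export_field_names` documents the expected field
mapping for anyone writing a converter.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "PipelineConfig",
    "read_localizations",
    "write_localizations",
    "validate_localizations",
    "load_config",
    "write_trimers",
    "mat_export_field_names",
]

REQUIRED_COLUMNS = ("trace_id", "x_nm", "y_nm", "z_nm")
OPTIONAL_COLUMNS = ("sigma_x_nm", "sigma_y_nm", "sigma_z_nm", "truth_id", "t")

#: Documented float format for round-trip-stable tables (3 decimal places,
#: i.e. picometre resolution — far below any localization error).
FLOAT_FORMAT = "%.3f"


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the trimer-identification pipeline.

    Defaults follow the reference protocol: traces with per-axis s.d. above
    10 nm or fewer than 3 localizations are dropped; localizations are
    clustered with DBSCAN at eps 30 nm / minpts 5 then again at eps 6.5 nm
    (the middle of the stated 6-7 nm range) / minpts 5; the Gaussian
    mixture is initialized at sigma 5 nm; fluorophore centres are clustered
    into trimers at eps 100 nm / minpts 3 with a 6-50 nm neighbour window
    (5-60 nm in the alternate variant used for strongly expanded
    conditions), a 100 nm isolation radius and a 120 degree maximum vertex
    angle.  ``z_range`` of None means "derive from the data" (5th-95th
    percentile of localization z).
    """

    max_trace_sd: float = 10.0
    min_locs_per_trace: int = 3
    dbscan1_eps: float = 30.0
    dbscan1_minpts: int = 5
    dbscan2_eps: float = 6.5
    dbscan2_minpts: int = 5
    gmm_init_sigma: float = 5.0
    trimer_eps: float = 100.0
    trimer_minpts: int = 3
    nn_min: float = 6.0
    nn_max: float = 50.0
    nn_min_alt: float = 5.0
    nn_max_alt: float = 60.0
    isolation: float = 100.0
    z_range: tuple[float, float] | None = None
    max_vertex_angle: float = 120.0

    def __post_init__(self) -> None:
        positive = (
            "max_trace_sd",
            "dbscan1_eps",
            "dbscan2_eps",
            "gmm_init_sigma",
            "trimer_eps",
            "isolation",
            "max_vertex_angle",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("min_locs_per_trace", "dbscan1_minpts", "dbscan2_minpts", "trimer_minpts"):
            if not getattr(self, name) >= 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0 < self.nn_min < self.nn_max:
            raise ConfigError(
                f"require 0 < nn_min < nn_max, got nn_min={self.nn_min}, nn_max={self.nn_max}"
            )
        if not 0 < self.nn_min_alt < self.nn_max_alt:
            raise ConfigError(
                "require 0 < nn_min_alt < nn_max_alt, got "
                f"nn_min_alt={self.nn_min_alt}, nn_max_alt={self.nn_max_alt}"
            )
        if self.z_range is not None:
            if len(self.z_range) != 2 or not self.z_range[0] < self.z_range[1]:
                raise ConfigError(
                    f"z_range must be (min, max) with min < max, got {self.z_range}"
                )

    def nn_window(self, variant: str = "standard") -> tuple[float, float]:
        """Neighbour-distance window for a variant ('standard' or 'alt')."""
        if variant == "standard":
            return (self.nn_min, self.nn_max)
        if variant == "alt":
            return (self.nn_min_alt, self.nn_max_alt)
        raise ConfigError(f"unknown nn variant {variant!r}; expected 'standard' or 'alt'")


def validate_localizations(table: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Validate a localization table in place and return it.

    Raises :class:`SchemaError` naming missing columns, or listing the file
    line numbers (header = line 1) of rows with non-finite coordinates or
    empty trace ids.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {', '.join(missing)}")
    coords = table[["x_nm", "y_nm", "z_nm"]].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(coords.to_numpy(dtype=float)).all(axis=1)
    empty_trace = table["trace_id"].isna() | (table["trace_id"].astype(str).str.len() == 0)
    offenders = np.flatnonzero(bad | empty_trace.to_numpy())
    if offenders.size:
        lines = ", ".join(str(i + 2) for i in offenders[:20])
        more = "" if offenders.size <= 20 else f" (+{offenders.size - 20} more)"
        raise SchemaError(
            f"{source}: {offenders.size} malformed row(s) — non-finite coordinate "
            f"or empty trace_id at line(s) {lines}{more}"
        )
    table[["x_nm", "y_nm", "z_nm"]] = coords
    table["trace_id"] = table["trace_id"].astype(str)
    return table


def read_localizations(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate a delimited localization table.

    Row order is preserved.  Non-finite coordinates are reported with their
    file line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file")
    table = pd.read_csv(path, sep=delimiter)
    return validate_localizations(table, source=str(path))


def write_localizations(table: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a localization table under the documented float format."""
    table.to_csv(path, sep=delimiter, index=False, float_format=FLOAT_FORMAT)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a pipeline configuration from a YAML ``key: value`` file.

    Unspecified keys take the defaults of :class:`PipelineConfig`; unknown
    keys and out-of-range values raise :class:`ConfigError` naming the key.
    ``path`` of None yields the all-defaults configuration.
    """
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of key: value pairs")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {', '.join(sorted(unknown))}")
    if "z_range" in raw and raw["z_range"] is not None:
        raw["z_range"] = tuple(float(v) for v in raw["z_range"])
    for key, value in raw.items():
        if key != "z_range" and not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: {key} must be numeric, got {value!r}")
        if key != "z_range" and not math.isfinite(float(value)):
            raise ConfigError(f"{path}: {key} must be finite")
    return PipelineConfig(**raw)


def write_trimers(trimers, path: str | Path) -> pd.DataFrame:
    """Write identified trimers to CSV and return the frame written.

    Columns: per-fluorophore centres/sigmas/localization counts
    (``f<k>_{x,y,z,sx,sy,sz,n}``), the three pairwise distances
    ``d01, d02, d12``, ``mean_d``, vertex ``angle0..2``, ``circumradius``,
    ``area`` and the provenance ``truth_id`` when known.
    """
    rows = []
    for t in trimers:
        row: dict[str, object] = {}
        for k, f in enumerate(t.fluors):
            row[f"f{k}_x"], row[f"f{k}_y"], row[f"f{k}_z"] = f.centre
            row[f"f{k}_sx"], row[f"f{k}_sy"], row[f"f{k}_sz"] = f.sigma
            row[f"f{k}_n"] = f.n_localizations
        row["d01"], row["d02"], row["d12"] = t.pairwise_d
        row["mean_d"] = t.mean_d
        row["angle0"], row["angle1"], row["angle2"] = t.angles
        row["circumradius"] = t.circumradius
        row["area"] = t.area
        row["truth_id"] = t.truth_id if t.truth_id is not None else ""
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return frame


def mat_export_field_names() -> dict[str, str]:
    """Field mapping a converter from the instrument ``.mat`` export needs.

    This is documentation, not a reader: vendor raw formats are a non-goal.
    """
    return {
        "tid": "trace_id",
        "loc (column 1, metres)": "x_nm (scale by 1e9)",
        "loc (column 2, metres)": "y_nm (scale by 1e9)",
        "loc (column 3, metres)": "z_nm (scale by 1e9)",
        "tim": "t",
    }
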