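"""CSV dialects for crystal trajectories, distances, pressures and dimensions.

All files are plain CSV with a ``time_s`` column:

* crystals:   ``time_s, c1_x, c1_y, c1_z, ..., c8_x, c8_y, c8_z`` (mm)
* distances:  ``time_s, d_1_2, d_1_3, ..., d_7_8`` (upper triangle, mm)
* pressure:   ``time_s, p_lv_mmHg[, p_la_mmHg, p_ao_mmHg]``
* dimensions: ``time_s, D_epi_mm, L_epi_mm``
* geometry (output): ``time_s, MAA_mm2, SL_mm, ICW_mm, ACI, NPA_deg, flags``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "InputFormatError",
    "read_crystals_csv",
    "write_crystals_csv",
    "read_distances_csv",
    "write_distances_csv",
    "read_pressure_csv",
    "write_pressure_csv",
    "read_dimensions_csv",
    "write_dimensions_csv",
    "write_geometry_csv",
    "read_geometry_csv",
    "load_config",
]

N_CRYSTALS = 8


class InputFormatError(ValueError):
    """Malformed input file (the message names file and offending column/row)."""


def _read(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise InputFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {missing}")
    bad = df[required].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise InputFormatError(f"{path}: missing value at row {row}")
    return df


def _crystal_columns() -> list[str]:
    return [f"c{i}_{ax}" for i in range(1, N_CRYSTALS + 1) for ax in "xyz"]


def read_crystals_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a crystal trajectory CSV -> (times (T,), coords (T, 8, 3))."""
    cols = _crystal_columns()
    df = _read(path, ["time_s"] + cols)
    times = df["time_s"].to_numpy(dtype=float)
    coords = df[cols].to_numpy(dtype=float).reshape(-1, N_CRYSTALS, 3)
    return times, coords


def write_crystals_csv(path: str | Path, times: np.ndarray, coords: np.ndarray) -> None:
    coords = np.asarray(coords, dtype=float)
    df = pd.DataFrame(coords.reshape(len(times), -1), columns=_crystal_columns())
    df.insert(0, "time_s", np.asarray(times, dtype=float))
    df.to_csv(path, index=False, float_format="%.6f")


def _distance_columns(n: int = N_CRYSTALS) -> list[tuple[int, int]]:
    return [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]


def read_distances_csv(path: str | Path, n: int = N_CRYSTALS) -> tuple[np.ndarray, np.ndarray]:
    """Read an upper-triangle distance CSV -> (times (T,), matrices (T, n, n))."""
    pairs = _distance_columns(n)
    cols = [f"d_{i}_{j}" for i, j in pairs]
    df = _read(path, ["time_s"] + cols)
    times = df["time_s"].to_numpy(dtype=float)
    mats = np.zeros((len(df), n, n))
    for (i, j), c in zip(pairs, cols):
        mats[:, i - 1, j - 1] = mats[:, j - 1, i - 1] = df[c].to_numpy(dtype=float)
    return times, mats


def write_distances_csv(path: str | Path, times: np.ndarray, matrices: np.ndarray) -> None:
    matrices = np.asarray(matrices, dtype=float)
    n = matrices.shape[-1]
    data = {"time_s": np.asarray(times, dtype=float)}
    for i, j in _distance_columns(n):
        data[f"d_{i}_{j}"] = matrices[:, i - 1, j - 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def read_pressure_csv(path: str | Path) -> pd.DataFrame:
    return _read(path, ["time_s", "p_lv_mmHg"])


def write_pressure_csv(path: str | Path, times: np.ndarray, p_lv: np.ndarray, **extra) -> None:
    data = {"time_s": np.asarray(times, dtype=float), "p_lv_mmHg": np.asarray(p_lv, dtype=float)}
    for key, val in extra.items():
        data[key] = np.asarray(val, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def read_dimensions_csv(path: str | Path) -> pd.DataFrame:
    return _read(path, ["time_s", "D_epi_mm", "L_epi_mm"])


def write_dimensions_csv(path: str | Path, times, d_epi, l_epi) -> None:
    pd.DataFrame(
        {
            "time_s": np.asarray(times, dtype=float),
            "D_epi_mm": np.asarray(d_epi, dtype=float),
            "L_epi_mm": np.asarray(l_epi, dtype=float),
        }
    ).to_csv(path, index=False, float_format="%.6f")


def write_geometry_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.9g")


def read_geometry_csv(path: str | Path) -> pd.DataFrame:
    return _read(path, ["time_s", "MAA_mm2", "SL_mm", "ICW_mm", "ACI", "NPA_deg"])


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — YAML superset) configuration file."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputFormatError(f"{path}: configuration must be a mapping")
    return cfg
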