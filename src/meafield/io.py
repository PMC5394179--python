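"""Recordings, electrode layouts and standard-format readers/writers.

Units are fixed package-wide: potentials in μV, time in ms, positions in mm.
All I/O converts at the boundary.  Two on-disk formats are supported:

* HDF5 — datasets ``/potentials`` (electrode × sample, float64, μV),
  ``/layout/positions_mm`` (electrode × 2), ``/layout/roles`` (int codes),
  root attributes ``sampling_interval_ms`` and ``schema_version``.
* CSV fallback — ``recording.csv`` (samples × electrodes),
  ``layout.csv`` (index, x_mm, y_mm, role) and ``meta.json`` in a directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeLayout",
    "Recording",
    "make_standard_layout",
    "load_recording",
    "save_recording",
]

SCHEMA_VERSION = 1

ROLE_ACTIVE = "active"
ROLE_REFERENCE = "reference"
ROLE_UNUSED = "unused"
_ROLE_CODES = {ROLE_ACTIVE: 0, ROLE_REFERENCE: 1, ROLE_UNUSED: 2}
_CODE_ROLES = {v: k for k, v in _ROLE_CODES.items()}


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


@dataclass(frozen=True)
class ElectrodeLayout:
    """2-D electrode positions (mm) with per-electrode roles.

    ``roles`` flags each electrode as ``"active"``, ``"reference"`` or
    ``"unused"``; only active electrodes enter pair averages downstream.
    """

    positions: np.ndarray  # (n, 2) mm
    roles: tuple  # length n, role strings
    spacing: float  # mm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "roles", tuple(self.roles))
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.roles) != pos.shape[0]:
            raise ValueError("roles length must match positions")
        bad = set(self.roles) - set(_ROLE_CODES)
        if bad:
            raise ValueError(f"unknown roles: {bad}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        uniq = {tuple(np.round(p, 12)) for p in pos}
        if len(uniq) != pos.shape[0]:
            raise ValueError("electrode positions must be unique")
        if len(self.active_indices) < 2:
            raise ValueError("layout needs at least 2 active electrodes")
        # active electrodes must sit on the stated grid
        scaled = pos[self.active_indices] / self.spacing
        if not np.allclose(scaled, np.round(scaled), atol=1e-9):
            raise ValueError("active positions do not lie on the stated grid")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def active_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == ROLE_ACTIVE], dtype=int)

    def pairwise_distances(self) -> np.ndarray:
        """Distance matrix (mm) between active electrodes."""
        p = self.positions[self.active_indices]
        d = p[:, None, :] - p[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))


@dataclass
class Recording:
    """An electrode × sample potential matrix with layout and sampling metadata."""

    potentials: np.ndarray  # (n_electrodes, n_samples) μV
    sampling_interval: float  # ms
    layout: ElectrodeLayout
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        if self.potentials.ndim != 2:
            raise ValueError("potentials must be 2-D (electrode × sample)")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.potentials.shape[0] != len(self.layout):
            raise ValueError(
                f"potentials has {self.potentials.shape[0]} rows but layout "
                f"has {len(self.layout)} electrodes"
            )
        if not np.all(np.isfinite(self.potentials)):
            el, sm = np.argwhere(~np.isfinite(self.potentials))[0]
            raise ValueError(
                f"non-finite potential at electrode {el}, sample {sm}"
            )

    @property
    def n_electrodes(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[1]

    @property
    def duration(self) -> float:
        """Registration length in ms."""
        return self.n_samples * self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return np.arange(self.n_samples) * self.sampling_interval

    def active_potentials(self) -> np.ndarray:
        return self.potentials[self.layout.active_indices]

    def copy(self) -> "Recording":
        return Recording(
            potentials=self.potentials.copy(),
            sampling_interval=self.sampling_interval,
            layout=self.layout,
            annotations=dict(self.annotations),
        )


def make_standard_layout(
    rows: int,
    cols: int,
    spacing: float,
    reference_index: Optional[int] = None,
    unused_indices: Optional[Sequence[int]] = None,
) -> ElectrodeLayout:
    """Rectangular grid layout with optional reference/unused electrodes.

    Electrodes are indexed row-major from the origin; positions are electrode
    centers.  ``unused_indices`` also supports the common vendor 60-electrode
    variant (8×8 minus the four corners).

    Parameters
    ----------
    rows, cols : int
        Grid shape, each ≥ 1.
    spacing : float
        Inter-electrode distance in mm (0.2 mm for the standard array).
    reference_index : int, optional
        Electrode used as voltage reference (excluded from the active set).
    unused_indices : sequence of int, optional
        Electrodes not recorded (excluded from the active set).
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    n = rows * cols
    unused = list(unused_indices or [])
    flagged = unused + ([reference_index] if reference_index is not None else [])
    if len(set(flagged)) != len(flagged):
        raise ValueError("reference/unused indices must be distinct")
    for i in flagged:
        if not 0 <= i < n:
            raise ValueError(f"electrode index {i} out of range for {rows}x{cols} grid")
    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows))
    positions = np.column_stack([xs.ravel(), ys.ravel()]).astype(float) * spacing
    roles = [ROLE_ACTIVE] * n
    for i in unused:
        roles[i] = ROLE_UNUSED
    if reference_index is not None:
        roles[reference_index] = ROLE_REFERENCE
    return ElectrodeLayout(positions=positions, roles=tuple(roles), spacing=spacing)


def save_recording(rec: Recording, path, format: str = "hdf5"):
    """Write a recording to disk; see module docstring for the on-disk layout.

    Returns the path written (the HDF5 file, or the CSV directory).
    """
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("potentials", data=rec.potentials, dtype="f8")
            g = f.create_group("layout")
            g.create_dataset("positions_mm", data=rec.layout.positions, dtype="f8")
            g.create_dataset(
                "roles", data=np.array([_ROLE_CODES[r] for r in rec.layout.roles], dtype="i4")
            )
            g.attrs["spacing_mm"] = rec.layout.spacing
            f.attrs["sampling_interval_ms"] = rec.sampling_interval
            f.attrs["schema_version"] = SCHEMA_VERSION
            if rec.annotations:
                f.attrs["annotations_json"] = json.dumps(rec.annotations, default=str)
        return path
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        # one row per sample, one column per electrode
        pd.DataFrame(rec.potentials.T, columns=[f"e{i}" for i in range(rec.n_electrodes)]).to_csv(
            path / "recording.csv", index=False, float_format="%.8f"
        )
        pd.DataFrame(
            {
                "index": np.arange(len(rec.layout)),
                "x_mm": rec.layout.positions[:, 0],
                "y_mm": rec.layout.positions[:, 1],
                "role": list(rec.layout.roles),
            }
        ).to_csv(path / "layout.csv", index=False)
        meta = {
            "sampling_interval_ms": rec.sampling_interval,
            "spacing_mm": rec.layout.spacing,
            "schema_version": SCHEMA_VERSION,
            "annotations": rec.annotations,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
        return path
    raise ValueError(f"unknown format {format!r}")


def load_recording(path, format: str = "hdf5") -> Recording:
    """Read a recording written by :func:`save_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            for key in ("potentials", "layout/positions_mm", "layout/roles"):
                if key not in f:
                    raise FormatError(f"missing dataset {key!r} in {path}")
            if "sampling_interval_ms" not in f.attrs:
                raise FormatError(f"missing attribute 'sampling_interval_ms' in {path}")
            potentials = f["potentials"][:]
            positions = f["layout/positions_mm"][:]
            codes = f["layout/roles"][:]
            spacing = float(f["layout"].attrs.get("spacing_mm", 0.2))
            si = float(f.attrs["sampling_interval_ms"])
            ann = json.loads(f.attrs.get("annotations_json", "{}"))
        roles = tuple(_CODE_ROLES[int(c)] for c in codes)
        layout = ElectrodeLayout(positions=positions, roles=roles, spacing=spacing)
        return Recording(potentials, si, layout, ann)
    if format == "csv":
        for name in ("recording.csv", "layout.csv", "meta.json"):
            if not (path / name).exists():
                raise FormatError(f"missing file {name!r} in {path}")
        pot = pd.read_csv(path / "recording.csv").to_numpy(dtype=float).T
        lay = pd.read_csv(path / "layout.csv")
        for col in ("x_mm", "y_mm", "role"):
            if col not in lay.columns:
                raise FormatError(f"layout.csv missing column {col!r}")
        meta = json.loads((path / "meta.json").read_text())
        layout = ElectrodeLayout(
            positions=lay[["x_mm", "y_mm"]].to_numpy(dtype=float),
            roles=tuple(lay["role"]),
            spacing=float(meta["spacing_mm"]),
        )
        return Recording(
            pot, float(meta["sampling_interval_ms"]), layout, meta.get("annotations", {})
        )
    raise ValueError(f"unknown format {format!r}")
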