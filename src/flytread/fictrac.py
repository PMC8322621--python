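"""FicTrac-format treadmill data: reading, writing and unit conversion.

FicTrac estimates the absolute orientation of a patterned, air-supported sphere
from camera frames and writes one 25-field numeric record per frame.  This
module consumes and produces that file format; the sphere-tracking algorithm
itself is out of scope.  Only three variables are interpreted here:

* ``integrated animal heading (lab)`` — radians in [0, 2pi);
* ``animal movement speed`` — radians of sphere rotation per camera frame;
* ``delta timestamp`` — seconds between consecutive camera frames.

All other fields are carried opaquely.  Column indices follow the published
FicTrac data-file layout (heading = column 17, movement speed = column 19,
delta timestamp = column 24, 1-based) but are configurable through a
:class:`FormatDescriptor` to tolerate dialect drift.

Physical conversions use the treadmill sphere geometry: a foam ball of 9 mm
diameter and 320 kg m^-3 density (mass ~0.12 g).  A sphere rotation of ``s``
radians in one camera frame corresponds to a path length of ``s * radius`` at
the fly's feet, so translational speed is ``s * radius / delta_t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FormatDescriptor",
    "DEFAULT_FORMAT",
    "SphereSpec",
    "FicTracData",
    "FicTracFormatError",
    "FicTracValidationError",
    "read_fictrac",
    "write_fictrac",
    "yaw_velocity",
    "translational_speed",
    "sphere_mass",
]


class FicTracFormatError(ValueError):
    """A data file does not match the 25-column numeric layout."""


class FicTracValidationError(ValueError):
    """Parsed values violate a FicTrac invariant (ordering, ranges)."""


@dataclass(frozen=True)
class FormatDescriptor:
    """Maps named variables to 1-based column indices of the data file."""

    n_columns: int = 25
    frame_counter_col: int = 1
    heading_col: int = 17
    movement_speed_col: int = 19
    delta_timestamp_col: int = 24

    def __post_init__(self) -> None:
        cols = (self.frame_counter_col, self.heading_col,
                self.movement_speed_col, self.delta_timestamp_col)
        if any(not 1 <= c <= self.n_columns for c in cols):
            raise ValueError("column indices must be within 1..n_columns")


DEFAULT_FORMAT = FormatDescriptor()


@dataclass(frozen=True)
class SphereSpec:
    """Treadmill sphere geometry."""

    diameter_mm: float = 9.0
    density_kg_m3: float = 320.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("diameter and density must be > 0")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


class FicTracData:
    """A sequence of 25-field FicTrac frames backed by an (n, 25) float array.

    Indexing returns the raw row for one frame; the interpreted variables are
    exposed as array properties.
    """

    def __init__(self, values: np.ndarray, fmt: FormatDescriptor = DEFAULT_FORMAT,
                 validate: bool = True):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != fmt.n_columns:
            raise FicTracFormatError(
                f"expected an (n, {fmt.n_columns}) array, got shape {values.shape}")
        self.values = values
        self.fmt = fmt
        if validate:
            self.validate()

    # -- interpreted columns -----------------------------------------------
    @property
    def frame_counter(self) -> np.ndarray:
        return self.values[:, self.fmt.frame_counter_col - 1]

    @property
    def heading_rad(self) -> np.ndarray:
        """Integrated heading direction in the lab frame, [0, 2pi)."""
        return self.values[:, self.fmt.heading_col - 1]

    @property
    def movement_speed_rad_per_frame(self) -> np.ndarray:
        return self.values[:, self.fmt.movement_speed_col - 1]

    @property
    def delta_timestamp_s(self) -> np.ndarray:
        return self.values[:, self.fmt.delta_timestamp_col - 1]

    @property
    def frame_times_s(self) -> np.ndarray:
        """Time of each camera frame: cumulative sum of delta timestamps."""
        return np.cumsum(self.delta_timestamp_s)

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i) -> np.ndarray:
        return self.values[i]

    def __eq__(self, other) -> bool:
        return (isinstance(other, FicTracData)
                and self.values.shape == other.values.shape
                and bool(np.array_equal(self.values, other.values)))

    def validate(self) -> None:
        fc = self.frame_counter
        if len(self) and np.any(np.diff(fc) <= 0):
            row = int(np.argmax(np.diff(fc) <= 0)) + 1
            raise FicTracValidationError(
                f"frame counter not strictly increasing at row {row}")
        dt = self.delta_timestamp_s
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0))
            raise FicTracValidationError(f"delta timestamp <= 0 at row {row}")
        h = self.heading_rad
        if np.any((h < 0) | (h >= 2 * np.pi)):
            row = int(np.argmax((h < 0) | (h >= 2 * np.pi)))
            raise FicTracValidationError(f"heading outside [0, 2pi) at row {row}")

    @classmethod
    def from_components(cls, heading_rad, movement_speed_rad_per_frame,
                        delta_timestamp_s, frame_counter=None,
                        fmt: FormatDescriptor = DEFAULT_FORMAT) -> "FicTracData":
        """Assemble frames from the interpreted variables; other fields zero."""
        h = np.asarray(heading_rad, dtype=float)
        n = len(h)
        vals = np.zeros((n, fmt.n_columns))
        vals[:, fmt.frame_counter_col - 1] = (np.arange(1, n + 1)
                                              if frame_counter is None else frame_counter)
        vals[:, fmt.heading_col - 1] = h
        vals[:, fmt.movement_speed_col - 1] = movement_speed_rad_per_frame
        vals[:, fmt.delta_timestamp_col - 1] = delta_timestamp_s
        return cls(vals, fmt)


def read_fictrac(path, fmt: FormatDescriptor = DEFAULT_FORMAT) -> FicTracData:
    """Read a FicTrac ".dat"-style delimited text file.

    Comma-delimited with optional whitespace; lines starting with '#' are
    skipped.  Raises :class:`FicTracFormatError` naming the first offending row
    on a wrong field count, :class:`FicTracValidationError` on bad values.
    """
    rows = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            fields = [p.strip() for p in s.split(",")]
            if len(fields) != fmt.n_columns:
                raise FicTracFormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {fmt.n_columns}")
            try:
                rows.append([float(p) for p in fields])
            except ValueError as exc:
                raise FicTracFormatError(f"{path}: line {lineno}: {exc}") from None
    return FicTracData(np.asarray(rows, dtype=float).reshape(-1, fmt.n_columns), fmt)


def write_fictrac(data: FicTracData, path) -> None:
    """Write frames as comma-delimited text; round-trips through read exactly."""
    np.savetxt(path, data.values, fmt="%.17g", delimiter=", ")


def yaw_velocity(data: FicTracData, degrees: bool = True) -> np.ndarray:
    """Yaw rotational velocity from the integrated heading.

    The wrapped heading is unwrapped (discontinuities > pi get +-2pi),
    first-differenced, and divided by the per-frame delta timestamp.  Returns
    one value per frame transition (length n-1), in deg/s by default; sample i
    sits at the time of camera frame i+1.
    """
    if len(data) < 2:
        raise FicTracValidationError("need at least 2 frames for yaw velocity")
    dt = data.delta_timestamp_s[1:]
    if np.any(dt <= 0):
        raise FicTracValidationError("delta timestamp must be > 0")
    dh = np.diff(np.unwrap(data.heading_rad))
    v = dh / dt
    return np.rad2deg(v) if degrees else v


def translational_speed(data: FicTracData,
                        sphere: SphereSpec = SphereSpec()) -> np.ndarray:
    """Walking speed in mm/s: movement speed (rad/frame) x radius / delta_t."""
    dt = data.delta_timestamp_s
    if np.any(dt <= 0):
        raise FicTracValidationError("delta timestamp must be > 0")
    return data.movement_speed_rad_per_frame * sphere.radius_mm / dt


def sphere_mass(sphere: SphereSpec = SphereSpec()) -> float:
    """Sphere mass in grams: density x (4/3) pi r^3."""
    r_m = sphere.radius_mm / 1000.0
    return sphere.density_kg_m3 * (4.0 / 3.0) * np.pi * r_m**3 * 1000.0
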