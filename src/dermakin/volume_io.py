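"""Image-volume containers, TIFF stack I/O, and fluorescein-referenced normalization.

Axis convention (used package-wide): volumes are indexed ``(x, y, z)`` where
``x`` is the loading direction and ``z`` is depth.  TIFF page ``k`` holds the
2D slice ``data[:, :, k]``.  Voxel sizes are in micrometres per axis and need
not be isotropic (the nominal acquisition grid is 1.144 x 1.144 x 1 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = [
    "ImageVolume",
    "CalibrationTable",
    "read_stack",
    "write_stack",
    "normalize_intensity",
]


@dataclass(frozen=True)
class ImageVolume:
    """One channel's 3D intensity grid plus acquisition metadata.

    Parameters
    ----------
    data:
        Non-negative intensity grid indexed ``(x, y, z)``.
    voxel_size:
        ``(dx, dy, dz)`` in micrometres.
    channel:
        Emission channel label, e.g. ``"SHG"`` or ``"TPEF"``.
    acquisition:
        Free-form acquisition settings; ``laser_power`` (mW) and
        ``detector_gain`` are the keys consulted for calibration lookup.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel: str = "SHG"
    acquisition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {data.shape}")
        if data.size == 0:
            raise ValueError("volume has zero size")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite intensities")
        if data.min() < 0:
            raise ValueError("volume contains negative intensities")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive floats, got {self.voxel_size}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=data)


@dataclass(frozen=True)
class CalibrationTable:
    """Map from ``(channel, laser_power, detector_gain)`` to the fluorescein
    reference intensity measured at those settings.

    Intensities collected at different powers/gains are made comparable by
    dividing by the reference; no interpolation between settings is done —
    an exact match is required.
    """

    entries: Mapping[tuple[str, float, float], float]

    def __post_init__(self) -> None:
        clean: dict[tuple[str, float, float], float] = {}
        for (channel, power, gain), ref in dict(self.entries).items():
            ref = float(ref)
            if not ref > 0:
                raise ValueError(
                    f"reference intensity must be positive, got {ref!r} for "
                    f"({channel}, {power}, {gain})"
                )
            clean[(str(channel), float(power), float(gain))] = ref
        object.__setattr__(self, "entries", clean)

    def lookup(self, channel: str, laser_power: float, detector_gain: float) -> float:
        key = (str(channel), float(laser_power), float(detector_gain))
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(
                f"no calibration entry for channel={channel!r}, "
                f"laser_power={laser_power}, detector_gain={detector_gain}"
            ) from None

    @classmethod
    def from_records(cls, records) -> "CalibrationTable":
        """Build from an iterable of dicts with keys
        ``channel, power_mW, gain, reference_intensity`` (the JSON/YAML layout)."""
        entries = {
            (r["channel"], float(r["power_mW"]), float(r["gain"])): float(r["reference_intensity"])
            for r in records
        }
        return cls(entries)


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    channel: str = "SHG",
    acquisition: Mapping[str, float] | None = None,
) -> ImageVolume:
    """Read a multi-page grayscale TIFF into an :class:`ImageVolume`.

    Page ``k`` of the file becomes z-index ``k``; all pages must share one
    shape and dtype.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:  # single page
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2D grayscale pages, got shape {pages.shape}")
    data = np.moveaxis(pages, 0, -1)  # (page, x, y) -> (x, y, z)
    return ImageVolume(
        data=data,
        voxel_size=voxel_size,
        channel=channel,
        acquisition=dict(acquisition or {}),
    )


def write_stack(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (page ``k`` = ``data[:, :, k]``)."""
    pages = np.moveaxis(vol.data, -1, 0)
    tifffile.imwrite(Path(path), pages)


def normalize_intensity(vol: ImageVolume, cal: CalibrationTable) -> ImageVolume:
    """Divide every voxel by the fluorescein reference for the volume's
    acquisition settings, making intensities unitless and comparable across
    power/gain combinations.

    Raises
    ------
    KeyError
        If the calibration table has no entry for the volume's
        ``(channel, laser_power, detector_gain)``.
    """
    acq = vol.acquisition
    if "laser_power" not in acq or "detector_gain" not in acq:
        raise KeyError("volume acquisition metadata must contain laser_power and detector_gain")
    ref = cal.lookup(vol.channel, acq["laser_power"], acq["detector_gain"])
    return vol.with_data(vol.data.astype(np.float64) / ref)
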