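"""Tissue and collagen masks plus undeformed-microstructure summaries.

The collagen segmenter is a named plug-in: the pipeline only requires a
boolean mask aligned to the SHG volume, so any classifier honouring that
contract (including an external per-slice CNN) can be swapped in.  The
default is a per-volume Otsu threshold applied slice-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .orientation import DirectionalVariance, OrientationField, directional_variance
from .volume_io import ImageVolume

__all__ = [
    "VoxelMask",
    "MicrostructureSummary",
    "tissue_mask",
    "collagen_mask",
    "summarize_microstructure",
    "register_segmenter",
]


@dataclass
class VoxelMask:
    """Boolean grid aligned to an :class:`ImageVolume`, tagged with the
    method that produced it."""

    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def shape(self):
        return self.data.shape

    def __and__(self, other: "VoxelMask") -> "VoxelMask":
        return VoxelMask(self.data & other.data, f"{self.provenance}&{other.provenance}")


@dataclass(frozen=True)
class MicrostructureSummary:
    """Per-volume summary of the unloaded microstructure: collagen-positive
    fraction of tissue (%), mean normalized SHG and TPEF intensities over
    collagen-positive voxels, and the 3D directional variance."""

    collagen_fraction: float
    mean_shg: float
    mean_tpef: float
    directional_variance: float | None
    n_collagen: int
    n_tissue: int


def tissue_mask(channels: Sequence[ImageVolume]) -> VoxelMask:
    """Tissue-positive mask: sum the normalized intensities of all emission
    channels and keep voxels at or above the summed volume's overall mean
    (ties inclusive, so a constant volume is wholly tissue)."""
    if len(channels) < 1:
        raise ValueError("need at least one channel")
    shapes = {c.data.shape for c in channels}
    if len(shapes) != 1:
        raise ValueError(f"channel shapes differ: {shapes}")
    total = np.zeros(channels[0].data.shape, dtype=np.float64)
    for c in channels:
        total += c.data
    return VoxelMask(total >= total.mean(), provenance="threshold-mean")


def _segment_otsu(data: np.ndarray) -> np.ndarray:
    if data.max() == data.min():
        return np.zeros(data.shape, dtype=bool)
    thr = threshold_otsu(data)
    return data > thr


def _segment_mean(data: np.ndarray) -> np.ndarray:
    return data >= data.mean()


_SEGMENTERS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "threshold-otsu": _segment_otsu,
    "threshold-mean": _segment_mean,
}


def register_segmenter(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a collagen segmenter plug-in; ``fn`` maps a 2D slice to a
    boolean mask of the same shape."""
    _SEGMENTERS[name] = fn


def collagen_mask(
    shg: ImageVolume,
    method: str | Callable[[np.ndarray], np.ndarray] = "threshold-otsu",
) -> VoxelMask:
    """Collagen-positive mask from the normalized SHG volume.

    Classification is applied per 2D z-slice and the slice masks recombined
    into a 3D mask.  Threshold methods compute their threshold once per
    volume so slices are classified on a common scale.  ``method`` may be a
    registered name or a callable ``slice -> bool mask``.
    """
    data = np.asarray(shg.data, dtype=np.float64)
    if callable(method):
        fn = method
        name = getattr(method, "__name__", "custom")
    else:
        try:
            fn = _SEGMENTERS[method]
        except KeyError:
            raise ValueError(
                f"unknown segmentation method {method!r}; known: {sorted(_SEGMENTERS)}"
            ) from None
        name = method
        if method == "threshold-otsu":
            if data.max() == data.min():
                return VoxelMask(np.zeros(data.shape, dtype=bool), provenance=name)
            thr = threshold_otsu(data)
            fn = lambda sl: sl > thr  # noqa: E731 - volume-wide threshold, slice-wise application
        elif method == "threshold-mean":
            mean = data.mean()
            fn = lambda sl: sl >= mean  # noqa: E731
    mask = np.zeros(data.shape, dtype=bool)
    for k in range(data.shape[2]):
        sl = fn(data[:, :, k])
        if sl.shape != data.shape[:2]:
            raise ValueError("segmenter returned a mask of the wrong shape")
        mask[:, :, k] = sl
    return VoxelMask(mask, provenance=name)


def summarize_microstructure(
    shg: ImageVolume,
    tpef: ImageVolume,
    collagen: VoxelMask,
    tissue: VoxelMask,
    orientation_field: OrientationField | None = None,
) -> MicrostructureSummary:
    """Collagen fraction (% of tissue-positive voxels that are also
    collagen-positive), mean normalized intensities over collagen-positive
    voxels, and — when an orientation field is supplied — the directional
    variance over collagen-positive voxels."""
    for m in (collagen, tissue):
        if m.shape != shg.data.shape:
            raise ValueError("mask shape must match volume shape")
    if tpef.data.shape != shg.data.shape:
        raise ValueError("SHG/TPEF shapes differ")
    n_tissue = int(tissue.data.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")
    both = collagen.data & tissue.data
    n_collagen = int(collagen.data.sum())
    if n_collagen == 0:
        raise ValueError("no collagen-positive voxels; means undefined")
    dv: DirectionalVariance | None = None
    if orientation_field is not None:
        dv = directional_variance(orientation_field, collagen.data)
    return MicrostructureSummary(
        collagen_fraction=100.0 * both.sum() / n_tissue,
        mean_shg=float(shg.data[collagen.data].mean()),
        mean_tpef=float(tpef.data[collagen.data].mean()),
        directional_variance=None if dv is None else dv.value,
        n_collagen=n_collagen,
        n_tissue=n_tissue,
    )
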