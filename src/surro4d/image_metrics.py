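"""Volumes, masks, MIP generation, segmentation and similarity metrics.

Coordinate convention (fixed once, documented here, used everywhere):
arrays are indexed ``[ix, iy, iz]`` with x = lateral, y = anterior-posterior,
z = superior-inferior.  The physical centre of voxel ``(i, j, k)`` is
``origin + (index + 0.5) * spacing`` in mm.  Centroid differences are
therefore reported as (X, Y, Z) = (lateral, A-P, S-I) in mm.

The similarity metrics follow the standard definitions used to compare an
"accepted" internal target volume (from the clinically sorted bellows data)
with a test volume (from the rpm-sorted data):

* Dice similarity coefficient  DSC = 2|A n B| / (|A| + |B|)
* overlap index                OI  = |A n B| / |A|   (A = accepted)
* percent volume change        (V_accepted - V_test) / V_accepted x 100,
  negative when the test volume is larger
* percent difference from the ground-truth ITV
  (V_true - V_test) / V_true x 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage as _ndi

__all__ = [
    "Volume3D",
    "Mask",
    "SimilarityReport",
    "GridMismatchError",
    "EmptySegmentationError",
    "UndefinedMetricError",
    "compute_mip",
    "segment_threshold",
    "segment_lungs_simple",
    "mask_volume",
    "centroid",
    "dsc",
    "oi",
    "percent_volume_change",
    "percent_diff_from_true",
    "difference_map",
    "compare_masks",
    "save_volume",
    "load_volume",
]


class GridMismatchError(ValueError):
    """Volumes/masks do not share the same grid geometry."""


class EmptySegmentationError(ValueError):
    """Segmentation produced no voxels."""


class UndefinedMetricError(ValueError):
    """Metric undefined for the given masks (e.g. both empty)."""


_26_CONN = np.ones((3, 3, 3), dtype=bool)  # component labelling
_6_CONN = _ndi.generate_binary_structure(3, 1)  # conservative flood fill


@dataclass
class Volume3D:
    """A 3D scalar (HU) volume with grid geometry.

    data is indexed [ix, iy, iz]; spacing/origin are (x, y, z) in mm.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume3D data must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Mask(Volume3D):
    """A binary voxel segmentation sharing Volume3D's grid conventions."""

    label: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class SimilarityReport:
    """All pairwise similarity metrics for one accepted/test comparison."""

    volume_accepted_cc: float
    volume_test_cc: float
    percent_volume_change: float
    dsc: float
    oi: float
    centroid_delta_mm: Tuple[float, float, float]
    label_accepted: str = ""
    label_test: str = ""

    def as_dict(self) -> dict:
        d = {
            "label_accepted": self.label_accepted,
            "label_test": self.label_test,
            "volume_accepted_cc": self.volume_accepted_cc,
            "volume_test_cc": self.volume_test_cc,
            "percent_volume_change": self.percent_volume_change,
            "dsc": self.dsc,
            "oi": self.oi,
            "centroid_dx_mm": self.centroid_delta_mm[0],
            "centroid_dy_mm": self.centroid_delta_mm[1],
            "centroid_dz_mm": self.centroid_delta_mm[2],
        }
        return d


def _require_same_grid(a: Volume3D, b: Volume3D) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"grid mismatch: {a.shape}/{a.spacing}/{a.origin} vs {b.shape}/{b.spacing}/{b.origin}"
        )


def compute_mip(phases: Sequence[Volume3D]) -> Volume3D:
    """Maximum intensity projection: voxelwise maximum over phase volumes."""
    if len(phases) == 0:
        raise ValueError("compute_mip requires at least one volume")
    first = phases[0]
    out = first.data.copy()
    for v in phases[1:]:
        _require_same_grid(first, v)
        np.maximum(out, v.data, out=out)
    return Volume3D(out, first.spacing, first.origin)


def segment_threshold(
    volume: Volume3D,
    hu_lo: float,
    hu_hi: float,
    roi: Optional[Tuple[slice, slice, slice]] = None,
    label: str = "",
) -> Mask:
    """Threshold segmentation inside an ROI, keeping the largest component.

    Voxels with ``hu_lo <= HU <= hu_hi`` inside *roi* (the whole grid when
    None) are selected, then only the largest 26-connected component is
    retained -- the voxel analogue of window/level auto-thresholding around
    a volume of interest.
    """
    sel = np.zeros(volume.shape, dtype=bool)
    region = roi if roi is not None else (slice(None), slice(None), slice(None))
    sub = volume.data[region]
    sel[region] = (sub >= hu_lo) & (sub <= hu_hi)
    if not sel.any():
        raise EmptySegmentationError(
            f"no voxels in [{hu_lo}, {hu_hi}] HU inside the ROI"
        )
    labels, n = _ndi.label(sel, structure=_26_CONN)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        sel = labels == int(np.argmax(counts))
    return Mask(sel, volume.spacing, volume.origin, label=label)


def segment_lungs_simple(
    volume: Volume3D,
    air_hu_max: float = -600.0,
    body_hu_min: float = -300.0,
) -> Mask:
    """Simplified automatic lung segmentation by enclosed-air flood fill.

    Air-range voxels (HU < ``air_hu_max``) connected to the grid boundary
    are discarded as outside air.  On the axial (z) slice whose two largest
    remaining air areas are maximal, those areas seed a 6-connected 3D
    flood fill over the enclosed air, yielding the lung mask.  A single
    enclosed component (one lung) is accepted with a warning; no enclosed
    air raises :class:`EmptySegmentationError`.
    """
    air = volume.data < air_hu_max
    if not air.any():
        raise EmptySegmentationError("no air-range voxels in volume")
    # remove air connected to the grid border (not enclosed by body)
    border_seed = np.zeros_like(air)
    border_seed[0, :, :] = border_seed[-1, :, :] = True
    border_seed[:, 0, :] = border_seed[:, -1, :] = True
    border_seed[:, :, 0] = border_seed[:, :, -1] = True
    labels, _ = _ndi.label(air, structure=_6_CONN)
    outside = np.unique(labels[border_seed & air])
    enclosed = air & ~np.isin(labels, outside)
    if not enclosed.any():
        raise EmptySegmentationError("no enclosed air regions found")
    # pick the axial slice with the two largest enclosed-air areas
    best_score, best_seeds = -1, None
    for k in range(volume.shape[2]):
        sl = enclosed[:, :, k]
        if not sl.any():
            continue
        lab2, n2 = _ndi.label(sl)
        areas = np.bincount(lab2.ravel())
        areas[0] = 0
        top = np.sort(areas)[::-1][:2]
        score = int(top.sum())
        if score > best_score:
            best_score = score
            comp_ids = np.argsort(areas)[::-1][: min(2, n2)]
            seeds = np.zeros_like(enclosed)
            for cid in comp_ids:
                if areas[cid] > 0:
                    seeds[:, :, k] |= lab2 == cid
            best_seeds = seeds
    assert best_seeds is not None
    # 3D flood fill from the seeds over enclosed air
    filled = np.zeros_like(enclosed)
    lab3, _ = _ndi.label(enclosed, structure=_6_CONN)
    for cid in np.unique(lab3[best_seeds]):
        if cid != 0:
            filled |= lab3 == cid
    comp_ids = set(np.unique(lab3[filled])) - {0}
    if len(comp_ids) < 2:
        warnings.warn("lung segmentation found a single enclosed component", stacklevel=2)
    return Mask(filled, volume.spacing, volume.origin, label="lungs")


def mask_volume(mask: Mask) -> float:
    """Mask volume in cc (voxel count x voxel volume)."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


def centroid(mask: Mask) -> Tuple[float, float, float]:
    """Unweighted mean of voxel-centre physical coordinates, in mm."""
    if mask.n_voxels == 0:
        raise UndefinedMetricError("centroid undefined for an empty mask")
    idx = np.argwhere(mask.data).astype(float)
    mean_idx = idx.mean(axis=0)
    return tuple(
        float(mask.origin[d] + (mean_idx[d] + 0.5) * mask.spacing[d]) for d in range(3)
    )


def dsc(a: Mask, b: Mask) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|)."""
    _require_same_grid(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise UndefinedMetricError("DSC undefined when both masks are empty")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def oi(accepted: Mask, test: Mask) -> float:
    """Overlap index |accepted n test| / |accepted| (not symmetric)."""
    _require_same_grid(accepted, test)
    if accepted.n_voxels == 0:
        raise UndefinedMetricError("OI undefined for an empty accepted mask")
    inter = int((accepted.data & test.data).sum())
    return inter / accepted.n_voxels


def percent_volume_change(accepted: Mask, test: Mask) -> float:
    """(V_accepted - V_test) / V_accepted x 100; negative if test is larger."""
    va = mask_volume(accepted)
    if va == 0:
        raise UndefinedMetricError("percent volume change undefined: accepted volume is zero")
    return (va - mask_volume(test)) / va * 100.0


def percent_diff_from_true(true_mask: Mask, test: Mask) -> float:
    """(V_true - V_test) / V_true x 100: underestimation of the ground truth."""
    vt = mask_volume(true_mask)
    if vt == 0:
        raise UndefinedMetricError("percent difference undefined: true volume is zero")
    return (vt - mask_volume(test)) / vt * 100.0


def difference_map(a: Volume3D, b: Volume3D) -> Volume3D:
    """Voxelwise a - b (e.g. MIP_bellows - MIP_rpm) on a shared grid."""
    _require_same_grid(a, b)
    return Volume3D(a.data.astype(float) - b.data.astype(float), a.spacing, a.origin)


def compare_masks(accepted: Mask, test: Mask) -> SimilarityReport:
    """Full similarity report between an accepted and a test mask."""
    ca = centroid(accepted)
    ct = centroid(test)
    return SimilarityReport(
        volume_accepted_cc=mask_volume(accepted),
        volume_test_cc=mask_volume(test),
        percent_volume_change=percent_volume_change(accepted, test),
        dsc=dsc(accepted, test),
        oi=oi(accepted, test),
        centroid_delta_mm=tuple(float(t - a) for a, t in zip(ca, ct)),
        label_accepted=accepted.label,
        label_test=test.label,
    )


def save_volume(volume: Volume3D, path: Union[str, Path]) -> None:
    """Write a volume (or mask) to NIfTI, encoding spacing and origin."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    data = volume.data.astype(np.uint8) if volume.data.dtype == bool else volume.data
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_volume(path: Union[str, Path]) -> Volume3D:
    """Read a NIfTI volume written by :func:`save_volume`."""
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    return Volume3D(
        np.asarray(img.dataobj),
        spacing=tuple(float(affine[d, d]) for d in range(3)),
        origin=tuple(float(affine[d, 3]) for d in range(3)),
    )
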