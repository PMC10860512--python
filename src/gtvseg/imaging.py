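"""NIfTI volume I/O, orientation canonicalization, HU windowing, slicing.

Volumes are axial stacks with array layout (slice, row, col) and spacing
(slice_thickness_mm, row_mm, col_mm).  The canonical in-memory convention is
head-first slice order; feet-first acquisitions are represented either by an
explicit ``orientation`` flag in memory or, on disk, by a negative
slice-direction in the NIfTI affine.  ``read_volume`` always returns a
canonical head-first volume regardless of how the file was stored.

Intensity preprocessing is the fixed-window normalization used for soft
tissue on CT: clip to [-150, +250] HU, then map that window linearly onto
[0, 1].  The window is a constant of the method, so the normalization is the
same affine map for every image (never per-image min/max), and no spatial
resampling or interpolation is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

HU = "HU"
NORMALIZED = "normalized"
HEAD_FIRST = "head-first"
FEET_FIRST = "feet-first"

#: Default CT soft-tissue window, in Hounsfield units.
WINDOW_LO = -150.0
WINDOW_HI = 250.0


@dataclass
class Volume:
    """A 3D scalar image: ``data[slice, row, col]`` plus geometry metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float]  # (slice_thickness_mm, row_mm, col_mm)
    orientation: str = HEAD_FIRST
    intensity_state: str = HU

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        if self.orientation not in (HEAD_FIRST, FEET_FIRST):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.intensity_state not in (HU, NORMALIZED):
            raise ValueError(f"unknown intensity_state {self.intensity_state!r}")
        if self.intensity_state == NORMALIZED:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError("normalized volume has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def canonicalize(self) -> "Volume":
        """Return a head-first copy (flips slice order if feet-first)."""
        if self.orientation == HEAD_FIRST:
            return self
        return replace(self, data=self.data[::-1].copy(), orientation=HEAD_FIRST)


@dataclass
class SlicePair:
    """One axial slice of a normalized image with its binary mask."""

    image: np.ndarray
    mask: np.ndarray
    subject_id: str
    slice_index: int

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")


def canonicalize_mask(mask: np.ndarray, orientation: str) -> np.ndarray:
    """Flip a mask stored feet-first into the head-first convention."""
    if orientation == FEET_FIRST:
        return np.ascontiguousarray(mask[::-1])
    return mask


def write_volume(vol: Volume, path, *, mask: bool = False) -> None:
    """Write a Volume (or a binary mask volume) as NIfTI.

    The array is stored with axes reordered to NIfTI's (x=col, y=row,
    z=slice); a feet-first volume gets a negative z direction in the affine,
    which is how scanner orientation reaches disk.
    """
    data = vol.data
    if mask:
        data = data.astype(np.uint8)
    arr = np.transpose(data, (2, 1, 0))
    dz = vol.spacing[0] if vol.orientation == HEAD_FIRST else -vol.spacing[0]
    affine = np.diag([vol.spacing[2], vol.spacing[1], dz, 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, str(path))


def read_volume(path, *, intensity_state: str = HU) -> Volume:
    """Read a 3D NIfTI file into a canonical head-first :class:`Volume`.

    Files whose affine has a negative slice (z) direction are treated as
    feet-first and flipped into head-first order on load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI, got {arr.ndim}D in {path.name}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid spacing metadata in {path.name}")
    data = np.transpose(arr, (2, 1, 0))
    feet_first = img.affine[2, 2] < 0
    if feet_first:
        data = data[::-1]
    return Volume(
        data=np.ascontiguousarray(data),
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        orientation=HEAD_FIRST,
        intensity_state=intensity_state,
    )


def window_normalize(v: Volume, lo: float = WINDOW_LO, hi: float = WINDOW_HI) -> Volume:
    """Clip HU intensities to [lo, hi] and rescale that window onto [0, 1].

    The divisor is the fixed window width (hi - lo), so -150 HU maps to 0.0
    and +250 HU maps to 1.0 in every image.  No resampling is performed.
    """
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    if v.intensity_state != HU:
        raise ValueError("window_normalize expects HU intensities")
    scaled = (np.clip(v.data.astype(np.float32), lo, hi) - lo) / (hi - lo)
    return replace(v, data=scaled, intensity_state=NORMALIZED)


def to_slices(v: Volume, m: np.ndarray, subject_id: str = "", include_empty: bool = True) -> list[SlicePair]:
    """Decompose a normalized volume and its mask into axial SlicePairs.

    With ``include_empty=False`` only slices containing at least one mask
    voxel are kept; ``slice_index`` always refers to the position in the
    original stack so the volume can be reassembled.
    """
    if v.intensity_state != NORMALIZED:
        raise ValueError("to_slices expects a normalized volume")
    m = np.asarray(m)
    if m.shape != v.data.shape:
        raise ValueError(f"mask grid {m.shape} does not match volume grid {v.data.shape}")
    pairs = []
    for idx in range(v.n_slices):
        mask_slice = m[idx].astype(np.uint8)
        if not include_empty and mask_slice.sum() == 0:
            continue
        pairs.append(SlicePair(image=v.data[idx], mask=mask_slice, subject_id=subject_id, slice_index=idx))
    return pairs


def stack_slices(pairs: list[SlicePair], n_slices: int) -> np.ndarray:
    """Reassemble masks from SlicePairs into a (n_slices, H, W) mask volume."""
    if not pairs:
        raise ValueError("no slices to stack")
    h, w = pairs[0].mask.shape
    out = np.zeros((n_slices, h, w), dtype=np.uint8)
    for p in pairs:
        out[p.slice_index] = p.mask
    return out
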