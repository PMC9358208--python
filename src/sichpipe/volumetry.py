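"""CT volumetry of intraparenchymal hemorrhage and perihematomal edema.

Two procedures are implemented:

* **ABC/2** — the bedside ellipsoid approximation.  On the axial slice
  with the largest lesion cross-section the rater measures the longest
  in-slice diameter A (cm) and the widest diameter B orthogonal to it;
  C is the craniocaudal extent, counted as eligible slices x slice
  thickness, where a slice is eligible when its lesion area is at least
  25% of the reference slice's.  Volume = A*B*C/2, the /2 correcting a
  box volume down to an ellipsoid (pi/6 ~ 1/2).

* **Dual-clustering segmentation** — each voxel is kept when its HU value
  lies in a tissue-specific window *and* a sufficient fraction of its
  neighbors does too; surviving voxels are grouped into connected
  components which are filtered by size and mean intensity.  Brain is
  extracted with a soft-tissue window plus a largest-component rule;
  hemorrhage with a blood window inside the brain; edema by dilating the
  hemorrhage into a candidate ring and re-segmenting the ring with an
  edema window.

Axis order is (slice, row, column); voxel size is (dz, dy, dx) in mm and
volumes are reported in ml (= cc).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import DomainError, NoBrainError, NoLesionError

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass
class CTVolume:
    """A CT grid in Hounsfield units with voxel geometry in mm."""

    values: np.ndarray          # (slice, row, column)
    voxel_size: tuple[float, float, float]  # (dz, dy, dx) mm

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DomainError("CT volume must be 3-D")
        if any(v <= 0 for v in self.voxel_size):
            raise DomainError("voxel dimensions must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx / 1000.0


@dataclass
class AbcMeasurement:
    """Rater-style ABC/2 measurement; lengths in cm."""

    a: float
    b: float
    n_slices: int
    slice_thickness: float = 0.5

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0 or self.slice_thickness <= 0:
            raise DomainError("ABC/2 dimensions must be positive")
        if self.n_slices < 1:
            raise DomainError("need at least one eligible slice")


@dataclass
class DualClusterParams:
    """Parameters for the dual-clustering voxel filter.

    A voxel survives when its HU is inside ``hu_window`` and at least
    ``neighbor_fraction`` of its neighborhood (26-neighborhood of radius
    ``neighborhood_radius``) is inside the window too.  Components below
    ``min_cluster_voxels`` or whose mean HU is below ``intensity_floor``
    are discarded.
    """

    hu_window: tuple[float, float]
    neighborhood_radius: int = 1
    neighbor_fraction: float = 0.5
    min_cluster_voxels: int = 1
    connectivity: int = 26
    intensity_floor: float = -1024.0

    def __post_init__(self):
        lo, hi = self.hu_window
        if not lo < hi:
            raise DomainError("HU window must satisfy lo < hi")
        if lo < HU_MIN or hi > HU_MAX:
            raise DomainError("HU window outside the representable range")
        if not 0.0 <= self.neighbor_fraction <= 1.0:
            raise DomainError("neighbor_fraction must be in [0, 1]")
        if self.connectivity not in (6, 26):
            raise DomainError("connectivity must be 6 or 26")


#: Default tissue windows (HU).  Deliberately configuration, not constants
#: baked into the algorithms.
DEFAULT_BRAIN_PARAMS = DualClusterParams(
    hu_window=(0.0, 80.0), min_cluster_voxels=100)
DEFAULT_HEMORRHAGE_PARAMS = DualClusterParams(
    hu_window=(45.0, 90.0), min_cluster_voxels=50, intensity_floor=45.0)
DEFAULT_EDEMA_PARAMS = DualClusterParams(
    hu_window=(5.0, 23.0), min_cluster_voxels=1, neighbor_fraction=0.3)
DEFAULT_DILATION_LIMIT = 10


@dataclass
class SegmentationMasks:
    """Aligned brain / hemorrhage / edema masks with their provenance."""

    brain: np.ndarray
    hemorrhage: np.ndarray
    edema: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.hemorrhage[~self.brain].sum() == 0):
            raise DomainError("hemorrhage mask escapes the brain mask")
        if not (self.edema[~self.brain].sum() == 0):
            raise DomainError("edema mask escapes the brain mask")
        if (self.hemorrhage & self.edema).any():
            raise DomainError("hemorrhage and edema masks overlap")


# ---------------------------------------------------------------- ABC/2

def abc2_volume(m: AbcMeasurement) -> float:
    """Ellipsoid-approximation volume A*B*C/2 in ml, with the craniocaudal
    extent C = eligible slices x slice thickness (cm)."""
    c = m.n_slices * m.slice_thickness
    return m.a * m.b * c / 2.0


def eligible_slices(hemorrhage_mask: np.ndarray,
                    fraction: float = 0.25) -> tuple[int, int]:
    """Count slices entering the C term of ABC/2.

    The reference slice carries the largest in-slice lesion area (ties
    broken toward the lowest index); a slice is eligible when its lesion
    area is at least ``fraction`` of the reference area.  Returns
    ``(n_slices, reference_slice)``.
    """
    mask = np.asarray(hemorrhage_mask, dtype=bool)
    areas = mask.reshape(mask.shape[0], -1).sum(axis=1)
    if areas.sum() == 0:
        raise NoLesionError("hemorrhage mask is empty")
    ref = int(np.argmax(areas))
    n = int((areas >= fraction * areas[ref]).sum())
    return n, ref


def abc2_phe(edema_measurement: AbcMeasurement,
             hematoma_volume: float) -> tuple[float, bool]:
    """Perihematomal edema volume: the ABC/2 volume of the edema extent
    minus the hematoma volume, clamped at zero.  Returns ``(ml, clamped)``.
    """
    if hematoma_volume < 0:
        raise DomainError("hematoma volume must be >= 0")
    raw = abc2_volume(edema_measurement) - hematoma_volume
    return (max(0.0, raw), raw < 0.0)


def measure_abc(mask: np.ndarray,
                voxel_size: tuple[float, float, float],
                slice_fraction: float = 0.25) -> AbcMeasurement:
    """Extract a rater-style ABC/2 measurement from a lesion mask.

    On the reference slice, A is the largest caliper (Feret) diameter of
    the lesion and B the maximal extent orthogonal to the A direction,
    both converted to cm; the slice count follows the eligibility rule.
    Assumes in-plane isotropy (dy == dx), as axial CT provides.
    """
    dz, dy, dx = voxel_size
    if abs(dy - dx) > 1e-9:
        raise DomainError("in-plane voxel size must be isotropic")
    n, ref = eligible_slices(mask, slice_fraction)
    sl = np.asarray(mask[ref], dtype=bool)
    pts = np.argwhere(sl).astype(float)
    # caliper diameter over the convex hull of pixel centers, padded by
    # one pixel to approximate pixel extents
    from scipy.spatial import ConvexHull
    if len(pts) > 3:
        hull = pts[ConvexHull(pts).vertices]
    else:
        hull = pts
    dmax, pair = 0.0, (hull[0], hull[0])
    for i in range(len(hull)):
        d = np.linalg.norm(hull - hull[i], axis=1)
        j = int(np.argmax(d))
        if d[j] > dmax:
            dmax, pair = d[j], (hull[i], hull[j])
    if dmax == 0:
        raise DomainError("degenerate single-pixel lesion")
    axis = (pair[1] - pair[0]) / dmax
    perp = np.array([-axis[1], axis[0]])
    width = float(np.ptp(hull @ perp))
    px_cm = dy / 10.0  # mm -> cm
    a_cm = (dmax + 1.0) * px_cm
    b_cm = (width + 1.0) * px_cm
    return AbcMeasurement(a=a_cm, b=b_cm, n_slices=n,
                          slice_thickness=dz / 10.0)


# ------------------------------------------------ dual-cluster segmentation

def _neighbor_fraction_in_window(inwin: np.ndarray, radius: int) -> np.ndarray:
    """Fraction of each voxel's cubic neighborhood (center excluded) that
    lies inside the HU window; at the grid edge the fraction is taken
    over the neighbors that exist, so boundary voxels are not penalized."""
    k = 2 * radius + 1
    kernel = np.ones((k, k, k))
    kernel[radius, radius, radius] = 0.0
    counts = ndimage.convolve(inwin.astype(float), kernel, mode="constant")
    valid = ndimage.convolve(np.ones_like(inwin, dtype=float), kernel,
                             mode="constant")
    return counts / valid


def dual_cluster_segment(vol: CTVolume, params: DualClusterParams,
                         within: np.ndarray | None = None) -> np.ndarray:
    """Dual-clustering tissue segmentation.

    Voxels pass when in-window and when the in-window fraction of their
    neighborhood reaches ``neighbor_fraction``; connected components
    (6 or 26 connectivity) below the size floor or mean-intensity floor
    are dropped.  ``within`` restricts the result to a region of interest.
    """
    lo, hi = params.hu_window
    inwin = (vol.values >= lo) & (vol.values <= hi)
    frac = _neighbor_fraction_in_window(inwin, params.neighborhood_radius)
    keep = inwin & (frac >= params.neighbor_fraction)
    if within is not None:
        keep &= np.asarray(within, dtype=bool)
    conn = 3 if params.connectivity == 26 else 1
    labels = measure.label(keep, connectivity=conn)
    if labels.max() == 0:
        return np.zeros_like(keep)
    out = np.zeros_like(keep)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size < params.min_cluster_voxels:
            continue
        if vol.values[comp].mean() < params.intensity_floor:
            continue
        out |= comp
    return out


def extract_brain(vol: CTVolume,
                  params: DualClusterParams = DEFAULT_BRAIN_PARAMS
                  ) -> np.ndarray:
    """Extract brain tissue from the skull: soft-tissue dual-clustering
    followed by keeping the single largest connected component."""
    mask = dual_cluster_segment(vol, params)
    conn = 3 if params.connectivity == 26 else 1
    labels = measure.label(mask, connectivity=conn)
    if labels.max() == 0:
        raise NoBrainError("no soft-tissue component found")
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def segment_edema(vol: CTVolume, hemorrhage: np.ndarray, brain: np.ndarray,
                  dilation_limit: int = DEFAULT_DILATION_LIMIT,
                  edema_params: DualClusterParams = DEFAULT_EDEMA_PARAMS
                  ) -> np.ndarray:
    """Segment perihematomal edema around a hemorrhage core.

    The hemorrhage is dilated ``dilation_limit`` times with a 6-connected
    structuring element; the dilated shell minus the core, restricted to
    brain, forms the candidate ring which is refined by a dual-clustering
    pass with edema HU.  The result is disjoint from the hemorrhage by
    construction.
    """
    hemorrhage = np.asarray(hemorrhage, dtype=bool)
    brain = np.asarray(brain, dtype=bool)
    if not hemorrhage.any():
        raise NoLesionError("hemorrhage mask is empty")
    if dilation_limit < 1:
        raise DomainError("dilation_limit must be >= 1")
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connected
    dilated = ndimage.binary_dilation(hemorrhage, structure=struct,
                                      iterations=dilation_limit)
    ring = dilated & ~hemorrhage & brain
    return dual_cluster_segment(vol, edema_params, within=ring)


def mask_volume(mask: np.ndarray,
                voxel_size: tuple[float, float, float]) -> float:
    """Volume of a binary mask in ml from the voxel geometry in mm."""
    dz, dy, dx = voxel_size
    return float(np.asarray(mask, dtype=bool).sum()) * dz * dy * dx / 1000.0


def segment_pipeline(vol: CTVolume,
                     brain_params: DualClusterParams = DEFAULT_BRAIN_PARAMS,
                     hemorrhage_params: DualClusterParams = DEFAULT_HEMORRHAGE_PARAMS,
                     edema_params: DualClusterParams = DEFAULT_EDEMA_PARAMS,
                     dilation_limit: int = DEFAULT_DILATION_LIMIT
                     ) -> SegmentationMasks:
    """Full semiautomated pipeline: brain, then hemorrhage inside brain,
    then edema in the dilated ring.  Invariants (containment within brain,
    hemorrhage/edema disjointness) are asserted at construction."""
    brain = extract_brain(vol, brain_params)
    hemorrhage = dual_cluster_segment(vol, hemorrhage_params, within=brain)
    if not hemorrhage.any():
        raise NoLesionError("no hemorrhage component inside brain")
    edema = segment_edema(vol, hemorrhage, brain, dilation_limit, edema_params)
    prov = {
        "brain": vars(brain_params).copy(),
        "hemorrhage": vars(hemorrhage_params).copy(),
        "edema": vars(edema_params).copy(),
        "dilation_limit": dilation_limit,
    }
    return SegmentationMasks(brain, hemorrhage, edema, prov)


# --------------------------------------------------------------- NIfTI I/O

def load_nifti(path: str | Path) -> CTVolume:
    """Read a CT volume from NIfTI; voxel sizes come from the header zooms
    and the data array is used in (slice, row, column) order as stored."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return CTVolume(values=data, voxel_size=(float(zooms[0]),
                                             float(zooms[1]),
                                             float(zooms[2])))


def save_nifti(vol_or_mask: np.ndarray | CTVolume,
               voxel_size: tuple[float, float, float] | None,
               path: str | Path) -> None:
    """Write a volume or mask as NIfTI with a diagonal affine from the
    voxel size."""
    if isinstance(vol_or_mask, CTVolume):
        data, vs = vol_or_mask.values, vol_or_mask.voxel_size
    else:
        data, vs = np.asarray(vol_or_mask), voxel_size
        if vs is None:
            raise DomainError("voxel_size required when saving a bare array")
    affine = np.diag([vs[0], vs[1], vs[2], 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
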