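"""Candidate-cell selection and masked-nucleus input construction.

The cell-by-cell network analyses one nucleus at a time: the well is
cropped around each candidate nucleus and the crop's middle channel is
replaced by the binary mask of that nucleus alone, prompting the network
to segment only that cell's sheaths.  Candidates are nuclei whose centroid
falls inside a membrane "blob" (binarized, morphologically closed then
opened membrane staining) — nuclei with no membrane signal nearby belong
to clearly non-ensheathing, unstained cells and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation
from skimage.filters import threshold_otsu

from .image_io import LabelMask, WellImage

__all__ = [
    "CandidateParams",
    "CandidateCell",
    "MaskedInput",
    "detect_nuclei",
    "filter_candidates",
    "build_masked_input",
    "build_training_set",
]


@dataclass
class CandidateParams:
    nucleus_min_area_um2: float = 15.0
    binarize_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.5
    close_radius_um: float = 2.0
    open_radius_um: float = 2.0
    crop_size_px: int = 256

    def __post_init__(self) -> None:
        if self.binarize_method not in ("otsu", "fixed"):
            raise ValueError("binarize_method must be 'otsu' or 'fixed'")
        if self.close_radius_um <= 0 or self.open_radius_um <= 0:
            raise ValueError("morphology radii must be positive")
        if self.crop_size_px < 2 or self.crop_size_px % 2:
            raise ValueError("crop_size_px must be even and >= 2")


@dataclass
class CandidateCell:
    cell_id: int
    centroid: tuple[float, float]  # (y, x) px
    nucleus_mask: np.ndarray  # full-frame binary raster


@dataclass
class MaskedInput:
    """3-channel crop: (membrane, nucleus-of-interest mask, all nuclei).

    ``crop`` has shape (3, crop_size, crop_size); channel 1 is the binary
    mask of exactly one nucleus, on which the crop is centered.  Other
    nuclei remain visible only in channel 2.  ``offset`` is the (y, x) of
    the crop's top-left corner in well coordinates (may be negative at
    borders, where the crop is zero-padded).
    """

    crop: np.ndarray
    well: str
    cell_id: int
    offset: tuple[int, int]


def _binarize(raster: np.ndarray, params: CandidateParams) -> np.ndarray:
    raster = np.asarray(raster, dtype=float)
    if params.binarize_method == "fixed":
        return raster > params.fixed_threshold
    if raster.max() <= raster.min():
        return np.zeros(raster.shape, dtype=bool)
    return raster > threshold_otsu(raster)


def detect_nuclei(nuclei_raster: np.ndarray,
                  params: CandidateParams | None = None,
                  pixel_size_um: float = 0.5) -> LabelMask:
    """Watershed detection of stained nuclei.

    Binarize, fill holes, split touching nuclei by a watershed on the
    distance transform seeded at suppressed local maxima, and drop
    components smaller than ``nucleus_min_area_um2``.
    """
    params = params or CandidateParams()
    raster = np.asarray(nuclei_raster, dtype=float)
    if raster.ndim != 2:
        raise ValueError("expected a 2-D nuclei raster")
    fg = ndi.binary_fill_holes(_binarize(raster, params))
    if not fg.any():
        return LabelMask(np.zeros(raster.shape, dtype=np.uint16))
    dist = ndi.distance_transform_edt(fg)
    # h-maxima at half a typical nucleus radius suppress spurious peaks
    h = max(0.5 * np.sqrt(params.nucleus_min_area_um2 / np.pi)
            / pixel_size_um, 1.0)
    peaks = morphology.h_maxima(dist, h)
    markers, _ = ndi.label(peaks, structure=np.ones((3, 3)))
    ws = segmentation.watershed(-dist, markers, mask=fg)

    min_px = params.nucleus_min_area_um2 / pixel_size_um ** 2
    out = np.zeros(raster.shape, dtype=np.uint16)
    next_id = 1
    for region in measure.regionprops(ws):
        if region.area < min_px:
            continue
        out[ws == region.label] = next_id
        next_id += 1
    return LabelMask(out)


def filter_candidates(nuclei: LabelMask, membrane_raster: np.ndarray,
                      params: CandidateParams | None = None,
                      pixel_size_um: float = 0.5) -> list[CandidateCell]:
    """Keep nuclei whose centroid lies inside a membrane blob.

    Blobs come from binarizing the membrane raster, then morphological
    closing followed by opening.  Cells with zero membrane staining near
    the nucleus are excluded from downstream analysis.
    """
    params = params or CandidateParams()
    membrane = np.asarray(membrane_raster, dtype=float)
    if membrane.shape != nuclei.shape:
        raise ValueError("membrane raster and nuclei mask shape mismatch")
    fg = _binarize(membrane, params)
    close_r = max(int(round(params.close_radius_um / pixel_size_um)), 1)
    open_r = max(int(round(params.open_radius_um / pixel_size_um)), 1)
    blobs = morphology.closing(fg, morphology.disk(close_r))
    blobs = morphology.opening(blobs, morphology.disk(open_r))

    out: list[CandidateCell] = []
    for region in measure.regionprops(nuclei.raster):
        cy, cx = region.centroid
        if blobs[int(round(cy)), int(round(cx))]:
            out.append(CandidateCell(
                cell_id=int(region.label), centroid=(cy, cx),
                nucleus_mask=nuclei.raster == region.label))
    return out


def _crop_window(centroid: tuple[float, float], crop: int,
                 shape: tuple[int, int]):
    """Crop geometry: returns offset and source/destination slices."""
    cy, cx = int(round(centroid[0])), int(round(centroid[1]))
    oy, ox = cy - crop // 2, cx - crop // 2
    src_y = slice(max(oy, 0), min(oy + crop, shape[0]))
    src_x = slice(max(ox, 0), min(ox + crop, shape[1]))
    dst_y = slice(src_y.start - oy, src_y.stop - oy)
    dst_x = slice(src_x.start - ox, src_x.stop - ox)
    return (oy, ox), (src_y, src_x), (dst_y, dst_x)


def build_masked_input(image: WellImage, cand: CandidateCell,
                       crop_size_px: int = 256) -> MaskedInput:
    """Crop the well around one candidate and mask its nucleus.

    The crop is centered on the (rounded) nucleus centroid and zero-padded
    where it extends past the image border.  Channel order: membrane,
    nucleus-of-interest binary mask, nuclei stain.
    """
    if not cand.nucleus_mask.any():
        raise ValueError("candidate has an empty nucleus mask")
    h, w = image.shape
    (oy, ox), (sy, sx), (dy, dx) = _crop_window(cand.centroid, crop_size_px,
                                                (h, w))
    crop = np.zeros((3, crop_size_px, crop_size_px), dtype=np.float32)
    crop[0, dy, dx] = image.channels["membrane"][sy, sx]
    crop[1, dy, dx] = cand.nucleus_mask[sy, sx]
    crop[2, dy, dx] = image.channels["nuclei"][sy, sx]
    return MaskedInput(crop=crop, well=image.name, cell_id=cand.cell_id,
                       offset=(oy, ox))


def build_training_set(
    image: WellImage,
    truth: tuple[LabelMask, LabelMask],
    params: CandidateParams | None = None,
) -> list[tuple[MaskedInput, np.ndarray]]:
    """One (masked input, binary truth crop) example per traced nucleus.

    ``truth`` is the (nuclei, sheaths) label-mask pair sharing cell
    labels.  The truth crop contains only that cell's sheath label, in the
    same window as the input; cells without sheaths yield all-zero truth
    crops (negative examples).
    """
    params = params or CandidateParams()
    nuclei_t, sheaths_t = truth
    if nuclei_t.shape != sheaths_t.shape or nuclei_t.shape != image.shape:
        raise ValueError("truth masks and image must share one shape")
    extra = set(sheaths_t.labels) - set(nuclei_t.labels)
    if extra:
        raise ValueError(f"sheath labels with no nucleus label: {extra}")

    crop = params.crop_size_px
    examples: list[tuple[MaskedInput, np.ndarray]] = []
    for region in measure.regionprops(nuclei_t.raster):
        cand = CandidateCell(cell_id=int(region.label),
                             centroid=region.centroid,
                             nucleus_mask=nuclei_t.raster == region.label)
        x = build_masked_input(image, cand, crop)
        (oy, ox), (sy, sx), (dy, dx) = _crop_window(region.centroid, crop,
                                                    image.shape)
        y = np.zeros((crop, crop), dtype=np.float32)
        y[dy, dx] = sheaths_t.raster[sy, sx] == region.label
        examples.append((x, y))
    return examples
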