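"""Post-inference operators resolving per-cell sheath assignment.

Three operators clean raw per-cell segmentations:

* :func:`resolve_overlaps` — "unfair distribution": a sheath component
  claimed by several cells is handed wholly to the claimant with the
  larger total sheath area, on the premise that an ambiguous segment more
  likely belongs to a heavily ensheathing cell than to a single-sheath one.
* :func:`remove_sticky` — skeleton branch pruning that severs spurious
  cross-fiber bridges ("sticky connections") between adjacent sheaths
  while restoring along-fiber connectivity through re-inserted branch
  points.
* :func:`filter_by_length` — drops sheaths below the 12 µm scoring floor,
  then applies a three-to-four-times stricter floor to cells left with
  only one or two sheaths (guarding against the false positives human
  non-experts tend to produce on sparsely ensheathing cells).

Lengths are the moment-equivalent major axis: ``sqrt(12·lambda_max + 1)``
pixels, where ``lambda_max`` is the largest eigenvalue of the pixel-set
covariance.  For an N-pixel straight bar this equals N exactly, and for a
single pixel it equals 1, so measured lengths agree with end-to-end
physical extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

__all__ = [
    "PostParams",
    "SheathRecord",
    "resolve_overlaps",
    "remove_sticky",
    "measure_length",
    "filter_by_length",
    "records_from_labels",
    "postprocess_cells",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class PostParams:
    min_length_um: float = 12.0
    strict_multiplier: float = 3.0  # lenient end of the 3–4x strict rule
    fiber_axis: str = "vertical"
    reconstruct_radius_px: int = 6

    def __post_init__(self) -> None:
        if self.min_length_um <= 0:
            raise ValueError("min_length_um must be positive")
        if self.strict_multiplier < 1:
            raise ValueError("strict_multiplier must be >= 1")
        if self.fiber_axis not in ("vertical", "horizontal"):
            raise ValueError("fiber_axis must be 'vertical' or 'horizontal'")


@dataclass
class SheathRecord:
    cell_id: int
    sheath_id: int
    pixels: np.ndarray  # (n, 2) row/col coordinates, 8-connected set
    length_um: float
    centroid: tuple[float, float] = field(default=(np.nan, np.nan))


# ---------------------------------------------------------------------------
# unfair distribution
# ---------------------------------------------------------------------------

def resolve_overlaps(
    per_cell_masks: dict[int, np.ndarray]
) -> dict[int, np.ndarray]:
    """Make per-cell sheath masks pairwise disjoint by unfair distribution.

    Each connected component of the union that is claimed by two or more
    cells is assigned wholly to the claimant with the larger total sheath
    pixel area; exact ties go to the lower cell id.  The result is
    independent of dict ordering.
    """
    if not per_cell_masks:
        return {}
    ids = sorted(per_cell_masks)
    shape = per_cell_masks[ids[0]].shape
    masks = {c: np.asarray(per_cell_masks[c], dtype=bool) for c in ids}
    if any(m.shape != shape for m in masks.values()):
        raise ValueError("per-cell masks must share one shape")

    union = np.zeros(shape, dtype=bool)
    for m in masks.values():
        union |= m
    comp, n_comp = ndi.label(union, structure=_EIGHT)
    if n_comp == 0:
        return {c: m.copy() for c, m in masks.items()}

    area = {c: int(m.sum()) for c, m in masks.items()}
    # claimants per component
    claimants: dict[int, list[int]] = {}
    for c in ids:
        for comp_id in np.unique(comp[masks[c]]):
            claimants.setdefault(int(comp_id), []).append(c)

    out = {c: m.copy() for c, m in masks.items()}
    for comp_id, cs in claimants.items():
        if len(cs) < 2:
            continue
        winner = max(cs, key=lambda c: (area[c], -c))
        comp_mask = comp == comp_id
        for c in cs:
            if c == winner:
                out[c][comp_mask] = True
            else:
                out[c][comp_mask] = False
    return out


# ---------------------------------------------------------------------------
# sticky removal
# ---------------------------------------------------------------------------

def _branch_extent_keep(rows: np.ndarray, cols: np.ndarray,
                        fiber_axis: str) -> bool:
    """A branch is kept iff its along-fiber extent >= cross-fiber extent."""
    row_span = rows.max() - rows.min() + 1
    col_span = cols.max() - cols.min() + 1
    along, across = ((row_span, col_span) if fiber_axis == "vertical"
                     else (col_span, row_span))
    return along >= across


def remove_sticky(mask: np.ndarray, params: PostParams) -> np.ndarray:
    """Sever cross-fiber bridges between adjacent sheaths.

    The mask is skeletonized; branch points (skeleton pixels with three or
    more skeleton neighbours) are removed; each remaining skeletal branch
    is deleted when its extent perpendicular to the fiber axis exceeds its
    extent along it; branch-point clusters adjacent to at least two
    retained branches are re-inserted to restore along-fiber connectivity.
    Finally every mask pixel is kept iff its nearest skeleton pixel
    (within ``reconstruct_radius_px``) is retained.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    skel = morphology.skeletonize(mask)
    if not skel.any():
        return np.zeros_like(mask)

    nb = ndi.convolve(skel.astype(int), _EIGHT, mode="constant") - 1
    branch_pts = skel & (nb >= 3)
    branches = skel & ~branch_pts
    blab, nb_branches = ndi.label(branches, structure=_EIGHT)

    keep = np.zeros(nb_branches + 1, dtype=bool)
    for b in range(1, nb_branches + 1):
        rows, cols = np.nonzero(blab == b)
        keep[b] = _branch_extent_keep(rows, cols, params.fiber_axis)

    retained = np.isin(blab, np.flatnonzero(keep[1:]) + 1)

    # re-insert branch-point clusters touching >=2 retained branches
    bp_lab, n_bp = ndi.label(branch_pts, structure=_EIGHT)
    reinserted = np.zeros_like(branch_pts)
    for k in range(1, n_bp + 1):
        cluster = bp_lab == k
        halo = ndi.binary_dilation(cluster, structure=_EIGHT)
        touching = np.unique(blab[halo & retained])
        if len(touching[touching > 0]) >= 2:
            reinserted |= cluster

    good_skel = retained | reinserted
    if not good_skel.any():
        return np.zeros_like(mask)

    # reconstruct: each mask pixel follows its nearest skeleton pixel
    _, (iy, ix) = ndi.distance_transform_edt(~skel, return_indices=True)
    near_good = good_skel[iy, ix]
    dist_good = ndi.distance_transform_edt(~good_skel)
    out = mask & near_good & (dist_good <= params.reconstruct_radius_px)
    return out


# ---------------------------------------------------------------------------
# length measurement and filtering
# ---------------------------------------------------------------------------

def measure_length(pixel_set: np.ndarray, pixel_size_um: float) -> float:
    """Moment-equivalent major-axis length of a pixel set, in µm.

    Computes the largest eigenvalue of the second central moments of the
    pixel coordinates and returns ``sqrt(12·lambda_max + 1)`` pixels
    scaled to µm — exact for axis-aligned bars and rotation-invariant to
    within discretization error.
    """
    coords = np.asarray(pixel_set, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) == 0:
        raise ValueError("pixel_set must be a non-empty (n, 2) array")
    if len(coords) == 1:
        return float(pixel_size_um)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    lam_max = float(np.linalg.eigvalsh(cov)[-1])
    return float(np.sqrt(12.0 * lam_max + 1.0) * pixel_size_um)


def records_from_labels(cell_id: int, sheath_labels: np.ndarray,
                        pixel_size_um: float) -> list[SheathRecord]:
    """Build sheath records from a labeled raster of one cell's sheaths."""
    records = []
    objects = ndi.find_objects(sheath_labels)
    for sheath_id, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = sheath_labels[sl] == sheath_id
        rows, cols = np.nonzero(sub)
        coords = np.column_stack([rows + sl[0].start, cols + sl[1].start])
        records.append(SheathRecord(
            cell_id=cell_id, sheath_id=sheath_id, pixels=coords,
            length_um=measure_length(coords, pixel_size_um),
            centroid=tuple(coords.mean(axis=0)),
        ))
    return records


def filter_by_length(cell_sheaths: list[SheathRecord],
                     params: PostParams) -> list[SheathRecord]:
    """Two-pass length filter.

    Pass 1 drops every sheath shorter than ``min_length_um``.  Pass 2
    re-counts the survivors per cell and, for cells left with one or two
    sheaths, additionally requires ``strict_multiplier × min_length_um``.
    Cells with no surviving sheath are non-ensheathing.  Idempotent.
    """
    survivors = [r for r in cell_sheaths if r.length_um >= params.min_length_um]
    by_cell: dict[int, list[SheathRecord]] = {}
    for r in survivors:
        by_cell.setdefault(r.cell_id, []).append(r)
    strict = params.strict_multiplier * params.min_length_um
    out: list[SheathRecord] = []
    for cell_id in sorted(by_cell):
        recs = by_cell[cell_id]
        if len(recs) <= 2:
            recs = [r for r in recs if r.length_um >= strict]
        out.extend(recs)
    return out


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def postprocess_cells(per_cell_masks: dict[int, np.ndarray],
                      params: PostParams,
                      pixel_size_um: float) -> dict[int, list[SheathRecord]]:
    """Apply the three operators in order on per-cell well-coordinate masks.

    Overlap resolution first (so sticky removal sees disjoint cells), then
    per-cell sticky removal, then the two-pass length filter.  Returns the
    surviving sheath records per cell (cells whose sheaths all fail the
    filters are omitted).
    """
    disjoint = resolve_overlaps(per_cell_masks)
    all_records: list[SheathRecord] = []
    for cell_id in sorted(disjoint):
        cleaned = remove_sticky(disjoint[cell_id], params)
        lab, _ = ndi.label(cleaned, structure=_EIGHT)
        all_records.extend(records_from_labels(cell_id, lab, pixel_size_um))
    kept = filter_by_length(all_records, params)
    out: dict[int, list[SheathRecord]] = {}
    for r in kept:
        out.setdefault(r.cell_id, []).append(r)
    return out
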