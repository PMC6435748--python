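"""Per-cell and per-well morphology, Jaccard evaluation, and power scaling.

Morphology is summarized per cell (sheath count, lengths, mean sheath
length per cell — mSLC) and per well (means ± SEM over cells, pooled
log10 lengths over sheaths).  Sheath lengths are analysed on the log10
scale because their distribution is log-normal.

Segmentations are compared by the Jaccard index, per commonly identified
cell (nuclei paired by centroid proximity) and globally over the union of
all per-cell masks.  :func:`min_detectable_difference` carries the
1/sqrt(n) scaling of the two-sample minimum detectable difference at
fixed power and significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .heuristic import CellSegmentation
from .postprocess import SheathRecord

__all__ = [
    "CellMorphology",
    "WellSummary",
    "JIReport",
    "jaccard",
    "per_cell_ji",
    "global_ji",
    "morphology_from_records",
    "summarize_well",
    "min_detectable_difference",
    "compare_groups",
]


@dataclass
class CellMorphology:
    cell_id: int
    lengths_um: list[float]

    @property
    def n_sheaths(self) -> int:
        return len(self.lengths_um)

    @property
    def ensheathing(self) -> bool:
        return self.n_sheaths >= 1

    @property
    def mean_length_um(self) -> float:
        return float(np.mean(self.lengths_um)) if self.lengths_um else np.nan

    @property
    def log10_lengths(self) -> list[float]:
        return [float(np.log10(v)) for v in self.lengths_um]


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.nan, np.nan
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) \
        if values.size > 1 else np.nan
    return mean, sem


@dataclass
class WellSummary:
    """Per-well aggregates: means ± SEM over cells (counts, mSLC) and over
    pooled sheaths (log10 lengths)."""

    n_candidates: int
    n_ensheathing_cells: int
    sheaths_per_cell_mean: float
    sheaths_per_cell_sem: float
    mslc_mean: float
    mslc_sem: float
    log10_length_mean: float
    log10_length_sem: float
    n_sheaths: int
    log10_lengths: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.n_ensheathing_cells > self.n_candidates:
            raise ValueError("more ensheathing cells than candidates")


def morphology_from_records(
    records: dict[int, list[SheathRecord]]
) -> list[CellMorphology]:
    return [CellMorphology(cell_id, [r.length_um for r in recs])
            for cell_id, recs in sorted(records.items())]


def summarize_well(cells: list[CellMorphology],
                   n_candidates: int) -> WellSummary:
    """Aggregate per-cell morphologies into one well summary."""
    ensheathing = [c for c in cells if c.ensheathing]
    counts = np.array([c.n_sheaths for c in ensheathing], dtype=float)
    mslc = np.array([c.mean_length_um for c in ensheathing], dtype=float)
    logs = [v for c in ensheathing for v in c.log10_lengths]
    spc_mean, spc_sem = _mean_sem(counts)
    mslc_mean, mslc_sem = _mean_sem(mslc)
    log_mean, log_sem = _mean_sem(np.asarray(logs))
    return WellSummary(
        n_candidates=n_candidates,
        n_ensheathing_cells=len(ensheathing),
        sheaths_per_cell_mean=spc_mean, sheaths_per_cell_sem=spc_sem,
        mslc_mean=mslc_mean, mslc_sem=mslc_sem,
        log10_length_mean=log_mean, log10_length_sem=log_sem,
        n_sheaths=len(logs), log10_lengths=list(map(float, logs)),
    )


# ---------------------------------------------------------------------------
# Jaccard evaluation
# ---------------------------------------------------------------------------

def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; 1.0 when both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _ji_flat(idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    union = len(np.union1d(idx_a, idx_b))
    if union == 0:
        return 1.0
    return len(np.intersect1d(idx_a, idx_b)) / union


@dataclass
class JIReport:
    per_cell: list[dict]
    global_ji: float
    pairing_radius_um: float
    n_ref: int
    n_test: int
    n_paired: int

    @property
    def mean_ji(self) -> float:
        if not self.per_cell:
            return np.nan
        return float(np.mean([r["ji"] for r in self.per_cell]))

    @property
    def median_ji(self) -> float:
        if not self.per_cell:
            return np.nan
        return float(np.median([r["ji"] for r in self.per_cell]))


def per_cell_ji(ref: list[CellSegmentation], test: list[CellSegmentation],
                pairing_radius_um: float = 10.0,
                pixel_size_um: float = 0.5) -> JIReport:
    """Pair cells by nucleus proximity and score each pair's overlap.

    Pairing is greedy closest-first and one-to-one within
    ``pairing_radius_um``; unpaired cells are excluded from the per-cell
    list but counted in the report.  The global JI compares the unions of
    all per-cell masks.
    """
    radius_px = pairing_radius_um / pixel_size_um
    pairs: list[tuple[float, int, int]] = []
    for i, r in enumerate(ref):
        for j, t in enumerate(test):
            d = float(np.hypot(r.nucleus_centroid[0] - t.nucleus_centroid[0],
                               r.nucleus_centroid[1] - t.nucleus_centroid[1]))
            if d <= radius_px:
                pairs.append((d, i, j))
    pairs.sort()
    used_r: set[int] = set()
    used_t: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_r or j in used_t:
            continue
        used_r.add(i)
        used_t.add(j)
        matched.append((i, j))

    per_cell = [
        dict(cell_id_ref=ref[i].cell_id, cell_id_test=test[j].cell_id,
             ji=_ji_flat(ref[i].pixel_indices, test[j].pixel_indices))
        for i, j in sorted(matched)
    ]
    return JIReport(per_cell=per_cell, global_ji=global_ji(ref, test),
                    pairing_radius_um=pairing_radius_um,
                    n_ref=len(ref), n_test=len(test), n_paired=len(matched))


def global_ji(ref: list[CellSegmentation],
              test: list[CellSegmentation]) -> float:
    """Jaccard of the unions of all per-cell masks across the whole well."""
    if not ref and not test:
        return 1.0
    ref_idx = (np.unique(np.concatenate([c.pixel_indices for c in ref]))
               if ref else np.empty(0, dtype=np.int64))
    test_idx = (np.unique(np.concatenate([c.pixel_indices for c in test]))
                if test else np.empty(0, dtype=np.int64))
    return _ji_flat(ref_idx, test_idx)


# ---------------------------------------------------------------------------
# power scaling and group comparison
# ---------------------------------------------------------------------------

def min_detectable_difference(n: int, n_ref: int,
                              delta_ref: float) -> float:
    """Minimum detectable difference at sample size n, scaled from a
    reference: ``delta_ref * sqrt(n_ref / n)``.

    At fixed power and significance the two-sample minimum detectable
    difference scales as 1/sqrt(n), so a benchmark (n_ref, delta_ref)
    fixes the whole curve.
    """
    if n <= 1 or n_ref <= 1:
        raise ValueError("sample sizes must exceed 1")
    if delta_ref <= 0:
        raise ValueError("delta_ref must be positive")
    return float(delta_ref * np.sqrt(n_ref / n))


def compare_groups(a: list[WellSummary],
                   b: list[WellSummary]) -> pd.DataFrame:
    """Effect table between two groups of wells.

    For sheaths/cell and pooled log10 length: difference of group means
    (mean of well means, b − a) ± combined SEM, with a Welch t-test
    p-value over well means passed through from standard routines (NaN
    when either group has a single well).
    """
    if not a or not b:
        raise ValueError("both groups need at least one well")

    def row(metric: str, attr_mean: str, attr_sem: str) -> dict:
        ma = np.array([getattr(w, attr_mean) for w in a], dtype=float)
        mb = np.array([getattr(w, attr_mean) for w in b], dtype=float)
        mean_a, sem_a = _mean_sem(ma)
        mean_b, sem_b = _mean_sem(mb)
        if len(ma) == 1:
            sem_a = float(getattr(a[0], attr_sem))
        if len(mb) == 1:
            sem_b = float(getattr(b[0], attr_sem))
        if len(ma) > 1 and len(mb) > 1:
            p = float(stats.ttest_ind(mb, ma, equal_var=False).pvalue)
        else:
            p = np.nan
        return dict(metric=metric, mean_a=mean_a, mean_b=mean_b,
                    difference=mean_b - mean_a,
                    sem=float(np.sqrt(np.nansum([sem_a ** 2, sem_b ** 2]))),
                    p_value=p)

    return pd.DataFrame([
        row("sheaths_per_cell", "sheaths_per_cell_mean",
            "sheaths_per_cell_sem"),
        row("mslc_um", "mslc_mean", "mslc_sem"),
        row("log10_length", "log10_length_mean", "log10_length_sem"),
    ])
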