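"""Nucleus-to-myotube assignment, differentiation/fusion indices, and statistics.

Definitions
-----------
With N the total number of segmented nuclei in an image,

* **MDI** (myogenic differentiation index) is the fraction of all nuclei
  whose centroid lies inside a myosin-heavy-chain-positive (MF20+)
  myotube ROI: ``MDI = n_inside / N``.
* **MFI** (myogenic fusion index) is the fraction of all nuclei residing
  in *multinucleated* MF20+ objects, i.e. objects holding at least
  ``mfi_min_nuclei`` (default 2) nuclei.  Mononucleated MF20+ objects are
  reported as a reference bin of the per-object nucleus-count histogram,
  so either denominator convention (all nuclei, or MF20+ nuclei only) can
  be recovered from the emitted tables.

Group comparison uses a two-sided unpaired Student t test (pooled
variance) on per-replicate index values.  A ddCt utility converts qPCR
cycle thresholds against a housekeeping reference into fold induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .imageproc import LabelMap
from .segmentation import PipelineParams

__all__ = [
    "NucleusRecord",
    "MyotubeRecord",
    "QuantResult",
    "GroupComparison",
    "QpcrSample",
    "assign_nuclei",
    "myotube_records",
    "compute_indices",
    "compare_groups",
    "delta_delta_ct",
]


@dataclass
class NucleusRecord:
    """One segmented nucleus: centroid, area and the ROI it falls in (0 = none)."""

    nucleus_id: int
    centroid: Tuple[float, float]
    area_px: float
    myotube_id: int


@dataclass
class MyotubeRecord:
    """One myotube ROI with its area and the number of nuclei assigned to it."""

    myotube_id: int
    area_px: float
    n_nuclei: int


@dataclass
class QuantResult:
    """Per-image quantification: totals, MDI, MFI and the nucleus-count histogram."""

    n_total: int
    n_inside: int
    n_outside: int
    mdi: float
    mfi: float
    histogram: Dict[str, int]
    params_echo: PipelineParams
    empty_warning: bool = False

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["params_echo"] = asdict(self.params_echo)
        return d


@dataclass
class GroupComparison:
    """Two-sided unpaired Student t test between two groups of index values."""

    group_a_values: List[float]
    group_b_values: List[float]
    t_statistic: float
    p_value: float
    mean_difference: float


@dataclass
class QpcrSample:
    """Cycle thresholds for a target gene and the housekeeping reference (18S)."""

    ct_target: float
    ct_reference: float
    condition: str = ""

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not np.isfinite(v) or v <= 0:
                raise ValueError("cycle threshold values must be finite and > 0")


def assign_nuclei(nuclei: LabelMap, myotubes: LabelMap) -> List[NucleusRecord]:
    """Assign each nucleus to the myotube ROI under its rounded centroid.

    ``myotube_id`` is the myotube label at the nucleus centroid pixel
    (0 when the centroid lies on background), so every nucleus is counted
    exactly once and ``n_inside + n_outside == n_total`` holds by
    construction.
    """
    if nuclei.shape != myotubes.shape:
        raise ValueError(f"shape mismatch: nuclei {nuclei.shape} vs myotubes {myotubes.shape}")
    records: List[NucleusRecord] = []
    if nuclei.n_labels == 0:
        return records
    index = np.arange(1, nuclei.n_labels + 1)
    centroids = ndi_center_of_mass(nuclei.raster, index)
    areas = np.bincount(nuclei.raster.ravel(), minlength=nuclei.n_labels + 1)[1:]
    for nid, (r, c), area in zip(index, centroids, areas):
        rr = int(round(r))
        cc = int(round(c))
        rr = min(max(rr, 0), nuclei.shape[0] - 1)
        cc = min(max(cc, 0), nuclei.shape[1] - 1)
        records.append(NucleusRecord(
            nucleus_id=int(nid), centroid=(float(r), float(c)),
            area_px=float(area), myotube_id=int(myotubes.raster[rr, cc])))
    return records


def ndi_center_of_mass(labels: np.ndarray, index: np.ndarray) -> List[Tuple[float, float]]:
    from scipy import ndimage as ndi

    return ndi.center_of_mass(labels > 0, labels, index)


def myotube_records(myotubes: LabelMap, nuclei: Sequence[NucleusRecord]) -> List[MyotubeRecord]:
    """Per-ROI area and nucleus count derived from an assignment."""
    counts = {k: 0 for k in range(1, myotubes.n_labels + 1)}
    for n in nuclei:
        if n.myotube_id:
            counts[n.myotube_id] += 1
    areas = np.bincount(myotubes.raster.ravel(), minlength=myotubes.n_labels + 1)
    return [MyotubeRecord(myotube_id=k, area_px=float(areas[k]), n_nuclei=counts[k])
            for k in range(1, myotubes.n_labels + 1)]


def _bin_label(edges: Sequence[int], i: int) -> str:
    lo = edges[i]
    if i + 1 < len(edges):
        hi = edges[i + 1] - 1
        return str(lo) if hi == lo else f"{lo}-{hi}"
    return f">={lo}"


def compute_indices(nuclei: Sequence[NucleusRecord], myotubes: Sequence[MyotubeRecord],
                    params: PipelineParams) -> QuantResult:
    """Compute MDI, MFI and the nuclei-per-myotube histogram for one image.

    An image without nuclei yields MDI = MFI = 0 with ``empty_warning``
    set rather than an exception.
    """
    n_total = len(nuclei)
    if any(m.n_nuclei < 0 for m in myotubes):
        raise ValueError("negative nucleus counts are invalid")
    counts_by_tube = {m.myotube_id: m.n_nuclei for m in myotubes}
    assigned = [n for n in nuclei if n.myotube_id]
    for n in assigned:
        if n.myotube_id not in counts_by_tube:
            raise ValueError(f"nucleus {n.nucleus_id} assigned to unknown myotube {n.myotube_id}")
    n_inside = len(assigned)
    n_outside = n_total - n_inside
    n_fused = sum(1 for n in assigned if counts_by_tube[n.myotube_id] >= params.mfi_min_nuclei)

    edges = list(params.histogram_bins)
    histogram = {_bin_label(edges, i): 0 for i in range(len(edges))}
    for m in myotubes:
        if m.n_nuclei < edges[0]:
            continue
        i = int(np.searchsorted(edges, m.n_nuclei, side="right")) - 1
        histogram[_bin_label(edges, i)] += 1

    if n_total == 0:
        return QuantResult(0, 0, 0, 0.0, 0.0, histogram, params, empty_warning=True)
    return QuantResult(
        n_total=n_total, n_inside=n_inside, n_outside=n_outside,
        mdi=n_inside / n_total, mfi=n_fused / n_total,
        histogram=histogram, params_echo=params)


def compare_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sided unpaired Student t test (pooled variance) between two groups.

    Degenerate case: zero pooled variance with equal means gives
    ``t = 0, p = 1``.
    """
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    mean_diff = float(np.mean(a) - np.mean(b))
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if mean_diff == 0:
            return GroupComparison(a, b, 0.0, 1.0, 0.0)
        # all variance in the mean difference: infinitely significant
        return GroupComparison(a, b, float(np.sign(mean_diff)) * np.inf, 0.0, mean_diff)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(a, b, float(t), float(p), mean_diff)


def delta_delta_ct(treated: QpcrSample, control: QpcrSample) -> float:
    """Fold induction by the ddCt method: ``2 ** -(dCt_treated - dCt_control)``.

    ``dCt = Ct_target - Ct_reference`` within each condition; the
    reference is a housekeeping gene (18S rRNA in the assay this mirrors).
    """
    d_treated = treated.ct_target - treated.ct_reference
    d_control = control.ct_target - control.ct_reference
    return float(2.0 ** (-(d_treated - d_control)))
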