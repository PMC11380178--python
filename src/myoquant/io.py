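"""Reading micrographs, QC overlay rendering, batch orchestration.

Micrographs come in as multichannel TIFFs; the channel axis is detected
as the axis of length <= 4 (channel-first or channel-last).  Outputs are
interoperable text/standard formats: CSV tables, JSON summaries, 16-bit
TIFF label maps and PNG overlays.  Every table and summary embeds the
full parameter echo so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .imageproc import LabelMap, Micrograph, binary_dilate
from .quantify import (
    NucleusRecord,
    QuantResult,
    assign_nuclei,
    compare_groups,
    compute_indices,
    myotube_records,
)
from .segmentation import PipelineParams, segment_myotubes, segment_nuclei

__all__ = [
    "ChannelCountError",
    "ChannelRoleError",
    "RunConfig",
    "read_micrograph",
    "write_micrograph",
    "write_labelmap",
    "render_overlay",
    "run_pipeline",
]

logger = logging.getLogger("myoquant")


class ChannelCountError(ValueError):
    """TIFF does not contain at least two channels."""


class ChannelRoleError(ValueError):
    """A channel role maps to an index outside the available channels."""


@dataclass
class RunConfig:
    """Batch configuration: inputs, channel roles, parameters, outputs."""

    input_paths: List[Path]
    channel_roles: Mapping[str, int] = field(default_factory=lambda: {"nuclei": 0, "myotubes": 1})
    params: PipelineParams = field(default_factory=PipelineParams)
    output_dir: Path = Path("myoquant_out")
    group_labels: Optional[Mapping[str, str]] = None
    overlay: bool = False
    strict: bool = False


def read_micrograph(path: str | Path, channel_roles: Mapping[str, int]) -> Micrograph:
    """Read a >=2-channel TIFF, auto-detecting the channel axis.

    The channel axis is the axis of length <= 4; channel-first and
    channel-last layouts are both accepted.  Intensities stay on the
    native scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise ChannelCountError(f"{path.name}: single-channel image, need >= 2 channels")
    if data.ndim != 3:
        raise ChannelCountError(f"{path.name}: expected a 2-D multichannel image, got shape {data.shape}")
    axis_candidates = [ax for ax in range(3) if data.shape[ax] <= 4]
    if not axis_candidates:
        raise ChannelCountError(f"{path.name}: no axis of length <= 4 to use as channels, shape {data.shape}")
    channel_axis = axis_candidates[0]
    channels = np.moveaxis(data, channel_axis, 0)
    if channels.shape[0] < 2:
        raise ChannelCountError(f"{path.name}: found {channels.shape[0]} channel(s), need >= 2")
    for role, idx in channel_roles.items():
        if not 0 <= idx < channels.shape[0]:
            raise ChannelRoleError(f"{path.name}: role {role!r} maps to channel {idx}, "
                                   f"but only {channels.shape[0]} channels exist")
    return Micrograph(channels=channels, channel_roles=dict(channel_roles))


def write_micrograph(path: str | Path, image: Micrograph) -> None:
    """Write channels as a channel-first multipage TIFF."""
    tifffile.imwrite(Path(path), np.asarray(image.channels))


def write_labelmap(path: str | Path, labels: LabelMap) -> None:
    """Write a label map as a 16-bit TIFF (labels above 65535 are rejected)."""
    if labels.n_labels > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.raster.astype(np.uint16))


# ---------------------------------------------------------------------------
# QC overlay

# 3x5 bitmap digits for burning nucleus counts into the overlay
_DIGITS = {
    "0": ["111", "101", "101", "101", "111"],
    "1": ["010", "110", "010", "010", "111"],
    "2": ["111", "001", "111", "100", "111"],
    "3": ["111", "001", "111", "001", "111"],
    "4": ["101", "101", "111", "001", "001"],
    "5": ["111", "100", "111", "001", "111"],
    "6": ["111", "100", "111", "101", "111"],
    "7": ["111", "001", "010", "010", "010"],
    "8": ["111", "101", "111", "101", "111"],
    "9": ["111", "101", "111", "001", "111"],
}


def _burn_text(canvas: np.ndarray, row: int, col: int, text: str, value: Sequence[int]) -> None:
    for k, ch in enumerate(text):
        glyph = _DIGITS.get(ch)
        if glyph is None:
            continue
        for r, line in enumerate(glyph):
            for c, bit in enumerate(line):
                if bit == "1":
                    rr, cc = row + r, col + k * 4 + c
                    if 0 <= rr < canvas.shape[0] and 0 <= cc < canvas.shape[1]:
                        canvas[rr, cc] = value


def _outline(mask: np.ndarray) -> np.ndarray:
    """Morphological gradient: dilate(mask) minus mask."""
    return binary_dilate(mask, 1) & ~mask


def _to_u8(raster: np.ndarray) -> np.ndarray:
    raster = raster.astype(np.float64)
    lo, hi = raster.min(), raster.max()
    if hi == lo:
        return np.zeros(raster.shape, dtype=np.uint8)
    return np.round(255 * (raster - lo) / (hi - lo)).astype(np.uint8)


def render_overlay(image: Micrograph, nuclei: LabelMap, myotubes: LabelMap,
                   records: Sequence[NucleusRecord]) -> np.ndarray:
    """Deterministic QC composite for manual validation of segmentation quality.

    The nuclear channel is mapped to blue, the MF20 channel to green;
    nucleus outlines are drawn cyan and myotube ROI outlines red, where
    an outline is exactly the morphological gradient (dilation minus
    mask) of the object's support.  Each ROI's nucleus count is burned in
    at its centroid.  Returns an RGB uint8 raster of the source shape.
    """
    for lm in (nuclei, myotubes):
        if lm.shape != image.shape:
            raise ValueError(f"label map shape {lm.shape} does not match image shape {image.shape}")
    rgb = np.zeros(image.shape + (3,), dtype=np.uint8)
    rgb[..., 2] = _to_u8(image.channel("nuclei"))
    rgb[..., 1] = _to_u8(image.channel("myotubes"))

    tube_edge = _outline(myotubes.mask())
    rgb[tube_edge] = (255, 0, 0)
    nuc_edge = _outline(nuclei.mask())
    rgb[nuc_edge] = (0, 255, 255)

    counts: Dict[int, int] = {}
    for rec in records:
        if rec.myotube_id:
            counts[rec.myotube_id] = counts.get(rec.myotube_id, 0) + 1
    if myotubes.n_labels:
        from scipy import ndimage as ndi

        index = np.arange(1, myotubes.n_labels + 1)
        centroids = ndi.center_of_mass(myotubes.mask(), myotubes.raster, index)
        for tube_id, (r, c) in zip(index, centroids):
            _burn_text(rgb, int(r) - 2, int(c) - 1, str(counts.get(int(tube_id), 0)),
                       (255, 255, 255))
    return rgb


# ---------------------------------------------------------------------------
# batch pipeline


def quantify_micrograph(image: Micrograph, params: PipelineParams):
    """Segment both channels, assign nuclei, and compute indices for one image."""
    nuclei = segment_nuclei(image, params)
    myotubes = segment_myotubes(image, params)
    nucleus_recs = assign_nuclei(nuclei, myotubes)
    tube_recs = myotube_records(myotubes, nucleus_recs)
    result = compute_indices(nucleus_recs, tube_recs, params)
    return nuclei, myotubes, nucleus_recs, tube_recs, result


def run_pipeline(config: RunConfig) -> dict:
    """Run the full quantification over a batch of images.

    Per image: read, segment nuclei and myotubes, assign nuclei, compute
    MDI/MFI, write per-image tables (and an overlay PNG if requested).
    With group labels, per-group means/SD and an unpaired t test on MDI
    and MFI are added.  Unreadable images are logged and skipped unless
    ``config.strict``; per-image failures are isolated.

    Returns the batch summary dict (also written to ``summary.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params_echo = dataclasses.asdict(config.params)

    per_image_rows = []
    per_myotube_rows = []
    failures: List[str] = []
    results: Dict[str, QuantResult] = {}

    paths = sorted(Path(p) for p in config.input_paths)
    for path in paths:
        stem = path.stem
        try:
            image = read_micrograph(path, config.channel_roles)
            nuclei, myotubes, nucleus_recs, tube_recs, result = quantify_micrograph(
                image, config.params)
        except Exception as exc:  # noqa: BLE001 - per-image isolation
            if config.strict:
                raise
            logger.warning("skipping %s: %s", path, exc)
            failures.append(str(path))
            continue
        results[stem] = result
        per_image_rows.append({
            "image_id": stem, "n_total": result.n_total, "n_inside": result.n_inside,
            "n_outside": result.n_outside, "n_myotubes": len(tube_recs),
            "mdi": result.mdi, "mfi": result.mfi,
        })
        for rec in tube_recs:
            per_myotube_rows.append({
                "image_id": stem, "myotube_id": rec.myotube_id,
                "area_px": rec.area_px, "n_nuclei": rec.n_nuclei,
            })
        if config.overlay:
            import imageio.v3 as iio

            overlay = render_overlay(image, nuclei, myotubes, nucleus_recs)
            iio.imwrite(out / f"{stem}.overlay.png", overlay)
        logger.info("%s: N=%d MDI=%.3f MFI=%.3f", stem, result.n_total, result.mdi, result.mfi)

    pd.DataFrame(per_image_rows, columns=["image_id", "n_total", "n_inside", "n_outside",
                                          "n_myotubes", "mdi", "mfi"]).to_csv(
        out / "per_image.csv", index=False)
    pd.DataFrame(per_myotube_rows, columns=["image_id", "myotube_id", "area_px",
                                            "n_nuclei"]).to_csv(
        out / "per_myotube.csv", index=False)

    summary: dict = {
        "version": __version__,
        "params": params_echo,
        "n_images": len(per_image_rows),
        "failures": failures,
        "images": {row["image_id"]: {k: row[k] for k in row if k != "image_id"}
                   for row in per_image_rows},
    }
    if not per_image_rows:
        logger.warning("no images quantified (empty or unreadable batch)")

    if config.group_labels:
        groups: Dict[str, List[str]] = {}
        for stem in results:
            label = config.group_labels.get(stem)
            if label is not None:
                groups.setdefault(label, []).append(stem)
        summary["groups"] = {
            label: {
                "n": len(stems),
                "mdi_mean": float(np.mean([results[s].mdi for s in stems])),
                "mdi_sd": float(np.std([results[s].mdi for s in stems], ddof=1)) if len(stems) > 1 else 0.0,
                "mfi_mean": float(np.mean([results[s].mfi for s in stems])),
                "mfi_sd": float(np.std([results[s].mfi for s in stems], ddof=1)) if len(stems) > 1 else 0.0,
            }
            for label, stems in sorted(groups.items())
        }
        if len(groups) == 2:
            (la, sa), (lb, sb) = sorted(groups.items())
            comparisons = {}
            for metric in ("mdi", "mfi"):
                va = [getattr(results[s], metric) for s in sa]
                vb = [getattr(results[s], metric) for s in sb]
                if len(va) >= 2 and len(vb) >= 2:
                    cmp_res = compare_groups(va, vb)
                    comparisons[metric] = {
                        "group_a": la, "group_b": lb,
                        "t_statistic": cmp_res.t_statistic,
                        "p_value": cmp_res.p_value,
                        "mean_difference": cmp_res.mean_difference,
                    }
            summary["comparisons"] = comparisons

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
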