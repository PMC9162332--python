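"""Semiautomated trap-movie image analysis.

Stages mirror the time-lapse pipeline: per-frame (x, y) registration,
morphological segmentation of a DIC-like channel, the top-k-pixel
fluorescence metric in the GFP channel, and cell-length measurement.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops_table
from skimage.morphology import black_tophat, dilation, disk, erosion, white_tophat
from skimage.registration import phase_cross_correlation

from .config import ConfigError, DataError, SegmentationParams

logger = logging.getLogger(__name__)

__all__ = [
    "TrapMovie", "LabeledFrame", "TopPixelsResult",
    "register_frames", "segment_frame", "top_pixels_metric", "cell_length",
    "length_percentile_stats", "LengthStats", "measure_traces",
    "link_centroids",
]


# ---------------------------------------------------------------------------
# Movie container and TIFF I/O
# ---------------------------------------------------------------------------

@dataclass
class TrapMovie:
    """Two-channel frame stack for one trap field.

    ``frames`` has shape (T, 2, H, W); channel 0 is DIC-like, channel 1 is
    GFP.  Frame index is 0-based and time(f) = f * frame_interval minutes.
    """

    frames: np.ndarray
    frame_interval: float = 12.0
    pixel_size: Optional[float] = None
    trap_id: str = "trap0"

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[1] != 2:
            raise DataError(
                f"movie frames must have shape (T, 2, H, W), got {self.frames.shape}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def time_minutes(self, frame: int) -> float:
        return frame * self.frame_interval

    def dic(self, frame: int) -> np.ndarray:
        return self.frames[frame, 0]

    def gfp(self, frame: int) -> np.ndarray:
        return self.frames[frame, 1]

    def to_tiff(self, path) -> None:
        tifffile.imwrite(
            path, self.frames.astype(np.float32),
            metadata={"axes": "TCYX",
                      "frame_interval_min": self.frame_interval,
                      "trap_id": self.trap_id})

    @classmethod
    def from_tiff(cls, path) -> "TrapMovie":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if data.ndim == 3:  # single frame, 2 channels
            data = data[None]
        return cls(frames=data,
                   frame_interval=float(meta.get("frame_interval_min", 12.0)),
                   trap_id=str(meta.get("trap_id", "trap0")))


def write_label_tiff(path, masks: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(masks).astype(np.uint16))


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def register_frames(movie: TrapMovie, upsample_factor: int = 20,
                    ) -> tuple[np.ndarray, TrapMovie]:
    """Estimate and correct per-frame (x, y) stage drift.

    Translation between consecutive DIC frames is estimated by the phase
    cross-correlation peak with subpixel refinement and accumulated so every
    frame is aligned to frame 0.  Returns ``(offsets, corrected)`` where
    ``offsets[f]`` is the estimated cumulative (dy, dx) drift of frame ``f``
    relative to frame 0, and ``corrected`` is the movie with each frame
    shifted by ``-offsets[f]`` (uncovered border pixels zero-filled).

    A featureless frame (zero variance) contributes a (0, 0) step with a
    warning.
    """
    if movie.n_frames < 2:
        raise DataError("registration requires at least 2 frames")
    T = movie.n_frames
    offsets = np.zeros((T, 2), dtype=float)
    for f in range(1, T):
        prev, cur = movie.dic(f - 1), movie.dic(f)
        if float(np.var(prev)) == 0.0 or float(np.var(cur)) == 0.0:
            warnings.warn(f"featureless frame at index {f}; assuming no shift")
            step = np.zeros(2)
        else:
            # phase_cross_correlation returns the shift that maps cur onto
            # prev, i.e. minus the drift step
            shift, _, _ = phase_cross_correlation(
                prev, cur, upsample_factor=upsample_factor,
                normalization=None)
            step = -np.asarray(shift, dtype=float)
        offsets[f] = offsets[f - 1] + step

    corrected = np.empty_like(movie.frames, dtype=float)
    for f in range(T):
        for ch in range(2):
            corrected[f, ch] = ndimage.shift(
                movie.frames[f, ch].astype(float), -offsets[f],
                order=1, mode="constant", cval=0.0)
    out = TrapMovie(frames=corrected, frame_interval=movie.frame_interval,
                    pixel_size=movie.pixel_size, trap_id=movie.trap_id)
    return offsets, out


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class LabeledFrame:
    """Integer label mask plus per-object properties computed from it."""

    labels: np.ndarray
    props: pd.DataFrame   # label, area, perimeter, eccentricity, centroids, length

    @property
    def n_objects(self) -> int:
        return len(self.props)

    def mask_of(self, label_value: int) -> np.ndarray:
        return self.labels == label_value


def _region_props(labels: np.ndarray) -> pd.DataFrame:
    if labels.max() == 0:
        return pd.DataFrame(columns=["label", "area", "perimeter",
                                     "eccentricity", "centroid_r",
                                     "centroid_c", "major_axis_length"])
    tab = regionprops_table(
        labels, properties=("label", "area", "perimeter", "eccentricity",
                            "centroid", "axis_major_length"))
    df = pd.DataFrame(tab).rename(columns={
        "centroid-0": "centroid_r", "centroid-1": "centroid_c",
        "axis_major_length": "major_axis_length"})
    return df


def segment_frame(image: np.ndarray,
                  params: Optional[SegmentationParams] = None) -> LabeledFrame:
    """Segment cells in a single DIC-like frame.

    Candidate cell borders are the sum of the top-hat (bright rims) and
    bottom-hat (dark interiors/edges) responses, thresholded (Otsu by
    default); the border map is closed by dilation, holes are filled, and
    erosion restores object extent.  Objects outside the configured area,
    perimeter, or eccentricity ranges are removed and the remainder is
    relabeled consecutively.
    """
    params = (params or SegmentationParams()).validate()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DataError("segment_frame expects a single-channel 2-D image")
    response = (white_tophat(img, disk(params.tophat_radius))
                + black_tophat(img, disk(params.bottomhat_radius)))
    if params.threshold == "otsu":
        if float(response.max()) <= float(response.min()):
            return LabeledFrame(labels=np.zeros(img.shape, dtype=np.int32),
                                props=_region_props(np.zeros(img.shape, int)))
        thr = threshold_otsu(response)
    else:
        thr = float(params.threshold)
    edges = response > thr
    closed = dilation(edges, disk(params.dilation_radius))
    filled = ndimage.binary_fill_holes(closed)
    interior = erosion(filled, disk(params.erosion_radius))
    labels = sk_label(interior, connectivity=1)
    props = _region_props(labels)

    lo_a, hi_a = params.area_range
    lo_p, hi_p = params.perimeter_range
    lo_e, hi_e = params.eccentricity_range
    keep = props[(props.area.between(lo_a, hi_a))
                 & (props.perimeter.between(lo_p, hi_p))
                 & (props.eccentricity.between(lo_e, hi_e))]
    relabeled = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(keep.label.to_numpy(), start=1):
        relabeled[labels == old] = new
    props = _region_props(relabeled)
    return LabeledFrame(labels=relabeled, props=props)


# ---------------------------------------------------------------------------
# Per-cell measurements
# ---------------------------------------------------------------------------

class TopPixelsResult(NamedTuple):
    value: float
    n_used: int
    truncated: bool   # object had fewer than k pixels


def top_pixels_metric(gfp_frame: np.ndarray, mask: np.ndarray,
                      k: int = 300) -> TopPixelsResult:
    """Mean of the k highest-intensity GFP pixels inside one object's mask.

    Objects with fewer than ``k`` pixels are averaged whole and flagged.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    vals = np.asarray(gfp_frame, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise DataError("top_pixels_metric: empty mask")
    if vals.size <= k:
        return TopPixelsResult(float(vals.mean()), int(vals.size), vals.size < k)
    top = np.partition(vals, vals.size - k)[vals.size - k:]
    return TopPixelsResult(float(top.mean()), k, False)


def cell_length(mask: np.ndarray) -> float:
    """Major-axis length (pixels) of one object's mask.

    Automated surrogate for a line drawn along the cell's long axis; the
    caller chooses the bud-initiation frame.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise DataError("cell_length: empty mask")
    lab = m.astype(np.int32)
    tab = regionprops_table(lab, properties=("axis_major_length",))
    return float(tab["axis_major_length"][0])


class LengthStats(NamedTuple):
    p95_white: float
    frac_mothers: float
    frac_daughters: float
    n_mothers: int
    n_daughters: int
    undefined: tuple


def length_percentile_stats(mothers, daughters, white_ref,
                            percentile: float = 95.0) -> LengthStats:
    """Fractions of mothers/daughters strictly longer than the white
    reference percentile (linear-interpolation percentile definition)."""
    white_ref = np.asarray(white_ref, dtype=float)
    if white_ref.size < 20:
        raise DataError("length_percentile_stats requires >= 20 white references")
    p95 = float(np.percentile(white_ref, percentile))
    undefined = []
    fracs = {}
    for name, group in (("mothers", np.asarray(mothers, dtype=float)),
                        ("daughters", np.asarray(daughters, dtype=float))):
        if group.size == 0:
            undefined.append(name)
            fracs[name] = float("nan")
        else:
            fracs[name] = float(np.mean(group > p95))
    if undefined:
        warnings.warn("empty length group(s): " + ", ".join(undefined))
    return LengthStats(p95, fracs["mothers"], fracs["daughters"],
                       int(np.size(mothers)), int(np.size(daughters)),
                       tuple(undefined))


# ---------------------------------------------------------------------------
# Trace extraction and simple tracking
# ---------------------------------------------------------------------------

def measure_traces(movie: TrapMovie, label_stack: np.ndarray,
                   k: int = 300) -> pd.DataFrame:
    """Per-cell, per-frame top-k metric given a label mask stack.

    ``label_stack`` (T, H, W) assigns each foreground pixel to a cell label
    (from curated tracking or ground truth).  Returns a tidy frame
    (label, frame, metric, area, truncated).
    """
    label_stack = np.asarray(label_stack)
    if label_stack.shape != (movie.n_frames,) + movie.frames.shape[2:]:
        raise DataError("label stack shape does not match movie")
    rows = []
    for f in range(movie.n_frames):
        labels = label_stack[f]
        gfp = movie.gfp(f)
        for lab in np.unique(labels):
            if lab == 0:
                continue
            mask = labels == lab
            res = top_pixels_metric(gfp, mask, k=k)
            rows.append(dict(label=int(lab), frame=f, metric=res.value,
                             area=int(mask.sum()), truncated=res.truncated))
    return pd.DataFrame(rows)


def link_centroids(labeled_frames: list[LabeledFrame],
                   max_displacement: float = 15.0) -> pd.DataFrame:
    """Greedy nearest-centroid frame-to-frame linking (tracking aid).

    Links each object to the nearest object in the previous frame within
    ``max_displacement`` pixels; unmatched objects start new tracks.
    Ambiguous, crowded traps should be resolved with a curated table — this
    helper covers the easy majority of links.
    """
    next_track = 1
    rows = []
    prev: list[tuple[int, float, float]] = []   # (track, r, c)
    for f, lf in enumerate(labeled_frames):
        cur = []
        taken = set()
        for _, obj in lf.props.iterrows():
            best_track, best_d = None, max_displacement
            for track, r, c in prev:
                if track in taken:
                    continue
                d = float(np.hypot(obj.centroid_r - r, obj.centroid_c - c))
                if d <= best_d:
                    best_track, best_d = track, d
            if best_track is None:
                best_track = next_track
                next_track += 1
            taken.add(best_track)
            cur.append((best_track, float(obj.centroid_r), float(obj.centroid_c)))
            rows.append(dict(frame=f, label=int(obj.label), track=best_track,
                             centroid_r=float(obj.centroid_r),
                             centroid_c=float(obj.centroid_c)))
        prev = cur
    return pd.DataFrame(rows)
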