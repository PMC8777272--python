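"""Two-photon movie preprocessing and anatomical mapping.

Covers the standard hygiene steps for nuclear-localized GCaMP movies:
translational XY registration against a template, movement-artifact
flagging from successive-frame correlations, marker-based watershed
segmentation of nuclei from a summary image, per-ROI trace extraction, and
least-squares affine registration of neuron centroids onto a shared
reference plane with hemisphere / rostro-caudal quadrant labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "MovieStack",
    "ArtifactMask",
    "ROIMap",
    "AffineMap",
    "RegionFrame",
    "flag_artifacts",
    "register_xy",
    "segment_nuclei",
    "extract_traces",
    "fit_affine",
    "assign_quadrants",
]


@dataclass
class MovieStack:
    """Time x rows x cols intensity stack."""

    frames: np.ndarray
    frame_rate: float = 3.91  # Hz
    pixel_size: float = 1.0  # micrometers per pixel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (time, rows, cols) stack of > 1 frame")
        if not np.all(np.isfinite(self.frames)) or self.frames.min() < 0:
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def mean_image(self) -> np.ndarray:
        return self.frames.mean(axis=0)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, frame_rate: float = 3.91, pixel_size: float = 1.0):
        return cls(tifffile.imread(path), frame_rate, pixel_size)


@dataclass(frozen=True)
class ArtifactMask:
    """Per-frame movement-artifact flags with the z-scores behind them."""

    flagged: np.ndarray  # bool per frame
    zscores: np.ndarray  # z-score of the successive-frame correlation

    @property
    def fraction_flagged(self) -> float:
        return float(self.flagged.mean())


@dataclass
class ROIMap:
    """Labeled nuclear segmentation: 0 = background, 1..N = ROIs."""

    label_image: np.ndarray
    centroids: np.ndarray  # (N, 2) row, col
    areas: np.ndarray  # (N,) pixel counts

    @property
    def n_rois(self) -> int:
        return len(self.areas)

    def to_files(self, tiff_path, csv_path) -> None:
        tifffile.imwrite(tiff_path, self.label_image.astype(np.uint16))
        pd.DataFrame(
            {
                "roi": np.arange(1, self.n_rois + 1),
                "row": self.centroids[:, 0],
                "col": self.centroids[:, 1],
                "area_px": self.areas,
            }
        ).to_csv(csv_path, index=False)


@dataclass(frozen=True)
class AffineMap:
    """2-D affine transform (source -> reference): y = A @ x + b."""

    linear: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    residual: float  # mean landmark error after mapping, micrometers

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("linear part must be invertible")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def to_dict(self) -> dict:
        return {
            "linear": self.linear.tolist(),
            "translation": self.translation.tolist(),
            "residual": self.residual,
        }


@dataclass(frozen=True)
class RegionFrame:
    """Reference-plane geometry for quadrant labeling.

    Lines are given in Hesse form ``(a, b, c)`` with ``a*row + b*col + c``;
    the sign of that expression decides the side.  For the midline the
    positive side is the right hemisphere; for the rostro-caudal divide
    (pretectum only) the positive side is caudal.  Points exactly on a line
    are assigned to the positive side.
    """

    midline: tuple[float, float, float]
    region: str = "tectum"  # "tectum" | "pretectum"
    rostrocaudal_divide: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.region not in ("tectum", "pretectum"):
            raise ValueError("region must be 'tectum' or 'pretectum'")
        if self.region == "pretectum" and self.rostrocaudal_divide is None:
            raise ValueError("pretectum frame needs a rostrocaudal divide")


# ---------------------------------------------------------------------------
# artifact flagging


def flag_artifacts(movie: MovieStack, z_cut: float = -3.0) -> ArtifactMask:
    """Flag frames whose correlation with the previous frame collapses.

    Computes the Pearson correlation of each frame with its predecessor,
    z-scores the series over the whole recording, and flags frames with
    z below ``z_cut`` (default -3).  Constant-frame pairs (zero variance)
    get correlation 1 by convention.  The first frame inherits the first
    computed correlation so every frame carries a z-score.
    """
    if movie.n_frames < 3:
        raise ValueError("need at least 3 frames")
    flat = movie.frames.reshape(movie.n_frames, -1)
    a = flat[:-1] - flat[:-1].mean(axis=1, keepdims=True)
    b = flat[1:] - flat[1:].mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", a, b) / (na * nb)
    r[(na == 0) | (nb == 0)] = 1.0
    corr = np.concatenate([[r[0]], r])
    sd = corr.std()
    z = np.zeros_like(corr) if sd == 0 else (corr - corr.mean()) / sd
    return ArtifactMask(flagged=z < z_cut, zscores=z)


# ---------------------------------------------------------------------------
# registration


def _best_shift(frame: np.ndarray, template_f: np.ndarray, shape) -> tuple[int, int]:
    """Integer (row, col) shift of ``frame`` maximizing cross-correlation
    with the template, via the phase of the FFT product."""
    f = np.fft.rfft2(frame - frame.mean())
    corr = np.fft.irfft2(template_f * np.conj(f), s=shape)
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    shift = []
    for i, n in zip(idx, shape):
        shift.append(i - n if i > n // 2 else i)
    return int(shift[0]), int(shift[1])


def _apply_shift(frame: np.ndarray, dr: int, dc: int, fill: float) -> np.ndarray:
    out = np.full_like(frame, fill)
    r0, r1 = max(dr, 0), frame.shape[0] + min(dr, 0)
    c0, c1 = max(dc, 0), frame.shape[1] + min(dc, 0)
    out[r0:r1, c0:c1] = frame[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def register_xy(
    movie: MovieStack, template: np.ndarray | None = None, max_shift: int = 20
) -> tuple[MovieStack, np.ndarray, np.ndarray]:
    """Translational registration of every frame against a template.

    The integer (row, col) shift maximizing the cross-correlation with the
    template is applied to each frame, with the vacated edge filled with the
    frame's median.  Frames whose best shift exceeds ``max_shift`` pixels in
    either axis are left unshifted and reported for exclusion.

    Returns
    -------
    (registered_movie, shifts, rejected)
        ``shifts`` is (n_frames, 2) of applied corrections; ``rejected`` is
        a boolean per frame.
    """
    if template is None:
        template = movie.frames[0]
    if template.shape != movie.frames.shape[1:]:
        raise ValueError("template shape must match frame shape")
    shape = template.shape
    template_f = np.fft.rfft2(template - template.mean())
    out = np.empty_like(movie.frames)
    shifts = np.zeros((movie.n_frames, 2), dtype=int)
    rejected = np.zeros(movie.n_frames, dtype=bool)
    for t in range(movie.n_frames):
        # shift of the frame relative to template; correction is its negation
        dr, dc = _best_shift(movie.frames[t], template_f, shape)
        if abs(dr) > max_shift or abs(dc) > max_shift:
            rejected[t] = True
            out[t] = movie.frames[t]
            continue
        shifts[t] = (dr, dc)
        out[t] = _apply_shift(
            movie.frames[t], dr, dc, fill=float(np.median(movie.frames[t]))
        )
    return (
        MovieStack(out, movie.frame_rate, movie.pixel_size),
        shifts,
        rejected,
    )


# ---------------------------------------------------------------------------
# segmentation


def segment_nuclei(
    summary_image: np.ndarray,
    smoothing: float = 2.0,
    min_distance: float = 5.0,
    area_bounds: tuple[float, float] = (10.0, 500.0),
    intensity_percentile: float = 75.0,
    pixel_size: float = 1.0,
) -> ROIMap:
    """Watershed segmentation of nuclei from a temporal summary image.

    The summary image (temporal mean or max projection) is Gaussian
    smoothed; local intensity maxima at least ``min_distance`` apart and
    above a global intensity floor (a percentile of the smoothed image) seed
    a marker-based watershed on the inverted image, restricted to the
    supra-floor mask; ROIs outside ``area_bounds`` are dropped and labels
    re-packed to 1..N.

    ``smoothing`` and ``min_distance`` are micrometers and are converted to
    pixels through ``pixel_size``; ``area_bounds`` are pixel counts.
    """
    img = np.asarray(summary_image, dtype=float)
    sigma_px = smoothing / pixel_size
    dist_px = max(1, int(round(min_distance / pixel_size)))
    smooth = gaussian(img, sigma=sigma_px, preserve_range=True)
    floor = np.percentile(smooth, intensity_percentile)
    peaks = peak_local_max(
        smooth, min_distance=dist_px, threshold_abs=floor, exclude_border=False
    )
    if len(peaks) == 0:
        warnings.warn("no local maxima above the intensity floor; empty ROI map")
        return ROIMap(
            np.zeros(img.shape, dtype=np.int32),
            np.empty((0, 2)),
            np.empty((0,), dtype=int),
        )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smooth, markers, mask=smooth > floor, connectivity=1)

    lo, hi = area_bounds
    out = np.zeros_like(labels)
    centroids, areas = [], []
    next_label = 0
    for prop in regionprops(labels):
        if lo <= prop.area <= hi:
            next_label += 1
            out[labels == prop.label] = next_label
            centroids.append(prop.centroid)
            areas.append(prop.area)
    return ROIMap(out, np.asarray(centroids).reshape(-1, 2), np.asarray(areas, dtype=int))


# ---------------------------------------------------------------------------
# trace extraction


def extract_traces(
    movie: MovieStack, rois: ROIMap, mask: ArtifactMask | None = None
) -> np.ndarray:
    """Mean fluorescence of each ROI's pixels per frame.

    Returns a (n_frames, n_rois) array.  Frames flagged as movement
    artifacts are set to NaN (propagated downstream, never interpolated).
    """
    if rois.label_image.shape != movie.frames.shape[1:]:
        raise ValueError("ROI map shape must match frame shape")
    if rois.n_rois == 0:
        raise ValueError("ROI map is empty")
    if np.any(rois.areas == 0):
        raise ValueError("empty ROI in map")
    index = np.arange(1, rois.n_rois + 1)
    traces = np.empty((movie.n_frames, rois.n_rois))
    for t in range(movie.n_frames):
        traces[t] = ndi.mean(movie.frames[t], labels=rois.label_image, index=index)
    if mask is not None:
        traces[mask.flagged] = np.nan
    return traces


# ---------------------------------------------------------------------------
# cross-larva registration


def fit_affine(landmarks_src: np.ndarray, landmarks_ref: np.ndarray) -> AffineMap:
    """Least-squares affine transform mapping source landmarks onto the
    reference set.  Requires >= 3 non-collinear landmark pairs."""
    src = np.asarray(landmarks_src, dtype=float)
    ref = np.asarray(landmarks_ref, dtype=float)
    if src.shape != ref.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("landmark sets must be matching (N, 2) arrays")
    if len(src) < 3:
        raise ValueError("need at least 3 landmark pairs")
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear or degenerate")
    params, *_ = np.linalg.lstsq(design, ref, rcond=None)
    linear = params[:2].T
    translation = params[2]
    mapped = src @ linear.T + translation
    residual = float(np.mean(np.linalg.norm(mapped - ref, axis=1)))
    return AffineMap(linear, translation, residual)


def assign_quadrants(
    centroids_ref: np.ndarray, frame: RegionFrame
) -> pd.DataFrame:
    """Label neurons by hemisphere (and rostral/caudal for the pretectum).

    Points exactly on a dividing line go to the positive side (right
    hemisphere / caudal).
    """
    pts = np.atleast_2d(np.asarray(centroids_ref, dtype=float))
    a, b, c = frame.midline
    side = a * pts[:, 0] + b * pts[:, 1] + c
    out = pd.DataFrame(
        {"hemisphere": np.where(side >= 0, "right", "left")}
    )
    if frame.region == "pretectum":
        a2, b2, c2 = frame.rostrocaudal_divide
        side2 = a2 * pts[:, 0] + b2 * pts[:, 1] + c2
        out["axis"] = np.where(side2 >= 0, "caudal", "rostral")
    return out
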