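"""Kymographic imaging: cross-section extraction, vocal-fold edge detection,
and the glottal width waveform (GWW).

A kymogram is built by stacking one fixed transverse pixel line from every
frame of a high-speed laryngeal video, giving a time x position image in
which the glottal gap appears as a dark band between the bright vocal-fold
tissue. The per-row width of that band, tracked over time, is the glottal
width waveform — the 1-D signal from which all temporal vibration
parameters are derived.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage


class UnusableRecordingError(ValueError):
    """Raised when a recording cannot be analysed (too short, no contrast,
    no detectable oscillation) — such recordings are excluded from study."""


@dataclasses.dataclass
class FrameStack:
    """Grayscale high-speed video: ``frames`` is (n_frames, height, width)."""

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, height, width) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_frames / self.fps


@dataclasses.dataclass
class KymogramImage:
    """Time x transverse-position intensity matrix at one glottal-length level.

    ``section_position`` is the fractional position along the glottal axis
    (0 = posterior commissure, 1 = anterior commissure).
    """

    matrix: np.ndarray
    fps: float
    section_position: float = 0.5

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.size == 0:
            raise ValueError("kymogram matrix must be a non-empty 2-D array")
        if not 0.0 <= self.section_position <= 1.0:
            raise ValueError("section_position must lie in [0, 1]")
        if not self.fps > 0:
            raise ValueError("fps must be positive")


@dataclasses.dataclass
class EdgeTrajectories:
    """Per-frame subpixel positions of the left and right tissue-gap edges."""

    left: np.ndarray
    right: np.ndarray
    valid: np.ndarray
    fps: float
    section_position: float = 0.5

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        both = self.valid & np.isfinite(self.left) & np.isfinite(self.right)
        if np.any(self.right[both] < self.left[both] - 1e-9):
            raise ValueError("right edge must not lie left of the left edge")


@dataclasses.dataclass
class GWWSignal:
    """Glottal width waveform: gap width (pixels) per frame at one section."""

    width: np.ndarray
    fps: float
    section_position: float = 0.5

    def __post_init__(self) -> None:
        self.width = np.asarray(self.width, dtype=float)
        if self.width.ndim != 1 or self.width.size < 2:
            raise ValueError("GWW must be a 1-D signal with >= 2 samples")
        if np.any(self.width < -1e-9):
            raise ValueError("glottal width cannot be negative")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        self.width = np.maximum(self.width, 0.0)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.width.size) * 1000.0 / self.fps

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.width.size / self.fps


def extract_cross_section(stack: FrameStack, section_position: float = 0.5) -> KymogramImage:
    """Build a kymogram from one pixel row of every frame.

    The row index is ``section_position`` mapped onto the frame height;
    the default 0.5 is the mid-glottal section, the conventional level of
    largest vibration amplitude.
    """
    if not 0.0 <= section_position <= 1.0:
        raise ValueError("section_position must lie in [0, 1]")
    height = stack.frames.shape[1]
    row = int(round(section_position * (height - 1)))
    matrix = stack.frames[:, row, :].copy()
    return KymogramImage(matrix=matrix, fps=stack.fps, section_position=section_position)


def _detect_edges_row(row: np.ndarray, threshold: float) -> tuple[float, float] | None:
    """Subpixel left/right crossings of ``threshold`` around the row minimum.

    Returns None when the row never drops below the threshold (closed glottis).
    """
    below = row < threshold
    if not below.any():
        return None
    jmin = int(np.argmin(row))
    if not below[jmin]:  # minimum itself above threshold: treat as closed
        return None
    # walk outwards from the minimum to the first samples above threshold
    jl = jmin
    while jl > 0 and row[jl - 1] < threshold:
        jl -= 1
    jr = jmin
    n = row.size
    while jr < n - 1 and row[jr + 1] < threshold:
        jr += 1
    # linear interpolation between the bracketing samples
    if jl == 0:
        left = 0.0
    else:
        a, b = row[jl - 1], row[jl]
        left = (jl - 1) + (a - threshold) / (a - b) if a != b else float(jl)
    if jr == n - 1:
        right = float(n - 1)
    else:
        a, b = row[jr], row[jr + 1]
        right = jr + (threshold - a) / (b - a) if a != b else float(jr)
    return left, right


def detect_edges(
    kymogram: KymogramImage,
    smooth_sigma_px: float = 0.5,
    contrast_floor: float = 0.1,
) -> EdgeTrajectories:
    """Detect the tissue-gap boundaries on every kymogram row.

    Per row the image line is smoothed with a small Gaussian, thresholded at
    the midpoint between the row-local gap minimum and the tissue median, and
    each threshold crossing is refined to subpixel precision by linear
    interpolation. Rows without a detectable gap are reported as closed
    (left = right, width 0), not missing; detection is normalized-contrast
    based, so it is invariant to intensity gain and offset.

    Raises :class:`UnusableRecordingError` when more than half of the rows
    have row contrast below ``contrast_floor`` x the global dynamic range.
    """
    m = kymogram.matrix
    if smooth_sigma_px > 0:
        m = ndimage.gaussian_filter1d(m, smooth_sigma_px, axis=1, mode="nearest")
    n_rows, n_cols = m.shape
    center = (n_cols - 1) / 2.0
    global_range = float(np.percentile(m, 98) - np.percentile(m, 2))
    scale = max(1.0, float(np.abs(m).max()))
    if global_range <= 1e-9 * scale:
        # uniform image: the glottis is closed throughout (no dark gap anywhere)
        pos = np.full(n_rows, center)
        return EdgeTrajectories(left=pos, right=pos.copy(),
                                valid=np.ones(n_rows, dtype=bool), fps=kymogram.fps,
                                section_position=kymogram.section_position)

    left = np.full(n_rows, np.nan)
    right = np.full(n_rows, np.nan)
    valid = np.zeros(n_rows, dtype=bool)
    low_contrast = 0

    row_min = m.min(axis=1)
    tissue_med = np.median(m, axis=1)
    for r in range(n_rows):
        contrast = tissue_med[r] - row_min[r]
        if contrast < contrast_floor * global_range:
            # closed glottis: no dark gap on this row
            low_contrast += 1
            left[r] = right[r] = center
            valid[r] = True
            continue
        threshold = 0.5 * (row_min[r] + tissue_med[r])
        hit = _detect_edges_row(m[r], threshold)
        if hit is None:
            left[r] = right[r] = center
            valid[r] = True
        else:
            left[r], right[r] = hit
            valid[r] = True

    if low_contrast > 0.5 * n_rows:
        raise UnusableRecordingError(
            f"{low_contrast}/{n_rows} kymogram rows below the contrast floor; "
            "recording unsuitable for analysis"
        )
    # prefer a stable closed-row position: last open-row gap centre
    open_rows = np.flatnonzero(right > left)
    if open_rows.size:
        centers = 0.5 * (left[open_rows] + right[open_rows])
        fill = np.interp(np.arange(n_rows), open_rows, centers)
        closed = right <= left
        left[closed] = right[closed] = fill[closed]
    return EdgeTrajectories(
        left=left, right=right, valid=valid, fps=kymogram.fps,
        section_position=kymogram.section_position,
    )


def compute_gww(edges: EdgeTrajectories, fps: float | None = None) -> GWWSignal:
    """Glottal width waveform from edge trajectories: width = right - left.

    Invalid rows are linearly interpolated from their valid neighbours;
    widths are clamped at zero.
    """
    fps = edges.fps if fps is None else fps
    valid = edges.valid & np.isfinite(edges.left) & np.isfinite(edges.right)
    if valid.sum() < 2:
        raise UnusableRecordingError("fewer than 2 valid rows; cannot form a waveform")
    width = edges.right - edges.left
    idx = np.arange(width.size)
    if not valid.all():
        width = np.interp(idx, idx[valid], width[valid])
    return GWWSignal(width=np.maximum(width, 0.0), fps=fps,
                     section_position=edges.section_position)


def edge_overlay(kymogram: KymogramImage, edges: EdgeTrajectories, path) -> None:
    """Write a QC overlay PNG: the kymogram with detected edges drawn on it."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(kymogram.matrix.T, aspect="auto", cmap="gray", origin="lower")
    t = np.arange(edges.left.size)
    ax.plot(t, edges.left, lw=0.5, color="tab:red")
    ax.plot(t, edges.right, lw=0.5, color="tab:blue")
    ax.set_xlabel("frame")
    ax.set_ylabel("transverse position (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
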