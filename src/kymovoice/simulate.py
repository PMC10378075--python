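"""Synthetic vocal-fold vibration data with known ground truth.

Generates quasi-periodic glottal width waveforms, kymographic frame
stacks, and full three-cohort datasets (normophonic / benign lesion /
malignant lesion) so that every downstream stage — edge detection, cycle
segmentation, perturbation metrics, statistics and classification — can
be validated against known ground truth without patient recordings.

The vibration model: cycle i has period T_i = (1/f0) * (1 + eps_i) with
eps_i iid Gaussian (SD ``sigma_T``, truncated at +-3 SD so periods stay
positive) and peak amplitude A_i = base * (1 - nonvibrating_fraction/2)
* (1 + eta_i) (SD ``sigma_A``, same truncation). Within a cycle the open
phase is a raised-cosine pulse occupying (1 - closed_quotient) of the
period, on top of a constant posterior-gap baseline. Cycles are realized
on a continuous time axis and then sampled at the camera frame rate, so
frame-grid quantization is an explicit, testable phenomenon.

A malignant-style stiff fold is modelled by ``nonvibrating_fraction`` > 0:
that fraction of one fold's amplitude is suppressed, shrinking the total
width excursion and (in frame stacks) making one edge nearly static.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .kymography import FrameStack, GWWSignal, UnusableRecordingError
from .perturbation import CycleSeries

GROUPS = ("normophonic", "benign", "malignant")


@dataclasses.dataclass
class SimulationParams:
    """Parameters of one simulated recording.

    Defaults follow the acquisition protocol emulated throughout the
    package: 3200 frames per second, 2000 frames (625 ms of phonation).
    """

    f0_hz: float = 250.0
    sigma_T: float = 0.0
    sigma_A: float = 0.0
    base_amplitude_px: float = 12.0
    closed_quotient: float = 0.4
    posterior_gap_px: float = 0.0
    asymmetry: float = 1.0
    nonvibrating_fraction: float = 0.0
    fps: float = 3200.0
    n_frames: int = 2000
    pixel_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 <= self.closed_quotient < 1.0:
            raise ValueError("closed_quotient must lie in [0, 1)")
        if self.sigma_T < 0 or self.sigma_A < 0:
            raise ValueError("perturbation SDs must be non-negative")
        if not 0.0 <= self.nonvibrating_fraction <= 1.0:
            raise ValueError("nonvibrating_fraction must lie in [0, 1]")
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.base_amplitude_px <= 0:
            raise ValueError("base_amplitude_px must be positive")
        if self.asymmetry <= 0:
            raise ValueError("asymmetry (left/right amplitude ratio) must be positive")


def _truncated_normal(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    """Gaussian draws truncated at +-3 SD (keeps periods/amplitudes positive)."""
    if sd == 0:
        return np.zeros(size)
    x = rng.normal(0.0, sd, size)
    bad = np.abs(x) > 3 * sd
    while bad.any():
        x[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(x) > 3 * sd
    return x


def _draw_cycles(params: SimulationParams, rng: np.random.Generator):
    """Continuous-time cycle starts, periods and amplitudes covering the
    recording; only complete cycles are kept as ground truth."""
    duration_s = params.n_frames / params.fps
    t_mean = 1.0 / params.f0_hz
    n_draw = int(math.ceil(duration_s / t_mean * 1.5)) + 8
    eps = _truncated_normal(rng, params.sigma_T, n_draw)
    eta = _truncated_normal(rng, params.sigma_A, n_draw)
    periods = t_mean * (1.0 + eps)
    amp_peak = params.base_amplitude_px * (1.0 - params.nonvibrating_fraction / 2.0)
    amps = np.maximum(amp_peak * (1.0 + eta), 0.05 * params.base_amplitude_px)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    # complete cycles: end within the recording
    complete = starts[1:] <= duration_s + 1e-12
    n_complete = int(complete.sum())
    if n_complete < 2:
        raise UnusableRecordingError(
            "fewer than 2 complete cycles fit in the recording; "
            "unsuitable for analysis"
        )
    return starts, periods, amps, n_complete


def _width_at(t: np.ndarray, starts, periods, amps, params: SimulationParams) -> np.ndarray:
    """Vectorized continuous glottal width w(t) in pixels."""
    ci = np.searchsorted(starts, t, side="right") - 1
    ci = np.clip(ci, 0, len(periods) - 1)
    phase = (t - starts[ci]) / periods[ci]
    open_frac = 1.0 - params.closed_quotient
    w = np.full(t.shape, params.posterior_gap_px, dtype=float)
    is_open = phase < open_frac
    ph = phase[is_open] / open_frac
    w[is_open] += amps[ci[is_open]] * 0.5 * (1.0 - np.cos(2.0 * np.pi * ph))
    return w


def generate_gww(params: SimulationParams) -> tuple[GWWSignal, CycleSeries]:
    """Sample a quasi-periodic glottal width waveform at the frame rate.

    Returns the waveform together with the ground-truth cycle series
    (continuous-time periods and peak amplitudes of every complete cycle).
    """
    rng = np.random.default_rng(params.seed)
    starts, periods, amps, n_complete = _draw_cycles(params, rng)
    t = np.arange(params.n_frames) / params.fps
    width = _width_at(t, starts, periods, amps, params)
    gww = GWWSignal(width=width, fps=params.fps)
    truth = CycleSeries(
        closure_instants=starts[: n_complete + 1] * 1000.0,
        periods=periods[:n_complete] * 1000.0,
        amplitudes=amps[:n_complete],
    )
    return gww, truth


def generate_frame_stack(
    params: SimulationParams,
    image_width: int | None = None,
    image_height: int = 48,
    tissue_intensity: float = 200.0,
    gap_intensity: float = 30.0,
) -> tuple[FrameStack, GWWSignal, CycleSeries]:
    """Render a grayscale high-speed frame stack of the vibrating glottis.

    Each frame shows a dark glottal gap between bright fold tissue. The
    gap's full width at the mid-glottal row follows the generated waveform
    w(t); along the glottal (vertical) axis the width tapers as
    sin(pi * y / H), widest at mid-glottis. The left/right edges sit at
    midline -+ w * share, with shares set by ``asymmetry`` (left/right
    amplitude ratio). Edges are rendered with linear partial-pixel coverage
    so subpixel detection is meaningful; Gaussian pixel noise is added and
    intensities are clipped to [0, 255].
    """
    gww, truth = generate_gww(params)
    max_w = params.base_amplitude_px * (1 + 3 * params.sigma_A) + params.posterior_gap_px
    if image_width is None:
        image_width = int(2 * math.ceil(max_w / 2 + 8))
    if image_width < max_w + 4:
        raise ValueError(
            f"image_width={image_width} too narrow for peak glottal width {max_w:.1f} px"
        )
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n, hgt, wid = params.n_frames, image_height, image_width
    mid = (wid - 1) / 2.0
    r = params.asymmetry
    share_l, share_r = r / (1 + r), 1 / (1 + r)
    taper = np.sin(np.pi * (np.arange(hgt) + 0.5) / hgt)  # (H,)

    cols = np.arange(wid)
    frames = np.empty((n, hgt, wid), dtype=float)
    for i in range(n):
        w_rows = gww.width[i] * taper  # (H,)
        left = mid - w_rows * share_l
        right = mid + w_rows * share_r
        # fraction of each pixel (centered on integer coordinate j, covering
        # [j-1/2, j+1/2)) inside the gap interval
        ov = np.clip(
            np.minimum(right[:, None], cols[None, :] + 0.5)
            - np.maximum(left[:, None], cols[None, :] - 0.5),
            0.0, 1.0,
        )
        frames[i] = tissue_intensity + (gap_intensity - tissue_intensity) * ov
    if params.pixel_noise_sd > 0:
        frames += rng.normal(0.0, params.pixel_noise_sd, frames.shape)
    np.clip(frames, 0.0, 255.0, out=frames)
    return FrameStack(frames=frames, fps=params.fps), gww, truth


# --------------------------------------------------------------------------
# cohort presets
# --------------------------------------------------------------------------

# Relative-SD medians back-derived from the target group medians of the
# perturbation measures via Jitt ~= 100*(2/sqrt(pi))*sigma_T (and the same
# closed form for Shimmer / sigma_A).
_J2S = math.sqrt(math.pi) / 200.0  # % -> sigma


@dataclasses.dataclass
class GroupPreset:
    """Distributional spec of SimulationParams for one cohort group."""

    f0_female_hz: float
    f0_male_hz: float
    sigma_T_median: float
    sigma_A_median: float
    log_spread: float  # lognormal sigma of per-subject sigma_T / sigma_A
    f0_log_spread: float
    gap_px_max: float
    nonvibrating_range: tuple[float, float]
    p_female: float


#: Group presets calibrated so that computed-parameter group medians track
#: the clinical ordering (normophonic < benign <= malignant for the Jitter
#: group; F0 mixture mean per group matches the reference cohort means).
PRESETS: dict[str, GroupPreset] = {
    "normophonic": GroupPreset(
        f0_female_hz=285.0, f0_male_hz=210.0,
        sigma_T_median=1.30 * _J2S, sigma_A_median=3.85 * _J2S,
        log_spread=0.7, f0_log_spread=0.25,
        gap_px_max=1.5, nonvibrating_range=(0.0, 0.0), p_female=25 / 38,
    ),
    "benign": GroupPreset(
        f0_female_hz=250.0, f0_male_hz=175.0,
        sigma_T_median=3.00 * _J2S, sigma_A_median=10.21 * _J2S,
        log_spread=0.7, f0_log_spread=0.25,
        gap_px_max=2.5, nonvibrating_range=(0.0, 0.0), p_female=41 / 64,
    ),
    "malignant": GroupPreset(
        f0_female_hz=290.0, f0_male_hz=203.0,
        sigma_T_median=4.26 * _J2S, sigma_A_median=10.81 * _J2S,
        log_spread=0.7, f0_log_spread=0.25,
        gap_px_max=2.5, nonvibrating_range=(0.3, 0.8), p_female=9 / 36,
    ),
}


@dataclasses.dataclass
class CohortSpec:
    """Sizes and per-group parameter distributions of a simulated cohort.

    The default counts (38, 64, 36) mirror the reference study group:
    38 normophonic subjects, 64 benign and 36 malignant lesions, 138 total.
    """

    counts: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"normophonic": 38, "benign": 64, "malignant": 36}
    )
    presets: dict[str, GroupPreset] = dataclasses.field(
        default_factory=lambda: dict(PRESETS)
    )
    fps: float = 3200.0
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if c < 0:
                raise ValueError("group counts must be >= 0")
        for g, p in self.presets.items():
            if not 0.0 <= p.p_female <= 1.0:
                raise ValueError("gender proportions must lie in [0, 1]")


@dataclasses.dataclass
class SubjectRecord:
    subject_id: str
    group: str
    gender: int  # 0 = female, 1 = male
    params: SimulationParams
    gww: GWWSignal
    truth: CycleSeries


@dataclasses.dataclass
class CohortDataset:
    """A simulated cohort: one record per subject, with ground truth."""

    records: list[SubjectRecord]
    seed: int

    def __len__(self) -> int:
        return len(self.records)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "group": [r.group for r in self.records],
                "gender": [r.gender for r in self.records],
                "seed": [r.params.seed for r in self.records],
            }
        )


def _draw_subject_params(
    group: str, preset: GroupPreset, rng: np.random.Generator,
    fps: float, n_frames: int, seed: int,
) -> tuple[SimulationParams, int]:
    gender = int(rng.random() >= preset.p_female)  # 0 = female, 1 = male
    f0_center = preset.f0_male_hz if gender else preset.f0_female_hz
    f0 = f0_center * math.exp(rng.normal(0.0, preset.f0_log_spread))
    f0 = float(np.clip(f0, 80.0, 600.0))
    sigma_t = float(np.clip(
        preset.sigma_T_median * math.exp(rng.normal(0.0, preset.log_spread)),
        0.0, 0.10,
    ))
    sigma_a = float(np.clip(
        preset.sigma_A_median * math.exp(rng.normal(0.0, preset.log_spread)),
        0.0, 0.25,
    ))
    lo, hi = preset.nonvibrating_range
    nvf = float(rng.uniform(lo, hi)) if hi > lo else lo
    params = SimulationParams(
        f0_hz=f0, sigma_T=sigma_t, sigma_A=sigma_a,
        base_amplitude_px=float(rng.uniform(9.0, 15.0)),
        closed_quotient=float(rng.uniform(0.3, 0.45)),
        posterior_gap_px=float(rng.uniform(0.0, preset.gap_px_max)),
        asymmetry=float(math.exp(rng.normal(0.0, 0.1))),
        nonvibrating_fraction=nvf,
        fps=fps, n_frames=n_frames,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return params, gender


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Simulate a full three-group cohort of GWW recordings.

    Each subject gets parameters drawn from their group's preset
    distribution, a generated waveform, and stored ground truth. Output is
    bit-reproducible for a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    idx = 0
    for group in GROUPS:
        count = spec.counts.get(group, 0)
        preset = spec.presets[group]
        for _ in range(count):
            params, gender = _draw_subject_params(
                group, preset, rng, spec.fps, spec.n_frames, spec.seed
            )
            gww, truth = generate_gww(params)
            records.append(
                SubjectRecord(
                    subject_id=f"S{idx:04d}", group=group, gender=gender,
                    params=params, gww=gww, truth=truth,
                )
            )
            idx += 1
    return CohortDataset(records=records, seed=spec.seed)


def cohort_features(
    dataset: CohortDataset, min_cycles: int = 10, on_error: str = "raise"
) -> pd.DataFrame:
    """Feature table of a cohort: one row per subject with the 12 computed
    parameters plus gender and group label.

    ``on_error='skip'`` drops subjects whose recording cannot be segmented
    (mirroring the clinical exclusion of unusable recordings).
    """
    from .perturbation import extract_features

    rows = []
    for rec in dataset.records:
        try:
            feats = extract_features(rec.gww, gender=rec.gender, min_cycles=min_cycles)
        except UnusableRecordingError:
            if on_error == "raise":
                raise
            continue
        rows.append({"subject_id": rec.subject_id, "group": rec.group, **feats})
    return pd.DataFrame(rows)
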