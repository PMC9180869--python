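"""Eye-movement indicators: pupil dilation, fixation/saccade ratios, gaze entropy.

Three per-round indicators are computed from the 60 Hz eye-tracker stream:

* **Pupil dilation amplitude** — the binocular-mean pupil area is
  blink-interpolated, divided by the mean of the first 10 samples of the
  round (the magnification M_t), and the round's maximum M_t is reported.
* **Fixation / saccade time ratios** — the per-eye fractions of round
  samples flagged as fixation (or saccade), averaged over the two eyes.
  The denominator counts *all* samples, including blink samples where both
  flags are false, so the two ratios generally sum to slightly less than 1.
* **Binned gaze entropy** — Shannon entropy (natural log, nats) of the
  empirical distribution of valid gaze samples over a 10 × 10-pixel grid
  partition of the view plane; low for dwelling on a few spots, high for
  wide scanning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_PLANE = (1920.0, 1080.0)
DEFAULT_BIN = 10.0
BASELINE_N = 10


class EyeError(ValueError):
    pass


@dataclass
class EyeRecording:
    """60 Hz binocular eye-tracker stream with explicit missingness.

    Pupil areas and gaze coordinates are NaN during blinks (and other
    detector drop-outs), during which the fixation and saccade flags are
    both false.  For each eye and sample, fixation and saccade are mutually
    exclusive.
    """

    pupil_left: np.ndarray
    pupil_right: np.ndarray
    fixation_left: np.ndarray
    fixation_right: np.ndarray
    saccade_left: np.ndarray
    saccade_right: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    rate: float = 60.0

    def __post_init__(self) -> None:
        arrs = [self.pupil_left, self.pupil_right, self.gaze_x, self.gaze_y]
        n = len(arrs[0])
        for name in ("pupil_left", "pupil_right", "gaze_x", "gaze_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("fixation_left", "fixation_right",
                     "saccade_left", "saccade_right"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        lengths = {len(getattr(self, f)) for f in (
            "pupil_left", "pupil_right", "fixation_left", "fixation_right",
            "saccade_left", "saccade_right", "gaze_x", "gaze_y")}
        if len(lengths) != 1:
            raise EyeError("all channels must have equal length")
        if np.any(self.fixation_left & self.saccade_left) or np.any(
            self.fixation_right & self.saccade_right
        ):
            raise EyeError("fixation and saccade flags are mutually exclusive")

    @property
    def n_samples(self) -> int:
        return len(self.pupil_left)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "pupil_area_L": self.pupil_left,
                "pupil_area_R": self.pupil_right,
                "fixation_L": self.fixation_left.astype(int),
                "fixation_R": self.fixation_right.astype(int),
                "saccade_L": self.saccade_left.astype(int),
                "saccade_R": self.saccade_right.astype(int),
                "gaze_x_px": self.gaze_x,
                "gaze_y_px": self.gaze_y,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rate: float = 60.0) -> "EyeRecording":
        return cls(
            pupil_left=df["pupil_area_L"].to_numpy(dtype=float),
            pupil_right=df["pupil_area_R"].to_numpy(dtype=float),
            fixation_left=df["fixation_L"].to_numpy(dtype=float) > 0.5,
            fixation_right=df["fixation_R"].to_numpy(dtype=float) > 0.5,
            saccade_left=df["saccade_L"].to_numpy(dtype=float) > 0.5,
            saccade_right=df["saccade_R"].to_numpy(dtype=float) > 0.5,
            gaze_x=df["gaze_x_px"].to_numpy(dtype=float),
            gaze_y=df["gaze_y_px"].to_numpy(dtype=float),
            rate=rate,
        )


@dataclass(frozen=True)
class PupilSeries:
    """Baseline-normalized pupil magnification over one analysis window."""

    magnification: np.ndarray
    window: tuple[int, int]
    baseline_n: int = BASELINE_N


# ---------------------------------------------------------------------------
# Pupil pipeline
# ---------------------------------------------------------------------------

def interpolate_pupil_gaps(area: np.ndarray) -> np.ndarray:
    """Fill NaN gaps (blinks, drop-outs) in a pupil-area series.

    Interior gaps are linearly interpolated between the flanking valid
    samples; gaps touching either edge are filled by constant extension of
    the nearest valid value.
    """
    area = np.asarray(area, dtype=float)
    valid = np.isfinite(area)
    if not valid.any():
        raise EyeError("cannot interpolate an all-missing series")
    if valid.all():
        return area.copy()
    idx = np.arange(len(area))
    # np.interp extends constantly at both edges
    return np.interp(idx, idx[valid], area[valid])


def binocular_mean_area(
    recording: EyeRecording, window: tuple[int, int]
) -> np.ndarray:
    """Gap-interpolated mean pupil area of the two eyes over a window.

    Falls back to the single available eye (with a warning) if the other is
    entirely missing within the window.
    """
    a, b = window
    if not 0 <= a < b <= recording.n_samples:
        raise EyeError(f"window {window} outside recording of {recording.n_samples}")
    left = recording.pupil_left[a:b]
    right = recording.pupil_right[a:b]
    have_left = np.isfinite(left).any()
    have_right = np.isfinite(right).any()
    if not (have_left or have_right):
        raise EyeError("both eyes entirely missing in window")
    if not have_right:
        warnings.warn("right-eye pupil entirely missing; using left eye only")
        return interpolate_pupil_gaps(left)
    if not have_left:
        warnings.warn("left-eye pupil entirely missing; using right eye only")
        return interpolate_pupil_gaps(right)
    return 0.5 * (interpolate_pupil_gaps(left) + interpolate_pupil_gaps(right))


def pupil_magnification(
    area: np.ndarray,
    baseline_n: int = BASELINE_N,
    window: tuple[int, int] | None = None,
) -> PupilSeries:
    """Normalize a pupil-area series by the mean of its first samples.

    M_t = A_t / mean(A_1 .. A_baseline_n); by construction the first
    ``baseline_n`` magnification values average to exactly 1.
    """
    area = np.asarray(area, dtype=float)
    if len(area) <= baseline_n:
        raise EyeError(
            f"series of {len(area)} samples too short for a "
            f"{baseline_n}-sample baseline"
        )
    base = float(area[:baseline_n].mean())
    if not np.isfinite(base) or base <= 0:
        raise EyeError(f"baseline mean {base} is not positive")
    return PupilSeries(
        magnification=area / base,
        window=window if window is not None else (0, len(area)),
        baseline_n=baseline_n,
    )


def dilation_amplitude(series: PupilSeries) -> float:
    """Maximum pupil magnification over the round — the dilation amplitude."""
    m = series.magnification
    if m.size == 0:
        raise EyeError("empty magnification series")
    return float(m.max())


# ---------------------------------------------------------------------------
# Fixation / saccade ratios
# ---------------------------------------------------------------------------

def fixation_saccade_ratios(
    recording: EyeRecording, window: tuple[int, int]
) -> tuple[float, float]:
    """Time ratios of fixation and saccade over a window, averaged over eyes.

    Each per-eye ratio is count(flag true) / N with N the total number of
    window samples — blink samples (both flags false) stay in the
    denominator, so r_fixation + r_saccade ≤ 1.
    """
    a, b = window
    if not 0 <= a < b <= recording.n_samples:
        raise EyeError(f"window {window} outside recording of {recording.n_samples}")
    n = b - a
    r_fix = 0.5 * (
        recording.fixation_left[a:b].sum() / n
        + recording.fixation_right[a:b].sum() / n
    )
    r_sac = 0.5 * (
        recording.saccade_left[a:b].sum() / n
        + recording.saccade_right[a:b].sum() / n
    )
    return float(r_fix), float(r_sac)


# ---------------------------------------------------------------------------
# Binned gaze entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GazeBinGrid:
    """Occupancy counts of gaze samples over a pixel-grid partition."""

    bin_size: tuple[float, float]
    plane: tuple[float, float]
    counts: np.ndarray  # n_i ≥ 1 for every stored (occupied) bin
    n_samples: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.size and (c.min() < 1 or c.sum() != self.n_samples):
            raise EyeError("bin counts must be ≥ 1 and sum to the sample count")
        object.__setattr__(self, "counts", c)


def bin_gaze(
    recording: EyeRecording,
    window: tuple[int, int],
    bin_size: float | tuple[float, float] = DEFAULT_BIN,
    plane: tuple[float, float] = DEFAULT_PLANE,
) -> GazeBinGrid:
    """Assign valid gaze samples in a window to grid bins.

    Bin assignment is ``(floor(x / bin_w), floor(y / bin_h))`` — lower edge
    inclusive, upper exclusive.  Samples outside the view plane are clamped
    to the boundary bin (and logged); NaN samples (blinks) are dropped.
    """
    a, b = window
    if not 0 <= a < b <= recording.n_samples:
        raise EyeError(f"window {window} outside recording of {recording.n_samples}")
    bw, bh = (bin_size, bin_size) if np.isscalar(bin_size) else bin_size
    if bw <= 0 or bh <= 0:
        raise EyeError("bin size must be positive")
    x = recording.gaze_x[a:b]
    y = recording.gaze_y[a:b]
    valid = np.isfinite(x) & np.isfinite(y)
    if not valid.any():
        raise EyeError("no valid gaze samples in window")
    x, y = x[valid], y[valid]
    outside = (x < 0) | (x >= plane[0]) | (y < 0) | (y >= plane[1])
    if outside.any():
        log.info("clamping %d gaze samples outside the view plane", outside.sum())
        x = np.clip(x, 0, np.nextafter(plane[0], 0))
        y = np.clip(y, 0, np.nextafter(plane[1], 0))
    ix = np.floor(x / bw).astype(np.int64)
    iy = np.floor(y / bh).astype(np.int64)
    n_cols = int(np.ceil(plane[0] / bw))
    _, counts = np.unique(iy * n_cols + ix, return_counts=True)
    return GazeBinGrid(
        bin_size=(float(bw), float(bh)),
        plane=(float(plane[0]), float(plane[1])),
        counts=counts,
        n_samples=int(valid.sum()),
    )


def binned_gaze_entropy(
    recording: EyeRecording,
    window: tuple[int, int],
    bin_size: float | tuple[float, float] = DEFAULT_BIN,
    plane: tuple[float, float] = DEFAULT_PLANE,
) -> float:
    """Shannon entropy (nats) of the binned gaze distribution.

    Computed as S = log N − (1/N) Σ_i n_i log n_i, the algebraic twin of
    −Σ (n_i/N) log(n_i/N); N counts only the valid (non-blink) samples.
    """
    grid = bin_gaze(recording, window, bin_size, plane)
    n = grid.counts.astype(float)
    N = float(grid.n_samples)
    return float(np.log(N) - (n * np.log(n)).sum() / N)


# ---------------------------------------------------------------------------
# Per-session convenience
# ---------------------------------------------------------------------------

def eye_metrics(
    recording: EyeRecording,
    timeline,
    *,
    baseline_n: int = BASELINE_N,
    bin_size: float | tuple[float, float] = DEFAULT_BIN,
    plane: tuple[float, float] = DEFAULT_PLANE,
) -> pd.DataFrame:
    """All eye indicators for one session, long-form (scenario, metric, value).

    Pupil dilation amplitude is defined only for the stimulus rounds; the
    fixation/saccade ratios and gaze entropy are also computed over the
    roaming baseline period.
    """
    from .timeline import round_window, roaming_window  # avoid cycle at import

    rows = []
    ra, rb = roaming_window(timeline, recording.rate)
    r_fix, r_sac = fixation_saccade_ratios(recording, (ra, rb))
    rows += [
        {"scenario": "Roaming", "metric": "r_fixation", "value": r_fix},
        {"scenario": "Roaming", "metric": "r_saccade", "value": r_sac},
        {"scenario": "Roaming", "metric": "gaze_entropy",
         "value": binned_gaze_entropy(recording, (ra, rb), bin_size, plane)},
    ]
    for i, scenario in enumerate(timeline.stimulus_labels, start=1):
        win = round_window(timeline, i, recording.rate)
        area = binocular_mean_area(recording, win)
        series = pupil_magnification(area, baseline_n, window=win)
        r_fix, r_sac = fixation_saccade_ratios(recording, win)
        rows += [
            {"scenario": scenario, "metric": "dilation_amplitude",
             "value": dilation_amplitude(series)},
            {"scenario": scenario, "metric": "r_fixation", "value": r_fix},
            {"scenario": scenario, "metric": "r_saccade", "value": r_sac},
            {"scenario": scenario, "metric": "gaze_entropy",
             "value": binned_gaze_entropy(recording, win, bin_size, plane)},
        ]
    return pd.DataFrame(rows)
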