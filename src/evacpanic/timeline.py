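"""Temporal structure of an evacuation-simulation session.

A session consists of a free-roaming baseline period followed by three
stimulus--evacuation rounds (Alarm, Smoke, Flame in one of three
counterbalanced orders), each followed by a buffer period.  All downstream
analysis windows (pupil rounds, gaze windows, fNIRS regressor onsets) are
derived from the :class:`SessionTimeline`, so its invariants are validated
eagerly at construction.

Conventions: time is in seconds from session start; sample indices are
0-based; windows are half-open ``[start, stop)``; sample ``k`` at rate ``r``
corresponds to time ``k / r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

SCENARIOS = ("Alarm", "Smoke", "Flame")
"""Stimulus scenarios, in severity-of-content order (not presentation order)."""

SEQUENCES = {
    "Alarm-Smoke-Flame": ("Alarm", "Smoke", "Flame"),
    "Smoke-Flame-Alarm": ("Smoke", "Flame", "Alarm"),
    "Flame-Alarm-Smoke": ("Flame", "Alarm", "Smoke"),
}
"""The three counterbalanced presentation orders used in the study design."""


class TimelineError(ValueError):
    """Raised when timeline parameters violate the session-structure invariants."""


@dataclass(frozen=True)
class SessionTimeline:
    """Validated temporal layout of one session.

    Parameters
    ----------
    roaming_start : float
        Start of the roaming baseline period, seconds from session start.
    roaming_duration : float
        Length of the roaming period (default 120 s).
    stimulus_onsets : tuple of float
        Onset times of the three stimuli, strictly increasing and equally
        spaced by the inter-stimulus spacing.
    stimulus_labels : tuple of str
        Scenario label of each stimulus; a permutation of ``SCENARIOS``.
    round_duration : float
        Length of each stimulus--evacuation round (default 20 s).
    buffer_duration : float
        Length of the post-round buffer (default 60 s).
    eye_rate, fnirs_rate : float
        Sampling rates of the eye tracker (60 Hz) and fNIRS device (10 Hz).
    """

    roaming_start: float = 0.0
    roaming_duration: float = 120.0
    stimulus_onsets: tuple[float, ...] = (120.0, 200.0, 280.0)
    stimulus_labels: tuple[str, ...] = SEQUENCES["Alarm-Smoke-Flame"]
    round_duration: float = 20.0
    buffer_duration: float = 60.0
    eye_rate: float = 60.0
    fnirs_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.roaming_duration < 0:
            raise TimelineError("roaming_duration must be non-negative")
        if self.round_duration <= 0 or self.buffer_duration < 0:
            raise TimelineError("round and buffer durations must be positive")
        if self.eye_rate <= 0 or self.fnirs_rate <= 0:
            raise TimelineError("sampling rates must be positive")
        if len(self.stimulus_onsets) != 3 or len(self.stimulus_labels) != 3:
            raise TimelineError("exactly three stimuli are required")
        if sorted(self.stimulus_labels) != sorted(SCENARIOS):
            raise TimelineError(
                f"stimulus_labels must be a permutation of {SCENARIOS}, "
                f"got {self.stimulus_labels}"
            )
        diffs = [
            b - a for a, b in zip(self.stimulus_onsets, self.stimulus_onsets[1:])
        ]
        if any(d <= 0 for d in diffs):
            raise TimelineError("stimulus_onsets must be strictly increasing")
        if abs(diffs[0] - diffs[1]) > 1e-9:
            raise TimelineError("stimulus onsets must be equally spaced")
        spacing = diffs[0]
        if self.round_duration + self.buffer_duration > spacing + 1e-9:
            raise TimelineError(
                f"round_duration + buffer_duration "
                f"({self.round_duration} + {self.buffer_duration}) exceeds "
                f"the inter-stimulus spacing ({spacing})"
            )

    @property
    def spacing(self) -> float:
        """Onset-to-onset inter-stimulus spacing, seconds."""
        return self.stimulus_onsets[1] - self.stimulus_onsets[0]

    @property
    def session_duration(self) -> float:
        """Total session length: last round plus its buffer."""
        return self.stimulus_onsets[-1] + self.round_duration + self.buffer_duration

    def n_samples(self, rate: float) -> int:
        return int(round(self.session_duration * rate))

    def onset_of(self, scenario: str) -> float:
        """Onset time of the named scenario, regardless of presentation order."""
        try:
            return self.stimulus_onsets[self.stimulus_labels.index(scenario)]
        except ValueError:
            raise TimelineError(f"unknown scenario {scenario!r}") from None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stimulus_onsets"] = list(d["stimulus_onsets"])
        d["stimulus_labels"] = list(d["stimulus_labels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionTimeline":
        d = dict(d)
        d["stimulus_onsets"] = tuple(d["stimulus_onsets"])
        d["stimulus_labels"] = tuple(d["stimulus_labels"])
        return cls(**d)


def build_timeline(
    sequence: str = "Alarm-Smoke-Flame",
    *,
    roaming_start: float = 0.0,
    roaming_duration: float = 120.0,
    spacing: float = 80.0,
    round_duration: float = 20.0,
    buffer_duration: float = 60.0,
    eye_rate: float = 60.0,
    fnirs_rate: float = 10.0,
) -> SessionTimeline:
    """Build a session timeline for one of the three presentation orders.

    The first stimulus onset is ``roaming_start + roaming_duration``;
    subsequent onsets follow at the inter-stimulus ``spacing`` (80 s by
    default, wide enough that the 30 s haemodynamic response to one stimulus
    has died away before the next).
    """
    if sequence not in SEQUENCES:
        raise TimelineError(
            f"unknown sequence {sequence!r}; expected one of {sorted(SEQUENCES)}"
        )
    first = roaming_start + roaming_duration
    onsets = (first, first + spacing, first + 2 * spacing)
    return SessionTimeline(
        roaming_start=roaming_start,
        roaming_duration=roaming_duration,
        stimulus_onsets=onsets,
        stimulus_labels=SEQUENCES[sequence],
        round_duration=round_duration,
        buffer_duration=buffer_duration,
        eye_rate=eye_rate,
        fnirs_rate=fnirs_rate,
    )


def round_window(
    timeline: SessionTimeline, stimulus_index: int, rate: float
) -> tuple[int, int]:
    """Half-open sample-index interval covering one stimulus--evacuation round.

    Parameters
    ----------
    stimulus_index : int
        1-based presentation index (1..3).
    rate : float
        Sampling rate in Hz of the device whose samples are being indexed.

    Returns
    -------
    (first, last) : tuple of int
        0-based indices such that samples ``first .. last-1`` cover
        ``[onset, onset + round_duration)``.  The onset is snapped to the
        nearest sample at the given rate.
    """
    if rate <= 0:
        raise TimelineError("rate must be positive")
    if not 1 <= stimulus_index <= 3:
        raise TimelineError(f"stimulus_index must be in 1..3, got {stimulus_index}")
    onset = timeline.stimulus_onsets[stimulus_index - 1]
    first = int(round(onset * rate))
    last = first + int(round(timeline.round_duration * rate))
    return first, last


def roaming_window(timeline: SessionTimeline, rate: float) -> tuple[int, int]:
    """Half-open sample-index interval covering the roaming baseline period."""
    if rate <= 0:
        raise TimelineError("rate must be positive")
    first = int(round(timeline.roaming_start * rate))
    last = first + int(round(timeline.roaming_duration * rate))
    return first, last
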