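"""Trial timeline of the two-group visuospatial relational-memory task.

Each trial presents three study objects sequentially (3 s each, onsets at
0, 3 and 6 s), a 2 s delay starting at 9 s, and a test display from 11 s
until 15 s during which the participant judges whether the relative spatial
relations were maintained. Analysis windows are defined relative to these
events; the epoch used for time-frequency analysis spans -2.5 s to 15 s
relative to the first study onset.

Two versions of the delay comparison circulate in descriptions of this
design (pre-stimulus -0.75..0 s with delay 0.75..1.5 s, versus -0.25..0 s
with 0.25..1.5 s); the former is the default here and the latter is
available by constructing a custom timeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["Window", "TrialTimeline", "default_timeline"]


@dataclass(frozen=True)
class Window:
    """A closed time interval [t0, t1] in seconds, absolute within the epoch
    unless ``relative_to_response`` is set (then relative to the button press)."""

    t0: float
    t1: float
    relative_to_response: bool = False

    def __post_init__(self) -> None:
        if not self.t0 < self.t1:
            raise ValueError(f"window start must precede end, got [{self.t0}, {self.t1}]")

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


def _default_windows() -> dict[str, Window]:
    return {
        # 0.75 s immediately preceding the first study onset
        "pre_stimulus": Window(-0.75, 0.0),
        # sustained window within the first study display (0..3 s)
        "first_study": Window(0.25, 2.5),
        # shorter first-study variant used as the response-locked baseline
        "first_study_short": Window(0.25, 1.25),
        # 0.75..1.5 s after delay onset (delay onset at 9 s)
        "delay": Window(9.75, 10.5),
        # 0.25..2.5 s after test onset (test onset at 11 s)
        "test": Window(11.25, 13.5),
        # 1 s immediately preceding the button press
        "response_locked": Window(-1.0, 0.0, relative_to_response=True),
    }


@dataclass(frozen=True)
class TrialTimeline:
    """Event times (s, relative to first study onset) and analysis windows."""

    study_onsets: tuple[float, float, float] = (0.0, 3.0, 6.0)
    delay_onset: float = 9.0
    test_onset: float = 11.0
    trial_end: float = 15.0
    epoch_start: float = -2.5
    windows: dict[str, Window] = field(default_factory=_default_windows)

    def __post_init__(self) -> None:
        if not (self.study_onsets[0] < self.delay_onset < self.test_onset < self.trial_end):
            raise ValueError("event times must be ordered: study < delay < test < end")
        for name, w in self.windows.items():
            if w.relative_to_response:
                continue
            if not (self.epoch_start <= w.t0 and w.t1 <= self.trial_end):
                raise ValueError(f"window {name!r} [{w.t0}, {w.t1}] lies outside the epoch")

    @property
    def epoch_duration(self) -> float:
        return self.trial_end - self.epoch_start

    def window(self, name: str) -> Window:
        try:
            return self.windows[name]
        except KeyError:
            raise KeyError(
                f"unknown window {name!r}; defined: {sorted(self.windows)}"
            ) from None

    def with_window(self, name: str, window: Window) -> "TrialTimeline":
        new = dict(self.windows)
        new[name] = window
        return replace(self, windows=new)


def default_timeline() -> TrialTimeline:
    return TrialTimeline()
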