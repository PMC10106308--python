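"""Beat window annotations shared by the hemodynamic and kinematic layers."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BeatWindow", "MIN_BEAT_SAMPLES"]

#: beats shorter than this many samples are discarded during segmentation
MIN_BEAT_SAMPLES = 10


@dataclass(frozen=True)
class BeatWindow:
    """One cardiac cycle delimited by consecutive end-diastoles.

    ``start`` is the end-diastolic (ED) sample index, ``end`` the next ED
    (exclusive: windows partition the record), ``es`` the end-systolic sample
    (minimum LV volume) and ``sp_max`` the peak-systolic-pressure sample.
    """

    start: int
    end: int
    es: int
    sp_max: int
    flag_corner_mismatch: bool = False

    def __post_init__(self) -> None:
        if not (self.start < self.es < self.end):
            raise ValueError(
                f"invalid beat window: need start < es < end, got "
                f"({self.start}, {self.es}, {self.end})"
            )
        if not (self.start <= self.sp_max < self.end):
            raise ValueError("sp_max index outside beat window")

    @property
    def n_samples(self) -> int:
        return self.end - self.start
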