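"""Timing of the verbal-fluency-task (VFT) block paradigm.

The measurement paradigm is a single block-design trial: a pre-task rest
period, a task period made of consecutive word-generation blocks with no
inter-block rest, and a post-task rest period, sampled at a fixed rate.
All window arithmetic in the package (baseline means, task means, the
panning window, the FC window) goes through this object so that sample
indexing is defined in exactly one place: times are in seconds,
``sample index = round(t * fs)``, windows are half-open ``[start, stop)``,
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Paradigm"]


@dataclass(frozen=True)
class Paradigm:
    """Rest/task/rest block structure of the VFT.

    Defaults are the trial's paradigm: 25 s pre-task rest, three
    consecutive 20 s task blocks (60 s task period), 55 s post-task rest,
    sampled at 5 Hz — 140 s, 700 samples.
    """

    pre_rest_s: float = 25.0
    task_block_s: float = 20.0
    n_blocks: int = 3
    post_rest_s: float = 55.0
    fs: float = 5.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.pre_rest_s <= 0 or self.task_block_s <= 0 or self.post_rest_s <= 0:
            raise ValueError("all durations must be positive")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")

    # -- durations -------------------------------------------------------
    @property
    def task_s(self) -> float:
        return self.n_blocks * self.task_block_s

    @property
    def total_s(self) -> float:
        return self.pre_rest_s + self.task_s + self.post_rest_s

    @property
    def n_samples(self) -> int:
        return round(self.total_s * self.fs)

    # -- sample indexing -------------------------------------------------
    def index(self, t_s: float) -> int:
        """Sample index of time ``t_s`` (round-to-nearest)."""
        return round(t_s * self.fs)

    @property
    def task_onset(self) -> int:
        return self.index(self.pre_rest_s)

    @property
    def task_offset(self) -> int:
        return self.index(self.pre_rest_s + self.task_s)

    @property
    def baseline_slice(self) -> slice:
        """Full pre-task rest window [0, pre_rest)."""
        return slice(0, self.task_onset)

    @property
    def task_slice(self) -> slice:
        """Task window [pre_rest, pre_rest + task)."""
        return slice(self.task_onset, self.task_offset)

    def pan_slice(self, tail_s: float = 10.0) -> slice:
        """Last ``tail_s`` seconds of the pre-task rest (panning window)."""
        if tail_s <= 0 or tail_s > self.pre_rest_s:
            raise ValueError("panning tail must lie within the pre-task rest")
        return slice(self.index(self.pre_rest_s - tail_s), self.task_onset)

    def times(self):
        import numpy as np

        return np.arange(self.n_samples) / self.fs
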