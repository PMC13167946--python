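"""In-memory container for one subject x session multichannel recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Recording", "GROUPS", "TIMEPOINTS"]

GROUPS = ("intervention", "control")
TIMEPOINTS = ("pre", "post")


@dataclass
class Recording:
    """One subject x session HbO2 time series (channels x samples).

    ``data`` holds oxy-haemoglobin concentration change x pathlength in
    mmol/L.mm, one row per channel in ``channel_ids`` order. A recording
    may optionally carry the raw dual-wavelength intensities it was
    derived from (or emitted as), shape (2, n_channels, n_samples), with
    ``wavelengths_nm`` and the per-channel reference intensity ``i0``.
    """

    subject_id: str
    group: str
    timepoint: str
    fs: float
    channel_ids: tuple[int, ...]
    data: np.ndarray
    hbr: np.ndarray | None = None
    intensity: np.ndarray | None = None
    wavelengths_nm: tuple[float, float] = (785.0, 825.0)
    i0: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match data rows")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, **meta) -> "Recording":
        """New recording with replaced samples and merged metadata."""
        return Recording(
            subject_id=self.subject_id,
            group=self.group,
            timepoint=self.timepoint,
            fs=self.fs,
            channel_ids=self.channel_ids,
            data=np.asarray(data, dtype=float),
            hbr=self.hbr,
            intensity=self.intensity,
            wavelengths_nm=self.wavelengths_nm,
            i0=self.i0,
            meta={**self.meta, **meta},
        )
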