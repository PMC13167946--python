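"""48-channel frontotemporal probe layout and its 9 regions of interest.

The cap has 15 light sources and 16 detectors forming 48 measurement
channels over bilateral frontal and temporal cortex, grouped into nine
ROIs: bilateral superior frontal cortex (SFC), dorsolateral prefrontal
cortex (DLPFC), superior temporal cortex (STC), ventrolateral prefrontal
cortex (VLPFC), and the medial prefrontal cortex (mPFC).

The full channel→ROI assignment is device-specific; the default shipped
here is a plausible fixture constrained to the three published anchors
(channels 16 and 36 in mPFC, channel 18 in lDLPFC) with equal left/right
channel counts for the eight lateral ROIs. Every downstream computation
is map-agnostic: supply your own map via :func:`load_montage`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ROI_NAMES",
    "ChannelDef",
    "Montage",
    "default_montage",
    "load_montage",
]

#: Canonical ROI order (right/left pairs, midline last). Deterministic
#: ordering of ROI-pair output tables derives from this tuple.
ROI_NAMES: tuple[str, ...] = (
    "rSFC",
    "lSFC",
    "rDLPFC",
    "lDLPFC",
    "rSTC",
    "lSTC",
    "rVLPFC",
    "lVLPFC",
    "mPFC",
)

N_CHANNELS = 48
N_SOURCES = 15
N_DETECTORS = 16

# Plausible default assignment; anchors: 16, 36 -> mPFC; 18 -> lDLPFC.
_DEFAULT_ROI_MAP: dict[str, tuple[int, ...]] = {
    "rSFC": (1, 2, 3, 4, 5),
    "lSFC": (6, 7, 8, 9, 10),
    "rDLPFC": (11, 12, 13, 14, 15),
    "lDLPFC": (18, 19, 20, 21, 22),
    "rSTC": (39, 40, 41, 42, 43),
    "lSTC": (44, 45, 46, 47, 48),
    "rVLPFC": (25, 26, 27, 28, 29),
    "lVLPFC": (30, 31, 32, 37, 38),
    "mPFC": (16, 17, 23, 24, 33, 34, 35, 36),
}


@dataclass(frozen=True)
class ChannelDef:
    """One source–detector light path."""

    id: int
    source: int
    detector: int
    roi: str

    def __post_init__(self) -> None:
        if not 1 <= self.id <= N_CHANNELS:
            raise ValueError(f"channel id {self.id} outside 1..{N_CHANNELS}")
        if not 1 <= self.source <= N_SOURCES:
            raise ValueError(f"source {self.source} outside 1..{N_SOURCES}")
        if not 1 <= self.detector <= N_DETECTORS:
            raise ValueError(f"detector {self.detector} outside 1..{N_DETECTORS}")
        if self.roi not in ROI_NAMES:
            raise ValueError(f"unknown ROI name {self.roi!r}")


@dataclass(frozen=True)
class Montage:
    """Validated probe layout: 48 channels partitioned into the 9 ROIs."""

    channels: tuple[ChannelDef, ...]
    n_sources: int = N_SOURCES
    n_detectors: int = N_DETECTORS
    _roi_of: dict[int, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.channels]
        if len(self.channels) != N_CHANNELS:
            raise ValueError(
                f"montage must define exactly {N_CHANNELS} channels, got {len(self.channels)}"
            )
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate channel ids: {dup}")
        if set(ids) != set(range(1, N_CHANNELS + 1)):
            missing = sorted(set(range(1, N_CHANNELS + 1)) - set(ids))
            raise ValueError(f"missing channel ids: {missing}")
        object.__setattr__(self, "_roi_of", {c.id: c.roi for c in self.channels})

    # -- lookups ---------------------------------------------------------
    @property
    def rois(self) -> dict[str, frozenset[int]]:
        """ROI name → set of member channel ids (a partition of 1..48)."""
        out: dict[str, set[int]] = {name: set() for name in ROI_NAMES}
        for c in self.channels:
            out[c.roi].add(c.id)
        return {k: frozenset(v) for k, v in out.items()}

    def roi_of(self, channel_id: int) -> str:
        try:
            return self._roi_of[channel_id]
        except KeyError:
            raise KeyError(f"unknown channel id {channel_id}") from None

    def roi_channels(self, roi: str) -> tuple[int, ...]:
        if roi not in ROI_NAMES:
            raise KeyError(f"unknown ROI name {roi!r}")
        return tuple(c.id for c in self.channels if c.roi == roi)

    def roi_pairs(self, include_self: bool = False) -> list[tuple[str, str]]:
        """All unordered ROI pairs in canonical order (36 pairs, 45 with self)."""
        if include_self:
            return list(itertools.combinations_with_replacement(ROI_NAMES, 2))
        return list(itertools.combinations(ROI_NAMES, 2))

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self._roi_of))

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Export the channel→ROI map as a two-column TSV."""
        lines = ["channel_id\troi"]
        lines += [f"{c.id}\t{c.roi}" for c in sorted(self.channels, key=lambda c: c.id)]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_sources": self.n_sources,
            "n_detectors": self.n_detectors,
            "channels": [
                {"id": c.id, "source": c.source, "detector": c.detector, "roi": c.roi}
                for c in sorted(self.channels, key=lambda c: c.id)
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _default_source_detector(cid: int) -> tuple[int, int]:
    # Synthetic scan-order layout staying inside the 15-source/16-detector
    # ranges; real optode geometry is figure-only information.
    return ((cid - 1) % N_SOURCES) + 1, ((cid - 1) % N_DETECTORS) + 1


def default_montage() -> Montage:
    """The documented plausible default layout (overridable via config)."""
    channels = []
    for roi, ids in _DEFAULT_ROI_MAP.items():
        for cid in ids:
            s, d = _default_source_detector(cid)
            channels.append(ChannelDef(id=cid, source=s, detector=d, roi=roi))
    channels.sort(key=lambda c: c.id)
    return Montage(channels=tuple(channels))


def load_montage(path: str | Path) -> Montage:
    """Read and validate a montage from a YAML config.

    Two layouts are accepted::

        # explicit
        n_sources: 15
        n_detectors: 16
        channels:
          - {id: 1, source: 1, detector: 1, roi: rSFC}
          ...

        # compact: roi -> channel-id list (source/detector auto-assigned)
        rois:
          rSFC: [1, 2, 3, 4, 5]
          ...

    Raises ``ValueError`` on duplicate ids, channels missing an ROI, or
    unknown ROI names.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError("montage config must be a mapping")
    channels: list[ChannelDef] = []
    if "channels" in doc:
        for entry in doc["channels"]:
            channels.append(
                ChannelDef(
                    id=int(entry["id"]),
                    source=int(entry.get("source", _default_source_detector(int(entry["id"]))[0])),
                    detector=int(
                        entry.get("detector", _default_source_detector(int(entry["id"]))[1])
                    ),
                    roi=str(entry["roi"]),
                )
            )
    elif "rois" in doc:
        seen: dict[int, str] = {}
        for roi, ids in doc["rois"].items():
            if roi not in ROI_NAMES:
                raise ValueError(f"unknown ROI name {roi!r}")
            for cid in ids:
                cid = int(cid)
                if cid in seen:
                    raise ValueError(
                        f"channel {cid} assigned to multiple ROIs ({seen[cid]}, {roi})"
                    )
                seen[cid] = roi
                s, d = _default_source_detector(cid)
                channels.append(ChannelDef(id=cid, source=s, detector=d, roi=roi))
    else:
        raise ValueError("montage config needs a 'channels' or 'rois' section")
    return Montage(
        channels=tuple(sorted(channels, key=lambda c: c.id)),
        n_sources=int(doc.get("n_sources", N_SOURCES)),
        n_detectors=int(doc.get("n_detectors", N_DETECTORS)),
    )
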