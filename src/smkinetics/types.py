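"""Shared containers for frame-discretized interval recordings.

A :class:`RecordingSet` mirrors the "intervals"-style output of
colocalization single-molecule spectroscopy (CoSMoS) image analysis: for
every surface location (a tethered DNA molecule, or a DNA-free control
spot) and every fluorescence channel, the frames during which a spot was
detected, as half-open 0-based frame intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CHANNELS = ("rnap", "greb", "probe")


@dataclass(frozen=True, order=True)
class FrameInterval:
    """A detected presence interval: frames [start_frame, end_frame), 0-based."""

    location_id: int
    channel: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError(
                f"empty interval [{self.start_frame}, {self.end_frame}) "
                f"at location {self.location_id}"
            )
        if self.start_frame < 0:
            raise ValueError("start_frame must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class Location:
    location_id: int
    kind: str  # "dna" or "control"

    def __post_init__(self) -> None:
        if self.kind not in ("dna", "control"):
            raise ValueError(f"unknown location kind {self.kind!r}")


@dataclass
class RecordingSet:
    """A multi-channel, multi-location interval recording.

    Attributes
    ----------
    frame_interval_s : float
        Acquisition interval, seconds per frame.
    n_frames : int
        Recording length in frames.
    locations : list[Location]
    intervals : list[FrameInterval]
        Sorted; intervals of one channel at one location are disjoint.
    concentrations : dict[str, float]
        Channel -> solution concentration (molar) of the labeled species.
    """

    frame_interval_s: float
    n_frames: int
    locations: list[Location] = field(default_factory=list)
    intervals: list[FrameInterval] = field(default_factory=list)
    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be > 0")
        self.validate()

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    def validate(self) -> None:
        ids = {loc.location_id for loc in self.locations}
        if len(ids) != len(self.locations):
            raise ValueError("duplicate location_id")
        self.intervals.sort(key=lambda iv: (iv.location_id, iv.channel, iv.start_frame))
        prev: dict[tuple[int, str], int] = {}
        for iv in self.intervals:
            if ids and iv.location_id not in ids:
                raise ValueError(f"interval references unknown location {iv.location_id}")
            if iv.end_frame > self.n_frames:
                raise ValueError(
                    f"interval [{iv.start_frame}, {iv.end_frame}) exceeds "
                    f"n_frames={self.n_frames}"
                )
            key = (iv.location_id, iv.channel)
            if key in prev and iv.start_frame < prev[key]:
                raise ValueError(
                    f"overlapping intervals in channel {iv.channel!r} at "
                    f"location {iv.location_id}"
                )
            prev[key] = iv.end_frame

    def channels(self) -> list[str]:
        return sorted({iv.channel for iv in self.intervals})

    def locations_of_kind(self, kind: str) -> list[Location]:
        return [loc for loc in self.locations if loc.kind == kind]

    def intervals_at(self, location_id: int, channel: str | None = None) -> list[FrameInterval]:
        return [
            iv
            for iv in self.intervals
            if iv.location_id == location_id
            and (channel is None or iv.channel == channel)
        ]

    def intervals_by_location(self, channel: str) -> dict[int, list[FrameInterval]]:
        """All intervals of one channel grouped by location (every location
        present as a key, possibly with an empty list)."""
        out: dict[int, list[FrameInterval]] = {loc.location_id: [] for loc in self.locations}
        for iv in self.intervals:
            if iv.channel == channel:
                out.setdefault(iv.location_id, []).append(iv)
        return out
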