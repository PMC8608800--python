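"""Piecewise-constant environmental forcing for life-cycle simulations.

A :class:`ForcingSchedule` is an ordered list of segments, each fixing the
temperature (degC) and the scaled functional response ``f`` in [0, 1] from a
start point onward.  A start point is either an age in days or the name of a
life-cycle event (``hatch``, ``birth``, ``metamorphosis``, ``puberty``),
which lets a scenario switch conditions exactly when a maturity threshold
fires (e.g. the dwarf-male scenario switches kappa and f at the completion
of metamorphosis).  kappa overrides follow the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Segment", "KappaOverride", "ForcingSchedule", "EVENT_NAMES"]

EVENT_NAMES = ("hatch", "birth", "metamorphosis", "puberty")


def _check_start(start, where: str):
    if isinstance(start, str):
        if start not in EVENT_NAMES:
            raise ValueError(
                f"{where}: unknown event start {start!r}; expected one of {EVENT_NAMES}"
            )
        return start
    start = float(start)
    if start < 0.0:
        raise ValueError(f"{where}: start age must be >= 0, got {start}")
    return start


@dataclass(frozen=True)
class Segment:
    """One forcing segment: from ``start`` onward, (T_celsius, f) apply."""

    start: float | str
    T_celsius: float
    f: float

    def __post_init__(self):
        _check_start(self.start, "segment")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"segment: f must lie in [0, 1], got {self.f}")
        if self.T_celsius <= -273.15:
            raise ValueError(f"segment: non-physical temperature {self.T_celsius} degC")


@dataclass(frozen=True)
class KappaOverride:
    """From ``start`` (age or event) onward, allocation fraction = kappa."""

    start: float | str
    kappa: float

    def __post_init__(self):
        _check_start(self.start, "kappa override")
        if not 0.0 < self.kappa < 1.0:
            raise ValueError(f"kappa override must lie in (0, 1), got {self.kappa}")


@dataclass
class ForcingSchedule:
    """Ordered forcing segments plus optional kappa overrides.

    The first segment must start at age 0; numeric starts must be strictly
    increasing.  Event-based segments activate when the event fires during
    the simulation, so they carry no fixed age at validation time.
    """

    segments: list[Segment] = field(default_factory=list)
    kappa_overrides: list[KappaOverride] = field(default_factory=list)

    def __post_init__(self):
        if not self.segments:
            raise ValueError("forcing schedule needs at least one segment")
        first = self.segments[0]
        if not (isinstance(first.start, float) and first.start == 0.0):
            raise ValueError("the first forcing segment must start at age 0")
        last = 0.0
        for i, seg in enumerate(self.segments[1:], start=2):
            if isinstance(seg.start, float):
                if seg.start <= last:
                    raise ValueError(
                        f"segment {i}: numeric starts must increase "
                        f"({seg.start} after {last})"
                    )
                last = seg.start

    @classmethod
    def constant(cls, T_celsius: float, f: float = 1.0,
                 kappa_overrides: list[KappaOverride] | None = None) -> "ForcingSchedule":
        return cls(
            segments=[Segment(0.0, T_celsius, f)],
            kappa_overrides=list(kappa_overrides or []),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"start": s.start, "T_celsius": s.T_celsius, "f": s.f}
                for s in self.segments
            ],
            "kappa_overrides": [
                {"start": o.start, "kappa": o.kappa} for o in self.kappa_overrides
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ForcingSchedule":
        try:
            segs = [
                Segment(d["start"], d["T_celsius"], d["f"])
                for d in doc.get("segments", [])
            ]
            overrides = [
                KappaOverride(d["start"], d["kappa"])
                for d in doc.get("kappa_overrides", [])
            ]
        except KeyError as exc:
            raise ValueError(f"forcing document missing key {exc}") from exc
        return cls(segments=segs, kappa_overrides=overrides)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ForcingSchedule":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        return cls.from_dict(doc)
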