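"""A 60-channel 10-10 scalp montage projected onto the unit disc.

The layout is the conventional top-view projection (nose up, left ear at
negative x): the outermost 10% ring carries Fp1/Fp2, F7/F8, T7/T8, P7/P8,
O1/O2 and the intermediate AF/FT/TP/PO electrodes; inner electrodes are
placed on straight chords between the midline and the outer ring.  FCz is
omitted (it is the usual online reference), which leaves exactly 60 labels.

Regions follow clinical convention: FC electrodes count as frontal, FT/TP as
temporal, CP as central and PO as occipital.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Tuple

import numpy as np

REGIONS = ("frontal", "central", "temporal", "parietal", "occipital")

_OUTER_RADIUS = 0.95

# Outer 10% ring: angle in degrees from the nose (+y axis), left negative.
_OUTER_RING = {
    "Fpz": 0, "Fp1": -18, "Fp2": 18,
    "AF7": -36, "AF8": 36,
    "F7": -54, "F8": 54,
    "FT7": -72, "FT8": 72,
    "T7": -90, "T8": 90,
    "TP7": -108, "TP8": 108,
    "P7": -126, "P8": 126,
    "PO7": -144, "PO8": 144,
    "O1": -162, "O2": 162,
    "Oz": 180,
}

# Midline electrodes (x = 0).  FCz/CPz radii kept as interpolation anchors.
_MIDLINE = {
    "AFz": 0.7125, "Fz": 0.475, "FCz": 0.2375, "Cz": 0.0,
    "CPz": -0.2375, "Pz": -0.475, "POz": -0.7125,
}


def _outer_xy(label: str) -> Tuple[float, float]:
    a = math.radians(_OUTER_RING[label])
    return (_OUTER_RADIUS * math.sin(a), _OUTER_RADIUS * math.cos(a))


def _lerp(p: Tuple[float, float], q: Tuple[float, float], f: float) -> Tuple[float, float]:
    return (p[0] + f * (q[0] - p[0]), p[1] + f * (q[1] - p[1]))


def _build_layout() -> Dict[str, Tuple[float, float]]:
    pos: Dict[str, Tuple[float, float]] = {}
    for name in _OUTER_RING:
        pos[name] = _outer_xy(name)
    for name, y in _MIDLINE.items():
        pos[name] = (0.0, y)
    # Inner rows: fractions of the chord from the midline anchor to the
    # outer-ring electrode of the same row.
    rows = [
        ("AFz", "AF7", {"AF3": 0.5}),
        ("AFz", "AF8", {"AF4": 0.5}),
        ("Fz", "F7", {"F1": 0.25, "F3": 0.5, "F5": 0.75}),
        ("Fz", "F8", {"F2": 0.25, "F4": 0.5, "F6": 0.75}),
        ("FCz", "FT7", {"FC1": 0.25, "FC3": 0.5, "FC5": 0.75}),
        ("FCz", "FT8", {"FC2": 0.25, "FC4": 0.5, "FC6": 0.75}),
        ("Cz", "T7", {"C1": 0.25, "C3": 0.5, "C5": 0.75}),
        ("Cz", "T8", {"C2": 0.25, "C4": 0.5, "C6": 0.75}),
        ("CPz", "TP7", {"CP1": 0.25, "CP3": 0.5, "CP5": 0.75}),
        ("CPz", "TP8", {"CP2": 0.25, "CP4": 0.5, "CP6": 0.75}),
        ("Pz", "P7", {"P1": 0.25, "P3": 0.5, "P5": 0.75}),
        ("Pz", "P8", {"P2": 0.25, "P4": 0.5, "P6": 0.75}),
        ("POz", "PO7", {"PO3": 0.5}),
        ("POz", "PO8", {"PO4": 0.5}),
    ]
    for mid, outer, inner in rows:
        for name, f in inner.items():
            pos[name] = _lerp(pos[mid], pos[outer], f)
    del pos["FCz"]
    return pos


# Front-to-back, left-to-right channel order; defines Epoch row order.
CANONICAL_ORDER: Tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

_LAYOUT = _build_layout()


def region_of(name: str) -> str:
    """Region label for a 10-10 electrode name."""
    if name.startswith(("FT", "TP")) or name in ("T7", "T8"):
        return "temporal"
    if name.startswith(("Fp", "AF", "F")):  # includes FC rows
        return "frontal"
    if name.startswith(("CP", "C")):
        return "central"
    if name.startswith(("PO", "O")):
        return "occipital"
    if name.startswith("P"):
        return "parietal"
    raise ValueError(f"unknown electrode label: {name!r}")


@dataclass(frozen=True)
class Montage:
    """Ordered electrode set with 2-D positions and region assignment."""

    channel_names: Tuple[str, ...]
    positions: np.ndarray          # (n, 2), unit-disc coordinates, nose up
    region_map: Dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in montage")
        if self.positions.shape != (len(names), 2):
            raise ValueError("positions shape must be (n_channels, 2)")
        radii = np.hypot(self.positions[:, 0], self.positions[:, 1])
        if np.any(radii > 1.0 + 1e-9):
            raise ValueError("all electrode positions must lie in the unit disc")
        for n in names:
            if self.region_map.get(n) not in REGIONS:
                raise ValueError(f"channel {n!r} lacks a valid region")

    def __len__(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def channels_in_region(self, regions: str | Iterable[str]) -> np.ndarray:
        """Sorted indices of channels whose region is in ``regions``."""
        if isinstance(regions, str):
            regions = (regions,)
        regions = tuple(regions)
        for r in regions:
            if r not in REGIONS:
                raise ValueError(f"unknown region {r!r}")
        return np.array(
            [i for i, n in enumerate(self.channel_names) if self.region_map[n] in regions],
            dtype=int,
        )

    def region_indices(self) -> Dict[str, np.ndarray]:
        return {r: self.channels_in_region(r) for r in REGIONS}


def build_montage(n_channels: int = 60) -> Montage:
    """Deterministic montage of the first ``n_channels`` canonical electrodes.

    ``n_channels=1`` is the degenerate single-channel case (Cz at the origin);
    values above the 60 available labels raise ``ValueError``.
    """
    if n_channels < 1 or n_channels > len(CANONICAL_ORDER):
        raise ValueError(
            f"n_channels must be in [1, {len(CANONICAL_ORDER)}], got {n_channels}"
        )
    if n_channels == 1:
        return Montage(("Cz",), np.zeros((1, 2)), {"Cz": "central"})
    names = CANONICAL_ORDER[:n_channels]
    pos = np.array([_LAYOUT[n] for n in names], dtype=float)
    return Montage(tuple(names), pos, {n: region_of(n) for n in names})
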