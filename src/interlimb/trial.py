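"""Core data containers: marker trials and gait events.

Axis convention used throughout the package: AP = +x along the walking
direction, ML = +y toward the participant's left, VT = +z up.  Marker
positions are stored in millimetres, body-relative (the treadmill belt is
the moving frame; ``belt_speed`` is carried as metadata and re-enters only
in the step-length computation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GapError, SchemaError

AXES = ("AP", "ML", "VT")
REQUIRED_MARKERS = ("heel_L", "heel_R", "sacrum")


@dataclass
class MarkerTrial:
    """Time-indexed 3D positions for named markers at a fixed sampling rate.

    Parameters
    ----------
    positions
        Mapping from marker name to an ``(n_samples, 3)`` float array with
        columns (AP, ML, VT) in mm.
    sample_rate
        Sampling rate in Hz.
    belt_speed
        Treadmill belt speed in m/s (0 for overground/static capture).
    trial_id
        Identifier used in reports and manifests.
    """

    positions: dict[str, np.ndarray]
    sample_rate: float
    belt_speed: float
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        for name in REQUIRED_MARKERS:
            if name not in self.positions:
                raise SchemaError(
                    f"trial {self.trial_id!r} is missing required marker {name!r}; "
                    f"required markers are {REQUIRED_MARKERS}"
                )
        lengths = set()
        for name, arr in self.positions.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise SchemaError(
                    f"marker {name!r} must be an (n, 3) array of (AP, ML, VT); "
                    f"got shape {arr.shape}"
                )
            if np.isnan(arr).any():
                row = int(np.where(np.isnan(arr).any(axis=1))[0][0])
                raise GapError(
                    f"marker {name!r} has a missing sample at row {row}; "
                    "gaps must be repaired before loading"
                )
            self.positions[name] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise SchemaError(f"marker series lengths differ: {sorted(lengths)}")
        if self.sample_rate <= 0 or not np.isfinite(self.sample_rate):
            raise SchemaError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def marker_names(self) -> list[str]:
        return list(self.positions)

    @property
    def n_samples(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    def channel(self, marker: str, axis: str) -> np.ndarray:
        """Return one scalar channel, e.g. ``channel("heel_L", "AP")``."""
        if axis not in AXES:
            raise SchemaError(f"unknown axis {axis!r}; axes are {AXES}")
        if marker not in self.positions:
            raise SchemaError(f"unknown marker {marker!r}; have {self.marker_names}")
        return self.positions[marker][:, AXES.index(axis)]


@dataclass
class GaitEvents:
    """Per-side heel-strike sample indices (ascending, original sampling).

    ``source`` records provenance: ``"ground_truth"`` for events emitted by
    the synthetic generator, ``"detected"`` for marker-based detection.
    """

    heel_strikes_L: np.ndarray
    heel_strikes_R: np.ndarray
    source: str = "detected"

    def __post_init__(self) -> None:
        self.heel_strikes_L = np.asarray(self.heel_strikes_L, dtype=int)
        self.heel_strikes_R = np.asarray(self.heel_strikes_R, dtype=int)
        for side, arr in (("L", self.heel_strikes_L), ("R", self.heel_strikes_R)):
            if arr.size and np.any(np.diff(arr) <= 0):
                raise SchemaError(f"heel strikes on side {side} are not strictly increasing")

    def merged(self) -> tuple[np.ndarray, np.ndarray]:
        """Merge both sides into one ascending sequence.

        Returns (indices, sides) where sides is an array of "L"/"R" labels.
        Alternation is *not* enforced here; step computations check it and
        report violations rather than silently repairing them.
        """
        idx = np.concatenate([self.heel_strikes_L, self.heel_strikes_R])
        side = np.array(["L"] * len(self.heel_strikes_L) + ["R"] * len(self.heel_strikes_R))
        order = np.argsort(idx, kind="stable")
        return idx[order], side[order]
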