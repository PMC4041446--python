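"""Shared in-memory containers for photon streams and camera traces.

Units are fixed package-wide: photon clocks are integer microseconds,
durations are seconds, intensities are counts per frame, E/S are unitless.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: detection-class codes: donor emission/donor excitation, acceptor/donor,
#: acceptor/acceptor, donor/acceptor (retained but excluded from E and S)
DD, AD, AA, DA = 0, 1, 2, 3
CLASS_NAMES = {DD: "DD", AD: "AD", AA: "AA", DA: "DA"}

DONOR, ACCEPTOR = 0, 1           # detection channel codes
DONOR_EXC, ACCEPTOR_EXC = 0, 1   # excitation-slot codes


@dataclass
class PhotonStream:
    """Timestamped, channel-labelled photons from a confocal ALEX experiment.

    Parameters
    ----------
    timestamps_us : int64 array, strictly increasing
    channel : int8 array, 0 = donor detector, 1 = acceptor detector
    excitation_slot : int8 array or None
        0 = donor excitation, 1 = acceptor excitation. Derived from the
        timestamps and the alternation gates by
        :func:`tatabend.bursts.classify_photons`.
    alternation_period_us : int
        Laser alternation period (default experiment value: 100 us).
    duration_s : float
        Total acquisition time.
    background_rates : dict or None
        Optional per-class background rates (photons/s), keys "DD", "AD",
        "AA", "DA".
    """

    timestamps_us: np.ndarray
    channel: np.ndarray
    alternation_period_us: int
    duration_s: float
    excitation_slot: np.ndarray | None = None
    background_rates: dict | None = None

    def __post_init__(self):
        self.timestamps_us = np.asarray(self.timestamps_us, dtype=np.int64)
        self.channel = np.asarray(self.channel, dtype=np.int8)
        if self.timestamps_us.shape != self.channel.shape:
            raise ValueError("timestamps and channel arrays differ in length")
        if self.excitation_slot is not None:
            self.excitation_slot = np.asarray(self.excitation_slot, dtype=np.int8)
        if self.timestamps_us.size > 1:
            if np.any(np.diff(self.timestamps_us) <= 0):
                bad = int(np.flatnonzero(np.diff(self.timestamps_us) <= 0)[0]) + 1
                raise ValueError(
                    f"timestamps must be strictly increasing (photon {bad})"
                )

    def __len__(self) -> int:
        return self.timestamps_us.size

    @property
    def class_labels(self) -> np.ndarray:
        """Per-photon detection class (DD/AD/AA/DA codes).

        Requires excitation slots; run ``classify_photons`` first if the
        stream was built without them.
        """
        if self.excitation_slot is None:
            raise ValueError("stream has no excitation slots; classify first")
        ch, ex = self.channel, self.excitation_slot
        labels = np.empty(len(self), dtype=np.int8)
        labels[(ch == DONOR) & (ex == DONOR_EXC)] = DD
        labels[(ch == ACCEPTOR) & (ex == DONOR_EXC)] = AD
        labels[(ch == ACCEPTOR) & (ex == ACCEPTOR_EXC)] = AA
        labels[(ch == DONOR) & (ex == ACCEPTOR_EXC)] = DA
        return labels

    def class_counts(self) -> dict:
        labels = self.class_labels
        return {CLASS_NAMES[c]: int(np.sum(labels == c)) for c in (DD, AD, AA, DA)}


@dataclass
class Trace:
    """One surface-immobilized molecule's donor/acceptor intensity trajectory.

    ``valid_range`` is the analysable (pre-bleach) half-open frame interval.
    """

    trace_id: str
    frame_period_s: float
    donor: np.ndarray
    acceptor: np.ndarray
    valid_range: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor channels differ in length")
        if self.valid_range is None:
            self.valid_range = (0, self.donor.size)

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period_s

    def efficiency(self) -> np.ndarray:
        """Per-frame proximity ratio E = I_A/(I_A + I_D), NaN where undefined."""
        total = self.donor + self.acceptor
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(total > 0, self.acceptor / total, np.nan)
        return e

    def valid_efficiency(self) -> np.ndarray:
        """E(t) restricted to the analysable pre-bleach range."""
        lo, hi = self.valid_range
        return self.efficiency()[lo:hi]
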