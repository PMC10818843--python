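"""Adjacent stimulation/measurement protocol and measurement frames.

The adjacent (neighbouring) protocol injects current through each of the
``nE`` neighbouring electrode pairs in turn and, for every injection,
records the differential voltage on each neighbouring electrode pair not
touching a drive electrode.  A full cycle therefore yields
``nE * (nE - 3)`` values; for 16 electrodes that is 208.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Protocol", "VoltageFrame", "build_protocol"]


@dataclass(frozen=True, eq=False)
class Protocol:
    """Ordered list of (drive pair, measurement pair) patterns.

    ``patterns`` has one row per measurement with columns
    ``(drive_a, drive_b, meas_a, meas_b)`` holding 0-based electrode
    indices; a pair ``(k, k+1 mod nE)`` is the adjacent pair starting at
    electrode ``k``.  Current is driven from ``drive_a`` (source, +I)
    to ``drive_b`` (sink, -I) and the voltage is measured as
    ``u(meas_a) - u(meas_b)``.
    """

    n_electrodes: int
    patterns: np.ndarray
    current: float = 1.0

    def __len__(self) -> int:
        return self.patterns.shape[0]

    @property
    def drive_index(self) -> np.ndarray:
        """Adjacent-pair index (== first drive electrode) per pattern."""
        return self.patterns[:, 0]

    @property
    def measure_index(self) -> np.ndarray:
        """Adjacent-pair index (== first measurement electrode) per pattern."""
        return self.patterns[:, 2]


@dataclass(eq=False)
class VoltageFrame:
    """One frame of boundary voltages (V), aligned with a protocol."""

    values: np.ndarray
    protocol: Protocol = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.shape[0] != len(self.protocol):
            raise ValueError(
                f"frame length {self.values.shape} does not match the "
                f"protocol length {len(self.protocol)}"
            )

    def __len__(self) -> int:
        return self.values.shape[0]


def build_protocol(n_electrodes: int = 16, current: float = 1.0) -> Protocol:
    """Build the adjacent protocol for ``n_electrodes`` electrodes.

    Drive pairs are enumerated in ascending order (1-2, 2-3, ...,
    nE-1); for each drive, the measurement pairs run in ascending
    electrode order, skipping any pair that shares an electrode with the
    drive pair.  That yields ``nE - 3`` measurements per drive.

    Raises
    ------
    ValueError
        If ``n_electrodes < 4`` (no valid measurement pair exists).
    """
    if n_electrodes < 4:
        raise ValueError("the adjacent protocol needs at least 4 electrodes")
    if current <= 0:
        raise ValueError("current must be positive")
    rows = []
    for d in range(n_electrodes):
        drive = {d, (d + 1) % n_electrodes}
        for m in range(n_electrodes):
            pair = {m, (m + 1) % n_electrodes}
            if pair & drive:
                continue
            rows.append((d, (d + 1) % n_electrodes, m, (m + 1) % n_electrodes))
    patterns = np.asarray(rows, dtype=np.intp)
    assert patterns.shape[0] == n_electrodes * (n_electrodes - 3)
    return Protocol(n_electrodes=n_electrodes, patterns=patterns, current=float(current))
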