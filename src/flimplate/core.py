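"""Core data containers for time-gated FLIM data.

A time-gated FLIM measurement is a stack of photon-count frames, one per
gate delay: the detector integrates emission over a boxcar window of
``gate_width_ps`` starting ``delay`` picoseconds after each excitation
pulse.  The instrument response is never measured explicitly; instead a
reference dye of known short lifetime is acquired on the same gate
schedule and carries the IRF implicitly (see :mod:`flimplate.fitting`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GatedStack", "ReferenceDecay", "validate_gate_schedule"]


def validate_gate_schedule(gate_delays_ps: np.ndarray, gate_width_ps: float) -> np.ndarray:
    """Check that gate delays are strictly increasing and the width positive.

    Returns the delays as a float array.
    """
    delays = np.asarray(gate_delays_ps, dtype=float)
    if delays.ndim != 1 or delays.size < 1:
        raise ValueError("gate_delays_ps must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(delays)):
        raise ValueError("gate delays must be finite")
    if delays.size > 1 and not np.all(np.diff(delays) > 0):
        raise ValueError("gate delays must be strictly increasing")
    if not (gate_width_ps > 0):
        raise ValueError("gate_width_ps must be > 0")
    return delays


@dataclass
class GatedStack:
    """A stack of photon-count frames indexed by gate delay.

    Parameters
    ----------
    counts
        Array of shape ``(n_gates, height, width)``; non-negative photon
        counts.
    gate_delays_ps
        Strictly increasing gate opening times in picoseconds.
    gate_width_ps
        Boxcar gate width in picoseconds (common to all gates).
    meta
        Free-form metadata (well id, FOV index, simulation seed, ...).
    """

    counts: np.ndarray
    gate_delays_ps: np.ndarray
    gate_width_ps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be 3-D (gate, row, col)")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")
        self.gate_delays_ps = validate_gate_schedule(self.gate_delays_ps, self.gate_width_ps)
        if self.counts.shape[0] != self.gate_delays_ps.size:
            raise ValueError(
                f"{self.counts.shape[0]} count frames but "
                f"{self.gate_delays_ps.size} gate delays"
            )

    @property
    def n_gates(self) -> int:
        return int(self.counts.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[1], self.counts.shape[2]

    def photon_image(self) -> np.ndarray:
        """Total photons per pixel summed over the gate schedule."""
        return self.counts.sum(axis=0)

    def binned_decay(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-gate decay pooled over ``mask`` (all pixels if None)."""
        if mask is None:
            return self.counts.reshape(self.n_gates, -1).sum(axis=1)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.frame_shape:
            raise ValueError("mask shape does not match frame shape")
        return self.counts[:, mask].sum(axis=1)


@dataclass
class ReferenceDecay:
    """Gated measurement of a short-lifetime reference dye.

    The reference (e.g. DASPI) is measured on the same gate schedule as
    the samples it calibrates; its known mono-exponential lifetime
    ``tau_ref_ps`` lets the fitting express any sample decay through the
    measured reference without an explicit IRF.
    """

    counts: np.ndarray
    gate_delays_ps: np.ndarray
    gate_width_ps: float
    tau_ref_ps: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("reference counts must be 1-D (one value per gate)")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("reference counts must be finite and non-negative")
        self.gate_delays_ps = validate_gate_schedule(self.gate_delays_ps, self.gate_width_ps)
        if self.counts.size != self.gate_delays_ps.size:
            raise ValueError("reference counts and gate delays differ in length")
        if not (self.tau_ref_ps > 0):
            raise ValueError("tau_ref_ps must be > 0")

    @property
    def n_gates(self) -> int:
        return int(self.counts.size)

    def matches_schedule(self, stack: GatedStack, rtol: float = 1e-9) -> bool:
        return (
            stack.n_gates == self.n_gates
            and np.allclose(stack.gate_delays_ps, self.gate_delays_ps, rtol=rtol)
            and np.isclose(stack.gate_width_ps, self.gate_width_ps, rtol=rtol)
        )
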