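"""Fluorescence trace container.

A :class:`FluorescenceTrace` holds the intensity time series of one presynaptic
bouton (region of interest) in arbitrary fluorescence units, together with the
acquisition rate and the experimental condition (temperature, extracellular
Ca2+, probe).  All analysis stages are trace-in / trace-out and never mutate
their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["Condition", "FluorescenceTrace"]


@dataclass(frozen=True)
class Condition:
    """Experimental condition metadata attached to a trace."""

    temperature_c: float = 24.0
    calcium_mm: float = 2.0
    probe: str = "vGluT1-pHluorin"


@dataclass
class FluorescenceTrace:
    """One bouton's fluorescence intensity time series.

    Parameters
    ----------
    samples
        Intensity values (arbitrary units), one per frame.
    sampling_rate_hz
        Acquisition rate in frames per second; single-vesicle experiments use
        10 or 40 Hz but any positive rate is accepted.
    t0_s
        Time of the first frame, seconds.
    bouton_id
        Identifier of the region of interest.
    condition
        Temperature / Ca2+ / probe metadata.
    metadata
        Free-form provenance (corrections applied, seeds, fit parameters).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    t0_s: float = 0.0
    bouton_id: str = "bouton0"
    condition: Condition = field(default_factory=Condition)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if not (self.sampling_rate_hz > 0):
            raise ValueError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sampling_rate_hz

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Frame times in seconds (length equals the number of samples)."""
        return self.t0_s + np.arange(self.samples.size) / self.sampling_rate_hz

    def frame_of(self, t_s: float) -> int:
        """Index of the first frame at or after time ``t_s``."""
        idx = int(np.ceil((t_s - self.t0_s) * self.sampling_rate_hz - 1e-9))
        return max(idx, 0)

    def with_samples(self, samples: np.ndarray, **meta: Any) -> "FluorescenceTrace":
        """Copy of this trace with new sample values and updated metadata."""
        new = replace(self, samples=np.asarray(samples, dtype=float))
        new.metadata = {**self.metadata, **meta}
        return new
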