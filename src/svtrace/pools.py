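"""Surface vs internal probe pools from acid-quench / NH4Cl epochs.

The drop from resting Tyrode's fluorescence to the acid-quench level measures
the surface pool; the rise from rest to the NH4Cl (fully alkalinised) level
measures the internal pool.  Differencing makes the fractions invariant to
affine rescaling of the camera's arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import FluorescenceTrace

__all__ = ["PoolMeasurement", "surface_internal_ratio"]

TRANSITION_EXCLUDE_S = 2.0  # perfusion mixing after each solution switch


@dataclass(frozen=True)
class PoolMeasurement:
    f_rest: float
    f_acid: float
    f_nh4: float
    surface: float
    internal: float
    surface_fraction: float | None
    internal_fraction: float | None
    flagged: bool
    flag_reason: str = ""


def _epoch_mean(trace: FluorescenceTrace, start_s: float, end_s: float) -> float:
    if end_s - start_s < 5.0:
        raise ValueError("each epoch must last at least 5 s")
    a = trace.frame_of(start_s + TRANSITION_EXCLUDE_S)
    b = trace.frame_of(end_s)
    if b <= a:
        raise ValueError("epoch is empty after excluding the transition period")
    return float(trace.samples[a:b].mean())


def surface_internal_ratio(
    trace: FluorescenceTrace, epoch_annotations: pd.DataFrame
) -> PoolMeasurement:
    """Partition probe fluorescence into surface and internal pools.

    ``epoch_annotations`` has rows (label, start_s, end_s) with labels
    'rest', 'acid' and 'nh4'.  surface = f_rest - f_acid,
    internal = f_nh4 - f_rest; fractions normalise by their sum.  Negative
    pool values are flagged and fractions withheld.
    """
    epochs = {str(r.label): (float(r.start_s), float(r.end_s)) for r in epoch_annotations.itertuples()}
    missing = {"rest", "acid", "nh4"} - set(epochs)
    if missing:
        raise ValueError(f"missing epoch annotations: {sorted(missing)}")
    f_rest = _epoch_mean(trace, *epochs["rest"])
    f_acid = _epoch_mean(trace, *epochs["acid"])
    f_nh4 = _epoch_mean(trace, *epochs["nh4"])
    surface = f_rest - f_acid
    internal = f_nh4 - f_rest
    if surface < 0 or internal < 0:
        return PoolMeasurement(
            f_rest, f_acid, f_nh4, surface, internal, None, None, True,
            "negative pool value (expected f_nh4 >= f_rest >= f_acid)",
        )
    total = surface + internal
    if total <= 0:
        return PoolMeasurement(
            f_rest, f_acid, f_nh4, surface, internal, None, None, True, "zero total pool"
        )
    return PoolMeasurement(
        f_rest, f_acid, f_nh4, surface, internal,
        surface / total, internal / total, False,
    )
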