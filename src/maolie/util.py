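"""Small numeric helpers used across modules."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, the convention used in printed tables.

    numpy/python round half to even, which disagrees with how results are
    conventionally reported (e.g. -9.35 -> -9.4, not -9.4 vs -9.3 depending
    on parity).
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def round_half_away_array(x, decimals: int = 1):
    return np.array([round_half_away(float(v), decimals) for v in np.asarray(x).ravel()]).reshape(
        np.shape(x)
    )
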