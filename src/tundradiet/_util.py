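"""Small shared helpers: decimal rounding and proportion checks."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import numpy as np


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at `ndigits` decimals.

    Reported diet statistics follow the round-half-up convention common in
    ecological tables (1.25 -> 1.3 at one decimal), which differs from
    Python's banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def check_proportions(p: Mapping[str, float], *, tol: float = 1e-6,
                      name: str = "profile") -> None:
    """Raise ValueError unless values are non-negative and sum to 1 +- tol."""
    vals = np.asarray(list(p.values()), dtype=float)
    if vals.size == 0:
        raise ValueError(f"{name} is empty")
    if (vals < -1e-12).any():
        raise ValueError(f"{name} has negative proportions")
    s = vals.sum()
    if abs(s - 1.0) > tol:
        raise ValueError(f"{name} sums to {s:.6g}, expected 1 within {tol}")


def normalized(p: Mapping[str, float]) -> dict[str, float]:
    """Return `p` rescaled to sum to 1; error if the total mass is zero."""
    total = float(sum(p.values()))
    if total <= 0:
        raise ValueError("cannot normalize: total mass is zero")
    return {k: float(v) / total for k, v in p.items()}
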