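"""Small shared helpers: display rounding and packaged-data access."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import pandas as pd


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as in printed percentage tables.

    Python's built-in ``round`` is banker's rounding (2.65 -> 2.6); printed
    biodiversity tables conventionally round 2.65 -> 2.7.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up to ``ndigits`` decimals."""
    return round_half_up(100.0 * numerator / denominator, ndigits)


def load_packaged_csv(name: str) -> pd.DataFrame:
    """Read a CSV shipped under ``mycocheck/data``."""
    ref = resources.files("mycocheck").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
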