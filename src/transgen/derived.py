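"""Deterministic per-animal derived quantities.

All operations here are pure arithmetic on measured inputs: average weight
gain over the exponential growth window, sperm-kinematics coefficients and
total sperm per ejaculate, and mean litter size per parity group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from transgen.util import round_half_up

GROWTH_WINDOW_DAYS = 35  # weeks 4 -> 9

#: Kinematics dialects.  "as-printed" follows the source table legend
#: (WOB = VSL/VAP x 100, which collides with the conventional STR);
#: "conventional" uses the common CASA definitions (STR = VSL/VAP,
#: WOB = VAP/VCL).
KINEMATICS_DIALECTS = ("as-printed", "conventional")


@dataclass(frozen=True)
class SpermDerived:
    tse: float  # 10^6 spermatozoa
    lin: float  # percent
    str_pct: float  # percent (straightness)
    wob: float  # percent
    defined: bool = True


def awg(w4: float, w9: float) -> float:
    """Average weight gain (g/day) between weeks 4 and 9: (w9 - w4) / 35."""
    if w4 < 0 or w9 < 0:
        raise ValueError("weights must be non-negative")
    return (w9 - w4) / GROWTH_WINDOW_DAYS


def sperm_derived(
    vol: float,
    con: float,
    vcl: float,
    vsl: float,
    vap: float,
    dialect: str = "as-printed",
) -> SpermDerived:
    """Total sperm per ejaculate and kinematic coefficients.

    Zero VCL or VAP leaves the affected ratios NaN with ``defined=False``
    rather than raising, so record streams keep flowing.
    """
    if dialect not in KINEMATICS_DIALECTS:
        raise ValueError(f"unknown kinematics dialect {dialect!r}")
    tse = vol * con
    if vcl <= 0 or vap <= 0:
        return SpermDerived(tse=tse, lin=math.nan, str_pct=math.nan, wob=math.nan,
                            defined=False)
    lin = 100.0 * vsl / vcl
    str_pct = 100.0 * vsl / vap
    wob = 100.0 * vsl / vap if dialect == "as-printed" else 100.0 * vap / vcl
    return SpermDerived(tse=tse, lin=lin, str_pct=str_pct, wob=wob)


def mean_litter_size(live_births: int, parities: int, ndigits: Optional[int] = None) -> float:
    """Live births per parity; optionally rounded half-up for table display."""
    if parities <= 0:
        raise ValueError("parities must be positive")
    if live_births < 0:
        raise ValueError("live_births must be non-negative")
    value = live_births / parities
    if ndigits is not None:
        return round_half_up(value, ndigits)
    return value
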