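"""Experimental-design helpers for the sugar-mixture validation library.

The reference wet-lab design prepares mixtures of four sugars (glucose,
sucrose, fructose, maltose) in 375 uL wells as a full factorial over four
volume levels per sugar (0, 30, 75, 120 uL), topped up with water.  Tuples
whose total sugar volume exceeds the well capacity, and the tuple with no
sugar at all, are discarded, leaving 240 distinct mixtures.  Ground-truth
fractional abundances follow from the volume ratios (water is the fifth
component).
"""

from __future__ import annotations

import itertools
from typing import Sequence

import pandas as pd

from .errors import ParameterError

__all__ = ["SUGARS", "VOLUME_LEVELS_UL", "WELL_VOLUME_UL", "sugar_mixture_design"]

SUGARS = ("glucose", "sucrose", "fructose", "maltose")
VOLUME_LEVELS_UL = (0.0, 30.0, 75.0, 120.0)
WELL_VOLUME_UL = 375.0


def sugar_mixture_design(
    levels: Sequence[float] = VOLUME_LEVELS_UL,
    sugars: Sequence[str] = SUGARS,
    well_volume: float = WELL_VOLUME_UL,
) -> pd.DataFrame:
    """Enumerate the admissible factorial sugar mixtures.

    Returns one row per mixture with the per-sugar volumes, the water
    top-up volume, and the ground-truth fractional abundances (volume
    fractions, water included) for each component.  With the default
    4-level x 4-sugar design and 375 uL cap this yields 240 mixtures.
    """
    if well_volume <= 0:
        raise ParameterError("well_volume must be > 0")
    rows = []
    for combo in itertools.product(levels, repeat=len(sugars)):
        total = sum(combo)
        if total > well_volume:  # exceeds the well
            continue
        if total == 0:  # the no-sugar tuple
            continue
        water = well_volume - total
        row = {f"{s}_ul": v for s, v in zip(sugars, combo)}
        row["water_ul"] = water
        for s, v in zip(sugars, combo):
            row[f"{s}_fraction"] = v / well_volume
        row["water_fraction"] = water / well_volume
        rows.append(row)
    return pd.DataFrame(rows)
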