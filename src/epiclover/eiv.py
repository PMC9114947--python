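"""Mean weighted Ellenberg indicator values per site.

Each plant species carries ordinal indicator values (1-9) for light (L),
soil moisture (M), soil reaction/pH (R) and soil nitrogen (N) describing
its realized environmental optimum.  A site's indicator value is the
abundance-weighted mean over the species recorded there:

    EIV_site = sum_s(abundance_s * EIV_s) / sum_s(abundance_s)

restricted to species with a numeric value for the indicator; species
marked indifferent ("x") or absent from the indicator list are excluded
from both sums.  Abundances are used on whatever cover scale is supplied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["mean_weighted_eiv", "INDICATORS"]

INDICATORS = ("L", "M", "R", "N")


def _normalize_name(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


def mean_weighted_eiv(releves: pd.DataFrame, eivs: pd.DataFrame, indicator: str) -> pd.Series:
    """Abundance-weighted mean indicator value per site.

    Parameters
    ----------
    releves : sites x species abundance table (non-negative).
    eivs : species x indicator table with NaN for indifferent species.
    indicator : one of ``L``, ``M``, ``R``, ``N``.

    Species names are matched exactly after whitespace and case
    normalization; unmatched relevé species are logged and excluded.
    """
    if indicator not in INDICATORS:
        raise ValidationError(f"unknown indicator {indicator!r}; expected one of {INDICATORS}")
    if indicator not in eivs.columns:
        raise ValidationError(f"indicator table has no column {indicator!r}")
    abund = releves.to_numpy(dtype=float)
    if (abund < 0).any():
        raise ValidationError("negative abundances in relevé table")
    if not (abund.sum(axis=1) > 0).all():
        empty = releves.index[abund.sum(axis=1) <= 0].tolist()
        raise ValidationError(f"sites without any recorded species: {empty}")

    lookup = {_normalize_name(sp): v for sp, v in eivs[indicator].items()}
    values = np.full(releves.shape[1], np.nan)
    unmatched = []
    for j, sp in enumerate(releves.columns):
        key = _normalize_name(sp)
        if key in lookup:
            values[j] = lookup[key]
        else:
            unmatched.append(str(sp))
    if unmatched:
        logger.warning("species without indicator values excluded: %s", ", ".join(unmatched))

    scorable = ~np.isnan(values)
    out = {}
    for i, site in enumerate(releves.index):
        w = abund[i, scorable]
        v = values[scorable]
        used = w > 0
        if not used.any():
            raise ValidationError(
                f"site {site!r}: no species with a numeric {indicator} value"
            )
        out[site] = float((w[used] * v[used]).sum() / w[used].sum())
    return pd.Series(out, name=f"eiv_{indicator}")
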