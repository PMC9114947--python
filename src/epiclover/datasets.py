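"""Packaged reference values from the red-clover grassland study system.

The published study genotyped *Trifolium pratense* from ten grassland
sites (populations 1-5 calcareous grassland, 6-10 oat-grass meadow; 16
individuals each) at 124 AFLP loci and 159 MSAP fragments scored into 408
u/m/h subepiloci.  Its per-population diversity table and habitat-level
indicator means are shipped here so aggregate statistics and group tests
can be recomputed without the raw fragment matrices (which were never
deposited in a public archive).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_reference_diversity",
    "reference_design",
    "REFERENCE_EIV_MEANS",
    "CG_POPULATIONS",
    "OM_POPULATIONS",
]

CG_POPULATIONS = ["1", "2", "3", "4", "5"]
OM_POPULATIONS = ["6", "7", "8", "9", "10"]

# columns: AFLP, MSAP-all, h, m, u; rows: populations 1..10
_PCT_BANDS = [
    [99.2, 71.8, 42.2, 84.7, 82.4],
    [98.4, 71.3, 39.7, 82.6, 85.1],
    [98.4, 69.4, 43.1, 81.3, 78.4],
    [100.0, 72.5, 44.8, 78.5, 88.5],
    [99.2, 76.0, 52.6, 84.0, 86.5],
    [97.6, 74.3, 46.6, 84.0, 86.5],
    [97.6, 81.6, 60.3, 88.2, 91.9],
    [97.6, 70.1, 33.6, 82.6, 86.5],
    [99.2, 75.2, 47.4, 81.9, 90.5],
    [99.2, 74.5, 42.2, 83.3, 91.2],
]
_PCT_PRIVATE = [
    [0.0, 1.7, 6.0, 0.0, 0.0],
    [0.0, 0.5, 0.9, 0.7, 0.0],
    [0.0, 1.0, 2.6, 0.7, 0.0],
    [0.0, 0.5, 1.7, 0.0, 0.0],
    [0.0, 0.5, 0.9, 0.7, 0.0],
    [0.0, 0.0, 0.0, 0.0, 0.0],
    [0.0, 1.0, 2.6, 0.7, 0.0],
    [0.0, 1.0, 2.6, 0.0, 0.7],
    [0.0, 1.2, 2.6, 0.7, 0.7],
    [0.0, 0.7, 2.6, 0.0, 0.0],
]
_PCT_POLYMORPHIC = [
    [46.8, 68.1, 42.2, 79.2, 77.7],
    [52.4, 68.1, 39.7, 79.2, 79.7],
    [50.0, 64.0, 43.1, 73.6, 71.0],
    [50.8, 67.7, 44.8, 75.0, 78.4],
    [48.4, 71.8, 52.6, 78.5, 80.4],
    [45.2, 69.1, 46.6, 79.9, 76.4],
    [54.0, 78.4, 60.3, 85.4, 85.8],
    [46.8, 65.4, 33.6, 79.9, 76.4],
    [50.0, 71.6, 47.4, 79.9, 82.4],
    [51.6, 69.1, 42.2, 78.5, 81.1],
]
_MEAN_SI = [
    [0.36, 0.45, 0.23, 0.54, 0.54],
    [0.40, 0.45, 0.22, 0.55, 0.55],
    [0.36, 0.42, 0.21, 0.52, 0.50],
    [0.35, 0.43, 0.22, 0.51, 0.52],
    [0.34, 0.49, 0.26, 0.57, 0.58],
    [0.31, 0.47, 0.25, 0.57, 0.55],
    [0.37, 0.52, 0.30, 0.61, 0.61],
    [0.34, 0.45, 0.17, 0.56, 0.56],
    [0.35, 0.48, 0.25, 0.57, 0.59],
    [0.35, 0.47, 0.22, 0.56, 0.57],
]

_MARKER_SETS = ["AFLP", "MSAP-all", "h", "m", "u"]

#: habitat-level mean weighted Ellenberg indicator values (CG vs OM).
REFERENCE_EIV_MEANS = {
    "L": {"CG": 7.45, "OM": 7.04},
    "M": {"CG": 3.43, "OM": 4.86},
    "R": {"CG": 7.63, "OM": 6.94},
    "N": {"CG": 2.69, "OM": 5.29},
}


def reference_design() -> dict:
    """Dimensions and marker counts of the reference study."""
    return {
        "n_individuals": 160,
        "n_populations": 10,
        "n_groups": 2,
        "n_per_population": 16,
        "n_aflp_loci": 124,
        "n_msap_fragments": 159,
        "n_subepiloci": {"total": 408, "h": 116, "m": 144, "u": 148},
        "genotyping_error_pct": {"AFLP": 5.24, "MSAP": 1.02},
    }


def load_reference_diversity(marker_set: str = "AFLP") -> pd.DataFrame:
    """Published per-population diversity values for one marker set
    (``AFLP``, ``MSAP-all``, ``h``, ``m`` or ``u``).

    Returns a DataFrame indexed by population ("1".."10"; 1-5 calcareous
    grassland, 6-10 oat-grass meadow) with columns ``pct_bands``,
    ``pct_private_bands``, ``pct_polymorphic`` and ``mean_SI``, as
    printed (population rows only; recompute aggregates as needed).
    """
    if marker_set not in _MARKER_SETS:
        raise KeyError(f"unknown marker set {marker_set!r}; expected one of {_MARKER_SETS}")
    j = _MARKER_SETS.index(marker_set)
    idx = pd.Index(CG_POPULATIONS + OM_POPULATIONS, name="population_id")
    return pd.DataFrame(
        {
            "pct_bands": [row[j] for row in _PCT_BANDS],
            "pct_private_bands": [row[j] for row in _PCT_PRIVATE],
            "pct_polymorphic": [row[j] for row in _PCT_POLYMORPHIC],
            "mean_SI": [row[j] for row in _MEAN_SI],
        },
        index=idx,
    )
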