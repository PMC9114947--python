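"""Per-population band diversity for dominant markers.

For every population the table reports

* ``pct_bands`` — percent of markers with at least one presence,
* ``pct_private_bands`` — percent of markers present here and absent from
  every other population,
* ``pct_polymorphic`` — percent of markers with both states observed
  within the population (no minimum-frequency threshold),
* ``mean_SI`` — the mean Shannon information index: per marker the
  two-state entropy ``-(p*log2(p) + (1-p)*log2(1-p))`` of the band
  frequency ``p``, averaged over all markers (monomorphic markers
  contribute 0), so ``0 <= mean_SI <= 1``.

A grand ``mean`` row and a ``s.e.`` row (sample standard deviation across
populations over sqrt(number of populations)) are appended.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .data import BinaryMarkerMatrix, SampleRecord, ValidationError, group_indices

__all__ = ["shannon_index_locus", "population_diversity"]


def shannon_index_locus(p: float) -> float:
    """Two-state Shannon entropy (base 2) of a band frequency, with the
    convention ``0*log2(0) = 0``; maximal (1.0) at p = 0.5."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"band frequency {p} outside [0, 1]")
    si = 0.0
    if 0.0 < p < 1.0:
        si = -(p * np.log2(p) + (1.0 - p) * np.log2(1.0 - p))
    return float(si)


def _entropy_vector(freqs: np.ndarray) -> np.ndarray:
    out = np.zeros_like(freqs, dtype=float)
    inner = (freqs > 0.0) & (freqs < 1.0)
    p = freqs[inner]
    out[inner] = -(p * np.log2(p) + (1.0 - p) * np.log2(1.0 - p))
    return out


def population_diversity(
    matrix: BinaryMarkerMatrix,
    samples: Sequence[SampleRecord],
    min_individuals: int = 2,
) -> pd.DataFrame:
    """Diversity table with one row per population plus ``mean`` and
    ``s.e.`` rows; columns ``pct_bands``, ``pct_private_bands``,
    ``pct_polymorphic``, ``mean_SI``.

    ``samples`` must assign every individual of ``matrix`` to a population
    of at least ``min_individuals`` members.
    """
    pop_of = {s.sample_id: s.population_id for s in samples}
    missing = [s for s in matrix.sample_ids if s not in pop_of]
    if missing:
        raise ValidationError(f"samples without population assignment: {missing[:5]}")
    pops = group_indices(matrix.sample_ids, [pop_of[s] for s in matrix.sample_ids])
    for pop, idx in pops.items():
        if len(idx) < min_individuals:
            raise ValidationError(
                f"population {pop!r} has {len(idx)} individuals (< {min_individuals})"
            )

    L = matrix.n_markers
    if L == 0:
        raise ValidationError("matrix has no markers")
    present = {pop: matrix.values[idx].any(axis=0) for pop, idx in pops.items()}

    rows = {}
    for pop, idx in pops.items():
        sub = matrix.values[idx]
        n = len(idx)
        freq = sub.mean(axis=0)
        others = [present[q] for q in pops if q != pop]
        present_elsewhere = np.logical_or.reduce(others) if others else np.zeros(L, dtype=bool)
        rows[pop] = {
            "pct_bands": 100.0 * present[pop].sum() / L,
            "pct_private_bands": 100.0 * (present[pop] & ~present_elsewhere).sum() / L,
            "pct_polymorphic": 100.0 * ((freq > 0.0) & (freq < 1.0)).sum() / L,
            "mean_SI": float(_entropy_vector(freq).mean()),
        }

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "population_id"
    grand = table.mean(axis=0)
    k = len(table)
    se = table.std(axis=0, ddof=1) / np.sqrt(k) if k > 1 else table.iloc[0] * np.nan
    table.loc["mean"] = grand
    table.loc["s.e."] = se
    return table
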