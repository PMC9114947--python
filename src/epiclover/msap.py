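"""MSAP subepilocus scoring ("mixed scoring 2") and reproducibility.

MSAP profiles come in pairs: the same fragments amplified after digestion
with HpaII and with MspI, two isoschizomers that cut CCGG sites but differ
in their sensitivity to cytosine methylation.  The pair of presence calls
at a fragment therefore encodes a methylation state:

=============  ==============  =========================================
HpaII call     MspI call       state
=============  ==============  =========================================
1              1               u  (unmethylated)
0              1               m  (internal cytosine hemi/fully methylated)
1              0               h  (external cytosine hemimethylated)
0              0               uninformative (fragment absent)
=============  ==============  =========================================

Mixed scoring 2 turns each fragment into three mutually exclusive binary
subepilocus columns (u, m, h): an individual scores 1 in exactly the
column matching its state and 0 elsewhere; uninformative individuals score
0 everywhere.  Columns that are all-zero across every individual carry no
signal and are dropped; monomorphic *present* columns are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (
    BinaryMarkerMatrix,
    MsapProfilePair,
    SubepilocusMatrix,
    ValidationError,
    METHYLATION_CLASSES,
)

__all__ = [
    "classify_fragment_state",
    "mixed_scoring_2",
    "genotyping_error_rate",
    "reconstruct_profiles",
    "ScoringReport",
]

#: state -> (HpaII call, MspI call)
STATE_TO_CALLS = {"u": (1, 1), "m": (0, 1), "h": (1, 0), "uninformative": (0, 0)}
_CALLS_TO_STATE = {v: k for k, v in STATE_TO_CALLS.items()}


@dataclass(frozen=True)
class ScoringReport:
    """Column bookkeeping of one mixed-scoring-2 run."""

    n_fragments: int
    n_subepiloci_total: int
    n_u: int
    n_m: int
    n_h: int
    n_dropped_columns: int

    def __post_init__(self) -> None:
        if self.n_u + self.n_m + self.n_h != self.n_subepiloci_total:
            raise ValidationError("class counts do not sum to total subepiloci")
        if self.n_subepiloci_total + self.n_dropped_columns != 3 * self.n_fragments:
            raise ValidationError("retained + dropped columns must equal 3 x fragments")

    def as_dict(self) -> dict:
        return {
            "n_fragments": self.n_fragments,
            "n_subepiloci_total": self.n_subepiloci_total,
            "n_u": self.n_u,
            "n_m": self.n_m,
            "n_h": self.n_h,
            "n_dropped_columns": self.n_dropped_columns,
        }


def classify_fragment_state(hpa_call: int, msp_call: int) -> str:
    """Methylation state of one individual at one fragment from its pair of
    enzyme-profile calls.  Total on binary inputs; see the module table."""
    if hpa_call not in (0, 1) or msp_call not in (0, 1):
        raise ValidationError(f"calls must be 0/1, got ({hpa_call!r}, {msp_call!r})")
    return _CALLS_TO_STATE[(int(hpa_call), int(msp_call))]


def mixed_scoring_2(profiles: MsapProfilePair) -> tuple[SubepilocusMatrix, ScoringReport]:
    """Score a paired HpaII/MspI profile into u/m/h subepilocus columns.

    Returns the subepilocus matrix (columns named ``<fragment>_<class>``)
    and a :class:`ScoringReport` with retained/dropped column counts.
    """
    hpa, msp = profiles.hpa.values, profiles.msp.values
    n_ind, n_frag = hpa.shape

    # per-fragment indicator stacks; order u, m, h within each fragment
    u = (hpa == 1) & (msp == 1)
    m = (hpa == 0) & (msp == 1)
    h = (hpa == 1) & (msp == 0)
    stacks = {"u": u, "m": m, "h": h}

    cols, col_ids, col_classes, col_source = [], [], [], []
    n_dropped = 0
    kept = {c: 0 for c in METHYLATION_CLASSES}
    for j, frag in enumerate(profiles.fragment_ids):
        for cls in METHYLATION_CLASSES:
            col = stacks[cls][:, j].astype(np.int8)
            if col.any():
                cols.append(col)
                col_ids.append(f"{frag}_{cls}")
                col_classes.append(cls)
                col_source.append(frag)
                kept[cls] += 1
            else:
                n_dropped += 1

    values = np.column_stack(cols) if cols else np.zeros((n_ind, 0), dtype=np.int8)
    base = BinaryMarkerMatrix(profiles.sample_ids, col_ids, values, label="MSAP-all")
    sub = SubepilocusMatrix(base=base, classes=col_classes, source_fragment=col_source)
    report = ScoringReport(
        n_fragments=n_frag,
        n_subepiloci_total=sum(kept.values()),
        n_u=kept["u"], n_m=kept["m"], n_h=kept["h"],
        n_dropped_columns=n_dropped,
    )
    return sub, report


def reconstruct_profiles(sub: SubepilocusMatrix, fragment_ids: list[str] | None = None) -> MsapProfilePair:
    """Invert mixed scoring 2: rebuild the HpaII/MspI call pair of every
    individual at every fragment from the subepilocus indicators.

    Fragments whose three columns were all dropped (all individuals
    uninformative) can only be reconstructed if listed in ``fragment_ids``;
    they come back as all-(0,0).
    """
    if fragment_ids is None:
        fragment_ids = list(dict.fromkeys(sub.source_fragment))
    n_ind = sub.base.n_samples
    hpa = np.zeros((n_ind, len(fragment_ids)), dtype=np.int8)
    msp = np.zeros_like(hpa)
    frag_pos = {f: j for j, f in enumerate(fragment_ids)}
    for col, (frag, cls) in enumerate(zip(sub.source_fragment, sub.classes)):
        j = frag_pos[frag]
        hp, ms = STATE_TO_CALLS[cls]
        present = sub.base.values[:, col] == 1
        hpa[present, j] |= hp
        msp[present, j] |= ms
    hpa_m = BinaryMarkerMatrix(sub.base.sample_ids, fragment_ids, hpa, label="HpaII")
    msp_m = BinaryMarkerMatrix(sub.base.sample_ids, fragment_ids, msp, label="MspI")
    return MsapProfilePair(hpa=hpa_m, msp=msp_m)


def genotyping_error_rate(original: BinaryMarkerMatrix, replicate: BinaryMarkerMatrix) -> float:
    """Reproducibility error in percent: mismatching cells over all compared
    cells, across the individuals present in both matrices.

    The replicate's samples must be a subset of the original's; markers
    must match exactly (same ids, same order not required).
    """
    if set(replicate.marker_ids) != set(original.marker_ids):
        raise ValidationError("original and replicate score different marker sets")
    rep = replicate.select_markers(original.marker_ids)
    shared = [s for s in rep.sample_ids if s in set(original.sample_ids)]
    if not shared:
        raise ValidationError("no overlapping samples between original and replicate")
    orig_rows = original.reindex_samples(shared).values
    rep_rows = rep.reindex_samples(shared).values
    mismatches = int((orig_rows != rep_rows).sum())
    total = orig_rows.size
    return 100.0 * mismatches / total
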