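"""Core data containers for band-based (epi)genetic analyses.

The currency of the whole pipeline is the binary presence/absence matrix:
individuals in rows, dominant markers (AFLP loci, MSAP fragments or the
u/m/h subepiloci derived from them) in columns, every cell 0 or 1 with no
missing calls.  Distances, diversity statistics and variance partitions are
all computed from these matrices, so the containers here validate their
invariants eagerly and everything downstream may assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "SiteRecord",
    "BinaryMarkerMatrix",
    "MsapProfilePair",
    "SubepilocusMatrix",
    "DistanceMatrix",
    "ValidationError",
    "METHYLATION_CLASSES",
]

#: Subepilocus methylation classes: u = unmethylated (band in both enzyme
#: profiles), m = internal-cytosine methylation (MspI-only band),
#: h = external-cytosine hemimethylation (HpaII-only band).
METHYLATION_CLASSES = ("u", "m", "h")


class ValidationError(ValueError):
    """An input violated a structural invariant of a container."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i, x in enumerate(ids):
        if x in seen:
            raise ValidationError(f"duplicated {what} {x!r} (positions {seen[x]} and {i})")
        seen[x] = i


@dataclass(frozen=True)
class SampleRecord:
    """One sampled individual and its place in the sampling hierarchy."""

    sample_id: str
    population_id: str
    habitat: str


@dataclass(frozen=True)
class SiteRecord:
    """A sampled population site: location, habitat group and optional
    mean weighted Ellenberg indicator values (light L, moisture M,
    soil reaction R, nitrogen N; each on the ordinal 1-9 scale)."""

    population_id: str
    habitat: str
    latitude: float
    longitude: float
    eiv_L: float | None = None
    eiv_M: float | None = None
    eiv_R: float | None = None
    eiv_N: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"site {self.population_id!r}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"site {self.population_id!r}: longitude {self.longitude} outside [-180, 180]"
            )
        for name in ("eiv_L", "eiv_M", "eiv_R", "eiv_N"):
            v = getattr(self, name)
            if v is not None and not (1.0 <= v <= 9.0):
                raise ValidationError(
                    f"site {self.population_id!r}: {name}={v} outside the Ellenberg range [1, 9]"
                )


def validate_metadata(samples: Sequence[SampleRecord], sites: Sequence[SiteRecord] | None = None) -> None:
    """Check hierarchy consistency: unique sample ids, one habitat per
    population, and (if sites are given) every population known."""
    _check_unique([s.sample_id for s in samples], "sample_id")
    hab_of: dict[str, str] = {}
    for s in samples:
        prev = hab_of.setdefault(s.population_id, s.habitat)
        if prev != s.habitat:
            raise ValidationError(
                f"population {s.population_id!r} assigned two habitats: {prev!r} and {s.habitat!r}"
            )
    if sites is not None:
        _check_unique([t.population_id for t in sites], "population_id")
        known = {t.population_id: t.habitat for t in sites}
        for s in samples:
            if s.population_id not in known:
                raise ValidationError(
                    f"sample {s.sample_id!r} references unknown population {s.population_id!r}"
                )
            if known[s.population_id] != s.habitat:
                raise ValidationError(
                    f"population {s.population_id!r}: habitat {s.habitat!r} in metadata "
                    f"but {known[s.population_id]!r} in site table"
                )


class BinaryMarkerMatrix:
    """Individuals x markers presence/absence matrix.

    Parameters
    ----------
    sample_ids : ordered ids of the individuals (rows).
    marker_ids : ordered ids of the markers (columns).
    values : array-like of shape (n_samples, n_markers), strictly 0/1.
    label : marker-set label, e.g. ``"AFLP"``, ``"MSAP-all"``, ``"m"``.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        marker_ids: Sequence[str],
        values,
        label: str = "",
    ) -> None:
        sample_ids = [str(x) for x in sample_ids]
        marker_ids = [str(x) for x in marker_ids]
        _check_unique(sample_ids, "sample_id")
        _check_unique(marker_ids, "marker_id")
        arr = np.asarray(values)
        if arr.ndim != 2 or arr.shape != (len(sample_ids), len(marker_ids)):
            raise ValidationError(
                f"values shape {arr.shape} inconsistent with {len(sample_ids)} samples "
                f"x {len(marker_ids)} markers"
            )
        if arr.size and not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise ValidationError(
                f"non-binary cell at sample {sample_ids[bad[0]]!r}, "
                f"marker {marker_ids[bad[1]]!r}: {arr[bad[0], bad[1]]!r}"
            )
        self.sample_ids = list(sample_ids)
        self.marker_ids = list(marker_ids)
        self.values = arr.astype(np.int8)
        self.label = label

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "BinaryMarkerMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(), label)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=self.sample_ids, columns=self.marker_ids)

    def reindex_samples(self, order: Sequence[str]) -> "BinaryMarkerMatrix":
        """Reorder rows to ``order`` (metadata order is authoritative)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in order if s not in pos]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing[:5]}")
        idx = [pos[s] for s in order]
        return BinaryMarkerMatrix(list(order), self.marker_ids, self.values[idx], self.label)

    def select_markers(self, marker_ids: Sequence[str], label: str | None = None) -> "BinaryMarkerMatrix":
        pos = {m: j for j, m in enumerate(self.marker_ids)}
        idx = [pos[m] for m in marker_ids]
        return BinaryMarkerMatrix(
            self.sample_ids, list(marker_ids), self.values[:, idx],
            self.label if label is None else label,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMarkerMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<BinaryMarkerMatrix{lab} {self.n_samples} samples x {self.n_markers} markers>"


@dataclass
class MsapProfilePair:
    """Paired EcoRI/HpaII and EcoRI/MspI fragment profiles of one MSAP run.

    Both matrices must list the same individuals and the same fragments in
    the same order; the pair of calls at a fragment encodes the methylation
    state of its CCGG site.
    """

    hpa: BinaryMarkerMatrix
    msp: BinaryMarkerMatrix

    def __post_init__(self) -> None:
        if self.hpa.sample_ids != self.msp.sample_ids:
            raise ValidationError("HpaII and MspI profiles list different samples (or order)")
        if self.hpa.marker_ids != self.msp.marker_ids:
            raise ValidationError("HpaII and MspI profiles list different fragments (or order)")

    @property
    def sample_ids(self) -> list[str]:
        return self.hpa.sample_ids

    @property
    def fragment_ids(self) -> list[str]:
        return self.hpa.marker_ids


@dataclass
class SubepilocusMatrix:
    """Binary marker matrix whose columns are u/m/h methylation-state
    indicators derived from MSAP fragments (``mixed scoring 2``)."""

    base: BinaryMarkerMatrix
    classes: list[str] = field(default_factory=list)
    source_fragment: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.classes) != self.base.n_markers or len(self.source_fragment) != self.base.n_markers:
            raise ValidationError("class / source-fragment annotations must match column count")
        bad = sorted(set(self.classes) - set(METHYLATION_CLASSES))
        if bad:
            raise ValidationError(f"unknown methylation classes: {bad}")
        seen: set[tuple[str, str]] = set()
        for frag, cls in zip(self.source_fragment, self.classes):
            if (frag, cls) in seen:
                raise ValidationError(f"fragment {frag!r} contributes class {cls!r} twice")
            seen.add((frag, cls))

    def class_subset(self, cls: str) -> BinaryMarkerMatrix:
        """The sub-matrix of one methylation class (u, m or h)."""
        if cls not in METHYLATION_CLASSES:
            raise ValidationError(f"unknown methylation class {cls!r}")
        ids = [m for m, c in zip(self.base.marker_ids, self.classes) if c == cls]
        return self.base.select_markers(ids, label=cls)

    def class_counts(self) -> dict[str, int]:
        return {c: self.classes.count(c) for c in METHYLATION_CLASSES}


class DistanceMatrix:
    """Labelled symmetric non-negative matrix with a zero diagonal.

    Used both at the individual level (squared Euclidean band distances)
    and at the population level (pairwise PhiPT, geographic km, habitat
    dissimilarity).
    """

    def __init__(self, labels: Sequence[str], values, name: str = "") -> None:
        labels = [str(x) for x in labels]
        _check_unique(labels, "label")
        arr = np.asarray(values, dtype=float)
        n = len(labels)
        if arr.shape != (n, n):
            raise ValidationError(f"distance matrix shape {arr.shape} != ({n}, {n})")
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal is not zero")
        if arr.size and arr.min() < -1e-10:
            raise ValidationError("distance matrix has negative entries")
        arr = (arr + arr.T) / 2.0
        np.fill_diagonal(arr, 0.0)
        np.clip(arr, 0.0, None, out=arr)
        self.labels = list(labels)
        self.values = arr
        self.name = name

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy ``squareform``) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = [pos[str(l)] for l in labels]
        return DistanceMatrix([str(l) for l in labels], self.values[np.ix_(idx, idx)], self.name)

    def permuted(self, order: np.ndarray) -> np.ndarray:
        """Values with rows and columns jointly reordered (labels dropped)."""
        return self.values[np.ix_(order, order)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "") -> "DistanceMatrix":
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=self.labels, columns=self.labels)

    def __repr__(self) -> str:
        nm = f" {self.name!r}" if self.name else ""
        return f"<DistanceMatrix{nm} n={self.n}>"


def group_indices(labels: Sequence[str], group_of: Mapping[str, str] | Iterable[str]) -> dict[str, np.ndarray]:
    """Map each group label to the integer row positions of its members."""
    if isinstance(group_of, Mapping):
        groups = [group_of[l] for l in labels]
    else:
        groups = list(group_of)
        if len(groups) != len(labels):
            raise ValidationError("group assignment length mismatch")
    out: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(groups):  # preserve first-appearance order
        out[g] = np.flatnonzero(np.asarray([x == g for x in groups]))
    return out
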