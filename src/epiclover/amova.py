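"""Hierarchical analysis of molecular variance (AMOVA) for band data.

Pairwise squared Euclidean distances between binary band profiles (the
number of markers at which two individuals differ) are partitioned into
hierarchical variance components — among habitat groups, among populations
within groups, within populations — following the classic distance-based
sums-of-squares decomposition with unequal-sample-size coefficients.
Fixation analogues for dominant data are reported as Phi-statistics:

* ``phi_RT`` = Va / (Va+Vb+Vc)    (among groups / total)
* ``phi_PR`` = Vb / (Vb+Vc)       (among populations / within groups)
* ``phi_PT`` = (Va+Vb) / (Va+Vb+Vc)  (among populations+groups / total)

Negative variance-component estimates are truncated to zero before
percentages and Phi are formed.  Significance comes from label
permutations with the (b+1)/(m+1) p-value estimator; each statistic has
its own permutation scheme (see :meth:`Amova.fit`).

Usage follows the model/results pattern::

    model = Amova(dist, populations=pop_of, groups=group_of)
    res = model.fit(n_permutations=999, seed=17)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data import BinaryMarkerMatrix, DistanceMatrix, ValidationError, group_indices

__all__ = [
    "squared_euclidean_distances",
    "Amova",
    "AmovaResults",
    "amova_coefficients",
    "pairwise_phi_pt",
]


def squared_euclidean_distances(matrix: BinaryMarkerMatrix) -> DistanceMatrix:
    """Individual-by-individual squared Euclidean distance: for 0/1 band
    data this is the count of markers at which the two profiles differ."""
    d = squareform(pdist(matrix.values.astype(float), metric="sqeuclidean"))
    return DistanceMatrix(matrix.sample_ids, d, name=matrix.label or "sqeuclidean")


def _pair_sum(d: np.ndarray, idx: np.ndarray) -> float:
    """Sum of d over unordered pairs within idx."""
    block = d[np.ix_(idx, idx)]
    return float(block.sum()) / 2.0


def amova_coefficients(pop_sizes: Sequence[int], group_of_pop: Sequence[int]) -> tuple[float, float, float]:
    """Unequal-sample-size coefficients (n', n'', n''') of the two-level
    design; with K populations of equal size n in G groups these reduce to
    n' = n'' = n and n''' = N/G."""
    sizes = np.asarray(pop_sizes, dtype=float)
    grp = np.asarray(group_of_pop)
    N = sizes.sum()
    K = len(sizes)
    glabels = list(dict.fromkeys(grp.tolist()))
    G = len(glabels)
    if K <= G or G < 2:
        raise ValidationError("coefficients need G >= 2 groups and K > G populations")
    s_g = []
    Ng2 = []
    for g in glabels:
        in_g = sizes[grp == g]
        s_g.append((in_g**2).sum() / in_g.sum())
        Ng2.append(in_g.sum() ** 2)
    s_g = np.asarray(s_g)
    n1 = (N - s_g.sum()) / (K - G)
    n2 = (s_g.sum() - (sizes**2).sum() / N) / (G - 1)
    n3 = (N - np.asarray(Ng2).sum() / N) / (G - 1)
    return float(n1), float(n2), float(n3)


def _components_two_level(d: np.ndarray, pop_idx: list[np.ndarray], grp_of_pop: np.ndarray) -> dict:
    """Sums of squares, mean squares and variance components of the
    group/population/individual decomposition from a squared-distance
    matrix.  Returns untruncated components; truncation happens in the
    results object."""
    N = d.shape[0]
    sizes = np.array([len(ix) for ix in pop_idx], dtype=float)
    K = len(pop_idx)
    glabels = list(dict.fromkeys(grp_of_pop.tolist()))
    G = len(glabels)

    ss_total = float(np.triu(d, 1).sum()) / N
    ss_wp = sum(_pair_sum(d, ix) / len(ix) for ix in pop_idx)
    ss_wg = 0.0
    for g in glabels:
        members = np.concatenate([pop_idx[k] for k in range(K) if grp_of_pop[k] == g])
        ss_wg += _pair_sum(d, members) / len(members)
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    df_ag, df_ap, df_wp = G - 1, K - G, N - K
    ms_wp = ss_wp / df_wp if df_wp else 0.0
    ms_ap = ss_ap / df_ap if df_ap else 0.0
    ms_ag = ss_ag / df_ag if df_ag else 0.0

    if df_ap > 0 and df_ag > 0:
        n1, n2, n3 = amova_coefficients(sizes.astype(int), grp_of_pop)
        vc = ms_wp
        vb = (ms_ap - vc) / n1
        va = (ms_ag - vc - n2 * vb) / n3
    else:
        # K == G: no among-population stratum; fall back to one level of groups
        n1 = n2 = n3 = float("nan")
        vc = ms_wp
        vb = 0.0
        n_eff = (N - (sizes**2).sum() / N) / (G - 1)
        va = (ms_ag - vc) / n_eff if df_ag else 0.0
    return {
        "df": (df_ag, df_ap, df_wp),
        "SS": (ss_ag, ss_ap, ss_wp),
        "MS": (ms_ag, ms_ap, ms_wp),
        "var": (va, vb, vc),
        "coef": (n1, n2, n3),
        "ss_total": ss_total,
    }


def _components_one_level(d: np.ndarray, pop_idx: list[np.ndarray]) -> dict:
    N = d.shape[0]
    sizes = np.array([len(ix) for ix in pop_idx], dtype=float)
    K = len(pop_idx)
    ss_total = float(np.triu(d, 1).sum()) / N
    ss_wp = sum(_pair_sum(d, ix) / len(ix) for ix in pop_idx)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = K - 1, N - K
    ms_wp = ss_wp / df_wp if df_wp else 0.0
    ms_ap = ss_ap / df_ap if df_ap else 0.0
    n1 = (N - (sizes**2).sum() / N) / (K - 1)
    vc = ms_wp
    vb = (ms_ap - vc) / n1
    return {
        "df": (df_ap, df_wp),
        "SS": (ss_ap, ss_wp),
        "MS": (ms_ap, ms_wp),
        "var": (vb, vc),
        "coef": (n1,),
        "ss_total": ss_total,
    }


def _truncate(components: Sequence[float]) -> np.ndarray:
    return np.clip(np.asarray(components, dtype=float), 0.0, None)


def _phi_from_components(va: float, vb: float, vc: float) -> dict[str, float]:
    va, vb, vc = _truncate([va, vb, vc])
    total = va + vb + vc
    if total <= 0.0:
        return {"phi_RT": 0.0, "phi_PR": 0.0, "phi_PT": 0.0}
    phi_pr = vb / (vb + vc) if (vb + vc) > 0 else 0.0
    return {"phi_RT": va / total, "phi_PR": phi_pr, "phi_PT": (va + vb) / total}


class Amova:
    """Two-level (or one-level) AMOVA model on a squared-distance matrix.

    Parameters
    ----------
    dist : DistanceMatrix
        Individual-level squared Euclidean distances.
    populations : mapping sample -> population, or a sequence aligned with
        ``dist.labels``.
    groups : mapping population -> group, optional.  Omitted, the model is
        the one-level partition among/within populations and only
        ``phi_PT`` is defined.
    """

    def __init__(
        self,
        dist: DistanceMatrix,
        populations: Mapping[str, str] | Sequence[str],
        groups: Mapping[str, str] | None = None,
    ) -> None:
        self.dist = dist
        if isinstance(populations, Mapping):
            missing = [s for s in dist.labels if s not in populations]
            if missing:
                raise ValidationError(f"samples without population: {missing[:5]}")
            pop_labels = [populations[s] for s in dist.labels]
        else:
            if len(populations) != dist.n:
                raise ValidationError("population assignment length mismatch")
            pop_labels = [str(p) for p in populations]
        self.pop_labels = pop_labels
        pops = group_indices(dist.labels, pop_labels)
        singleton = [p for p, ix in pops.items() if len(ix) < 2]
        if singleton:
            raise ValidationError(f"singleton populations not allowed: {singleton}")
        self.pop_names = list(pops)
        self.pop_idx = [pops[p] for p in self.pop_names]
        if groups is not None:
            missing = [p for p in self.pop_names if p not in groups]
            if missing:
                raise ValidationError(f"populations without group: {missing}")
            self.group_of_pop = np.asarray([groups[p] for p in self.pop_names])
            if len(dict.fromkeys(self.group_of_pop.tolist())) < 2:
                raise ValidationError("two-level AMOVA needs at least 2 groups")
        else:
            self.group_of_pop = None

    @classmethod
    def from_marker_matrix(
        cls,
        matrix: BinaryMarkerMatrix,
        samples: Sequence,
        two_level: bool = True,
    ) -> "Amova":
        """Build the model straight from a band matrix and sample records."""
        pop_of = {s.sample_id: s.population_id for s in samples}
        grp_of = {s.population_id: s.habitat for s in samples}
        dist = squared_euclidean_distances(matrix)
        return cls(dist, populations=pop_of, groups=grp_of if two_level else None)

    # -- fitting -----------------------------------------------------------

    def _observed(self) -> dict:
        d = self.dist.values
        if self.group_of_pop is not None:
            return _components_two_level(d, self.pop_idx, self.group_of_pop)
        return _components_one_level(d, self.pop_idx)

    def _phi_observed(self, comp: dict) -> dict[str, float]:
        if self.group_of_pop is not None:
            va, vb, vc = comp["var"]
            return _phi_from_components(va, vb, vc)
        vb, vc = comp["var"]
        return {"phi_PT": _phi_from_components(0.0, vb, vc)["phi_PT"]}

    def fit(self, n_permutations: int = 999, seed=None, statistics: Sequence[str] | None = None) -> "AmovaResults":
        """Estimate components and Phi-statistics, with permutation tests.

        Permutation schemes: ``phi_PT`` shuffles individuals across all
        populations; ``phi_RT`` shuffles whole populations among groups;
        ``phi_PR`` shuffles individuals among populations within their
        group.  ``n_permutations=0`` skips the tests; ``statistics``
        restricts them to a subset (each statistic gets its own stream).
        """
        if n_permutations < 0:
            raise ValidationError("n_permutations must be >= 0")
        comp = self._observed()
        phi = self._phi_observed(comp)
        if sum(_truncate(comp["var"])) <= 0.0:
            warnings.warn("total variance is zero; Phi-statistics reported as 0", stacklevel=2)

        if statistics is None:
            statistics = sorted(phi)
        else:
            unknown = [s for s in statistics if s not in phi]
            if unknown:
                raise ValidationError(f"statistics not defined for this design: {unknown}")
        p_values: dict[str, float] = {}
        if n_permutations >= 1:
            rng = np.random.default_rng(seed)
            streams = rng.spawn(len(statistics))
            for stat, stream in zip(statistics, streams):
                p_values[stat] = self._permutation_p(stat, phi[stat], n_permutations, stream)
        return AmovaResults(self, comp, phi, p_values, n_permutations)

    def _permutation_p(self, statistic: str, observed: float, n_perm: int, rng) -> float:
        if n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        d = self.dist.values
        n = d.shape[0]
        count = 0
        if statistic == "phi_RT":
            # reassign whole populations to groups, preserving group sizes
            grp = np.asarray(self.group_of_pop)
            for _ in range(n_perm):
                perm_grp = rng.permutation(grp)
                c = _components_two_level(d, self.pop_idx, perm_grp)
                if _phi_from_components(*c["var"])["phi_RT"] >= observed - 1e-12:
                    count += 1
        elif statistic == "phi_PR":
            # shuffle individuals among populations within their group
            grp = np.asarray(self.group_of_pop)
            glabels = list(dict.fromkeys(grp.tolist()))
            members = {g: np.concatenate([ix for ix, gg in zip(self.pop_idx, grp) if gg == g])
                       for g in glabels}
            for _ in range(n_perm):
                mapping = np.empty(n, dtype=int)
                for g in glabels:
                    mapping[members[g]] = rng.permutation(members[g])
                idx = [mapping[ix] for ix in self.pop_idx]
                c = _components_two_level(d, idx, grp)
                if _phi_from_components(*c["var"])["phi_PR"] >= observed - 1e-12:
                    count += 1
        elif statistic == "phi_PT":
            # shuffle individuals across all populations
            for _ in range(n_perm):
                perm = rng.permutation(n)
                idx = [perm[ix] for ix in self.pop_idx]
                if self.group_of_pop is not None:
                    c = _components_two_level(d, idx, self.group_of_pop)
                    val = _phi_from_components(*c["var"])["phi_PT"]
                else:
                    c = _components_one_level(d, idx)
                    vb, vc = c["var"]
                    val = _phi_from_components(0.0, vb, vc)["phi_PT"]
                if val >= observed - 1e-12:
                    count += 1
        else:
            raise ValidationError(f"unknown statistic {statistic!r}")
        return (count + 1) / (n_perm + 1)


_TWO_LEVEL_ROWS = ["among_groups", "among_populations", "within_populations"]
_ONE_LEVEL_ROWS = ["among_populations", "within_populations"]


class AmovaResults:
    """Fitted AMOVA: the variance-partition table, Phi-statistics and
    their permutation p-values.

    Attributes
    ----------
    table : DataFrame with one row per hierarchy level (df, SS, MS,
        est_var, pct); percentages use zero-truncated components.
    phi : dict of the defined Phi-statistics.
    p_values : dict of permutation p-values (empty if no permutations).
    """

    def __init__(self, model: Amova, comp: dict, phi: dict, p_values: dict, n_permutations: int) -> None:
        self.model = model
        self._comp = comp
        self.phi = phi
        self.p_values = p_values
        self.n_permutations = n_permutations
        self.coefficients = comp["coef"]

        labels = _TWO_LEVEL_ROWS if len(comp["var"]) == 3 else _ONE_LEVEL_ROWS
        est = _truncate(comp["var"])
        total = est.sum()
        pct = 100.0 * est / total if total > 0 else np.zeros_like(est)
        self.table = pd.DataFrame(
            {
                "df": comp["df"],
                "SS": comp["SS"],
                "MS": comp["MS"],
                "est_var": est,
                "pct": pct,
            },
            index=pd.Index(labels, name="source"),
        )
        self.raw_components = dict(zip(labels, comp["var"]))
        self.ss_total = comp["ss_total"]

    @property
    def phi_pt(self) -> float:
        return self.phi["phi_PT"]

    def summary(self) -> str:
        lines = [
            "AMOVA (squared Euclidean band distances)",
            f"  N = {self.model.dist.n} individuals, "
            f"{len(self.model.pop_names)} populations"
            + ("" if self.model.group_of_pop is None
               else f", {len(dict.fromkeys(self.model.group_of_pop.tolist()))} groups"),
            "",
            self.table.round(4).to_string(),
            "",
        ]
        for stat in ("phi_RT", "phi_PR", "phi_PT"):
            if stat in self.phi:
                p = self.p_values.get(stat)
                ptxt = f"  p = {p:.4g} ({self.n_permutations} permutations)" if p is not None else ""
                lines.append(f"  {stat} = {self.phi[stat]:.4f}{ptxt}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<AmovaResults phi={ {k: round(v, 4) for k, v in self.phi.items()} }>"


def pairwise_phi_pt(
    dist: DistanceMatrix,
    populations: Mapping[str, str] | Sequence[str],
    n_permutations: int = 999,
    seed=None,
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """Population-level PhiPT matrix: for every pair of populations a
    one-level AMOVA restricted to that pair; negative Phi truncated to 0.

    Returns the symmetric PhiPT matrix and a matching p-value table
    (p = NaN on the diagonal; permutations skipped if ``n_permutations=0``).
    """
    if isinstance(populations, Mapping):
        pop_labels = [populations[s] for s in dist.labels]
    else:
        pop_labels = [str(p) for p in populations]
    pops = group_indices(dist.labels, pop_labels)
    names = list(pops)
    if len(names) < 2:
        raise ValidationError("pairwise PhiPT needs at least 2 populations")
    k = len(names)
    phi = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for a in range(k):
        for b in range(a + 1, k):
            idx = np.concatenate([pops[names[a]], pops[names[b]]])
            labels = [dist.labels[i] for i in idx]
            sub = dist.submatrix(labels)
            sub_pops = [pop_labels[i] for i in idx]
            model = Amova(sub, populations=sub_pops)
            res = model.fit(n_permutations=n_permutations, seed=rng.spawn(1)[0] if n_permutations else None)
            phi[a, b] = phi[b, a] = res.phi_pt
            if n_permutations:
                pmat[a, b] = pmat[b, a] = res.p_values["phi_PT"]
    phi_dm = DistanceMatrix(names, phi, name="PhiPT")
    p_df = pd.DataFrame(pmat, index=names, columns=names)
    return phi_dm, p_df
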