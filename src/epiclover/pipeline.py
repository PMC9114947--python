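"""End-to-end analysis pipeline and expectation checking.

``run_full_study`` executes the whole chain on either a directory of
input CSVs or a simulation config:

1. MSAP subepilocus scoring (mixed scoring 2) and scoring report;
2. per-population diversity for AFLP, all subepiloci and the u/m/h
   classes;
3. two-level AMOVA (habitat / population / individual) per marker set,
   with permutation p-values, plus pairwise population PhiPT matrices;
4. geographic and habitat-dissimilarity matrices; simple and partial
   Mantel tests and MMRR per differentiation matrix;
5. habitat group comparisons of diversity and site covariates, the
   genetic-vs-epigenetic paired test and correlation, and
   diversity-environment correlations;
6. optional mean weighted Ellenberg indicator values from relevé inputs
   (skipped with a logged notice when absent).

Every stochastic step derives its stream from one seed, and all outputs
are written as CSV tables plus a JSON run summary, so a rerun with the
same inputs and seed reproduces the bundle exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import io as eio
from .amova import Amova, pairwise_phi_pt, squared_euclidean_distances
from .data import (
    BinaryMarkerMatrix,
    DistanceMatrix,
    MsapProfilePair,
    SampleRecord,
    SiteRecord,
    ValidationError,
)
from .diversity import population_diversity
from .eiv import INDICATORS, mean_weighted_eiv
from .group_stats import (
    paired_t_test,
    pearson_correlation,
    spearman_correlation,
    two_sample_test,
)
from .matrix_tests import (
    Mmrr,
    geographic_distance_matrix,
    habitat_dissimilarity_matrix,
    mantel,
    partial_mantel,
)
from .msap import mixed_scoring_2
from .simulate import SimulationConfig, Study, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["run_full_study", "load_study_directory", "check_against_expectations", "StudyReport"]


class StudyReport:
    """Bundle of all pipeline outputs.

    Attributes
    ----------
    tables : dict of DataFrames (diversity, AMOVA, Mantel, MMRR, group
        comparisons), one per published-table analogue.
    matrices : dict of DistanceMatrix (pairwise PhiPT, geographic,
        habitat dissimilarity).
    metrics : flat name -> number dict, also written to the JSON summary.
    """

    def __init__(self) -> None:
        self.tables: dict[str, pd.DataFrame] = {}
        self.matrices: dict[str, DistanceMatrix] = {}
        self.metrics: dict[str, float] = {}
        self.scoring_report: dict = {}
        self.seed: int | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", float_format="%.12g")
        for name, dm in self.matrices.items():
            eio.write_distance_matrix(dm, outdir / f"{name}.csv")
        summary = {
            "package_version": __version__,
            "seed": self.seed,
            "scoring_report": self.scoring_report,
            "metrics": self.metrics,
        }
        eio.write_run_summary(outdir / "run_summary.json", summary)


def load_study_directory(indir: str | Path) -> Study:
    """Read a study previously written by :func:`epiclover.simulate.write_study`
    (or assembled by hand in the same formats)."""
    indir = Path(indir)
    samples = eio.read_metadata(indir / "metadata.csv", free_labels=True)
    sites = eio.read_sites(indir / "sites.csv")
    order = [s.sample_id for s in samples]
    aflp = eio.read_marker_matrix(indir / "aflp.csv", label="AFLP").reindex_samples(order)
    hpa = eio.read_marker_matrix(indir / "msap_hpa.csv", label="HpaII").reindex_samples(order)
    msp = eio.read_marker_matrix(indir / "msap_msp.csv", label="MspI").reindex_samples(order)
    releves = eivs = None
    if (indir / "releves.csv").exists() and (indir / "species_eiv.csv").exists():
        releves = eio.read_releve_table(indir / "releves.csv")
        eivs = eio.read_eiv_table(indir / "species_eiv.csv")
    truth = {}
    if (indir / "truth.json").exists():
        truth = json.loads((indir / "truth.json").read_text())
    return Study(config=None, sites=sites, samples=samples, aflp=aflp,
                 msap=MsapProfilePair(hpa=hpa, msp=msp),
                 releves=releves, eivs=eivs, truth=truth)


def _site_order(sites: Sequence[SiteRecord], samples: Sequence[SampleRecord]) -> list[SiteRecord]:
    pop_order = list(dict.fromkeys(s.population_id for s in samples))
    by_id = {s.population_id: s for s in sites}
    missing = [p for p in pop_order if p not in by_id]
    if missing:
        raise ValidationError(f"populations without site records: {missing}")
    return [by_id[p] for p in pop_order]


def run_full_study(
    source: Study | SimulationConfig | str | Path,
    outdir: str | Path | None = None,
    amova_permutations: int = 999,
    mantel_permutations: int = 9999,
    pairwise_permutations: int = 99,
    seed: int = 0,
) -> StudyReport:
    """Run the full analysis chain; see the module docstring for stages.

    ``source`` may be an in-memory :class:`Study`, a
    :class:`SimulationConfig` (data are generated first) or a directory
    path of input CSVs.
    """
    if isinstance(source, Study):
        study = source
    elif isinstance(source, SimulationConfig):
        study = simulate_study(source)
    else:
        study = load_study_directory(source)

    report = StudyReport()
    report.seed = seed
    rng = np.random.default_rng(seed)
    samples = study.samples
    pop_of = {s.sample_id: s.population_id for s in samples}
    grp_of = {s.population_id: s.habitat for s in samples}
    sites = _site_order(study.sites, samples)

    # -- stage 1: subepilocus scoring -------------------------------------
    sub, scoring = mixed_scoring_2(study.msap)
    report.scoring_report = scoring.as_dict()
    logger.info("scoring: %s", scoring.as_dict())

    marker_sets: dict[str, BinaryMarkerMatrix] = {"AFLP": study.aflp, "MSAP-all": sub.base}
    for cls in ("h", "m", "u"):
        marker_sets[cls] = sub.class_subset(cls)

    # -- stage 2: diversity -----------------------------------------------
    diversity_tables: dict[str, pd.DataFrame] = {}
    for name, matrix in marker_sets.items():
        div = population_diversity(matrix, samples)
        diversity_tables[name] = div
        report.tables[f"diversity_{name}"] = div
        report.metrics[f"diversity.{name}.mean_SI"] = float(div.loc["mean", "mean_SI"])
        report.metrics[f"diversity.{name}.pct_polymorphic"] = float(div.loc["mean", "pct_polymorphic"])
        report.metrics[f"diversity.{name}.pct_bands"] = float(div.loc["mean", "pct_bands"])

    # -- stage 3: AMOVA and pairwise PhiPT --------------------------------
    phi_matrices: dict[str, DistanceMatrix] = {}
    amova_rows = []
    for name, matrix in marker_sets.items():
        dist = squared_euclidean_distances(matrix)
        res = Amova(dist, populations=pop_of, groups=grp_of).fit(
            n_permutations=amova_permutations, seed=rng.spawn(1)[0]
        )
        tbl = res.table.copy()
        tbl.insert(0, "marker_set", name)
        amova_rows.append(tbl.reset_index())
        report.tables[f"amova_{name}"] = res.table
        for stat, val in res.phi.items():
            report.metrics[f"amova.{name}.{stat}"] = val
        for stat, p in res.p_values.items():
            report.metrics[f"amova.{name}.{stat}.p"] = p
        phi, phi_p = pairwise_phi_pt(
            dist, pop_of, n_permutations=pairwise_permutations, seed=rng.spawn(1)[0]
        )
        phi_matrices[name] = phi
        report.matrices[f"phipt_{name}"] = phi
        report.tables[f"phipt_p_{name}"] = phi_p
    report.tables["amova_all"] = pd.concat(amova_rows, ignore_index=True)

    # -- stage 4: matrix tests --------------------------------------------
    geo = geographic_distance_matrix(sites)
    hab = habitat_dissimilarity_matrix(sites)
    report.matrices["geographic_km"] = geo
    report.matrices["habitat_dissimilarity"] = hab

    gen_epi = mantel(phi_matrices["AFLP"], phi_matrices["MSAP-all"],
                     n_perm=mantel_permutations, seed=rng.spawn(1)[0])
    geo_hab = mantel(geo, hab, n_perm=mantel_permutations, seed=rng.spawn(1)[0])
    report.metrics["mantel.AFLP_vs_MSAP.r"] = gen_epi.r
    report.metrics["mantel.AFLP_vs_MSAP.p"] = gen_epi.p
    report.metrics["mantel.geo_vs_habitat.r"] = geo_hab.r
    report.metrics["mantel.geo_vs_habitat.p"] = geo_hab.p

    mantel_rows, mmrr_rows = [], []
    for name, phi in phi_matrices.items():
        ibd = mantel(phi, geo, n_perm=mantel_permutations, seed=rng.spawn(1)[0])
        ibd_part = partial_mantel(phi, geo, hab, n_perm=mantel_permutations, seed=rng.spawn(1)[0])
        ibh = mantel(phi, hab, n_perm=mantel_permutations, seed=rng.spawn(1)[0])
        ibh_part = partial_mantel(phi, hab, geo, n_perm=mantel_permutations, seed=rng.spawn(1)[0])
        mantel_rows.append({
            "marker_set": name,
            "ibd_r": ibd.r, "ibd_p": ibd.p,
            "ibd_partial_r": ibd_part.r, "ibd_partial_p": ibd_part.p,
            "ibh_r": ibh.r, "ibh_p": ibh.p,
            "ibh_partial_r": ibh_part.r, "ibh_partial_p": ibh_part.p,
        })
        for key, res in (("ibd", ibd), ("ibh", ibh)):
            report.metrics[f"mantel.{name}.{key}.r"] = res.r
            report.metrics[f"mantel.{name}.{key}.p"] = res.p
        mm = Mmrr(phi, {"geographic": geo, "habitat": hab}).fit(
            n_permutations=mantel_permutations, seed=rng.spawn(1)[0]
        )
        mmrr_rows.append({
            "marker_set": name,
            "F": mm.f_statistic, "F_p": mm.f_p, "R2": mm.r_squared,
            "coef_geographic": mm.coefficients.loc["geographic", "coefficient"],
            "p_geographic": mm.coefficients.loc["geographic", "p"],
            "coef_habitat": mm.coefficients.loc["habitat", "coefficient"],
            "p_habitat": mm.coefficients.loc["habitat", "p"],
        })
        report.metrics[f"mmrr.{name}.F"] = mm.f_statistic
        report.metrics[f"mmrr.{name}.F_p"] = mm.f_p
    report.tables["mantel_tests"] = pd.DataFrame(mantel_rows).set_index("marker_set")
    report.tables["mmrr"] = pd.DataFrame(mmrr_rows).set_index("marker_set")

    # -- stage 5: group comparisons and correlations ----------------------
    habitats = list(dict.fromkeys(s.habitat for s in sites))
    pop_rows = {s.population_id: s.habitat for s in sites}
    compare_rows = []
    si_by_set = {}
    for name, div in diversity_tables.items():
        pops = [p for p in div.index if p in pop_rows]
        si = div.loc[pops, "mean_SI"]
        si_by_set[name] = si
        if len(habitats) == 2:
            a = si[[p for p in pops if pop_rows[p] == habitats[0]]]
            b = si[[p for p in pops if pop_rows[p] == habitats[1]]]
            res = two_sample_test(a, b, force="t")
            compare_rows.append({
                "variable": f"SI_{name}",
                f"mean_{habitats[0]}": a.mean(), f"mean_{habitats[1]}": b.mean(),
                "statistic": res.statistic, "p": res.p, "method": res.method,
            })
            report.metrics[f"compare.SI.{name}.p"] = res.p
    if len(habitats) == 2:
        for ind in INDICATORS:
            vals = {h: [] for h in habitats}
            ok = True
            for s in sites:
                v = getattr(s, f"eiv_{ind}")
                if v is None:
                    ok = False
                    break
                vals[s.habitat].append(v)
            if ok:
                res = two_sample_test(vals[habitats[0]], vals[habitats[1]], force="auto")
                compare_rows.append({
                    "variable": f"eiv_{ind}",
                    f"mean_{habitats[0]}": np.mean(vals[habitats[0]]),
                    f"mean_{habitats[1]}": np.mean(vals[habitats[1]]),
                    "statistic": res.statistic, "p": res.p, "method": res.method,
                })
                report.metrics[f"compare.eiv_{ind}.p"] = res.p
    if compare_rows:
        report.tables["group_comparisons"] = pd.DataFrame(compare_rows).set_index("variable")

    paired = paired_t_test(si_by_set["AFLP"], si_by_set["MSAP-all"])
    report.metrics["paired.SI_gen_vs_SI_epi.t"] = paired.statistic
    report.metrics["paired.SI_gen_vs_SI_epi.p"] = paired.p
    pear = pearson_correlation(si_by_set["AFLP"], si_by_set["MSAP-all"])
    spear = spearman_correlation(si_by_set["AFLP"], si_by_set["MSAP-all"])
    report.metrics["corr.SI_gen_vs_SI_epi.pearson_r"] = pear.statistic
    report.metrics["corr.SI_gen_vs_SI_epi.pearson_p"] = pear.p
    report.metrics["corr.SI_gen_vs_SI_epi.spearman_rho"] = spear.statistic
    report.metrics["corr.SI_gen_vs_SI_epi.spearman_p"] = spear.p

    env_rows = []
    for ind in INDICATORS:
        env = [getattr(s, f"eiv_{ind}") for s in sites]
        if any(v is None for v in env):
            continue
        env = pd.Series(env, index=[s.population_id for s in sites])
        for name, si in si_by_set.items():
            res = pearson_correlation(env.loc[si.index], si)
            env_rows.append({"indicator": ind, "marker_set": name,
                             "r": res.statistic, "p": res.p})
            report.metrics[f"corr.SI.{name}.eiv_{ind}.r"] = res.statistic
            report.metrics[f"corr.SI.{name}.eiv_{ind}.p"] = res.p
    if env_rows:
        report.tables["environment_correlations"] = (
            pd.DataFrame(env_rows).set_index(["indicator", "marker_set"])
        )

    # -- stage 6: Ellenberg indicator values from relevés (optional) ------
    if study.releves is not None and study.eivs is not None:
        eiv_rows = {}
        for ind in INDICATORS:
            if ind in study.eivs.columns:
                eiv_rows[f"eiv_{ind}"] = mean_weighted_eiv(study.releves, study.eivs, ind)
        report.tables["site_eiv"] = pd.DataFrame(eiv_rows)
    else:
        logger.info("no relevé inputs; Ellenberg indicator stage skipped")

    if outdir is not None:
        report.write(outdir)
    return report


_COMPARATORS = {
    "eq": lambda v, t, tol: abs(v - t) <= tol,
    "le": lambda v, t, tol: v <= t + tol,
    "ge": lambda v, t, tol: v >= t - tol,
}


def check_against_expectations(metrics: Mapping[str, float] | str | Path,
                               expectations: str | Path | list[dict]) -> list[dict]:
    """Compare run-summary metrics against an expectations file.

    Expectations are a JSON/YAML list of ``{id, key, cmp, value, tol}``
    records; ``cmp`` is ``eq``/``le``/``ge`` and ``tol`` defaults to 0.
    Returns one ``{id, key, observed, expected, cmp, tol, passed}`` record
    per target.
    """
    if not isinstance(metrics, Mapping):
        summary = json.loads(Path(metrics).read_text())
        metrics = summary.get("metrics", summary)
    if not isinstance(expectations, list):
        text = Path(expectations).read_text()
        try:
            expectations = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            expectations = yaml.safe_load(text)
    if not isinstance(expectations, list):
        raise ValidationError("expectations must be a list of target records")

    results = []
    for exp in expectations:
        try:
            tid, key, cmp_name, target = exp["id"], exp["key"], exp["cmp"], exp["value"]
        except (TypeError, KeyError) as err:
            raise ValidationError(f"malformed expectation record {exp!r}") from err
        if cmp_name not in _COMPARATORS:
            raise ValidationError(f"unknown comparator {cmp_name!r} in target {tid!r}")
        tol = float(exp.get("tol", 0.0))
        observed = metrics.get(key)
        passed = observed is not None and _COMPARATORS[cmp_name](float(observed), float(target), tol)
        results.append({
            "id": tid, "key": key, "observed": observed, "expected": target,
            "cmp": cmp_name, "tol": tol, "passed": bool(passed),
        })
    return results
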