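"""Synthetic study generator with known ground truth.

Emulates a two-habitat grassland study of a band-genotyped plant:
``n_groups`` habitat types x ``pops_per_group`` populations x
``n_per_pop`` individuals, with an AFLP band matrix and a paired
HpaII/MspI MSAP profile per individual, site environmental covariates
(Ellenberg-style indicator means) and a small vegetation relevé table.

Band presence is simulated at the band (phenotype) level: an ancestral
band frequency per locus drifts to habitat groups and then to populations
under Balding-Nichols Beta steps whose variance is ``theta * p * (1-p)``,
so the simulated ``theta_pop`` / ``theta_group`` are directly the
PhiPT/PhiRT-scale differentiation targets of the dataset.  Methylation
states of present MSAP fragments follow a logit model with a
habitat-linked shift on the m state and an environment (soil moisture)
effect on state evenness.  Given a seed, a config fully determines the
dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    BinaryMarkerMatrix,
    MsapProfilePair,
    SampleRecord,
    SiteRecord,
    ValidationError,
)
from . import io as eio
from .matrix_tests import geographic_distance_matrix

__all__ = ["SimulationConfig", "Study", "simulate_sites", "simulate_aflp",
           "simulate_msap", "simulate_releves", "simulate_study", "write_study"]

_EPS = 1e-9

#: habitat-specific covariate means (L, M, R, N): calcareous grasslands are
#: light-rich, dry, alkaline and nutrient-poor; oat-grass meadows wetter and
#: nitrogen-rich.
_HABITAT_EIV_MEANS = {
    "CG": {"L": 7.45, "M": 3.43, "R": 7.63, "N": 2.69},
    "OM": {"L": 7.04, "M": 4.86, "R": 6.94, "N": 5.29},
}
_EIV_SD = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    """Study dimensions and effect sizes of one synthetic dataset.

    Defaults mirror the reference study design: 2 habitats x 5 populations
    x 16 individuals, 124 AFLP loci, 159 MSAP fragments, and weak
    hierarchical differentiation (population-level theta 0.05 plus a
    group-level 0.02, i.e. a global PhiPT around 0.07).
    """

    n_groups: int = 2
    pops_per_group: int = 5
    n_per_pop: int = 16
    n_aflp_loci: int = 124
    n_msap_fragments: int = 159
    theta_pop: float = 0.05
    theta_group: float = 0.02
    habitat_methylation_shift: float = 0.5
    env_effect: float = 0.3
    ibd_strength: float = 0.0
    state_drift_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_groups", "pops_per_group", "n_per_pop", "n_aflp_loci", "n_msap_fragments"):
            if getattr(self, f) < 1:
                raise ValidationError(f"{f} must be positive")
        for f in ("theta_pop", "theta_group"):
            v = getattr(self, f)
            if not 0.0 <= v < 1.0:
                raise ValidationError(f"{f}={v} outside [0, 1)")
        if not 0.0 <= self.ibd_strength <= 1.0:
            raise ValidationError("ibd_strength must lie in [0, 1]")

    @property
    def n_populations(self) -> int:
        return self.n_groups * self.pops_per_group

    @property
    def n_individuals(self) -> int:
        return self.n_populations * self.n_per_pop

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Study:
    """One complete synthetic dataset plus its generating truth."""

    config: SimulationConfig | None
    sites: list[SiteRecord]
    samples: list[SampleRecord]
    aflp: BinaryMarkerMatrix
    msap: MsapProfilePair
    releves: pd.DataFrame | None
    eivs: pd.DataFrame | None
    truth: dict


def _habitat_label(g: int, n_groups: int) -> str:
    if n_groups == 2:
        return ("CG", "OM")[g]
    return f"H{g + 1}"


def simulate_sites(config: SimulationConfig, rng: np.random.Generator) -> list[SiteRecord]:
    """Sites scattered in a ~100 x 60 km box with alternating habitats and
    habitat-specific environmental covariates."""
    lat0, lon0 = 48.35, 9.20  # box origin; extent ~0.54 deg lat x 1.35 deg lon
    sites = []
    for k in range(config.n_populations):
        g = k % config.n_groups  # habitats interleave spatially
        hab = _habitat_label(g, config.n_groups)
        lat = lat0 + rng.uniform(0.0, 0.54)
        lon = lon0 + rng.uniform(0.0, 1.35)
        means = _HABITAT_EIV_MEANS.get(hab, {"L": 7.0, "M": 4.0, "R": 7.0, "N": 4.0})
        eiv = {
            f"eiv_{ind}": float(np.clip(rng.normal(means[ind], _EIV_SD), 1.0, 9.0))
            for ind in ("L", "M", "R", "N")
        }
        sites.append(SiteRecord(f"pop{k + 1:02d}", hab, lat, lon, **eiv))
    return sites


def _beta_drift(p: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols step: Beta draw with mean p, variance theta*p*(1-p);
    theta = 0 passes frequencies through unchanged."""
    if theta <= 0.0:
        return p.copy()
    a = p * (1.0 - theta) / theta
    b = (1.0 - p) * (1.0 - theta) / theta
    return np.clip(rng.beta(a, b), _EPS, 1.0 - _EPS)


def _pop_frequencies(
    config: SimulationConfig,
    sites: list[SiteRecord],
    n_loci: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ancestral, group, population) frequencies of shape (L,), (G, L),
    (K, L); populations drift independently, or with distance-correlated
    deviations when ``ibd_strength > 0``."""
    anc = rng.uniform(0.1, 0.9, size=n_loci)
    grp = np.stack([_beta_drift(anc, config.theta_group, rng) for _ in range(config.n_groups)])
    K = config.n_populations
    pop = np.empty((K, n_loci))
    if config.ibd_strength <= 0.0:
        for k in range(K):
            pop[k] = _beta_drift(grp[k % config.n_groups], config.theta_pop, rng)
        return anc, grp, pop

    # IBD: population deviations share a spatial Gaussian field whose
    # correlation decays with distance (range 30 km); ibd_strength is the
    # fraction of the drift variance that is spatially structured.
    d = geographic_distance_matrix(sites).values
    corr = np.exp(-d / 30.0)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(K))
    w = config.ibd_strength
    for l in range(n_loci):
        base = grp[np.arange(K) % config.n_groups, l]
        sd = np.sqrt(config.theta_pop * base * (1.0 - base))
        z = np.sqrt(w) * chol @ rng.standard_normal(K) + np.sqrt(1.0 - w) * rng.standard_normal(K)
        pop[:, l] = np.clip(base + sd * z, _EPS, 1.0 - _EPS)
    return anc, grp, pop


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    sample_ids, pop_ids = [], []
    for k in range(config.n_populations):
        for i in range(config.n_per_pop):
            sample_ids.append(f"pop{k + 1:02d}_ind{i + 1:02d}")
            pop_ids.append(f"pop{k + 1:02d}")
    return sample_ids, pop_ids


def simulate_aflp(
    config: SimulationConfig,
    sites: list[SiteRecord],
    rng: np.random.Generator,
) -> tuple[BinaryMarkerMatrix, dict]:
    """Bernoulli band calls from hierarchically drifted band frequencies."""
    anc, grp, pop = _pop_frequencies(config, sites, config.n_aflp_loci, rng)
    sample_ids, pop_ids = _sample_ids(config)
    pop_index = {s.population_id: i for i, s in enumerate(sites)}
    rows = np.empty((len(sample_ids), config.n_aflp_loci), dtype=np.int8)
    for i, p_id in enumerate(pop_ids):
        rows[i] = rng.random(config.n_aflp_loci) < pop[pop_index[p_id]]
    matrix = BinaryMarkerMatrix(
        sample_ids, [f"aflp{j + 1:03d}" for j in range(config.n_aflp_loci)], rows, label="AFLP"
    )
    truth = {
        "ancestral_freq": anc.tolist(),
        "group_freq": grp.tolist(),
        "population_freq": pop.tolist(),
        "theta_pop": config.theta_pop,
        "theta_group": config.theta_group,
    }
    return matrix, truth


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=-1, keepdims=True)
    if not np.allclose(out.sum(axis=-1), 1.0, atol=1e-8):
        raise AssertionError("state probabilities failed to normalize")
    return out


def simulate_msap(
    config: SimulationConfig,
    sites: list[SiteRecord],
    rng: np.random.Generator,
) -> tuple[MsapProfilePair, dict]:
    """Paired HpaII/MspI profiles realizing the u/m/h/absent state model.

    Fragment presence drifts like AFLP bands; for present fragments the
    (u, m, h) state probabilities come from per-fragment baseline logits,
    shifted on the m state by ``habitat_methylation_shift`` in the second
    habitat and flattened (more even, hence more diverse) with rising site
    soil moisture at rate ``env_effect``.
    """
    F = config.n_msap_fragments
    anc, grp, pop = _pop_frequencies(config, sites, F, rng)
    base_logits = rng.normal(0.0, 0.7, size=(F, 3))  # u, m, h baseline
    moisture = np.array([s.eiv_M if s.eiv_M is not None else 4.0 for s in sites])
    z_moist = (moisture - moisture.mean()) / (moisture.std() + 1e-12)

    sample_ids, pop_ids = _sample_ids(config)
    pop_index = {s.population_id: i for i, s in enumerate(sites)}
    habitat_of = {s.population_id: s.habitat for s in sites}
    second_habitat = _habitat_label(1, config.n_groups) if config.n_groups > 1 else None

    # population-level state logits: (K, F, 3)
    K = config.n_populations
    state_logits = np.broadcast_to(base_logits, (K, F, 3)).copy()
    state_logits += rng.normal(0.0, config.state_drift_sd, size=(K, F, 3))
    for s in sites:
        k = pop_index[s.population_id]
        if second_habitat is not None and s.habitat == second_habitat:
            state_logits[k, :, 1] += config.habitat_methylation_shift
        # wetter sites: logits shrink toward equality -> flatter state
        # distribution -> higher epiallele diversity
        state_logits[k] *= np.exp(-config.env_effect * z_moist[k])
    state_probs = _softmax(state_logits)

    n = len(sample_ids)
    hpa = np.zeros((n, F), dtype=np.int8)
    msp = np.zeros((n, F), dtype=np.int8)
    states = np.full((n, F), "uninformative", dtype=object)
    for i, p_id in enumerate(pop_ids):
        k = pop_index[p_id]
        present = rng.random(F) < pop[k]
        u = rng.random(F)
        cum = state_probs[k].cumsum(axis=1)
        state_idx = (u[:, None] > cum).sum(axis=1)  # 0=u, 1=m, 2=h
        for j in np.flatnonzero(present):
            st = ("u", "m", "h")[state_idx[j]]
            states[i, j] = st
            hp, ms = {"u": (1, 1), "m": (0, 1), "h": (1, 0)}[st]
            hpa[i, j], msp[i, j] = hp, ms
    frag_ids = [f"frag{j + 1:03d}" for j in range(F)]
    pair = MsapProfilePair(
        hpa=BinaryMarkerMatrix(sample_ids, frag_ids, hpa, label="HpaII"),
        msp=BinaryMarkerMatrix(sample_ids, frag_ids, msp, label="MspI"),
    )
    truth = {
        "population_presence_freq": pop.tolist(),
        "state_probs_mean_by_pop": state_probs.mean(axis=1).tolist(),
        "habitat_methylation_shift": config.habitat_methylation_shift,
        "env_effect": config.env_effect,
        "habitat_of": habitat_of,
        "states": states.tolist(),
    }
    return pair, truth


#: synthetic species pool: name -> (L, M, R, N) indicator values; a few are
#: indifferent (None) for some indicators, as in real indicator lists.
_SPECIES_POOL: dict[str, tuple[float | None, ...]] = {
    f"species_{i:02d}": vals
    for i, vals in enumerate(
        [
            (8, 3, 8, 2), (7, 3, 8, 2), (8, 2, 7, 1), (7, 4, 8, 3), (9, 3, 9, 2),
            (7, 3, 7, 3), (8, 4, 7, 2), (7, 2, 8, 2), (8, 3, None, 2), (7, 4, 7, 4),
            (7, 5, 7, 5), (6, 5, 7, 6), (7, 6, 6, 6), (6, 5, 6, 5), (7, 5, 6, 7),
            (6, 6, 7, 5), (7, 5, None, 6), (6, 6, 6, 7), (7, 6, 7, 6), (6, 5, 7, 7),
            (7, 4, 7, 4), (7, 5, 7, 4), (6, 4, 7, 5), (7, 4, 6, 5), (None, 5, 7, 5),
        ],
        start=1,
    )
}


def simulate_releves(
    config: SimulationConfig,
    sites: list[SiteRecord],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site x species abundance table plus a species indicator table.

    Species abundances at a site favour species whose indicator profile is
    close to the site's covariates, so the abundance-weighted means
    recover covariates resembling the site table.
    """
    species = list(_SPECIES_POOL)
    eiv_df = pd.DataFrame(
        [[v if v is not None else np.nan for v in _SPECIES_POOL[sp]] for sp in species],
        index=pd.Index(species, name="species"),
        columns=["L", "M", "R", "N"],
    )
    rows = {}
    for s in sites:
        target = np.array([s.eiv_L or 7.0, s.eiv_M or 4.0, s.eiv_R or 7.0, s.eiv_N or 4.0])
        ab = np.zeros(len(species))
        for j, sp in enumerate(species):
            vals = np.array([np.nan if v is None else v for v in _SPECIES_POOL[sp]], dtype=float)
            ok = ~np.isnan(vals)
            dist2 = float(((vals[ok] - target[ok]) ** 2).mean())
            ab[j] = np.exp(-dist2 / 3.0) * rng.lognormal(0.0, 0.4)
        ab = np.round(100.0 * ab / ab.sum(), 2)  # percent cover
        rows[s.population_id] = ab
    releves = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    releves.index.name = "population_id"
    return releves, eiv_df


def simulate_study(config: SimulationConfig | None = None) -> Study:
    """Generate a full dataset (sites, samples, AFLP, MSAP, relevés) from a
    config; deterministic given ``config.seed``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    site_rng, aflp_rng, msap_rng, veg_rng = rng.spawn(4)
    sites = simulate_sites(config, site_rng)
    aflp, aflp_truth = simulate_aflp(config, sites, aflp_rng)
    msap, msap_truth = simulate_msap(config, sites, msap_rng)
    releves, eivs = simulate_releves(config, sites, veg_rng)
    sample_ids, pop_ids = _sample_ids(config)
    habitat_of = {s.population_id: s.habitat for s in sites}
    samples = [SampleRecord(s, p, habitat_of[p]) for s, p in zip(sample_ids, pop_ids)]
    truth = {
        "config": config.to_dict(),
        "seed": config.seed,
        "aflp": aflp_truth,
        "msap": msap_truth,
    }
    return Study(config=config, sites=sites, samples=samples, aflp=aflp,
                 msap=msap, releves=releves, eivs=eivs, truth=truth)


def write_study(config: SimulationConfig, outdir: str | Path) -> Study:
    """Simulate and write the full file set readable by every pipeline
    stage: metadata.csv, sites.csv, aflp.csv, msap_hpa.csv, msap_msp.csv,
    releves.csv, species_eiv.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config)
    pd.DataFrame(
        [{"sample_id": s.sample_id, "population_id": s.population_id, "habitat": s.habitat}
         for s in study.samples]
    ).to_csv(outdir / "metadata.csv", index=False)
    eio.write_sites(study.sites, outdir / "sites.csv")
    eio.write_marker_matrix(study.aflp, outdir / "aflp.csv")
    eio.write_marker_matrix(study.msap.hpa, outdir / "msap_hpa.csv")
    eio.write_marker_matrix(study.msap.msp, outdir / "msap_msp.csv")
    study.releves.to_csv(outdir / "releves.csv")
    study.eivs.to_csv(outdir / "species_eiv.csv")
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(study.truth, fh, indent=2)
        fh.write("\n")
    return study
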