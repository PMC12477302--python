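"""Seeded synthetic-data generator for the two-morph x two-area design.

Generates tidy long-format trait tables with the hierarchical structure the
downstream analysis assumes: individuals nested in area x morph cells;
inflorescences, flowers, nectar samples and pollen-scored stigmas nested in
individuals.  Distributional choices mirror the model families used to
analyse each trait:

* continuous lengths/heights — truncated-at-zero normal (truncation is
  negligible at the default coefficients of variation);
* counts — NB1 negative binomial (``Var = mu * (1 + alpha)``) drawn as a
  gamma–Poisson mixture with shape ``mu/alpha`` and scale ``alpha``;
* pollen grains — NB1 with structural zero inflation;
* nectar concentration — beta on the proportion scale (mean/precision
  parameterisation), scaled to percent.

Individual-level intercepts (additive for continuous traits, mean-one
log-normal for counts) give the random-effect machinery real signal to
absorb.  All draws are deterministic given ``config.seed``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import AREAS, MORPHS, COUNT_TRAITS, PopulationConfig

TABLE_COLUMNS = ["area", "morph", "individual_id", "unit_id", "trait", "value"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_nb1(mean: float, alpha: float, n: int, seed) -> np.ndarray:
    """Draw ``n`` NB1 (linear-parameterisation) negative binomial variates.

    The NB1 law has ``E[X] = mean`` and ``Var[X] = mean * (1 + alpha)``.  It
    is sampled as a gamma–Poisson mixture: ``lambda ~ Gamma(shape=mean/alpha,
    scale=alpha)``, ``X | lambda ~ Poisson(lambda)``; ``alpha = 0``
    short-circuits to the Poisson limit.

    Parameters
    ----------
    mean : float
        Population mean, must be > 0.
    alpha : float
        NB1 dispersion, must be >= 0 (0 gives Poisson).
    n : int
        Number of draws, >= 1.
    seed : int or numpy.random.Generator
        Source of randomness; a given int always yields the same vector.
    """
    if not mean > 0:
        raise ValueError(f"NB1 mean must be > 0, got {mean}")
    if alpha < 0:
        raise ValueError(f"NB1 dispersion alpha must be >= 0, got {alpha}")
    if int(n) < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(seed)
    if alpha == 0:
        return rng.poisson(mean, size=int(n))
    lam = rng.gamma(shape=mean / alpha, scale=alpha, size=int(n))
    return rng.poisson(lam)


def sample_zero_inflated(mean: float, alpha: float, pi: float, n: int, seed) -> np.ndarray:
    """Draw from a zero-inflated NB1: structural zero w.p. ``pi``, else NB1.

    ``E[X] = (1 - pi) * mean``.  ``pi`` must lie in ``[0, 1)``.
    """
    if not 0 <= pi < 1:
        raise ValueError(f"zero-inflation pi must be in [0, 1), got {pi}")
    rng = _as_rng(seed)
    counts = sample_nb1(mean, alpha, n, rng)
    structural = rng.random(int(n)) < pi
    return np.where(structural, 0, counts)


def _trunc_normal(mean, sd, size, rng) -> np.ndarray:
    """Normal(mean, sd) truncated at zero; degenerate at ``mean`` if sd == 0."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    if np.isscalar(sd):
        sd = np.full(size, float(sd))
    sd = np.asarray(sd, dtype=float)
    out = mean.copy()
    pos = sd > 0
    if pos.any():
        a = (0.0 - mean[pos]) / sd[pos]
        out[pos] = stats.truncnorm.rvs(
            a, np.inf, loc=mean[pos], scale=sd[pos], random_state=rng
        )
    return out


class _Recorder:
    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def add(self, area, morph, individual_id, unit_id, trait, values) -> None:
        values = np.atleast_1d(values)
        unit_ids = np.atleast_1d(unit_id)
        for uid, v in zip(unit_ids, values, strict=True):
            self.rows.append((area, morph, individual_id if np.isscalar(individual_id)
                              else individual_id, uid, trait, float(v)))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=TABLE_COLUMNS)


def generate_dataset(config: PopulationConfig) -> pd.DataFrame:
    """Generate one tidy trait table from ``config`` (seeded by ``config.seed``).

    Returns a DataFrame with columns ``area, morph, individual_id, unit_id,
    trait, value`` covering every sampling layer.  Re-running with the same
    config reproduces the table exactly.
    """
    config.validate()
    rng = np.random.default_rng(int(config.seed))
    rec = _Recorder()

    for area in AREAS:
        for morph in MORPHS:
            cell = f"{area}-{morph}"
            # ---------- individual layer ----------
            ind_ids = [f"{cell}-i{k:02d}" for k in range(1, config.n_individuals_per_cell + 1)]
            ph = _trunc_normal(config.trait_mean("plant_height", area, morph),
                               config.plant_height_sd, len(ind_ids), rng)
            sd_ = _trunc_normal(config.trait_mean("stem_diameter", area, morph),
                                config.stem_diameter_sd, len(ind_ids), rng)
            ninf = sample_nb1(config.trait_mean("n_inflorescences", area, morph),
                              config.nb1_dispersion["n_inflorescences"], len(ind_ids), rng)
            for i, ind in enumerate(ind_ids):
                rec.add(area, morph, ind, ind, "plant_height", ph[i])
                rec.add(area, morph, ind, ind, "stem_diameter", sd_[i])
                rec.add(area, morph, ind, ind, "n_inflorescences", ninf[i])

            # per-individual intercepts, shared across that individual's units
            b_add = rng.normal(0.0, config.individual_sd, len(ind_ids))
            u_log = rng.normal(-0.5 * config.individual_sd_log**2,
                               config.individual_sd_log, len(ind_ids))

            # ---------- inflorescence layer (length + buds) ----------
            owners = [k % len(ind_ids) for k in range(config.n_inflorescences_sampled)]
            mu_len = config.trait_mean("inflorescence_length", area, morph)
            mu_buds = config.trait_mean("n_buds", area, morph)
            for j, k in enumerate(owners):
                uid = f"{cell}-infl{j + 1:02d}"
                length = _trunc_normal(mu_len + b_add[k],
                                       config.inflorescence_length_sd, 1, rng)[0]
                buds = sample_nb1(mu_buds * np.exp(u_log[k]),
                                  config.nb1_dispersion["n_buds"], 1, rng)[0]
                rec.add(area, morph, ind_ids[k], uid, "inflorescence_length", length)
                rec.add(area, morph, ind_ids[k], uid, "n_buds", buds)

            # ---------- infructescence layer (fruit counts) ----------
            n_fruit_inds = min(11, len(ind_ids))
            owners = [k % n_fruit_inds for k in range(config.n_fruit_inflorescences)]
            mu_fruits = config.trait_mean("n_fruits", area, morph)
            for j, k in enumerate(owners):
                uid = f"{cell}-fruit{j + 1:02d}"
                fruits = sample_nb1(mu_fruits * np.exp(u_log[k]),
                                    config.nb1_dispersion["n_fruits"], 1, rng)[0]
                rec.add(area, morph, ind_ids[k], uid, "n_fruits", fruits)

            # ---------- flower morphometry layer ----------
            fl_inds = ind_ids[: config.n_flower_individuals]
            for trait, per_morph in config.flower_trait_means.items():
                mu = config.trait_mean(trait, area, morph)
                sd = config.flower_trait_sds[trait]
                b_trait = rng.normal(0.0, config.individual_sd, len(fl_inds))
                for k, ind in enumerate(fl_inds):
                    vals = _trunc_normal(mu + b_trait[k], sd,
                                         config.flowers_per_individual, rng)
                    uids = [f"{ind}-fl{f + 1}" for f in range(config.flowers_per_individual)]
                    rec.add(area, morph, ind, uids, trait, vals)

            # ---------- nectar layer ----------
            mu_vol = config.trait_mean("nectar_volume", area, morph)
            conc_mean = config.trait_mean("nectar_concentration", area, morph) / 100.0
            conc_mean = min(conc_mean, 0.999)
            phi = config.nectar_concentration_precision
            for j in range(config.n_nectar_flowers):
                ind = fl_inds[j % len(fl_inds)]
                uid = f"{cell}-nec{j + 1:02d}"
                k = ind_ids.index(ind)
                vol = _trunc_normal(mu_vol + b_add[k], config.nectar_volume_sd, 1, rng)[0]
                conc = 100.0 * rng.beta(conc_mean * phi, (1 - conc_mean) * phi)
                rec.add(area, morph, ind, uid, "nectar_volume", vol)
                rec.add(area, morph, ind, uid, "nectar_concentration", conc)

            # ---------- pollen-deposition layer ----------
            mu_pol = config.trait_mean("pollen_grains", area, morph)
            for j in range(config.n_pollen_flowers):
                ind = fl_inds[j % len(fl_inds)]
                uid = f"{cell}-pol{j + 1:03d}"
                k = ind_ids.index(ind)
                grains = sample_zero_inflated(mu_pol * np.exp(u_log[k]),
                                              config.nb1_dispersion["pollen_grains"],
                                              config.zero_inflation_prob, 1, rng)[0]
                rec.add(area, morph, ind, uid, "pollen_grains", grains)

    return rec.frame()


# ----------------------------------------------------------------------
# table I/O and validation
# ----------------------------------------------------------------------

def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy trait table against the schema invariants.

    Checks column presence, factor levels, the one-to-one mapping of
    individuals to area x morph cells, integer non-negative counts, positive
    lengths and in-range concentrations.  Returns the table unchanged.
    """
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    bad_area = set(table["area"].unique()) - set(AREAS)
    if bad_area:
        raise ValueError(f"unknown area levels: {sorted(bad_area)}")
    bad_morph = set(table["morph"].unique()) - set(MORPHS)
    if bad_morph:
        raise ValueError(f"unknown morph levels: {sorted(bad_morph)}")
    cells = table.groupby("individual_id")[["area", "morph"]].nunique()
    multi = cells[(cells > 1).any(axis=1)]
    if len(multi):
        raise ValueError(
            f"individuals mapped to more than one area x morph cell: {list(multi.index)[:5]}"
        )
    counts = table[table["trait"].isin(COUNT_TRAITS)]["value"]
    if len(counts) and ((counts < 0).any() or (counts % 1 != 0).any()):
        raise ValueError("count traits must be non-negative integers")
    lengths = table[~table["trait"].isin(COUNT_TRAITS + ("nectar_concentration",))]["value"]
    if len(lengths) and (lengths <= 0).any():
        raise ValueError("lengths/heights/volumes must be strictly positive")
    conc = table[table["trait"] == "nectar_concentration"]["value"]
    if len(conc) and ((conc <= 0) | (conc >= 100)).any():
        raise ValueError("nectar_concentration must lie in (0, 100)")
    return table


def write_trait_table(table: pd.DataFrame, path: str | Path,
                      config: PopulationConfig | None = None) -> None:
    """Write the table as CSV; optionally record config + seed in sidecars."""
    path = Path(path)
    table.to_csv(path, index=False)
    if config is not None:
        config.to_yaml(path.with_suffix(".config.yaml"))
        sidecar = {"seed": int(config.seed), "config_hash": config.content_hash(),
                   "n_rows": int(len(table))}
        path.with_suffix(".provenance.json").write_text(json.dumps(sidecar, indent=2))


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy trait-table CSV."""
    table = pd.read_csv(path, dtype={"area": str, "morph": str,
                                     "individual_id": str, "unit_id": str,
                                     "trait": str})
    return validate_trait_table(table)
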