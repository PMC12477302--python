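"""Population configuration for the synthetic-data generator.

The configuration encodes the sampling design of a distylous plant population
studied across a burned ("fire") and an adjacent unburned ("no_fire") area:
two floral morphs (L = long-styled, S = short-styled) in each area, with
traits measured at the individual, inflorescence, flower, nectar and
pollen-deposition levels.

Default values reproduce the study conditions the analysis assumes: about 17
individuals per morph per area for individual traits, ~80 flowers per morph
per area for floral morphometry (10 flower-sampled individuals x 8 flowers),
~22 inflorescences per cell for buds, ~36 infructescences per cell for
fruits, ~10 nectar flowers and ~96 pollen-scored flowers per cell.  Organ
height means default to the reported population marginal means (L stigma
16.46 mm, S anther 16.51 mm as the high organs; S stigma 10.42 mm, L anther
10.83 mm as the low organs) in both areas, i.e. fire leaves reproductive
organ heights untouched, while fire effects on inflorescence length, corolla
length, anther length, L-morph stigma length and S-morph fruit number are
expressed multiplicatively at their reported magnitudes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

AREAS = ("no_fire", "fire")
MORPHS = ("L", "S")

#: traits measured once per individual
INDIVIDUAL_TRAITS = ("plant_height", "stem_diameter", "n_inflorescences")
#: traits measured per sampled inflorescence
INFLORESCENCE_TRAITS = ("inflorescence_length", "n_buds")
#: continuous traits measured per flower
FLOWER_TRAITS = (
    "corolla_length",
    "corolla_diameter",
    "stigma_height",
    "anther_height",
    "stigma_length",
    "anther_length",
)
COUNT_TRAITS = ("n_inflorescences", "n_buds", "n_fruits", "pollen_grains")


def _per_morph(value: float | Mapping[str, float]) -> dict[str, float]:
    """Normalise a scalar or ``{morph: value}`` mapping to a full dict."""
    if isinstance(value, Mapping):
        out = {m: float(value[m]) for m in MORPHS}
    else:
        out = {m: float(value) for m in MORPHS}
    return out


@dataclass
class PopulationConfig:
    """Parameters of the synthetic distylous population.

    Continuous trait means are per morph (dict ``{"L": .., "S": ..}``) or a
    single number applying to both morphs; SDs are flower-to-flower (or
    unit-to-unit) within individuals.  Count traits follow an NB1
    (linear-parameterisation) negative binomial with ``Var = mu * (1 +
    alpha)``.  Fire acts multiplicatively on means via ``fire_effects``:
    ``{trait: {"both"|"L"|"S": multiplier}}``.
    """

    # --- cell sizes -------------------------------------------------------
    n_individuals_per_cell: int = 17
    n_flower_individuals: int = 10
    flowers_per_individual: int = 8
    n_inflorescences_sampled: int = 22
    n_fruit_inflorescences: int = 36
    n_nectar_flowers: int = 10
    n_pollen_flowers: int = 96

    # --- individual traits (mm unless noted) ------------------------------
    plant_height_mean: float = 1500.0          # mm
    plant_height_sd: float = 300.0
    stem_diameter_mean: float = 30.0
    stem_diameter_sd: float = 8.0
    n_inflorescences_mean: float = 10.0

    # --- inflorescence traits --------------------------------------------
    inflorescence_length_mean: float = 26.77
    inflorescence_length_sd: float = 2.9
    n_buds_mean: float = 25.0

    # --- flower morphometry (means per morph, mm) -------------------------
    flower_trait_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "corolla_length": {"L": 14.21, "S": 14.21},
            "corolla_diameter": {"L": 5.0, "S": 5.0},
            "stigma_height": {"L": 16.46, "S": 10.42},
            "anther_height": {"L": 10.83, "S": 16.51},
            "stigma_length": {"L": 1.55, "S": 3.89},
            "anther_length": {"L": 3.70, "S": 3.70},
        }
    )
    flower_trait_sds: dict[str, float] = field(
        default_factory=lambda: {
            "corolla_length": 0.4,
            "corolla_diameter": 0.4,
            "stigma_height": 1.1,
            "anther_height": 1.1,
            "stigma_length": 0.30,
            "anther_length": 0.20,
        }
    )

    # --- counts (NB1) -----------------------------------------------------
    n_fruits_mean: dict[str, float] = field(
        default_factory=lambda: {"L": 95.0, "S": 89.77}
    )
    nb1_dispersion: dict[str, float] = field(
        default_factory=lambda: {
            "n_inflorescences": 2.0,
            "n_buds": 3.0,
            "n_fruits": 7.0,
            "pollen_grains": 8.0,
        }
    )
    pollen_grains_mean: float = 60.0
    zero_inflation_prob: float = 0.3           # structural zeros, pollen only

    # --- nectar -----------------------------------------------------------
    nectar_volume_mean: dict[str, float] = field(
        default_factory=lambda: {"L": 13.9, "S": 15.8}   # microlitres
    )
    nectar_volume_sd: float = 3.0
    nectar_concentration_mean: float = 20.0    # % w/w (Brix)
    nectar_concentration_precision: float = 50.0  # beta precision phi

    # --- hierarchy --------------------------------------------------------
    individual_sd: float = 0.05      # additive individual intercept, mm
    individual_sd_log: float = 0.1   # log-scale intercept for count traits

    # --- fire effects (multiplicative on means) ---------------------------
    fire_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "inflorescence_length": {"both": 24.26 / 26.77},
            "corolla_length": {"both": 13.54 / 14.21},
            "anther_length": {"both": 3.48 / 3.70},
            "stigma_length": {"L": 1.03 / 1.55},
            "n_fruits": {"S": 121.47 / 89.77},
        }
    )

    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.flower_trait_means = {
            t: _per_morph(v) for t, v in self.flower_trait_means.items()
        }
        self.n_fruits_mean = _per_morph(self.n_fruits_mean)
        self.nectar_volume_mean = _per_morph(self.nectar_volume_mean)
        self.validate()

    def validate(self) -> None:
        """Check the physical and distributional invariants."""
        sizes = (
            self.n_individuals_per_cell,
            self.n_flower_individuals,
            self.flowers_per_individual,
            self.n_inflorescences_sampled,
            self.n_fruit_inflorescences,
            self.n_nectar_flowers,
            self.n_pollen_flowers,
        )
        if any(int(s) < 1 for s in sizes):
            raise ValueError("all cell sizes must be >= 1")
        positives = {
            "plant_height_mean": self.plant_height_mean,
            "stem_diameter_mean": self.stem_diameter_mean,
            "n_inflorescences_mean": self.n_inflorescences_mean,
            "inflorescence_length_mean": self.inflorescence_length_mean,
            "n_buds_mean": self.n_buds_mean,
            "pollen_grains_mean": self.pollen_grains_mean,
            "nectar_concentration_precision": self.nectar_concentration_precision,
        }
        for trait, per_morph in self.flower_trait_means.items():
            for m, v in per_morph.items():
                positives[f"{trait}[{m}]"] = v
        for m, v in self.n_fruits_mean.items():
            positives[f"n_fruits[{m}]"] = v
        for m, v in self.nectar_volume_mean.items():
            positives[f"nectar_volume[{m}]"] = v
        for name, v in positives.items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        sds = {
            "plant_height_sd": self.plant_height_sd,
            "stem_diameter_sd": self.stem_diameter_sd,
            "inflorescence_length_sd": self.inflorescence_length_sd,
            "nectar_volume_sd": self.nectar_volume_sd,
            "individual_sd": self.individual_sd,
            "individual_sd_log": self.individual_sd_log,
            **{f"sd[{t}]": v for t, v in self.flower_trait_sds.items()},
        }
        for name, v in sds.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for trait, a in self.nb1_dispersion.items():
            if a < 0:
                raise ValueError(f"nb1_dispersion[{trait}] must be >= 0, got {a}")
        if not 0 <= self.zero_inflation_prob < 1:
            raise ValueError(
                f"zero_inflation_prob must be in [0, 1), got {self.zero_inflation_prob}"
            )
        if not 0 < self.nectar_concentration_mean < 100:
            raise ValueError("nectar_concentration_mean must be in (0, 100)")
        for trait, eff in self.fire_effects.items():
            for key, mult in eff.items():
                if key not in ("both", "L", "S"):
                    raise ValueError(f"fire_effects[{trait}]: unknown key {key!r}")
                if mult <= 0:
                    raise ValueError(f"fire_effects[{trait}][{key}] must be > 0")

    # ------------------------------------------------------------------
    def fire_multiplier(self, trait: str, morph: str) -> float:
        """Multiplicative fire effect on the mean of ``trait`` for ``morph``."""
        eff = self.fire_effects.get(trait, {})
        if morph in eff:
            return eff[morph]
        return eff.get("both", 1.0)

    def trait_mean(self, trait: str, area: str, morph: str) -> float:
        """Population mean of a trait in one area x morph cell."""
        base: float
        if trait in self.flower_trait_means:
            base = self.flower_trait_means[trait][morph]
        elif trait == "plant_height":
            base = self.plant_height_mean
        elif trait == "stem_diameter":
            base = self.stem_diameter_mean
        elif trait == "n_inflorescences":
            base = self.n_inflorescences_mean
        elif trait == "inflorescence_length":
            base = self.inflorescence_length_mean
        elif trait == "n_buds":
            base = self.n_buds_mean
        elif trait == "n_fruits":
            base = self.n_fruits_mean[morph]
        elif trait == "pollen_grains":
            base = self.pollen_grains_mean
        elif trait == "nectar_volume":
            base = self.nectar_volume_mean[morph]
        elif trait == "nectar_concentration":
            base = self.nectar_concentration_mean
        else:
            raise KeyError(f"unknown trait {trait!r}")
        if area == "fire":
            base *= self.fire_multiplier(trait, morph)
        elif area != "no_fire":
            raise KeyError(f"unknown area {area!r}")
        return base

    def without_fire_effects(self) -> "PopulationConfig":
        """Copy of the config with every fire multiplier reset to 1 (null scenario)."""
        cfg = dataclasses.replace(self, fire_effects={})
        return cfg

    # --- serialisation ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PopulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable short hash of the configuration (for provenance records)."""
        import hashlib

        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
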