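"""Percent effect sizes between group marginal means, and nectar energetics.

Effect sizes are reported as the signed percent difference of a focal group's
(back-transformed) marginal mean relative to a reference group's mean — for
area comparisons the unburned (no-fire) group is the reference, for morph
comparisons the group named second in the comparison is the reference.

Nectar energetics follow the standard field workflow: a refractometer
concentration (% w/w, "Brix") is converted to sucrose equivalents in
ug sucrose per uL nectar via the density of aqueous sucrose solutions,
and sugar mass is converted to energy at 4 calories per mg sugar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GroupMean:
    """A (back-transformed) marginal mean +- SE for one labelled group."""

    group: str
    mean: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean):
            raise ValueError("mean must be finite")
        if self.se < 0:
            raise ValueError("se must be >= 0")


@dataclass(frozen=True)
class EffectRecord:
    """Signed percent effect of ``focal`` relative to ``reference``."""

    focal: str
    reference: str
    percent_effect: float   # 100 * (focal - reference) / reference, 2 dp
    direction: str          # "increase" | "decrease" | "none"


def percent_effect(focal: GroupMean, reference: GroupMean) -> EffectRecord:
    """Percent difference of the focal mean relative to the reference mean.

    Reported to two decimals; the sign carries the direction (positive =
    focal larger).  A zero reference mean is rejected.
    """
    if reference.mean == 0:
        raise ValueError("reference mean must be non-zero")
    pct = round(100.0 * (focal.mean - reference.mean) / reference.mean, 2)
    direction = "increase" if pct > 0 else ("decrease" if pct < 0 else "none")
    return EffectRecord(focal=focal.group, reference=reference.group,
                        percent_effect=pct, direction=direction)


# ----------------------------------------------------------------------
# nectar energetics
# ----------------------------------------------------------------------

#: Density (g/mL at 20 C) of aqueous sucrose solutions by % w/w, from the
#: standard sucrose concentrative-properties table; linear interpolation
#: between the tabulated points.
_SUCROSE_PCT = np.array(
    [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0,
     55.0, 60.0, 65.0, 70.0])
_SUCROSE_DENSITY = np.array(
    [0.99823, 1.01785, 1.03810, 1.05900, 1.08096, 1.10356, 1.12698,
     1.15128, 1.17648, 1.20254, 1.22946, 1.25721, 1.28573, 1.31490,
     1.34717])


def sucrose_density(concentration: float) -> float:
    """Density (g/mL) of a ``concentration`` % w/w sucrose solution at 20 C."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0) or np.any(c > _SUCROSE_PCT[-1]):
        raise ValueError(
            f"concentration must be within [0, {_SUCROSE_PCT[-1]}] % w/w")
    out = np.interp(c, _SUCROSE_PCT, _SUCROSE_DENSITY)
    return float(out) if np.isscalar(concentration) else out


def brix_to_sucrose_equivalents(concentration: float) -> float:
    """Convert % w/w sugar concentration to ug sucrose per uL nectar.

    A C % w/w solution of density rho (g/mL) carries ``10 * C * rho``
    micrograms of sucrose per microlitre.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0) or np.any(c >= 100):
        raise ValueError("concentration must be in [0, 100) % w/w")
    out = 10.0 * c * sucrose_density(concentration)
    return float(out) if np.isscalar(concentration) else out


def sugar_to_calories(sugar_mass_mg: float) -> float:
    """Energy content of ``sugar_mass_mg`` mg of sugar at 4 cal per mg."""
    m = np.asarray(sugar_mass_mg, dtype=float)
    if np.any(m < 0):
        raise ValueError("sugar mass must be >= 0")
    out = 4.0 * m
    return float(out) if np.isscalar(sugar_mass_mg) else out


def nectar_energy(volume_ul: float, concentration: float) -> float:
    """Calories in ``volume_ul`` uL of nectar at ``concentration`` % w/w sugar."""
    v = np.asarray(volume_ul, dtype=float)
    if np.any(v < 0):
        raise ValueError("nectar volume must be >= 0")
    sugar_mg = v * brix_to_sucrose_equivalents(concentration) / 1000.0
    return sugar_to_calories(sugar_mg)


def add_nectar_calories(table: pd.DataFrame) -> pd.DataFrame:
    """Append per-flower ``nectar_calories`` rows derived from volume x concentration.

    Flowers are matched on ``unit_id``; flowers missing either measurement are
    skipped.  Returns a new table with the derived rows appended.
    """
    nectar = table[table["trait"].isin(["nectar_volume", "nectar_concentration"])]
    if nectar.empty:
        return table
    wide = nectar.pivot_table(index=["area", "morph", "individual_id", "unit_id"],
                              columns="trait", values="value").reset_index()
    wide = wide.dropna(subset=["nectar_volume", "nectar_concentration"])
    cal = nectar_energy(wide["nectar_volume"].to_numpy(),
                        wide["nectar_concentration"].to_numpy())
    new = wide[["area", "morph", "individual_id", "unit_id"]].copy()
    new["trait"] = "nectar_calories"
    new["value"] = cal
    out = pd.concat([table[table["trait"] != "nectar_calories"], new],
                    ignore_index=True)
    return out


def effect_table(means: pd.DataFrame, comparisons: list[tuple[str, str]]
                 ) -> pd.DataFrame:
    """Percent effects for named (focal, reference) group pairs.

    ``means`` must have columns ``group, mean, se`` (one row per group).
    """
    lookup = {r.group: GroupMean(r.group, r.mean, getattr(r, "se", 0.0))
              for r in means.itertuples(index=False)}
    rows = []
    for focal, reference in comparisons:
        rec = percent_effect(lookup[focal], lookup[reference])
        rows.append({"focal": rec.focal, "reference": rec.reference,
                     "percent_effect": rec.percent_effect,
                     "direction": rec.direction})
    return pd.DataFrame(rows)
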