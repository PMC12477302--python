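"""Between-morph reciprocity via the adaptive-accuracy (inaccuracy) statistic.

In a distylous population the long-styled (L) morph presents high stigmas and
low anthers while the short-styled (S) morph presents the reverse, so
legitimate (intermorph) pollination pairs organs at matching heights: the
*high* level pairs S-morph anthers with L-morph stigmas, the *low* level
pairs L-morph anthers with S-morph stigmas.  For one level, with anther
height mean/variance (A, V_A) and stigma height mean/variance (S, V_S),

    maladaptive bias = (A - S)^2        (systematic departure from optimum)
    imprecision      = V_A + V_S        (scatter around the means)
    inaccuracy       = bias + imprecision

and the total inaccuracy of a morph pairing is the sum of its high- and
low-level inaccuracies.  Lower inaccuracy means tighter reciprocity.  With
plants sampled in a burned and an unburned area there are four legitimate
morph pairings (within each area and the two cross-area pairings), each
drawing its four organ populations from specific area x morph groups.

Units are mm for organ heights, hence mm^2 for every inaccuracy component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import AREAS, MORPHS

Group = tuple[str, str]  # (area, morph)

ORGANS = ("stigma", "anther")
ORGAN_TRAITS = {"stigma": "stigma_height", "anther": "anther_height"}


def organ_level(morph: str, organ: str) -> str:
    """Height level of an organ given its morph: L-stigma and S-anther are high."""
    if morph not in MORPHS or organ not in ORGANS:
        raise ValueError(f"unknown morph/organ: {morph!r}/{organ!r}")
    high = (morph == "L" and organ == "stigma") or (morph == "S" and organ == "anther")
    return "high" if high else "low"


@dataclass(frozen=True)
class OrganSummary:
    """Sample mean/variance of one organ height in one area x morph group."""

    area: str
    morph: str
    organ: str          # "stigma" | "anther"
    mean: float         # mm
    variance: float     # mm^2, n-1 denominator
    n: int

    @property
    def level(self) -> str:
        return organ_level(self.morph, self.organ)

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.n < 2:
            raise ValueError(
                f"group ({self.area}, {self.morph}) {self.organ}: need n >= 2, got {self.n}"
            )
        organ_level(self.morph, self.organ)  # validates labels


@dataclass(frozen=True)
class Combination:
    """One legitimate morph pairing: which group fills each organ slot."""

    label: str
    high_anther: Group   # an S-morph group
    high_stigma: Group   # an L-morph group
    low_anther: Group    # an L-morph group
    low_stigma: Group    # an S-morph group

    def slots(self) -> dict[str, Group]:
        return {
            "high_anther": self.high_anther,
            "high_stigma": self.high_stigma,
            "low_anther": self.low_anther,
            "low_stigma": self.low_stigma,
        }


@dataclass(frozen=True)
class InaccuracyResult:
    """Inaccuracy decomposition for one morph pairing (all values mm^2)."""

    combination: str
    maladaptive_bias_high: float
    imprecision_high: float
    inaccuracy_high: float
    maladaptive_bias_low: float
    imprecision_low: float
    inaccuracy_low: float
    total_inaccuracy: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "combination": self.combination,
            "maladaptive_bias_high": self.maladaptive_bias_high,
            "imprecision_high": self.imprecision_high,
            "inaccuracy_high": self.inaccuracy_high,
            "maladaptive_bias_low": self.maladaptive_bias_low,
            "imprecision_low": self.imprecision_low,
            "inaccuracy_low": self.inaccuracy_low,
            "total_inaccuracy": self.total_inaccuracy,
        }


COMPONENT_NAMES = [
    "maladaptive_bias_high", "imprecision_high", "inaccuracy_high",
    "maladaptive_bias_low", "imprecision_low", "inaccuracy_low",
    "total_inaccuracy",
]


def summarize_organs(table: pd.DataFrame) -> dict[tuple[str, str, str], OrganSummary]:
    """Per-group organ-height summaries from a tidy trait table.

    Returns a dict keyed by ``(area, morph, organ)`` with sample mean and
    sample variance (n-1 denominator).  Every area x morph group must carry
    at least two stigma-height and two anther-height records.
    """
    out: dict[tuple[str, str, str], OrganSummary] = {}
    for area in AREAS:
        for morph in MORPHS:
            for organ, trait in ORGAN_TRAITS.items():
                vals = table.loc[
                    (table["area"] == area) & (table["morph"] == morph)
                    & (table["trait"] == trait), "value"
                ].to_numpy(dtype=float)
                if len(vals) < 2:
                    raise ValueError(
                        f"group ({area}, {morph}) has {len(vals)} {trait} records; "
                        "need at least 2"
                    )
                out[(area, morph, organ)] = OrganSummary(
                    area=area, morph=morph, organ=organ,
                    mean=float(np.mean(vals)),
                    variance=float(np.var(vals, ddof=1)),
                    n=len(vals),
                )
    return out


def inaccuracy_component(anther: OrganSummary, stigma: OrganSummary
                         ) -> tuple[float, float, float]:
    """(maladaptive bias, imprecision, inaccuracy) for one anther/stigma pair.

    The pairing is legitimate only when both organs sit at the same height
    level (high with high, low with low); mismatched levels raise.
    The formula is symmetric in the two organs.
    """
    if anther.organ != "anther" or stigma.organ != "stigma":
        raise ValueError("arguments must be an anther summary and a stigma summary")
    if anther.level != stigma.level:
        raise ValueError(
            f"illegitimate pairing: {anther.level} anther with {stigma.level} stigma"
        )
    bias = (anther.mean - stigma.mean) ** 2
    imprecision = anther.variance + stigma.variance
    return bias, imprecision, bias + imprecision


def enumerate_combinations(groups: Iterable[Group] | None = None) -> list[Combination]:
    """The four legitimate morph pairings across the two areas.

    Each area x morph group appears in exactly one high slot and one low
    slot.  ``groups`` defaults to all four cells; supplying fewer raises.
    """
    expected = {(a, m) for a in AREAS for m in MORPHS}
    got = expected if groups is None else set(groups)
    if got != expected:
        raise ValueError(
            f"need exactly the four area x morph groups {sorted(expected)}, got {sorted(got)}"
        )
    return [
        Combination("no_fire_L x no_fire_S",
                    high_anther=("no_fire", "S"), high_stigma=("no_fire", "L"),
                    low_anther=("no_fire", "L"), low_stigma=("no_fire", "S")),
        Combination("fire_L x fire_S",
                    high_anther=("fire", "S"), high_stigma=("fire", "L"),
                    low_anther=("fire", "L"), low_stigma=("fire", "S")),
        Combination("no_fire_S x fire_L",
                    high_anther=("no_fire", "S"), high_stigma=("fire", "L"),
                    low_anther=("fire", "L"), low_stigma=("no_fire", "S")),
        Combination("no_fire_L x fire_S",
                    high_anther=("fire", "S"), high_stigma=("no_fire", "L"),
                    low_anther=("no_fire", "L"), low_stigma=("fire", "S")),
    ]


def _slot_summary(summaries: Mapping, group: Group, organ: str) -> OrganSummary:
    key = (group[0], group[1], organ)
    if key not in summaries:
        raise ValueError(f"missing organ summary for group {group}, organ {organ}")
    return summaries[key]


def inaccuracy_for_combination(summaries: Mapping[tuple[str, str, str], OrganSummary],
                               combination: Combination) -> InaccuracyResult:
    """Full inaccuracy decomposition for one morph pairing."""
    ha = _slot_summary(summaries, combination.high_anther, "anther")
    hs = _slot_summary(summaries, combination.high_stigma, "stigma")
    la = _slot_summary(summaries, combination.low_anther, "anther")
    ls = _slot_summary(summaries, combination.low_stigma, "stigma")
    bh, ih, inh = inaccuracy_component(ha, hs)
    bl, il, inl = inaccuracy_component(la, ls)
    return InaccuracyResult(
        combination=combination.label,
        maladaptive_bias_high=bh, imprecision_high=ih, inaccuracy_high=inh,
        maladaptive_bias_low=bl, imprecision_low=il, inaccuracy_low=inl,
        total_inaccuracy=inh + inl,
    )


def standardize_result(result: InaccuracyResult,
                       summaries: Mapping[tuple[str, str, str], OrganSummary],
                       combination: Combination) -> InaccuracyResult:
    """Size-standardised variant: divide each level by its squared mean organ height.

    This is an opt-in extension (dimensionless output); the reference analysis
    reports raw mm^2 values.
    """
    ha = _slot_summary(summaries, combination.high_anther, "anther").mean
    hs = _slot_summary(summaries, combination.high_stigma, "stigma").mean
    la = _slot_summary(summaries, combination.low_anther, "anther").mean
    ls = _slot_summary(summaries, combination.low_stigma, "stigma").mean
    s_high = ((ha + hs) / 2.0) ** 2
    s_low = ((la + ls) / 2.0) ** 2
    return InaccuracyResult(
        combination=result.combination + " (standardized)",
        maladaptive_bias_high=result.maladaptive_bias_high / s_high,
        imprecision_high=result.imprecision_high / s_high,
        inaccuracy_high=result.inaccuracy_high / s_high,
        maladaptive_bias_low=result.maladaptive_bias_low / s_low,
        imprecision_low=result.imprecision_low / s_low,
        inaccuracy_low=result.inaccuracy_low / s_low,
        total_inaccuracy=result.inaccuracy_high / s_high + result.inaccuracy_low / s_low,
    )


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------

def _flower_heights(table: pd.DataFrame) -> dict[Group, pd.DataFrame]:
    """Per-group wide frame of (stigma_height, anther_height) per flower."""
    sub = table[table["trait"].isin(ORGAN_TRAITS.values())]
    out: dict[Group, pd.DataFrame] = {}
    for area in AREAS:
        for morph in MORPHS:
            g = sub[(sub["area"] == area) & (sub["morph"] == morph)]
            wide = g.pivot_table(index=["individual_id", "unit_id"], columns="trait",
                                 values="value").reset_index()
            out[(area, morph)] = wide
    return out


def bootstrap_inaccuracy(table: pd.DataFrame, combination: Combination,
                         B: int = 1000, seed: int = 0,
                         cluster_by_individual: bool = False) -> pd.DataFrame:
    """Nonparametric bootstrap percentile CIs for all inaccuracy components.

    Flowers are resampled with replacement within each area x morph group
    (keeping each flower's stigma and anther heights paired); with
    ``cluster_by_individual=True`` whole individuals are resampled instead
    (cluster bootstrap).  Returns a frame with point estimate, 2.5% and
    97.5% percentiles per component.  Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    rng = np.random.default_rng(seed)
    wide = _flower_heights(table)
    for g, frame in wide.items():
        if len(frame) < 2:
            raise ValueError(f"group {g} has fewer than 2 flowers with organ heights")

    point = inaccuracy_for_combination(summarize_organs(table), combination)

    # resampled mean/variance per (group, organ), vectorised over all B draws
    needed_groups = sorted(set(combination.slots().values()))
    moments: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}
    for group in needed_groups:
        frame = wide[group]
        if cluster_by_individual:
            codes = pd.factorize(frame["individual_id"])[0]
            n_ind = codes.max() + 1
            picks = rng.integers(0, n_ind, size=(B, n_ind))
            members = [np.flatnonzero(codes == i) for i in range(n_ind)]
            idx = [np.concatenate([members[i] for i in row]) for row in picks]
        else:
            n = len(frame)
            idx = rng.integers(0, n, size=(B, n))
        for organ, trait in ORGAN_TRAITS.items():
            vals = frame[trait].to_numpy(dtype=float)
            if cluster_by_individual:
                means = np.array([vals[i].mean() for i in idx])
                variances = np.array([vals[i].var(ddof=1) for i in idx])
            else:
                draws_v = vals[idx]
                means = draws_v.mean(axis=1)
                variances = draws_v.var(axis=1, ddof=1)
            moments[(group[0], group[1], organ)] = (means, variances)

    def comp(anther_key, stigma_key):
        am, av = moments[anther_key]
        sm_, sv = moments[stigma_key]
        bias = (am - sm_) ** 2
        imprec = av + sv
        return bias, imprec, bias + imprec

    s = combination.slots()
    bh, ih, inh = comp((*s["high_anther"], "anther"), (*s["high_stigma"], "stigma"))
    bl, il, inl = comp((*s["low_anther"], "anther"), (*s["low_stigma"], "stigma"))
    draws = np.column_stack([bh, ih, inh, bl, il, inl, inh + inl])

    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "component": COMPONENT_NAMES,
        "estimate": [getattr(point, c) for c in COMPONENT_NAMES],
        "ci_lower": lo,
        "ci_upper": hi,
    })


# ----------------------------------------------------------------------
# estimator facade
# ----------------------------------------------------------------------

class ReciprocityAnalysis(BaseEstimator):
    """Estimator computing the four-combination inaccuracy decomposition.

    Parameters
    ----------
    bootstrap_B : int or None
        Number of bootstrap resamples for percentile CIs (None disables).
    seed : int
        Bootstrap RNG seed.
    standardize : bool
        Also compute the size-standardised (dimensionless) variant.
    cluster_by_individual : bool
        Resample whole individuals instead of flowers in the bootstrap.

    Attributes (after :meth:`fit`)
    ------------------------------
    summaries_ : dict mapping (area, morph, organ) to :class:`OrganSummary`
    results_ : list of :class:`InaccuracyResult`, one per combination
    table_ : tidy DataFrame of all components per combination
    ci_ : dict mapping combination label to a bootstrap CI frame (if enabled)
    """

    def __init__(self, bootstrap_B: int | None = None, seed: int = 0,
                 standardize: bool = False, cluster_by_individual: bool = False):
        self.bootstrap_B = bootstrap_B
        self.seed = seed
        self.standardize = standardize
        self.cluster_by_individual = cluster_by_individual

    def fit(self, X: pd.DataFrame, y=None) -> "ReciprocityAnalysis":
        """Compute summaries and inaccuracies from a tidy trait table ``X``."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a tidy trait table DataFrame")
        self.summaries_ = summarize_organs(X)
        combos = enumerate_combinations()
        self.results_ = [inaccuracy_for_combination(self.summaries_, c) for c in combos]
        rows = [r.as_dict() for r in self.results_]
        if self.standardize:
            rows += [standardize_result(r, self.summaries_, c).as_dict()
                     for r, c in zip(self.results_, combos)]
        self.table_ = pd.DataFrame(rows)
        self.ci_ = {}
        if self.bootstrap_B is not None:
            for c in combos:
                self.ci_[c.label] = bootstrap_inaccuracy(
                    X, c, B=self.bootstrap_B, seed=self.seed,
                    cluster_by_individual=self.cluster_by_individual)
        return self

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Return the fitted component table (ignores ``X``)."""
        if not hasattr(self, "table_"):
            raise RuntimeError("ReciprocityAnalysis is not fitted")
        return self.table_


def population_inaccuracy(config, combination: Combination) -> InaccuracyResult:
    """Closed-form population inaccuracy implied by a generator config.

    Uses the configured cell means and total flower-level variances
    (within-individual variance + individual-intercept variance) in the same
    formulas the sample statistic applies; serves as the consistency target
    for estimates on synthetic data.
    """
    def summ(group: Group, organ: str) -> OrganSummary:
        area, morph = group
        trait = ORGAN_TRAITS[organ]
        mean = config.trait_mean(trait, area, morph)
        var = config.flower_trait_sds[trait] ** 2 + config.individual_sd ** 2
        return OrganSummary(area=area, morph=morph, organ=organ,
                            mean=mean, variance=var, n=2)

    summaries = {(g[0], g[1], organ): summ(g, organ)
                 for g in [(a, m) for a in AREAS for m in MORPHS]
                 for organ in ORGANS}
    return inaccuracy_for_combination(summaries, combination)
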