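"""Factorial ``trait ~ area * morph`` models with type-II Wald inference.

Each measured trait is modelled against area (no_fire / fire), morph (L / S)
and their interaction using the family appropriate to its support:

* ``gaussian-identity`` — normal errors, identity link;
* ``gamma-log`` — gamma errors, log link (positive continuous traits);
* ``nb1-log`` — NB1 negative binomial (``Var = mu * (1 + alpha)``), log link,
  optionally with a structural zero-inflation component (constant
  probability);
* ``beta-logit`` — beta regression on (0, 1) proportions, logit link;
* ``binomial-logit`` — Bernoulli presence/absence, logit link.

Plant individuals are repeated-measures clusters.  Gaussian models absorb
them with a ML-fitted random intercept (MixedLM); for the other families the
package uses a cluster-aware marginal fit — GEE with exchangeable working
correlation (gamma, binomial) or maximum likelihood with a cluster-robust
sandwich covariance grouped by individual (NB1, zero-inflated NB1, beta).
The handling actually used is recorded in ``ModelFit.re_handling``.

Models flagged ``dispersion_by_group`` accommodate cell-wise
heteroscedasticity through heteroscedasticity-robust (sandwich) covariances
rather than an explicit dispersion submodel; Wald inference is then based on
the robust covariance.

Hypothesis tests are type-II Wald chi-square tests (1 df per term in the
2 x 2 design): each main effect is tested adjusting for the other main
effect while ignoring the interaction, the interaction last, all from the
single full-model fit and its coefficient covariance.  Marginal means are
averaged over the factor grid on the link scale, back-transformed, with
delta-method standard errors — the convention of the emmeans/ggeffects
tooling this module mirrors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomialP
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.othermod.betareg import BetaModel
from statsmodels.regression.mixed_linear_model import MixedLM

from .config import AREAS, MORPHS
from .effects import GroupMean

FAMILIES = ("gaussian-identity", "gamma-log", "nb1-log", "beta-logit",
            "binomial-logit")

DESIGN_COLUMNS = ["Intercept", "area[T.fire]", "morph[T.S]",
                  "area[T.fire]:morph[T.S]"]

TERMS = {"area": [1], "morph": [2], "area:morph": [3]}
#: higher-order relatives of each term (containment in the 2x2 design)
_RELATIVES = {"area": ["area:morph"], "morph": ["area:morph"], "area:morph": []}


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one factorial trait model."""

    trait: str
    family: str
    dispersion_by_group: bool = False
    zero_inflated: bool = False
    random_intercept: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.zero_inflated and self.family != "nb1-log":
            raise ValueError("zero inflation is only supported for nb1-log")


def default_registry() -> list[ModelSpec]:
    """The sixteen default trait models (family, link, extra parameter, RE).

    Individual-level traits (plant height, stem diameter, inflorescence
    number) are independent samplings and carry no random intercept; all
    other traits are repeated measures within individuals.
    """
    g, ga, nb, be = "gaussian-identity", "gamma-log", "nb1-log", "beta-logit"
    return [
        ModelSpec("plant_height", ga, random_intercept=False, label="M.1"),
        ModelSpec("stem_diameter", ga, random_intercept=False, label="M.2"),
        ModelSpec("n_inflorescences", nb, random_intercept=False, label="M.3"),
        ModelSpec("inflorescence_length", g, label="M.4"),
        ModelSpec("n_buds", nb, label="M.5"),
        ModelSpec("n_fruits", nb, dispersion_by_group=True, label="M.6"),
        ModelSpec("corolla_length", ga, dispersion_by_group=True, label="M.7"),
        ModelSpec("corolla_diameter", g, label="M.8"),
        ModelSpec("stigma_height", g, label="M.9"),
        ModelSpec("anther_height", ga, dispersion_by_group=True, label="M.10"),
        ModelSpec("stigma_length", ga, label="M.11"),
        ModelSpec("anther_length", ga, dispersion_by_group=True, label="M.12"),
        ModelSpec("nectar_volume", g, dispersion_by_group=True, label="M.13"),
        ModelSpec("nectar_concentration", be, label="M.14"),
        ModelSpec("nectar_calories", g, label="M.15"),
        ModelSpec("pollen_grains", nb, zero_inflated=True, label="M.16"),
    ]


def pollen_presence_spec() -> ModelSpec:
    """Binomial view of pollen deposition: presence/absence per stigma."""
    return ModelSpec("pollen_deposited", "binomial-logit", label="M.16b")


@dataclass
class ModelFit:
    """A fitted factorial model: design coefficients, covariance, extras."""

    spec: ModelSpec
    params: pd.Series            # the four design coefficients
    cov: pd.DataFrame            # their covariance (robust where applicable)
    converged: bool
    llf: float | None
    n_obs: int
    backend: str                 # statsmodels backend used
    re_handling: str             # how individual clustering was absorbed
    alpha: float | None = None   # NB1 dispersion
    zi_prob: float | None = None  # structural-zero probability
    scale: float | None = None   # residual variance / dispersion scale
    warnings: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------
# data preparation
# ----------------------------------------------------------------------

def _design_matrix(area: np.ndarray, morph: np.ndarray) -> np.ndarray:
    a = (area == "fire").astype(float)
    m = (morph == "S").astype(float)
    return np.column_stack([np.ones_like(a), a, m, a * m])


def _extract(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in the table")
    data = sub[["area", "morph", "individual_id", "value"]].dropna().copy()
    for factor in ("area", "morph"):
        if data[factor].nunique() < 2:
            raise ValueError(
                f"trait {trait!r}: factor {factor!r} has fewer than 2 levels"
            )
    return data.reset_index(drop=True)


def _check_support(y: np.ndarray, spec: ModelSpec) -> None:
    if spec.family in ("nb1-log",):
        bad = (y < 0) | (y % 1 != 0)
        if bad.any():
            raise ValueError(
                f"{spec.trait}: count family needs non-negative integers; "
                f"offending rows {np.where(bad)[0][:5].tolist()}"
            )
    elif spec.family == "gamma-log":
        bad = y <= 0
        if bad.any():
            raise ValueError(
                f"{spec.trait}: gamma family needs strictly positive values; "
                f"offending rows {np.where(bad)[0][:5].tolist()}"
            )
    elif spec.family == "beta-logit":
        bad = (y <= 0) | (y >= 1)
        if bad.any():
            raise ValueError(
                f"{spec.trait}: beta family needs values in (0, 1); "
                f"offending rows {np.where(bad)[0][:5].tolist()}"
            )
    elif spec.family == "binomial-logit":
        bad = ~np.isin(y, (0.0, 1.0))
        if bad.any():
            raise ValueError(
                f"{spec.trait}: binomial family needs 0/1 values; "
                f"offending rows {np.where(bad)[0][:5].tolist()}"
            )


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _fit_ml_with_retries(model, n_params: int, seed: int = 0, **fit_kws):
    """Fit an ML model, retrying from jittered starts on non-convergence."""
    rng = np.random.default_rng(seed)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=500, **fit_kws)
        except Exception:
            res = None
        for _ in range(3):
            if res is not None and _ml_converged(res):
                break
            start = rng.normal(0.0, 0.5, n_params)
            try:
                res = model.fit(start_params=start, disp=0, maxiter=500,
                                method="bfgs", **fit_kws)
            except Exception:
                continue
    if res is None:
        raise RuntimeError("maximum-likelihood fit failed from all starts")
    return res


def _ml_converged(res) -> bool:
    conv = getattr(res, "mle_retvals", None)
    if conv is not None:
        return bool(conv.get("converged", True))
    return bool(getattr(res, "converged", True))


class _RobustResults:
    """Minimal results view carrying a replacement (sandwich) covariance."""

    def __init__(self, res, cov: np.ndarray):
        self._res = res
        self._cov = cov
        self.params = np.asarray(res.params)
        self.llf = getattr(res, "llf", None)

    def cov_params(self) -> np.ndarray:
        return self._cov


def _manual_sandwich(res, codes: np.ndarray | None) -> _RobustResults:
    """Cluster (or HC0) sandwich covariance from score_obs and the Hessian.

    ``V = B^{-1} M B^{-1}`` with ``B = -Hessian`` of the log-likelihood and
    ``M`` the outer-product sum of per-cluster scores, with a ``G/(G-1)``
    small-sample factor for clustering.
    """
    model = res.model
    params = np.asarray(res.params)
    if hasattr(model, "score_obs"):
        s = np.asarray(model.score_obs(params))
    else:
        from statsmodels.tools.numdiff import approx_fprime

        s = approx_fprime(params, model.loglikeobs)
    H = np.asarray(model.hessian(params))
    Binv = np.linalg.inv(-H)
    n, p = s.shape
    if codes is None:
        M = s.T @ s
        corr = 1.0
    else:
        G = int(codes.max()) + 1
        sg = np.zeros((G, p))
        np.add.at(sg, codes, s)
        M = sg.T @ sg
        # the conventional cluster small-sample factor
        corr = (G / (G - 1.0)) * ((n - 1.0) / (n - p))
    return _RobustResults(res, corr * (Binv @ M @ Binv))


class TraitModel(BaseEstimator):
    """Estimator for one factorial trait model.

    Parameters mirror :class:`ModelSpec`; ``interaction=False`` drops the
    area x morph term (then conditional contrasts are unavailable).

    Attributes (after :meth:`fit`)
    ------------------------------
    fit_ : :class:`ModelFit` — coefficients, covariance and extras
    result_ : the underlying statsmodels results object
    """

    def __init__(self, trait: str = "", family: str = "gaussian-identity",
                 dispersion_by_group: bool = False, zero_inflated: bool = False,
                 random_intercept: bool = True, interaction: bool = True,
                 seed: int = 0, label: str = ""):
        self.trait = trait
        self.family = family
        self.dispersion_by_group = dispersion_by_group
        self.zero_inflated = zero_inflated
        self.random_intercept = random_intercept
        self.interaction = interaction
        self.seed = seed
        self.label = label

    @classmethod
    def from_spec(cls, spec: ModelSpec, seed: int = 0) -> "TraitModel":
        return cls(trait=spec.trait, family=spec.family,
                   dispersion_by_group=spec.dispersion_by_group,
                   zero_inflated=spec.zero_inflated,
                   random_intercept=spec.random_intercept,
                   seed=seed, label=spec.label)

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.trait, self.family, self.dispersion_by_group,
                         self.zero_inflated, self.random_intercept, self.label)

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "TraitModel":
        """Fit the model on a tidy trait table ``X``."""
        spec = self.spec
        data = _extract(X, self.trait)
        yv = data["value"].to_numpy(dtype=float)
        _check_support(yv, spec)
        exog = _design_matrix(data["area"].to_numpy(), data["morph"].to_numpy())
        cols = list(DESIGN_COLUMNS)
        if not self.interaction:
            exog = exog[:, :3]
            cols = cols[:3]
        groups = data["individual_id"].to_numpy()
        notes: list[str] = []
        alpha = zi_prob = scale = None
        llf = None
        converged = True

        robust_wanted = spec.dispersion_by_group

        if spec.family == "gaussian-identity":
            if spec.random_intercept and not robust_wanted:
                res = self._fit_mixedlm(yv, exog, groups, notes)
                if res is not None:
                    converged = True
                    params = np.asarray(res.fe_params)
                    cov = np.asarray(res.cov_params())[: len(cols), : len(cols)]
                    llf = float(res.llf)
                    scale = float(res.scale)
                    backend, re_handling = "MixedLM(ML)", "random intercept (ML)"
                else:  # boundary/singular mixed fit: marginal fallback
                    codes = pd.factorize(groups)[0]
                    res = sm.OLS(yv, exog).fit(cov_type="cluster",
                                               cov_kwds={"groups": codes})
                    params = np.asarray(res.params)
                    cov = np.asarray(res.cov_params())
                    llf = float(res.llf)
                    scale = float(res.scale)
                    backend = "OLS + cluster"
                    re_handling = "cluster-robust sandwich by individual (MixedLM fallback)"
            elif spec.random_intercept and robust_wanted:
                res = sm.GEE(yv, exog, groups=groups,
                             family=sm.families.Gaussian(),
                             cov_struct=sm.cov_struct.Exchangeable()).fit()
                params = np.asarray(res.params)
                cov = np.asarray(res.cov_params())
                scale = float(res.scale)
                backend = "GEE(gaussian, exchangeable)"
                re_handling = "exchangeable working correlation, robust SE"
                notes.append("cell-wise dispersion absorbed by sandwich covariance")
            else:
                res = sm.OLS(yv, exog).fit(
                    cov_type="HC3" if robust_wanted else "nonrobust")
                params = np.asarray(res.params)
                cov = np.asarray(res.cov_params())
                llf = float(res.llf)
                scale = float(res.scale)
                backend = "OLS" + (" + HC3" if robust_wanted else "")
                re_handling = "none (independent samples)"

        elif spec.family in ("gamma-log", "binomial-logit"):
            fam = (sm.families.Gamma(sm.families.links.Log())
                   if spec.family == "gamma-log"
                   else sm.families.Binomial())
            if spec.random_intercept:
                res = sm.GEE(yv, exog, groups=groups, family=fam,
                             cov_struct=sm.cov_struct.Exchangeable()).fit()
                params = np.asarray(res.params)
                cov = np.asarray(res.cov_params())
                scale = float(res.scale)
                backend = f"GEE({spec.family}, exchangeable)"
                re_handling = "exchangeable working correlation, robust SE"
            else:
                res = sm.GLM(yv, exog, family=fam).fit(
                    cov_type="HC3" if robust_wanted else "nonrobust")
                params = np.asarray(res.params)
                cov = np.asarray(res.cov_params())
                llf = float(res.llf)
                scale = float(res.scale)
                converged = bool(getattr(res, "converged", True))
                backend = f"GLM({spec.family})" + (" + HC3" if robust_wanted else "")
                re_handling = "none (independent samples)"

        elif spec.family == "nb1-log":
            if spec.zero_inflated:
                model = ZeroInflatedNegativeBinomialP(
                    yv, exog, exog_infl=np.ones((len(yv), 1)), p=1)
                res = _fit_ml_with_retries(model, exog.shape[1] + 2, seed=self.seed)
                converged = _ml_converged(res)
                full = np.asarray(res.params)
                # parameter order: [inflate_const, design..., alpha]
                zi_prob = float(1.0 / (1.0 + np.exp(-full[0])))
                alpha = float(full[-1])
                sl = slice(1, 1 + len(cols))
            else:
                model = NegativeBinomialP(yv, exog, p=1)
                res = _fit_ml_with_retries(model, exog.shape[1] + 1, seed=self.seed)
                converged = _ml_converged(res)
                full = np.asarray(res.params)
                alpha = float(full[-1])
                sl = slice(0, len(cols))
            llf = float(res.llf)
            if spec.random_intercept:
                res = self._robustify(res, groups, notes)
                re_handling = "cluster-robust sandwich by individual"
            else:
                re_handling = "none (independent samples)"
                if robust_wanted:
                    res = self._robustify(res, None, notes)
            params = np.asarray(res.params)[sl]
            cov = np.asarray(res.cov_params())[sl, sl]
            backend = ("ZINB1(ML)" if spec.zero_inflated else "NB1(ML)")

        elif spec.family == "beta-logit":
            model = BetaModel(yv, exog)
            res = _fit_ml_with_retries(model, exog.shape[1] + 1, seed=self.seed)
            converged = _ml_converged(res)
            llf = float(res.llf)
            scale = float(np.asarray(res.params)[-1])  # precision phi
            if spec.random_intercept:
                res = self._robustify(res, groups, notes)
                re_handling = "cluster-robust sandwich by individual"
            else:
                re_handling = "none (independent samples)"
            params = np.asarray(res.params)[: len(cols)]
            cov = np.asarray(res.cov_params())[: len(cols), : len(cols)]
            backend = "BetaModel(ML)"

        else:  # pragma: no cover — guarded by ModelSpec
            raise ValueError(f"unknown family {spec.family!r}")

        self.result_ = res
        self.fit_ = ModelFit(
            spec=spec,
            params=pd.Series(params, index=cols),
            cov=pd.DataFrame(cov, index=cols, columns=cols),
            converged=converged,
            llf=llf,
            n_obs=len(yv),
            backend=backend,
            re_handling=re_handling,
            alpha=alpha,
            zi_prob=zi_prob,
            scale=scale,
            warnings=notes,
        )
        return self

    @staticmethod
    def _fit_mixedlm(yv, exog, groups, notes: list[str]):
        """ML MixedLM fit, cycling optimizers; None if no optimizer converges."""
        model = MixedLM(yv, exog, groups=groups)
        for method in (None, "powell", "cg", "nm"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    kws = {} if method is None else {"method": method,
                                                     "maxiter": 2000}
                    res = model.fit(reml=False, **kws)
                if bool(getattr(res, "converged", True)):
                    if method is not None:
                        notes.append(f"MixedLM converged with {method} optimizer")
                    return res
            except Exception:
                continue
        notes.append("MixedLM did not converge; cluster-robust OLS fallback")
        return None

    @staticmethod
    def _robustify(res, groups, notes: list[str]):
        """Swap in a sandwich covariance (cluster if groups given, else HC0).

        Uses statsmodels' robust results when the model supports them and
        otherwise computes the score-based sandwich directly from
        ``score_obs``/``hessian`` at the ML estimate.
        """
        codes = pd.factorize(groups)[0] if groups is not None else None
        try:
            if codes is not None:
                return res.get_robustcov_results(cov_type="cluster", groups=codes)
            return res.get_robustcov_results(cov_type="HC0")
        except (AttributeError, NotImplementedError):
            pass
        try:
            return _manual_sandwich(res, codes)
        except Exception as exc:  # keep the ML covariance, but say so
            notes.append(f"robust covariance unavailable ({exc}); using ML covariance")
            return res

    # convenience delegates -------------------------------------------
    def wald_type2(self) -> pd.DataFrame:
        return wald_type2_tests(self.fit_)

    def marginal_means(self) -> pd.DataFrame:
        return marginal_means(self.fit_)

    def conditional_contrasts(self) -> pd.DataFrame:
        return conditional_contrasts(self.fit_)


def fit_trait_model(table: pd.DataFrame, spec: ModelSpec, seed: int = 0) -> ModelFit:
    """Fit one factorial trait model and return its :class:`ModelFit`."""
    return TraitModel.from_spec(spec, seed=seed).fit(table).fit_


# ----------------------------------------------------------------------
# type-II Wald chi-square tests
# ----------------------------------------------------------------------

def _conjugate_complement(X: np.ndarray, Z: np.ndarray, ip: np.ndarray) -> np.ndarray:
    """Basis of the subspace of span(Z) conjugate-orthogonal to span(X) wrt ``ip``."""
    M = Z.T @ ip @ X
    rank = np.linalg.matrix_rank(M)
    if rank == 0:
        return Z
    Q, _ = np.linalg.qr(M, mode="complete")
    return Z @ Q[:, rank:]


def _type2_hypothesis(term: str, cov: np.ndarray) -> np.ndarray:
    """Type-II hypothesis matrix for ``term`` in the 2x2 factorial design."""
    p = cov.shape[0]
    eye = np.eye(p)
    subs_term = TERMS[term]
    subs_rel = [c for rel in _RELATIVES[term] for c in TERMS[rel] if c < p]
    hyp1 = eye[subs_rel].copy()
    hyp1[:, subs_term] = 0.0
    hyp2 = eye[subs_rel + subs_term]
    if len(subs_rel) == 0:
        return hyp2
    return _conjugate_complement(hyp1.T, hyp2.T, cov).T


def wald_type2_tests(fit: ModelFit | TraitModel) -> pd.DataFrame:
    """Type-II Wald chi-square table for area, morph and area:morph.

    Each main effect is tested after the other main effect, ignoring the
    interaction; the interaction is tested last.  All tests use the single
    full-model coefficient covariance (robust where the fit is robust).
    """
    if isinstance(fit, TraitModel):
        fit = fit.fit_
    if not fit.converged:
        raise RuntimeError(
            f"model for {fit.spec.trait!r} did not converge; tests unavailable")
    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    terms = ["area", "morph"] + (["area:morph"] if len(beta) == 4 else [])
    rows = []
    for term in terms:
        L = _type2_hypothesis(term, V)
        Lb = L @ beta
        W = float(Lb.T @ np.linalg.solve(L @ V @ L.T, Lb))
        df = L.shape[0]
        rows.append({"term": term, "chi2": W, "df": df,
                     "p_value": float(stats.chi2.sf(W, df))})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# marginal means and contrasts
# ----------------------------------------------------------------------

def _invlink(family: str):
    if family == "gaussian-identity":
        return (lambda e: e), (lambda e: np.ones_like(e))
    if family in ("gamma-log", "nb1-log"):
        return np.exp, np.exp
    # logit links
    def expit(e):
        return 1.0 / (1.0 + np.exp(-e))

    return expit, (lambda e: expit(e) * (1.0 - expit(e)))


def _cell_row(area: str, morph: str, p: int) -> np.ndarray:
    x = np.zeros(p)
    x[0] = 1.0
    if area == "fire":
        x[1] = 1.0
    if morph == "S":
        x[2] = 1.0
    if p == 4 and area == "fire" and morph == "S":
        x[3] = 1.0
    return x


def marginal_means(fit: ModelFit | TraitModel) -> pd.DataFrame:
    """Back-transformed predicted means per cell and per factor margin.

    Predictions are averaged over the factor grid on the link scale (each
    cell weighted equally, not observation-weighted) and then inverse-linked;
    standard errors are delta-method.  For zero-inflated fits the means refer
    to the count component (structural zeros excluded).
    """
    if isinstance(fit, TraitModel):
        fit = fit.fit_
    if not fit.converged:
        raise RuntimeError(
            f"model for {fit.spec.trait!r} did not converge; means unavailable")
    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    p = len(beta)
    inv, dinv = _invlink(fit.spec.family)

    grid = {}
    for area in AREAS:
        for morph in MORPHS:
            grid[(area, morph)] = _cell_row(area, morph, p)

    rows = []

    def emit(kind: str, label: str, x: np.ndarray, area="", morph=""):
        eta = float(x @ beta)
        se_eta = float(np.sqrt(x @ V @ x))
        mean = float(inv(np.asarray(eta)))
        se = float(np.abs(dinv(np.asarray(eta)))) * se_eta
        rows.append({"kind": kind, "group": label, "area": area, "morph": morph,
                     "mean": mean, "se": se})

    for (area, morph), x in grid.items():
        emit("cell", f"{area}:{morph}", x, area, morph)
    for area in AREAS:
        x = np.mean([grid[(area, m)] for m in MORPHS], axis=0)
        emit("area", area, x, area=area)
    for morph in MORPHS:
        x = np.mean([grid[(a, morph)] for a in AREAS], axis=0)
        emit("morph", morph, x, morph=morph)
    return pd.DataFrame(rows)


def group_means(fit: ModelFit | TraitModel) -> list[GroupMean]:
    """Marginal means as :class:`~reciprostat.effects.GroupMean` records."""
    mm = marginal_means(fit)
    return [GroupMean(r.group, r.mean, r.se) for r in mm.itertuples(index=False)]


def conditional_contrasts(fit: ModelFit | TraitModel) -> pd.DataFrame:
    """Fire vs no-fire contrast within each morph, on the link scale.

    Requires the interaction term in the fit; Wald z tests per morph.  The
    ``ratio``/``difference`` column back-transforms the contrast for log /
    identity links respectively.
    """
    if isinstance(fit, TraitModel):
        fit = fit.fit_
    if not fit.converged:
        raise RuntimeError(
            f"model for {fit.spec.trait!r} did not converge; contrasts unavailable")
    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    if len(beta) < 4:
        raise ValueError(
            "no interaction term in the fit: read the area main effect instead")
    L = {"L": np.array([0.0, 1.0, 0.0, 0.0]),
         "S": np.array([0.0, 1.0, 0.0, 1.0])}
    rows = []
    for morph, l in L.items():
        est = float(l @ beta)
        se = float(np.sqrt(l @ V @ l))
        z = est / se if se > 0 else np.inf * np.sign(est)
        rows.append({
            "morph": morph,
            "contrast": "fire - no_fire",
            "estimate_link": est,
            "se": se,
            "z": z,
            "p_value": float(2.0 * stats.norm.sf(abs(z))),
            "back_transformed": float(np.exp(est))
            if fit.spec.family in ("gamma-log", "nb1-log") else est,
        })
    return pd.DataFrame(rows)
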