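"""GLM engine for individual healthcare cost models.

Fits generalized linear models of annual cost on sex, 5-year age band and
AMG indicators, over the family/link menu customary for skewed cost data:
families gaussian / poisson / gamma / inverse gaussian (variance
proportional to mu^p, p = 0..3) crossed with identity / log / square-root
("power 0.5") links. Estimation is iteratively reweighted least squares
via statsmodels; this module owns the design-matrix convention, the
maximum-likelihood dispersion used in information criteria, and a
serialisable fitted-model artifact.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special

from .catalog import age_band

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian", "poisson", "gamma", "inverse_gaussian")
LINKS = ("identity", "log", "power_half")

#: variance-power exponent of each family (Var[Y] proportional to mu^p)
FAMILY_VARIANCE_POWER = {
    "gaussian": 0,
    "poisson": 1,
    "gamma": 2,
    "inverse_gaussian": 3,
}


def _sm_link(link: str):
    if link == "identity":
        return sm.families.links.Identity()
    if link == "log":
        return sm.families.links.Log()
    if link == "power_half":
        return sm.families.links.Power(power=0.5)
    raise ValueError(f"unknown link: {link!r}")


# statsmodels validates family/link pairs against a safe list and rejects
# e.g. gaussian with a power link outright; the cost-model menu crosses all
# three links with all four families, so widen the admissible links.
class _Gaussian(sm.families.Gaussian):
    links = list(sm.families.Gaussian.links) + [sm.families.links.Power]


class _Poisson(sm.families.Poisson):
    links = list(sm.families.Poisson.links) + [sm.families.links.Power]


class _Gamma(sm.families.Gamma):
    links = list(sm.families.Gamma.links) + [sm.families.links.Power]


class _InverseGaussian(sm.families.InverseGaussian):
    links = list(sm.families.InverseGaussian.links) + [sm.families.links.Power]


def _sm_family(family: str, link: str):
    cls = {
        "gaussian": _Gaussian,
        "poisson": _Poisson,
        "gamma": _Gamma,
        "inverse_gaussian": _InverseGaussian,
    }.get(family)
    if cls is None:
        raise ValueError(f"unknown family: {family!r}")
    with warnings.catch_warnings():
        # non-canonical family/link pairs are intentional here
        warnings.simplefilter("ignore")
        return cls(link=_sm_link(link))


@dataclass(frozen=True)
class ModelSpec:
    """A (family, link) choice on the fixed covariate encoding."""

    family: str = "gamma"
    link: str = "log"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family: {self.family!r}")
        if self.link not in LINKS:
            raise ValueError(f"unknown link: {self.link!r}")


@dataclass(frozen=True)
class DesignEncoding:
    """Factor levels behind the design matrix.

    Treatment coding with reference levels age band 0, AMG code 1 and
    sex 0 (male): columns are ``const``, ``sex``, ``age_<b>`` for each
    non-reference band present, then ``amg_<c>`` for each non-reference
    code, in ascending order.
    """

    age_bands: tuple[int, ...]
    amg_codes: tuple[int, ...]

    @property
    def columns(self) -> list[str]:
        cols = ["const", "sex"]
        cols += [f"age_{b}" for b in self.age_bands if b != 0]
        cols += [f"amg_{c}" for c in self.amg_codes if c != 1]
        return cols


def infer_encoding(records: pd.DataFrame) -> DesignEncoding:
    bands = np.sort(age_band(records["age_years"]).unique())
    codes = np.sort(records["amg_code"].unique())
    return DesignEncoding(tuple(int(b) for b in bands), tuple(int(c) for c in codes))


def build_design(
    records: pd.DataFrame, encoding: DesignEncoding | None = None
) -> tuple[pd.DataFrame, pd.Series, DesignEncoding]:
    """Design matrix and response for a person-level cost table.

    Parameters
    ----------
    records
        Columns ``sex`` (0/1, 1 = female), ``age_years``, ``amg_code``
        and optionally ``cost_eur`` (the response; zeros in its place if
        absent, e.g. at predict time).
    encoding
        Factor levels to encode against. Inferred from the data when
        omitted; at predict time pass the training encoding, and any
        level unseen there raises ``ValueError`` naming the level.
    """
    bands = age_band(records["age_years"])
    if encoding is None:
        encoding = infer_encoding(records)
    else:
        bad_bands = set(bands.unique()) - set(encoding.age_bands)
        if bad_bands:
            raise ValueError(f"unseen age band level(s): {sorted(bad_bands)}")
        bad_codes = set(records["amg_code"].unique()) - set(encoding.amg_codes)
        if bad_codes:
            raise ValueError(f"unseen AMG code level(s): {sorted(bad_codes)}")

    n = len(records)
    X = pd.DataFrame(0.0, index=records.index, columns=encoding.columns)
    X["const"] = 1.0
    X["sex"] = records["sex"].to_numpy(dtype=float)
    for b in encoding.age_bands:
        if b != 0:
            X[f"age_{b}"] = (bands.to_numpy() == b).astype(float)
    codes = records["amg_code"].to_numpy()
    for c in encoding.amg_codes:
        if c != 1:
            X[f"amg_{c}"] = (codes == c).astype(float)

    if "cost_eur" in records:
        y = records["cost_eur"].astype(float).rename("cost_eur")
    else:
        y = pd.Series(np.zeros(n), index=records.index, name="cost_eur")
    return X, y, encoding


@dataclass
class FittedGLM:
    """Coefficients-plus-dispersion bundle for one (family, link) fit."""

    spec: ModelSpec
    coefficients: pd.Series
    bse: pd.Series
    dispersion_ml: float  # ML estimate used in the likelihood / AIC / BIC
    dispersion_pearson: float  # Pearson chi^2 / (n - k), used for SEs
    deviance: float
    null_deviance: float
    loglik: float
    n: int
    k: int  # parameters entering AIC/BIC (mean params + dispersion if estimated)
    converged: bool
    iterations: int
    encoding: DesignEncoding | None = None
    _sm_result: object = field(default=None, repr=False, compare=False)

    def require_converged(self):
        if not self.converged:
            raise RuntimeError(
                f"GLM ({self.spec.family}/{self.spec.link}) did not converge; "
                "refusing downstream use"
            )

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "link": self.spec.link,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "dispersion_ml": self.dispersion_ml,
            "dispersion_pearson": self.dispersion_pearson,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "loglik": self.loglik,
            "n": self.n,
            "k": self.k,
            "converged": self.converged,
            "iterations": self.iterations,
            "encoding": None
            if self.encoding is None
            else {
                "age_bands": list(self.encoding.age_bands),
                "amg_codes": list(self.encoding.amg_codes),
            },
        }

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "FittedGLM":
        enc = d.get("encoding")
        return cls(
            spec=ModelSpec(d["family"], d["link"]),
            coefficients=pd.Series(d["coefficients"], dtype=float),
            bse=pd.Series(d["bse"], dtype=float),
            dispersion_ml=d["dispersion_ml"],
            dispersion_pearson=d["dispersion_pearson"],
            deviance=d["deviance"],
            null_deviance=d["null_deviance"],
            loglik=d["loglik"],
            n=d["n"],
            k=d["k"],
            converged=d["converged"],
            iterations=d["iterations"],
            encoding=None
            if enc is None
            else DesignEncoding(tuple(enc["age_bands"]), tuple(enc["amg_codes"])),
        )

    @classmethod
    def load(cls, path) -> "FittedGLM":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _gamma_ml_shape(y: np.ndarray, mu: np.ndarray) -> float:
    """ML estimate of the gamma shape nu given fitted means.

    Solves d/dnu of the gamma log-likelihood = 0, i.e.
    log(nu) - psi(nu) = mean(y/mu - log(y/mu) - 1).
    """
    ratio = y / mu
    c = float(np.mean(ratio - np.log(ratio) - 1.0))
    if c <= 0:  # exact fit
        return np.inf

    def score(log_nu):
        nu = np.exp(log_nu)
        return np.log(nu) - special.digamma(nu) - c

    # log(nu)-psi(nu) ~ 1/(2 nu); bracket around the moment guess
    lo, hi = np.log(1.0 / (2 * c)) - 8, np.log(1.0 / (2 * c)) + 8
    return float(np.exp(optimize.brentq(score, lo, hi, xtol=1e-12)))


def _loglik_ml(family: str, y: np.ndarray, mu: np.ndarray, p: int):
    """(log-likelihood at ML dispersion, ML dispersion, k for IC).

    Dispersion is profiled out by maximum likelihood for the families
    that carry one (gaussian sigma^2, gamma 1/nu, inverse-gaussian
    lambda); it then counts as a parameter in AIC/BIC. The poisson
    family on continuous costs is quasi-likelihood: its "log-likelihood"
    uses the poisson density with gamma-function factorials at scale 1.
    """
    n = len(y)
    if family == "gaussian":
        sigma2 = float(np.mean((y - mu) ** 2))
        if sigma2 == 0:
            return np.inf, 0.0, p + 1
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        return float(ll), sigma2, p + 1
    if family == "poisson":
        ll = float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))
        return ll, 1.0, p
    if family == "gamma":
        nu = _gamma_ml_shape(y, mu)
        if not np.isfinite(nu):
            return np.inf, 0.0, p + 1
        ll = float(
            np.sum(
                nu * np.log(nu * y / mu)
                - nu * y / mu
                - np.log(y)
                - special.gammaln(nu)
            )
        )
        return ll, 1.0 / nu, p + 1
    if family == "inverse_gaussian":
        # ML of the IG dispersion (1/lambda) is closed form
        disp = float(np.mean((y - mu) ** 2 / (mu**2 * y)))
        if disp == 0:
            return np.inf, 0.0, p + 1
        lam = 1.0 / disp
        ll = float(
            np.sum(
                0.5 * np.log(lam / (2 * np.pi * y**3))
                - lam * (y - mu) ** 2 / (2 * mu**2 * y)
            )
        )
        return ll, disp, p + 1
    raise ValueError(f"unknown family: {family!r}")


def _start_params(X: np.ndarray, y: np.ndarray, link: str) -> np.ndarray | None:
    """OLS on the link-transformed response: a cheap, usually interior start.

    Keeps mu positive through early IRLS iterations for identity/power
    links with gamma or inverse-gaussian variance, where statsmodels'
    default start can step outside the mean's domain.
    """
    if link == "log":
        z = np.log(y)
    elif link == "power_half":
        z = np.sqrt(y)
    else:
        z = y
    try:
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        return beta
    except np.linalg.LinAlgError:  # pragma: no cover
        return None


def fit_glm(
    X: pd.DataFrame,
    y: pd.Series,
    spec: ModelSpec = ModelSpec(),
    encoding: DesignEncoding | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> FittedGLM:
    """Fit one GLM by IRLS.

    Convergence is declared on relative deviance change below `tol`
    within `maxiter` iterations; a non-converged fit is returned with
    ``converged=False`` (consumers must check, see
    :meth:`FittedGLM.require_converged`) and a warning logged. A
    rank-deficient design raises ``ValueError``.
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("non-finite values in design matrix")
    if spec.family in ("gamma", "inverse_gaussian") and np.any(yv <= 0):
        raise ValueError(f"{spec.family} family requires strictly positive response")
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient (separation or collinearity)")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fam = _sm_family(spec.family, spec.link)
        model = sm.GLM(yv, Xv, family=fam)
    start = _start_params(Xv, yv, spec.link)
    # Convergence on RELATIVE deviance change < tol (tiny absolute floor
    # so exact fits with deviance ~0 also terminate cleanly). The IRLS
    # runs at fixed scale 1: point estimates do not depend on the scale,
    # and letting statsmodels divide its convergence criterion by an
    # estimated Pearson scale breaks down on near-exact fits (scale -> 0).
    fit_kw = dict(maxiter=maxiter, scale=1.0, atol=1e-10, rtol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(start_params=start, **fit_kw)
            converged = bool(getattr(res, "converged", True))
        except Exception:
            # retry from statsmodels' own default start before giving up
            try:
                res = model.fit(**fit_kw)
                converged = bool(getattr(res, "converged", True))
            except Exception as exc:
                raise ValueError(f"GLM fit failed: {exc}") from exc

    mu = np.asarray(res.mu, dtype=float)
    p = Xv.shape[1]
    ll, disp_ml, k = _loglik_ml(spec.family, yv, mu, p)
    # Pearson dispersion for standard errors: X^2 / (n - p)
    var_mu = fam.variance(mu)
    pearson = float(np.sum((yv - mu) ** 2 / var_mu) / max(len(yv) - p, 1))
    fitted = FittedGLM(
        spec=spec,
        coefficients=pd.Series(res.params, index=list(X.columns)),
        bse=pd.Series(res.bse * np.sqrt(pearson), index=list(X.columns)),
        dispersion_ml=disp_ml,
        dispersion_pearson=pearson,
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        loglik=ll,
        n=len(yv),
        k=k,
        converged=converged,
        iterations=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        encoding=encoding,
        _sm_result=res,
    )
    if not converged:
        logger.warning(
            "GLM %s/%s did not converge in %d iterations",
            spec.family,
            spec.link,
            maxiter,
        )
    return fitted


def linear_predictor(model: FittedGLM, X: pd.DataFrame) -> np.ndarray:
    beta = model.coefficients.reindex(X.columns)
    if beta.isna().any():
        missing = list(beta.index[beta.isna()])
        raise ValueError(f"design has columns unknown to the model: {missing}")
    return np.asarray(X, dtype=float) @ beta.to_numpy()


def predict(model: FittedGLM, X: pd.DataFrame) -> pd.DataFrame:
    """Per-record linear predictor eta and mean mu = g^{-1}(eta).

    For the identity link mu can be non-positive; this is allowed but
    logged, since a cost mean below zero signals a poorly placed fit.
    """
    model.require_converged()
    eta = linear_predictor(model, X)
    if model.spec.link == "log":
        mu = np.exp(eta)
    elif model.spec.link == "power_half":
        mu = eta**2
    else:
        mu = eta
        n_bad = int(np.sum(mu <= 0))
        if n_bad:
            logger.warning("identity link produced %d non-positive means", n_bad)
    return pd.DataFrame({"eta": eta, "mu": mu}, index=X.index)


def information_criteria(model: FittedGLM) -> dict:
    """AIC/BIC (and per-observation versions) at the ML dispersion."""
    model.require_converged()
    if not np.isfinite(model.loglik):
        raise ValueError("log-likelihood is not finite (degenerate exact fit)")
    aic = -2 * model.loglik + 2 * model.k
    bic = -2 * model.loglik + model.k * np.log(model.n)
    return {
        "aic": aic,
        "bic": bic,
        "aic_per_obs": aic / model.n,
        "bic_per_obs": bic / model.n,
    }


def pseudo_r2_deviance(model: FittedGLM) -> float:
    """Explained pseudo-variance via deviance change: 1 - D/D_null."""
    if model.null_deviance <= 0:
        return 0.0
    return 1.0 - model.deviance / model.null_deviance
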