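"""Association models between fragmentation covariates and NO2 variation.

Four Gaussian-family, log-link additive models relate the per-station DTW
variation score Y_i to the six fragmentation covariates:

* UFB / UFD — linear fragmentation terms only, response before / during
  lockdown:  log E(Y_i) = a + b1*Ind_ED + b2*Pub_ED + b3*Ind_LSI
  + b4*Pub_LSI + b5*UF_AI + b6*UF_NP
* UFCB / UFCD — the same plus penalized-spline smooths of ten controlling
  variables (population, AQI, PM2.5, PM10, O3, CO, SO2, temperature,
  humidity, wind speed), smoothing level chosen by AIC.

"log E(Y)" with a Gaussian response is implemented literally as a log-link
Gaussian model (not a log-transformed response); a log-transform alternative
is available for sensitivity via ``log_transform_response``. Fragmentation
covariates enter untransformed, so coefficients are per-unit effects on the
log of the expected variation. 95% CIs are Wald (+-1.96 SE); R² is the
squared Pearson correlation of fitted vs observed response; deviance
explained is 1 - residual/null deviance. A VIF screen (threshold 10) checks
multicollinearity of the six covariates before fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from fragno2.landscape import FragmentationProfile

logger = logging.getLogger(__name__)

FRAG_COLUMNS = FragmentationProfile.COLUMNS
CONTROL_COLUMNS = ("pop", "aqi", "pm25", "pm10", "o3", "co", "so2", "tem", "hum", "wind")
VARIANTS = ("UFB", "UFD", "UFCB", "UFCD")

#: shared smoothing-parameter grid scanned for the AIC-optimal penalty
DEFAULT_ALPHA_GRID = tuple(10.0 ** np.arange(-1, 7))


@dataclass(frozen=True)
class ModelSpec:
    """One of the four model variants, per the design matrix check-marks."""

    variant: str

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @property
    def response(self) -> str:
        return "dtw_before" if self.variant.endswith("B") else "dtw_during"

    @property
    def smooth_terms(self) -> tuple[str, ...]:
        return CONTROL_COLUMNS if "C" in self.variant else ()

    @property
    def linear_terms(self) -> tuple[str, ...]:
        return FRAG_COLUMNS


@dataclass
class FitResult:
    """Coefficients, CIs and fit quality of one association model."""

    variant: str
    alpha: float  # intercept
    betas: pd.Series  # index: the six fragmentation covariates
    ci_lower: pd.Series
    ci_upper: pd.Series
    r_squared: float
    deviance_explained: float
    aic: float
    edf: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": self.variant,
                "covariate": self.betas.index,
                "estimate": self.betas.to_numpy(),
                "ci_lo": self.ci_lower.to_numpy(),
                "ci_hi": self.ci_upper.to_numpy(),
            }
        )


@dataclass
class VifReport:
    """Variance inflation factors of the six fragmentation covariates."""

    vif: pd.Series
    threshold: float = 10.0

    @property
    def passed(self) -> pd.Series:
        return self.vif < self.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"covariate": self.vif.index, "vif": self.vif.to_numpy(),
             "pass": self.passed.to_numpy()}
        )


def compute_vif(covariates: pd.DataFrame, threshold: float = 10.0) -> VifReport:
    """VIF_j = 1 / (1 - R²_j) from regressing covariate j on the others with
    an intercept. Perfect collinearity is reported as infinity, not raised.
    """
    cols = [c for c in covariates.columns if c != "station_id"]
    if len(cols) < 2:
        raise ValueError("need at least two covariate columns")
    x = covariates[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite for the VIF screen")
    if x.shape[0] < 8:
        raise ValueError("need at least 8 stations for a meaningful VIF screen")
    vifs = {}
    for j, name in enumerate(cols):
        yj = x[:, j]
        xj = sm.add_constant(np.delete(x, j, axis=1))
        res = sm.OLS(yj, xj).fit()
        r2 = min(res.rsquared, 1.0)
        vifs[name] = float("inf") if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    return VifReport(vif=pd.Series(vifs), threshold=threshold)


class FragmentationGAM(BaseEstimator):
    """Gaussian log-link additive model: linear fragmentation terms plus
    optional penalized-spline smooths of controlling variables.

    Parameters
    ----------
    smooth_terms
        Column names to smooth (empty tuple = plain GLM).
    alpha_grid
        Candidate shared smoothing parameters; the AIC-minimising value is
        kept.
    spline_df, spline_degree
        B-spline basis dimension and degree per smooth term.
    log_transform_response
        Fit an identity-link Gaussian model to log(y) instead of a log-link
        model to y (sensitivity alternative).

    Attributes (after ``fit``)
    --------------------------
    intercept_, coef_, se_, conf_int_ : coefficient table pieces
    r_squared_, deviance_explained_, aic_ : fit quality
    alpha_ : selected smoothing parameter (NaN without smooths)
    edf_ : effective degrees of freedom per smooth term
    """

    def __init__(
        self,
        smooth_terms: Sequence[str] = (),
        alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
        spline_df: int = 10,
        spline_degree: int = 3,
        log_transform_response: bool = False,
        ci_z: float = 1.96,
    ):
        self.smooth_terms = tuple(smooth_terms)
        self.alpha_grid = tuple(alpha_grid)
        self.spline_df = spline_df
        self.spline_degree = spline_degree
        self.log_transform_response = log_transform_response
        self.ci_z = ci_z

    def _family(self):
        link = sm.families.links.Identity() if self.log_transform_response \
            else sm.families.links.Log()
        return sm.families.Gaussian(link=link)

    def fit(self, X: pd.DataFrame, y: Sequence[float]):
        """Fit on a covariate frame holding the six fragmentation columns
        (and the smooth-term columns when requested) and a positive response.
        """
        y = np.asarray(y, dtype=float)
        missing = [c for c in FRAG_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"missing fragmentation columns: {missing}")
        if np.any(~np.isfinite(y)) or np.any(y <= 0):
            raise ValueError(
                "response must be strictly positive and finite for the log link; "
                "check the variation scores"
            )
        exog = sm.add_constant(X[list(FRAG_COLUMNS)].to_numpy(dtype=float))
        names = ["const", *FRAG_COLUMNS]
        if len(y) <= exog.shape[1]:
            raise ValueError(f"n = {len(y)} stations <= {exog.shape[1]} linear parameters")
        endog = np.log(y) if self.log_transform_response else y
        family = self._family()

        if not self.smooth_terms:
            res = self._fit_glm(endog, exog, family)
            self.alpha_ = float("nan")
            self.edf_ = {}
        else:
            # the spline basis must leave residual dof: shrink it with n and
            # degrade to linear control terms when even a minimal basis
            # (4 df per smooth) cannot be supported
            n_smooth = len(self.smooth_terms)
            df_budget = (len(y) - exog.shape[1] - 1) // n_smooth
            df_eff = min(self.spline_df, df_budget)
            if df_eff >= 4:
                res = self._fit_gam(endog, exog, X, family, df_eff)
            else:
                logger.info(
                    "n = %d cannot support spline smooths of %d controls; "
                    "controls enter linearly", len(y), n_smooth
                )
                controls = X[list(self.smooth_terms)].to_numpy(dtype=float)
                exog_lin = np.column_stack([exog, controls])
                if len(y) <= exog_lin.shape[1]:
                    raise ValueError(
                        f"n = {len(y)} stations <= {exog_lin.shape[1]} parameters even "
                        "with linear controls; more stations are needed for this variant"
                    )
                res = self._fit_glm(endog, exog_lin, family)
                self.alpha_ = float("inf")
                self.edf_ = {t: 1.0 for t in self.smooth_terms}
                self.aic_ = float(res.aic)
        self.results_ = res
        params = np.asarray(res.params, dtype=float)[: len(names)]
        ses = np.asarray(res.bse, dtype=float)[: len(names)]
        self.intercept_ = float(params[0])
        self.coef_ = pd.Series(params[1:], index=FRAG_COLUMNS)
        self.se_ = pd.Series(ses[1:], index=FRAG_COLUMNS)
        self.conf_int_ = pd.DataFrame(
            {
                "ci_lo": self.coef_ - self.ci_z * self.se_,
                "ci_hi": self.coef_ + self.ci_z * self.se_,
            }
        )
        fitted = np.asarray(res.fittedvalues, dtype=float)
        if self.log_transform_response:
            fitted = np.exp(fitted)
        corr = np.corrcoef(fitted, y)[0, 1]
        self.r_squared_ = float(corr**2)
        null_dev = self._null_deviance(endog, family)
        self.deviance_explained_ = float(1.0 - res.deviance / null_dev) if null_dev > 0 else 0.0
        if not self.smooth_terms:
            self.aic_ = float(res.aic)
        self.n_ = int(len(y))
        self.fitted_values_ = fitted
        return self

    # -- fitting backends ---------------------------------------------------

    @staticmethod
    def _start_params(endog, exog, family, n_extra: int = 0):
        """Stable IRLS start: OLS of the link-transformed response."""
        if isinstance(family.link, sm.families.links.Log):
            z = np.log(np.maximum(endog, 1e-8))
        else:
            z = endog
        beta = np.linalg.lstsq(exog, z, rcond=None)[0]
        return np.concatenate([beta, np.zeros(n_extra)])

    def _fit_glm(self, endog, exog, family):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(endog, exog, family=family)
            try:
                return model.fit()
            except Exception:  # noqa: BLE001 - retry with explicit start
                return model.fit(start_params=self._start_params(endog, exog, family))

    def _fit_gam(self, endog, exog, X, family, spline_df: int):
        from statsmodels.gam.api import BSplines, GLMGam

        missing = [c for c in self.smooth_terms if c not in X.columns]
        if missing:
            raise ValueError(f"missing smooth-term columns: {missing}")
        controls = X[list(self.smooth_terms)].to_numpy(dtype=float)
        k = len(self.smooth_terms)
        degree = min(self.spline_degree, spline_df - 1)
        smoother = BSplines(controls, df=[spline_df] * k, degree=[degree] * k)
        best = None
        start = self._start_params(endog, exog, family, n_extra=smoother.dim_basis)
        for alpha in self.alpha_grid:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    model = GLMGam(
                        endog, exog=exog, smoother=smoother, alpha=[alpha] * k, family=family
                    )
                    try:
                        res = model.fit()
                    except Exception:  # noqa: BLE001
                        res = model.fit(start_params=start)
                    aic = self._gam_aic(res, endog)
                except Exception as exc:  # noqa: BLE001
                    logger.warning("alpha %.3g failed (%s); skipped", alpha, exc)
                    continue
            if np.isfinite(aic) and (best is None or aic < best[0]):
                best = (aic, alpha, res)
        if best is None:
            raise RuntimeError("no smoothing parameter in the grid produced a finite fit")
        self.aic_, self.alpha_, res = best
        try:
            edf = np.asarray(res.edf, dtype=float)
            k0 = exog.shape[1]
            per = smoother.dim_basis // k
            self.edf_ = {
                term: float(edf[k0 + i * per: k0 + (i + 1) * per].sum())
                for i, term in enumerate(self.smooth_terms)
            }
        except Exception:  # noqa: BLE001
            self.edf_ = {}
        return res

    @staticmethod
    def _gam_aic(res, endog) -> float:
        """Gaussian AIC with penalized effective degrees of freedom.

        statsmodels' own AIC can be NaN when the effective residual dof is
        tiny (small station counts); n log(RSS/n) + 2(edf + 1) is used then.
        """
        aic = float(res.aic)
        if np.isfinite(aic):
            return aic
        n = len(endog)
        rss = float(np.sum((endog - np.asarray(res.fittedvalues)) ** 2))
        try:
            edf = float(np.asarray(res.edf).sum())
        except Exception:  # noqa: BLE001
            edf = float(len(res.params))
        return n * np.log(max(rss, 1e-12) / n) + 2.0 * (edf + 1.0)

    @staticmethod
    def _null_deviance(endog, family):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = sm.GLM(endog, np.ones((len(endog), 1)), family=family).fit()
        return float(null.deviance)


def fit_association_model(
    variation: pd.DataFrame,
    profiles: pd.DataFrame,
    controls: pd.DataFrame | None,
    spec: ModelSpec,
    **gam_kwargs,
) -> FitResult:
    """Assemble the per-station design (variation scores + fragmentation
    profiles + controls), drop incomplete stations with a log entry, and fit
    the variant's model.

    ``variation`` needs columns station_id, dtw_before, dtw_during;
    ``profiles`` station_id plus the six covariates; ``controls`` station_id
    plus the ten controlling variables (required for *C variants).
    """
    frame = variation.merge(profiles, on="station_id", how="inner")
    if spec.smooth_terms:
        if controls is None:
            raise ValueError(f"{spec.variant} requires the controlling-variable table")
        frame = frame.merge(controls, on="station_id", how="inner")
    needed = [spec.response, *FRAG_COLUMNS, *spec.smooth_terms]
    complete = frame[needed].notna().all(axis=1)
    dropped = frame.loc[~complete, "station_id"].tolist()
    if dropped:
        logger.info("%s: dropping %d incomplete stations: %s",
                    spec.variant, len(dropped), dropped)
    frame = frame.loc[complete]
    gam = FragmentationGAM(smooth_terms=spec.smooth_terms, **gam_kwargs)
    gam.fit(frame, frame[spec.response].to_numpy())
    return FitResult(
        variant=spec.variant,
        alpha=gam.intercept_,
        betas=gam.coef_,
        ci_lower=gam.conf_int_["ci_lo"],
        ci_upper=gam.conf_int_["ci_hi"],
        r_squared=gam.r_squared_,
        deviance_explained=gam.deviance_explained_,
        aic=gam.aic_,
        edf=gam.edf_,
        n=gam.n_,
    )


def mediated_impact_table(
    fit_before: FitResult, fit_during: FitResult, limited_band: float = 0.1
) -> pd.DataFrame:
    """Before-vs-during coefficient comparison.

    Per covariate: delta_abs = |beta_during| - |beta_before| (positive =
    association amplified under emission restriction), a sign-agreement flag,
    and whether the raw coefficient change stays within the limited-impact
    band |beta_during - beta_before| < ``limited_band``.
    """
    if list(fit_before.betas.index) != list(fit_during.betas.index):
        raise ValueError("fits have mismatched covariate sets")
    b, d = fit_before.betas, fit_during.betas
    return pd.DataFrame(
        {
            "covariate": b.index,
            "beta_before": b.to_numpy(),
            "beta_during": d.to_numpy(),
            "delta_abs": np.abs(d.to_numpy()) - np.abs(b.to_numpy()),
            "sign_agreement": np.sign(b.to_numpy()) == np.sign(d.to_numpy()),
            "limited_impact": np.abs(d.to_numpy() - b.to_numpy()) < limited_band,
        }
    )
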