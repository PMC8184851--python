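"""Counterfactual (business-as-usual) NO2 forecasting with seasonal ARIMA.

Each station's NO2 series is fitted with SARIMAX(p,d,q)(P,D,Q)_s models over
a grid of orders, taking air temperature, relative humidity and wind speed as
exogenous regressors, and the minimum-AIC fit forecasts the evaluation window
under the no-intervention assumption. The seasonal kernel period defaults to
7 days (the weekly traffic cycle); the annual cycle is captured by a
sin/cos Fourier pair of period 365.25 days appended to the exogenous set,
since seasonal differencing at lag 365 is numerically impractical for daily
data. Exogenous variables are never forecast: observed meteorology over the
forecast window drives the counterfactual, so only the intervention (and
model error) separates observed from predicted NO2.

The training cutoff is chosen by the mean observed-predicted error (MOPE)
across stations: each candidate cutoff is evaluated by forecasting its
held-out window, and the candidate with the lowest mean MOPE wins, ties going
to the latest cutoff (which maximises training data).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from fragno2.synthetic import StationPanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SarimaxOrder:
    """Nonseasonal (p,d,q) and seasonal (P,D,Q)_s orders."""

    p: int
    d: int
    q: int
    P: int = 0
    D: int = 0
    Q: int = 0
    s: int = 7

    def __post_init__(self) -> None:
        vals = (self.p, self.d, self.q, self.P, self.D, self.Q)
        if any(v < 0 for v in vals):
            raise ValueError("all orders must be >= 0")
        if self.s < 1:
            raise ValueError("seasonal period must be >= 1")
        if self.d + self.D > 3:
            raise ValueError("d + D must be <= 3")

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def seasonal_order(self) -> tuple[int, int, int, int]:
        return (self.P, self.D, self.Q, self.s)

    def __str__(self) -> str:
        return f"({self.p},{self.d},{self.q})({self.P},{self.D},{self.Q})_{self.s}"


def default_order_grid(seasonal_period: int = 7) -> list[SarimaxOrder]:
    """The default 24-order grid: six nonseasonal x four seasonal shapes."""
    nonseasonal = [(0, 0, 0), (1, 0, 0), (0, 0, 1), (1, 0, 1), (2, 0, 1), (1, 1, 1)]
    seasonal = [(0, 0, 0), (1, 0, 0), (0, 0, 1), (1, 0, 1)]
    return [
        SarimaxOrder(p, d, q, P, D, Q, seasonal_period)
        for (p, d, q) in nonseasonal
        for (P, D, Q) in seasonal
    ]


@dataclass
class ForecastResult:
    """Counterfactual forecast with 1-SD and 2-SD bands and diagnostics."""

    station_id: str
    forecast_dates: pd.DatetimeIndex
    no2_predicted: np.ndarray
    sd1_lower: np.ndarray
    sd1_upper: np.ndarray
    sd2_lower: np.ndarray
    sd2_upper: np.ndarray
    chosen_order: SarimaxOrder
    aic: float
    ljung_box_p: float
    jarque_bera_p: float

    def to_frame(self, observed: pd.Series | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "date": self.forecast_dates.strftime("%Y-%m-%d"),
                "no2_predicted": self.no2_predicted,
                "sd1_lo": self.sd1_lower,
                "sd1_hi": self.sd1_upper,
                "sd2_lo": self.sd2_lower,
                "sd2_hi": self.sd2_upper,
            }
        )
        if observed is not None:
            frame.insert(1, "no2_observed", observed.reindex(self.forecast_dates).to_numpy())
        return frame


@dataclass
class CutoffReport:
    """MOPE per candidate training cutoff and the selected cutoff."""

    table: pd.DataFrame  # columns: cutoff, station_id, mope
    mean_mope: pd.Series  # index: cutoff
    selected: pd.Timestamp


def mope(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean observed-predicted error in percent:
    (Σ_k |obs_k - pred_k| / obs_k) / n * 100.

    NaN pairs (unfilled observation gaps) are excluded from the mean. A zero
    observed value makes the ratio undefined and raises.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 1:
        raise ValueError("observed and predicted must be equal-length 1-D series")
    keep = ~(np.isnan(obs) | np.isnan(pred))
    if not keep.any():
        raise ValueError("no complete observed/predicted pairs")
    obs, pred = obs[keep], pred[keep]
    if np.any(obs == 0):
        raise ValueError("observed values of 0 make the relative error undefined")
    return float(np.mean(np.abs(obs - pred) / obs) * 100.0)


def adf_pvalue(series: Sequence[float]) -> float:
    """Augmented Dickey-Fuller p-value (stationarity diagnostic).

    Offered alongside the Ljung-Box and Jarque-Bera residual checks; none of
    these gate the order grid — AIC decides.
    """
    from statsmodels.tsa.stattools import adfuller

    arr = np.asarray(series, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 20:
        raise ValueError("need at least 20 observations for the ADF test")
    return float(adfuller(arr, autolag="AIC")[1])


def _fourier_terms(day_index: np.ndarray, period: float, harmonics: int = 1) -> np.ndarray:
    cols = []
    for h in range(1, harmonics + 1):
        cols.append(np.sin(2 * np.pi * h * day_index / period))
        cols.append(np.cos(2 * np.pi * h * day_index / period))
    return np.column_stack(cols)


class AllOrdersFailedError(RuntimeError):
    """Every order in the grid failed to converge for a station."""


class CounterfactualForecaster(BaseEstimator):
    """Per-station SARIMAX forecaster with AIC order selection.

    Parameters
    ----------
    order_grid
        Candidate :class:`SarimaxOrder` list; ``None`` uses the default
        24-order grid at ``seasonal_period``.
    seasonal_period
        Seasonal kernel period in days (default 7, the weekly cycle).
    fourier_annual
        Append a sin/cos pair of period ``annual_period`` to the exogenous
        regressors to capture the annual cycle.
    annual_period
        Period of the annual Fourier pair, days.
    interpolate_limit
        Observation gaps up to this many days are linearly interpolated
        before fitting; longer gaps stay missing (state-space fits handle
        missing endog; MOPE excludes them).

    Attributes (after ``fit``)
    --------------------------
    results_ : the selected statsmodels results object
    chosen_order_ : SarimaxOrder minimising AIC
    aic_ : float
    ljung_box_p_, jarque_bera_p_ : residual diagnostics (not gates)
    """

    def __init__(
        self,
        order_grid: Sequence[SarimaxOrder] | None = None,
        seasonal_period: int = 7,
        fourier_annual: bool = True,
        annual_period: float = 365.25,
        interpolate_limit: int = 3,
        maxiter: int = 200,
    ):
        self.order_grid = order_grid
        self.seasonal_period = seasonal_period
        self.fourier_annual = fourier_annual
        self.annual_period = annual_period
        self.interpolate_limit = interpolate_limit
        self.maxiter = maxiter

    # -- internal helpers ---------------------------------------------------

    def _exog(self, panel: StationPanel) -> pd.DataFrame:
        day_index = np.arange(len(panel.dates), dtype=float)
        data = {
            "temperature": panel.temperature,
            "humidity": panel.humidity,
            "wind_speed": panel.wind_speed,
        }
        frame = pd.DataFrame(data, index=panel.dates)
        if self.fourier_annual:
            four = _fourier_terms(day_index, self.annual_period)
            frame["annual_sin"] = four[:, 0]
            frame["annual_cos"] = four[:, 1]
        return frame

    def _endog(self, panel: StationPanel) -> pd.Series:
        y = pd.Series(panel.no2_observed, index=panel.dates)
        return y.interpolate(limit=self.interpolate_limit, limit_area="inside")

    # -- estimator API ------------------------------------------------------

    def fit(self, panel: StationPanel, train_end: date | str | pd.Timestamp):
        """Fit every order in the grid on history up to ``train_end``
        (exclusive) and keep the minimum-AIC convergent fit."""
        from statsmodels.tsa.statespace.sarimax import SARIMAX

        train_end = pd.Timestamp(train_end)
        grid = list(self.order_grid) if self.order_grid is not None else default_order_grid(
            self.seasonal_period
        )
        if not grid:
            raise ValueError("order grid is empty")
        y = self._endog(panel)
        X = self._exog(panel)
        train = y.index < train_end
        min_len = 2 * max(o.s for o in grid) + 30
        if train.sum() < min_len:
            raise ValueError(
                f"training window ({int(train.sum())} days) shorter than required {min_len}"
            )
        # constant exogenous columns duplicate the trend/level term; drop them
        keep_cols = [c for c in X.columns if X.loc[train, c].nunique() > 1]
        X = X[keep_cols]
        y_train, x_train = y[train], X.loc[train]
        if x_train.shape[1] == 0:
            x_train = None
            X = None

        best = None
        for order in grid:
            trend = "c" if order.d + order.D == 0 else "n"
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = SARIMAX(
                        y_train,
                        exog=x_train,
                        order=order.order,
                        seasonal_order=order.seasonal_order,
                        trend=trend,
                    )
                    res = model.fit(disp=False, maxiter=self.maxiter)
                aic = float(res.aic)
                if not np.isfinite(aic):
                    raise ValueError("non-finite AIC")
            except Exception as exc:  # noqa: BLE001 - any fit failure skips the order
                logger.warning(
                    "station %s: order %s failed (%s); skipped", panel.station_id, order, exc
                )
                continue
            if best is None or aic < best[0]:
                best = (aic, order, res)
        if best is None:
            raise AllOrdersFailedError(
                f"station {panel.station_id}: no order in the grid converged"
            )
        self.aic_, self.chosen_order_, self.results_ = best
        self._panel = panel
        self._train_end = train_end
        self._exog_full = X
        self.ljung_box_p_, self.jarque_bera_p_ = self._diagnostics(self.results_)
        return self

    @staticmethod
    def _diagnostics(res) -> tuple[float, float]:
        from scipy import stats
        from statsmodels.stats.diagnostic import acorr_ljungbox

        resid = np.asarray(res.resid, dtype=float)
        resid = resid[np.isfinite(resid)]
        try:
            lb = acorr_ljungbox(resid, lags=[min(10, max(1, resid.size // 5))])
            lb_p = float(lb["lb_pvalue"].iloc[0])
        except Exception:  # noqa: BLE001
            lb_p = float("nan")
        try:
            jb_p = float(stats.jarque_bera(resid).pvalue)
        except Exception:  # noqa: BLE001
            jb_p = float("nan")
        return lb_p, jb_p

    def predict(self, horizon_end: date | str | pd.Timestamp) -> ForecastResult:
        """Forecast [train_end, horizon_end] with 1-SD and 2-SD bands, using
        the observed exogenous series over the horizon."""
        if not hasattr(self, "results_"):
            raise RuntimeError("forecaster is not fitted")
        horizon_end = pd.Timestamp(horizon_end)
        fc_dates = pd.date_range(self._train_end, horizon_end, freq="D")
        if fc_dates.empty:
            raise ValueError("empty forecast horizon")
        if self._exog_full is None:
            x_fc = None
        else:
            missing = fc_dates.difference(self._exog_full.index)
            if len(missing):
                raise ValueError(f"exogenous series missing for {missing[0].date()}...")
            x_fc = self._exog_full.loc[fc_dates]
        fc = self.results_.get_forecast(steps=len(fc_dates), exog=x_fc)
        mean = np.asarray(fc.predicted_mean, dtype=float)
        se = np.asarray(fc.se_mean, dtype=float)
        return ForecastResult(
            station_id=str(self._panel.station_id),
            forecast_dates=fc_dates,
            no2_predicted=mean,
            sd1_lower=mean - se,
            sd1_upper=mean + se,
            sd2_lower=mean - 2 * se,
            sd2_upper=mean + 2 * se,
            chosen_order=self.chosen_order_,
            aic=self.aic_,
            ljung_box_p=self.ljung_box_p_,
            jarque_bera_p=self.jarque_bera_p_,
        )


def fit_sarimax(
    panel: StationPanel,
    train_end: date | str | pd.Timestamp,
    horizon_end: date | str | pd.Timestamp,
    order_grid: Sequence[SarimaxOrder] | None = None,
    **kwargs,
) -> ForecastResult:
    """Fit the AIC-selected SARIMAX on history before ``train_end`` and
    forecast through ``horizon_end``. Thin wrapper over
    :class:`CounterfactualForecaster`."""
    forecaster = CounterfactualForecaster(order_grid=order_grid, **kwargs)
    return forecaster.fit(panel, train_end).predict(horizon_end)


def select_training_cutoff(
    panels: Sequence[StationPanel],
    candidates: Sequence[date | str | pd.Timestamp],
    eval_end: date | str | pd.Timestamp,
    order_grid: Sequence[SarimaxOrder] | None = None,
    **kwargs,
) -> CutoffReport:
    """Evaluate each candidate training cutoff by per-station MOPE on
    [cutoff, eval_end] and select the lowest-mean-MOPE candidate, ties broken
    toward the latest cutoff.

    Stations where every order fails are dropped from that candidate's mean
    with a logged warning.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    if len(panels) == 0:
        raise ValueError("no panels")
    eval_end = pd.Timestamp(eval_end)
    cand = sorted(pd.Timestamp(c) for c in candidates)
    rows = []
    for cutoff in cand:
        for panel in panels:
            try:
                fc = fit_sarimax(panel, cutoff, eval_end, order_grid=order_grid, **kwargs)
            except AllOrdersFailedError as exc:
                logger.warning("cutoff %s: %s", cutoff.date(), exc)
                continue
            obs = pd.Series(panel.no2_observed, index=panel.dates).reindex(fc.forecast_dates)
            rows.append(
                {
                    "cutoff": cutoff,
                    "station_id": panel.station_id,
                    "mope": mope(obs.to_numpy(), fc.no2_predicted),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise AllOrdersFailedError("no station could be forecast for any candidate")
    mean_mope = table.groupby("cutoff")["mope"].mean()
    best = None
    for cutoff in cand:  # ascending: later candidates win ties
        if cutoff not in mean_mope.index:
            continue
        if best is None or mean_mope[cutoff] <= mean_mope[best] + 1e-12:
            best = cutoff
    return CutoffReport(table=table, mean_mope=mean_mope, selected=best)
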