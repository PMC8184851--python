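"""Dynamic-time-warping divergence between observed and counterfactual NO2.

The variation statistic is the minimum over admissible warping paths of
sqrt(Σ_k (t_act,i - t_con,j)²): squared pointwise differences accumulated
along the path and square-rooted once. Steps are {(1,0), (0,1), (1,1)} with
unit weights, no window constraint and no path-length normalisation, so a
longer or more divergent lockdown window yields a larger score. The statistic
is computed separately before and during the lockdown, giving the response
variable of the association models.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from fragno2.forecast import ForecastResult
    from fragno2.synthetic import StationPanel

_BRUTEFORCE_LIMIT = 36


@dataclass
class VariationResult:
    """Per-station DTW divergence split at the lockdown date."""

    station_id: str
    dtw_before: float
    dtw_during: float
    k_before: int
    k_during: int

    def as_dict(self) -> dict:
        return {
            "station_id": self.station_id,
            "dtw_before": self.dtw_before,
            "dtw_during": self.dtw_during,
        }


def _validate(series: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a nonempty 1-D series")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or infinite values")
    return arr


def dtw_distance(
    t_act: Sequence[float], t_con: Sequence[float], *, return_path: bool = False
):
    """DTW divergence between two series by O(n·m) dynamic programming.

    Returns the scalar divergence, or ``(divergence, path)`` with the optimal
    warping path as a list of 0-based index pairs when ``return_path`` is set.
    Zero iff the aligned series are identical. Symmetric in its arguments.
    """
    a = _validate(t_act, "t_act")
    b = _validate(t_con, "t_con")
    n, m = a.size, b.size
    sq = (a[:, None] - b[None, :]) ** 2
    acc = np.empty((n, m))
    acc[0, 0] = sq[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + sq[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + sq[i, 0]
        row, prev = acc[i], acc[i - 1]
        for j in range(1, m):
            row[j] = sq[i, j] + min(prev[j], row[j - 1], prev[j - 1])
    dist = float(np.sqrt(acc[n - 1, m - 1]))
    if not return_path:
        return dist
    # traceback of one optimal path
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = ((acc[i - 1, j - 1], i - 1, j - 1),
                          (acc[i - 1, j], i - 1, j),
                          (acc[i, j - 1], i, j - 1))
            _, i, j = min(candidates)
        path.append((i, j))
    path.reverse()
    return dist, path


def dtw_bruteforce(t_act: Sequence[float], t_con: Sequence[float]) -> float:
    """Exhaustive-enumeration DTW for tiny inputs (len product <= 36).

    Enumerates every admissible warping path explicitly; serves as an
    independent oracle for :func:`dtw_distance`.
    """
    a = _validate(t_act, "t_act")
    b = _validate(t_con, "t_con")
    n, m = a.size, b.size
    if n * m > _BRUTEFORCE_LIMIT:
        raise ValueError(f"bruteforce limited to len products <= {_BRUTEFORCE_LIMIT}")

    best = [np.inf]

    def walk(i: int, j: int, cost: float) -> None:
        cost += (a[i] - b[j]) ** 2
        if i == n - 1 and j == m - 1:
            if cost < best[0]:
                best[0] = cost
            return
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)

    walk(0, 0, 0.0)
    return float(np.sqrt(best[0]))


def score_variation(
    panel: "StationPanel",
    forecast: "ForecastResult",
    lockdown_date: date | str | pd.Timestamp,
) -> VariationResult:
    """DTW divergence between observed and counterfactual NO2, split into the
    windows before (< lockdown_date) and during (>= lockdown_date) lockdown.

    Observed and counterfactual sub-series are aligned on identical date
    ranges (the intersection of panel and forecast dates) before warping.
    """
    lockdown = pd.Timestamp(lockdown_date)
    obs = pd.Series(np.asarray(panel.no2_observed, dtype=float),
                    index=pd.DatetimeIndex(panel.dates))
    pred = pd.Series(np.asarray(forecast.no2_predicted, dtype=float),
                     index=pd.DatetimeIndex(forecast.forecast_dates))
    common = obs.index.intersection(pred.index)
    if common.empty:
        raise ValueError(f"station {panel.station_id}: no overlapping dates")
    obs, pred = obs.loc[common], pred.loc[common]

    results: dict[str, tuple[float, int]] = {}
    for name, sel in (("before", common < lockdown), ("during", common >= lockdown)):
        if not sel.any():
            raise ValueError(
                f"station {panel.station_id}: empty {name}-lockdown window"
            )
        dist, path = dtw_distance(obs[sel].to_numpy(), pred[sel].to_numpy(),
                                  return_path=True)
        results[name] = (dist, len(path))
    return VariationResult(
        station_id=str(panel.station_id),
        dtw_before=results["before"][0],
        dtw_during=results["during"][0],
        k_before=results["before"][1],
        k_during=results["during"][1],
    )


def variation_table(results: Sequence[VariationResult]) -> pd.DataFrame:
    """Assemble per-station variation results into the output table."""
    return pd.DataFrame([r.as_dict() for r in results])
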