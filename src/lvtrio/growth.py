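"""Logistic growth-curve fitting and growth-rate-based outcome prediction.

Fits the logistic model N(t) = K / (1 + ((K - N0)/N0) exp(-r t)) to
plate-reader OD time series (24 h, 10-min interval by convention), computes
the spent-media growth-difference metric, and applies the one-standard-
deviation growth-rate rule for predicting pairwise competition outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: Floor applied to blank-corrected OD readings.
OD_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD time series.

    ``media_id`` is either ``"fresh"`` or ``"spent:<strain>"``.
    """

    sample_id: str
    strain_id: str
    media_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if len(times) != len(od):
            raise ValueError("times and od must have equal length")
        if len(times) < 4:
            raise ValueError("need at least 4 time points")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(od)):
            raise ValueError("od values must be finite")

    def blank_corrected(self, blank: float) -> "GrowthCurve":
        """Subtract a constant blank, flooring at OD_FLOOR."""
        return GrowthCurve(
            sample_id=self.sample_id,
            strain_id=self.strain_id,
            media_id=self.media_id,
            times=self.times,
            od=np.maximum(self.od - blank, OD_FLOOR),
        )


@dataclass(frozen=True)
class LogisticFit:
    """Estimated logistic parameters for one growth curve."""

    K_fit: float
    r_fit: float
    N0_fit: float
    sse: float
    converged: bool
    max_od: float
    reason: str = ""


@dataclass(frozen=True)
class GrowthRateSummary:
    """Replicate-averaged intrinsic growth rate of one strain."""

    strain_id: str
    mean_r: float
    sd_r: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sd_r < 0:
            raise ValueError("sd_r must be non-negative")


# ---------------------------------------------------------------------------
# Logistic model and fitting
# ---------------------------------------------------------------------------

def logistic(t: np.ndarray, K: float, r: float, N0: float) -> np.ndarray:
    """Closed-form logistic growth: K / (1 + ((K - N0)/N0) exp(-r t))."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def _initial_guess(times: np.ndarray, od: np.ndarray) -> tuple[float, float, float]:
    K0 = float(np.max(od))
    positive = od[od > 0]
    N00 = float(positive[0]) if len(positive) else OD_FLOOR
    N00 = min(N00, 0.9 * K0) if K0 > 0 else OD_FLOOR
    # early-phase slope of log(od): take points below half the maximum
    mask = (od > 0) & (od < 0.5 * K0)
    if mask.sum() >= 2:
        slope = np.polyfit(times[mask], np.log(od[mask]), 1)[0]
        r0 = float(max(slope, 0.01))
    else:
        r0 = 0.5
    return K0, r0, max(N00, OD_FLOOR)


def fit_logistic(curve: GrowthCurve) -> LogisticFit:
    """Least-squares logistic fit of one growth curve.

    Returns ``converged=False`` (never raises) when the series shows no
    growth, the optimizer fails, or the fitted rate is non-positive.
    Parameters are bounded positive; a fit is valid only when
    0 < N0_fit < K_fit.
    """
    times, od = curve.times, curve.od
    max_od = float(np.max(od))
    # no-growth screen: a flat or declining series never rises meaningfully
    # above its starting density
    first = max(float(od[0]), OD_FLOOR)
    if max_od <= first * 1.05 + 1e-9:
        return LogisticFit(
            K_fit=float("nan"),
            r_fit=float("nan"),
            N0_fit=float("nan"),
            sse=float("nan"),
            converged=False,
            max_od=max_od,
            reason="no growth detected",
        )

    K0, r0, N00 = _initial_guess(times, od)

    def resid(theta: np.ndarray) -> np.ndarray:
        K, r, N0 = theta
        return logistic(times, K, r, N0) - od

    try:
        res = least_squares(
            resid,
            x0=[K0, r0, N00],
            bounds=([OD_FLOOR, 1e-6, OD_FLOOR], [np.inf, np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except Exception as exc:  # numerical failure inside the optimizer
        return LogisticFit(
            K_fit=float("nan"),
            r_fit=float("nan"),
            N0_fit=float("nan"),
            sse=float("nan"),
            converged=False,
            max_od=max_od,
            reason=f"optimizer error: {exc}",
        )
    K, r, N0 = (float(v) for v in res.x)
    sse = float(np.sum(res.fun**2))
    ok = bool(res.success) and r > 0 and 0 < N0 < K
    return LogisticFit(
        K_fit=K,
        r_fit=r,
        N0_fit=N0,
        sse=sse,
        converged=ok,
        max_od=max_od,
        reason="" if ok else "optimizer did not converge to a valid fit",
    )


def fit_plate(
    plate: pd.DataFrame, platemap: pd.DataFrame, blank: float = 0.0
) -> pd.DataFrame:
    """Fit every well of a long-form plate-reader table.

    ``plate`` has columns time_h, well, od; ``platemap`` has well,
    strain_id, media_id, replicate.  Returns one row per well with the
    fitted parameters.
    """
    rows = []
    meta = platemap.set_index("well")
    for well, grp in plate.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        info = meta.loc[well]
        curve = GrowthCurve(
            sample_id=str(well),
            strain_id=str(info["strain_id"]),
            media_id=str(info["media_id"]),
            times=grp["time_h"].to_numpy(),
            od=grp["od"].to_numpy(),
        )
        if blank:
            curve = curve.blank_corrected(blank)
        fit = fit_logistic(curve)
        rows.append(
            {
                "sample_id": curve.sample_id,
                "strain_id": curve.strain_id,
                "media_id": curve.media_id,
                "K_fit": fit.K_fit,
                "r_fit": fit.r_fit,
                "N0_fit": fit.N0_fit,
                "sse": fit.sse,
                "converged": fit.converged,
                "max_od": fit.max_od,
            }
        )
    return pd.DataFrame(rows)


def summarize_growth_rates(fits: pd.DataFrame, strain_id: str) -> GrowthRateSummary:
    """Mean and SD of r over a strain's converged replicate fits."""
    sub = fits[(fits["strain_id"] == strain_id) & fits["converged"]]
    if len(sub) < 2:
        raise ValueError(
            f"need >= 2 converged replicates for {strain_id!r}, got {len(sub)}"
        )
    r = sub["r_fit"].to_numpy()
    return GrowthRateSummary(
        strain_id=strain_id,
        mean_r=float(np.mean(r)),
        sd_r=float(np.std(r, ddof=1)),
        n_replicates=len(r),
    )


# ---------------------------------------------------------------------------
# Spent-media metric and the 1-SD prediction rule
# ---------------------------------------------------------------------------

def spent_media_difference(growth_in_spent: float, growth_in_fresh: float) -> float:
    """Relative growth difference: spent / fresh - 1.

    0 means the strain grows equally well in spent and fresh media
    (no detectable resource overlap); -1 means no growth at all in the
    spent media.  The growth metric is typically maximum OD; a rate-based
    comparison uses the same formula.
    """
    if growth_in_fresh <= 0:
        raise ValueError("growth_in_fresh must be positive")
    return growth_in_spent / growth_in_fresh - 1.0


def predict_pairwise_outcome(
    competitor: GrowthRateSummary, focal: GrowthRateSummary
) -> str:
    """Predict a pairwise competition outcome from monoculture growth rates.

    The faster strain is predicted to exclude the slower one only when its
    mean rate exceeds the other's mean by more than one standard deviation
    (the excluded strain's own SD); rates within one SD predict
    coexistence.  The boundary (difference exactly one SD) counts as
    within, hence coexist.
    """
    for summary in (competitor, focal):
        if summary.n_replicates < 2:
            raise ValueError(
                f"sd_r undefined for {summary.strain_id!r} (n_replicates < 2)"
            )
        if not (math.isfinite(summary.mean_r) and math.isfinite(summary.sd_r)):
            raise ValueError(f"non-finite growth-rate summary for {summary.strain_id!r}")
    if competitor.mean_r > focal.mean_r + focal.sd_r:
        return "competitor_excludes_focal"
    if focal.mean_r > competitor.mean_r + competitor.sd_r:
        return "focal_excludes_competitor"
    return "coexist"
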