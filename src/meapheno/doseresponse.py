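"""Cumulative concentration-response analysis: four-parameter logistic
(Hill) fits on log concentration, EC50 extraction and fold-shift ratios.

The response model is

    R(c) = R0 + (Rinf - R0) / (1 + (ec50 / c) ** h),        h > 0,

where ``R0`` is the zero-concentration asymptote and ``Rinf`` the
high-concentration asymptote (the *top* by convention). The native episode
(c = 0, response 100%) cannot sit on a log axis, so it anchors ``R0``
through an extra residual instead. Direction is carried by the asymptote
order and reported as a signed Hill slope. Fits are multi-started over a
grid of candidate log-EC50s and slopes; the best residual sum of squares
wins and the ``converged`` flag is honest (flat data never converges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

log = logging.getLogger(__name__)

__all__ = ["DoseResponseFit", "fit_hill", "fold_shift", "curve_table", "fit_parameter"]

#: fitted |T - B| below this many %-of-native points counts as flat
FLAT_SPAN_PCT = 5.0


@dataclass(frozen=True)
class DoseResponseFit:
    parameter: str
    bottom: float  # % of native, zero-concentration asymptote
    top: float  # % of native, high-concentration asymptote
    ec50: float  # molar
    hill_slope: float  # signed; negative = response decreases with c
    direction: str  # "increase" | "decrease"
    rss: float
    n_points: int
    converged: bool
    extrapolated: bool  # ec50 outside tested range x [1/10, 10]
    pooled: bool = True


def _hill(logc: np.ndarray, r0: float, rinf: float, logec50: float, h: float) -> np.ndarray:
    return r0 + (rinf - r0) / (1.0 + 10.0 ** (h * (logec50 - logc)))


def fit_hill(
    concentrations: np.ndarray,
    responses: np.ndarray,
    parameter: str = "",
    anchor: float = 100.0,
    pooled: bool = True,
) -> DoseResponseFit:
    """Fit the 4-parameter logistic to (concentration, response-%) points.

    Zero concentrations are treated as native anchors constraining the
    zero-concentration asymptote to ``anchor`` (weighted like one data point
    each). Requires >= 3 distinct nonzero concentrations and >= 4 points in
    total; degenerate (flat) data returns ``converged=False`` with a missing
    EC50; non-monotone data is fit anyway and judged by its diagnostics.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    ok = np.isfinite(conc) & np.isfinite(resp)
    conc, resp = conc[ok], resp[ok]
    nz = conc > 0
    n_anchor = int((~nz).sum())
    logc = np.log10(conc[nz])
    y = resp[nz]
    unfit = DoseResponseFit(parameter, float("nan"), float("nan"), float("nan"),
                            float("nan"), "none", float("nan"),
                            int(conc.size), False, False, pooled)
    if np.unique(conc[nz]).size < 3 or conc.size < 4:
        return unfit

    if y.max() - y.min() < FLAT_SPAN_PCT and abs(y.mean() - anchor) < FLAT_SPAN_PCT:
        return unfit

    lo, hi = logc.min(), logc.max()

    def residuals(theta: np.ndarray) -> np.ndarray:
        r0, rinf, logec50, h = theta
        res = _hill(logc, r0, rinf, logec50, h) - y
        if n_anchor:
            res = np.concatenate([res, np.full(n_anchor, r0 - anchor)])
        return res

    span = max(abs(y - anchor).max(), 10.0)
    bounds = (
        [-5 * span + anchor, -5 * span + anchor, lo - 3.0, 0.1],
        [5 * span + anchor, 5 * span + anchor, hi + 3.0, 8.0],
    )
    best = None
    rinf_guess = float(np.mean(y[logc >= np.partition(logc, -2)[-2]]))
    for logec50_0 in np.linspace(lo, hi, max(int(round(hi - lo)) + 1, 3)):
        for h0 in (0.5, 1.0, 2.0):
            theta0 = np.array([anchor, rinf_guess, logec50_0, h0])
            theta0 = np.clip(theta0, np.array(bounds[0]) + 1e-9, np.array(bounds[1]) - 1e-9)
            try:
                sol = least_squares(residuals, theta0, bounds=bounds, method="trf")
            except Exception:  # pragma: no cover - solver pathologies
                continue
            rss = float(np.sum(sol.fun**2))
            if sol.success and (best is None or rss < best[0]):
                best = (rss, sol.x)
    if best is None:
        return unfit
    rss, (r0, rinf, logec50, h) = best
    ec50 = float(10.0**logec50)
    flat = abs(rinf - r0) < FLAT_SPAN_PCT
    direction = "none" if flat else ("increase" if rinf > r0 else "decrease")
    extrapolated = not (10.0**lo / 10.0 <= ec50 <= 10.0**hi * 10.0)
    return DoseResponseFit(
        parameter=parameter,
        bottom=float(r0),
        top=float(rinf),
        ec50=float("nan") if flat else ec50,
        hill_slope=float(h if rinf > r0 else -h),
        direction=direction,
        rss=rss,
        n_points=int(conc.size),
        converged=not flat,
        extrapolated=extrapolated,
        pooled=pooled,
    )


def fit_parameter(
    matrix: pd.DataFrame,
    parameter: str,
    per_network: bool = False,
) -> DoseResponseFit | dict[str, DoseResponseFit]:
    """Fit one registry parameter's concentration-response from a parameter
    matrix.

    Default pools per-concentration network means (the published-figure-style curve);
    ``per_network=True`` instead returns one fit per network, exposing the
    dispersion of EC50 estimates.
    """
    sel = matrix[matrix["parameter_name"] == parameter][
        ["network_id", "concentration_M", "normalized_pct"]
    ].dropna()
    if per_network:
        out = {}
        for net, g in sel.groupby("network_id"):
            out[str(net)] = fit_hill(
                g["concentration_M"].to_numpy(),
                g["normalized_pct"].to_numpy(),
                parameter=parameter,
                pooled=False,
            )
        return out
    means = sel.groupby("concentration_M")["normalized_pct"].mean()
    return fit_hill(means.index.to_numpy(), means.to_numpy(), parameter=parameter)


def fit_shift_global(
    conc_alone: np.ndarray,
    resp_alone: np.ndarray,
    conc_combo: np.ndarray,
    resp_combo: np.ndarray,
    parameter: str = "",
    anchor: float = 100.0,
) -> dict:
    """Global EC50-shift fit: both curves share bottom, top and slope and
    differ only in log-EC50.

    The estimator of choice when the shifted curve is truncated by the
    tested range: a free-asymptote fit of a right-shifted curve that never
    approaches its plateau rides a (top, EC50) likelihood ridge, whereas the
    shared-parameter fit stays identifiable because the reference curve pins
    the asymptotes. Appropriate when the shift is surmountable (same maximal
    effect, altered potency). Returns both fits plus ``ratio`` =
    ec50_combo / ec50_alone.
    """
    pairs = []
    for conc, resp in ((conc_alone, resp_alone), (conc_combo, resp_combo)):
        conc = np.asarray(conc, float)
        resp = np.asarray(resp, float)
        ok = np.isfinite(conc) & np.isfinite(resp)
        pairs.append((conc[ok], resp[ok]))
    (ca, ya), (cb, yb) = pairs
    nza, nzb = ca > 0, cb > 0
    n_anchor = int((~nza).sum() + (~nzb).sum())
    logca, logcb = np.log10(ca[nza]), np.log10(cb[nzb])
    y_a, y_b = ya[nza], yb[nzb]
    lo = min(logca.min(), logcb.min())
    hi = max(logca.max(), logcb.max())
    y_all = np.concatenate([y_a, y_b])
    span = max(abs(y_all - anchor).max(), 10.0)

    def residuals(theta: np.ndarray) -> np.ndarray:
        r0, rinf, h, lec_a, lec_b = theta
        res = np.concatenate(
            [
                _hill(logca, r0, rinf, lec_a, h) - y_a,
                _hill(logcb, r0, rinf, lec_b, h) - y_b,
            ]
        )
        if n_anchor:
            res = np.concatenate([res, np.full(n_anchor, r0 - anchor)])
        return res

    bounds = (
        [anchor - 5 * span, anchor - 5 * span, 0.1, lo - 3.0, lo - 3.0],
        [anchor + 5 * span, anchor + 5 * span, 8.0, hi + 3.0, hi + 3.0],
    )
    rinf_guess = float(np.mean(np.concatenate([y_a[logca >= logca.max()],
                                               y_b[logcb >= logcb.max()]])))
    best = None
    for lec_a0 in np.linspace(logca.min(), logca.max(), 4):
        for shift0 in (0.0, 1.0, 2.0):
            theta0 = np.array([anchor, rinf_guess, 1.0, lec_a0, lec_a0 + shift0])
            theta0 = np.clip(theta0, np.array(bounds[0]) + 1e-9, np.array(bounds[1]) - 1e-9)
            try:
                sol = least_squares(residuals, theta0, bounds=bounds, method="trf")
            except Exception:  # pragma: no cover
                continue
            rss = float(np.sum(sol.fun**2))
            if sol.success and (best is None or rss < best[0]):
                best = (rss, sol.x)
    if best is None:
        return {"ratio": float("nan"), "converged": False}
    rss, (r0, rinf, h, lec_a, lec_b) = best
    flat = abs(rinf - r0) < FLAT_SPAN_PCT

    def _as_fit(lec: float, conc: np.ndarray) -> DoseResponseFit:
        ec50 = float(10.0**lec)
        lo_c, hi_c = conc[conc > 0].min(), conc.max()
        return DoseResponseFit(
            parameter=parameter, bottom=float(r0), top=float(rinf),
            ec50=float("nan") if flat else ec50,
            hill_slope=float(h if rinf > r0 else -h),
            direction="none" if flat else ("increase" if rinf > r0 else "decrease"),
            rss=rss, n_points=int(conc.size), converged=not flat,
            extrapolated=not (lo_c / 10.0 <= ec50 <= hi_c * 10.0), pooled=True,
        )

    fit_a, fit_b = _as_fit(lec_a, ca), _as_fit(lec_b, cb)
    return {
        "fit_alone": fit_a,
        "fit_combo": fit_b,
        "ratio": float("nan") if flat else float(10.0 ** (lec_b - lec_a)),
        "converged": not flat,
    }


def fold_shift(fit_alone: DoseResponseFit, fit_combo: DoseResponseFit) -> float:
    """EC50 ratio combo / alone; > 1 is a right-shift (loss of potency).
    NaN unless both fits converged."""
    if not (fit_alone.converged and fit_combo.converged):
        return float("nan")
    return fit_combo.ec50 / fit_alone.ec50


def curve_table(matrix: pd.DataFrame, curveset: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Mean +- SEM of normalized % across networks per concentration for the
    curve-set parameters (SEM is NaN at n = 1)."""
    from .parameters import CURVESET

    names = curveset or CURVESET
    sel = matrix[matrix["parameter_name"].isin(names)][
        ["parameter_name", "concentration_M", "normalized_pct"]
    ].dropna()
    g = sel.groupby(["parameter_name", "concentration_M"])["normalized_pct"]
    out = g.agg(
        mean_pct="mean",
        sem_pct=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan,
        n="count",
    ).reset_index()
    out = out.rename(columns={"parameter_name": "parameter"})
    order = {p: i for i, p in enumerate(names)}
    out["_o"] = out["parameter"].map(order)
    return out.sort_values(["_o", "concentration_M"]).drop(columns="_o").reset_index(drop=True)


def fits_table(fits: list[DoseResponseFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": f.parameter,
                "bottom": f.bottom,
                "top": f.top,
                "ec50_M": f.ec50,
                "hill": f.hill_slope,
                "direction": f.direction,
                "rss": f.rss,
                "n": f.n_points,
                "converged": f.converged,
                "extrapolated": f.extrapolated,
            }
            for f in fits
        ]
    )
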