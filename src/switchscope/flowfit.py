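"""Flow-cytometry analysis of Wor1 autoregulation.

Events are filtered by two rectangular gates (scatter; GFP vs violet
autofluorescence), fluorescence channels are normalized by forward scatter,
and the reporter response is fit per strain-day as a 4-parameter
log-logistic (Hill) function of per-cell protein level:

    log10(reporter) = c + (d - c) / (1 + exp(-h * (ln x - log_K)))

with the half-max level parameterized on the natural-log scale (log_K).
The default loss is least median of squares, resistant to the clumping and
bimodality artifacts of strong Wor1 induction; an ordinary least-squares
fit seeds the robust optimization.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ConfigError, DataError, GateSet

logger = logging.getLogger(__name__)

__all__ = [
    "GateReport", "HillFitResult", "gate_events", "normalize_events",
    "hill_log10", "fit_hill", "summarize_fits", "FitSummary",
]

REQUIRED_CHANNELS = ("FSC", "SSC", "GFP", "mCherry", "V670")


def load_events_csv(path) -> pd.DataFrame:
    """Load a per-well (or pooled) flow-event CSV with the standard channels."""
    df = pd.read_csv(path)
    missing = [ch for ch in REQUIRED_CHANNELS if ch not in df.columns]
    if missing:
        raise DataError(f"flow CSV {path} missing channels: {missing}")
    return df


# ---------------------------------------------------------------------------
# Gating and normalization
# ---------------------------------------------------------------------------

class GateReport(NamedTuple):
    n_in: int
    n_out: int
    per_well: pd.Series


def gate_events(events: pd.DataFrame, gates: Optional[GateSet] = None,
                ) -> tuple[pd.DataFrame, GateReport]:
    """Filter events through the scatter gate and the GFP/violet gate.

    An event passes iff it lies inside both rectangular gates.  Returns the
    passing events and per-well pass counts.  Emits a warning if no event
    survives.
    """
    gates = (gates or GateSet()).validate()
    if len(events) == 0:
        raise DataError("gate_events: empty event table")
    for ch in REQUIRED_CHANNELS:
        if ch not in events.columns:
            raise DataError(f"gate_events: missing channel column {ch!r}")
    inside = np.ones(len(events), dtype=bool)
    for ch, (lo, hi) in (("FSC", gates.fsc_range), ("SSC", gates.ssc_range),
                         ("GFP", gates.gfp_range), ("V670", gates.v670_range)):
        inside &= (events[ch].to_numpy() >= lo) & (events[ch].to_numpy() <= hi)
    passed = events.loc[inside].copy()
    if len(passed) == 0:
        warnings.warn("all events removed by gating")
    if "well" in events.columns:
        per_well = passed.groupby("well").size()
    else:
        per_well = pd.Series({"all": len(passed)})
    return passed, GateReport(n_in=len(events), n_out=len(passed),
                              per_well=per_well)


def normalize_events(events: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Append forward-scatter-normalized channels gfp_n and mcherry_n.

    Events with nonpositive FSC cannot be normalized; they are dropped and
    tallied.  Original channels are retained.
    """
    for ch in ("FSC", "GFP", "mCherry"):
        if ch not in events.columns:
            raise DataError(f"normalize_events: missing channel column {ch!r}")
    fsc = events["FSC"].to_numpy(dtype=float)
    good = fsc > 0
    n_dropped = int((~good).sum())
    out = events.loc[good].copy()
    out["gfp_n"] = out["GFP"].to_numpy(dtype=float) / out["FSC"].to_numpy(dtype=float)
    out["mcherry_n"] = out["mCherry"].to_numpy(dtype=float) / out["FSC"].to_numpy(dtype=float)
    return out, n_dropped


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

@dataclass
class HillFitResult:
    """4-parameter log-logistic fit of log10(response) vs ln(predictor)."""

    c: float                    # lower asymptote (log10 response units)
    d: float                    # upper asymptote
    log_K: float                # ln of the half-max predictor level
    h: float                    # Hill coefficient (> 0, activation form)
    residual_scale: float       # robust residual scale (MAD-consistent)
    n_points: int
    converged: bool
    loss: str = "lms"

    @property
    def K(self) -> float:
        return math.exp(self.log_K)


def hill_log10(x: np.ndarray, c: float, d: float, log_K: float,
               h: float) -> np.ndarray:
    """Model curve: c + (d - c) / (1 + exp(-h (ln x - log_K)))."""
    z = np.clip(h * (np.log(x) - log_K), -500, 500)
    return c + (d - c) / (1.0 + np.exp(-z))


def _ols_seed(lx: np.ndarray, y: np.ndarray) -> np.ndarray:
    c0 = float(np.percentile(y, 5))
    d0 = float(np.percentile(y, 95))
    mid = 0.5 * (c0 + d0)
    # ln-x where the response crosses its midpoint, from a coarse profile
    order = np.argsort(lx)
    lxs, ys = lx[order], y[order]
    n_bins = max(8, min(40, len(y) // 200))
    edges = np.linspace(lxs[0], lxs[-1], n_bins + 1)
    idx = np.clip(np.searchsorted(edges, lxs, side="right") - 1, 0, n_bins - 1)
    med = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() >= 5:
            med[b] = np.median(ys[sel])
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = np.isfinite(med)
    logk0 = float(centers[ok][np.argmin(np.abs(med[ok] - mid))]) if ok.any() \
        else float(np.median(lx))
    return np.array([c0, d0, logk0, 2.0])


def _ls_fit(lx: np.ndarray, y: np.ndarray, p0: np.ndarray) -> tuple[np.ndarray, bool]:
    def resid(p):
        c, d, logk, h = p
        z = np.clip(h * (lx - logk), -500, 500)
        return c + (d - c) / (1.0 + np.exp(-z)) - y

    try:
        res = optimize.least_squares(
            resid, p0, bounds=([-np.inf, -np.inf, -np.inf, 1e-3],
                               [np.inf, np.inf, np.inf, 50.0]),
            max_nfev=2000)
        return res.x, bool(res.success)
    except Exception:   # pragma: no cover - optimizer pathologies
        return p0, False


def _lms_objective(lx: np.ndarray, y: np.ndarray):
    def obj(p):
        c, d, logk, h = p
        if h <= 0:
            return np.inf
        z = np.clip(h * (lx - logk), -500, 500)
        r = c + (d - c) / (1.0 + np.exp(-z)) - y
        return float(np.median(r * r))
    return obj


def fit_hill(x: np.ndarray, y: np.ndarray,
             log10_response: bool = True,
             hormone: Optional[np.ndarray] = None,
             x_max_conc: Optional[float] = None,
             robust: str = "median",
             x_floor_quantile: float = 0.001) -> HillFitResult:
    """Fit the 4-parameter log-logistic response on pooled single cells.

    ``x`` is the per-cell predictor (FSC-normalized GFP, i.e. protein
    proxy), ``y`` the per-cell response (FSC-normalized mCherry), log10
    transformed by default.  When ``x_max_conc`` is given, cells from wells
    at ``hormone >= x_max_conc`` are excluded before fitting (used for the
    dimerizing fusion, whose reporter declines at high hormone).

    ``robust="median"`` minimizes the median of squared residuals via
    multi-start Nelder-Mead seeded from an ordinary least-squares fit;
    ``robust="ols"`` stops at the least-squares fit.  The optimizer is
    deterministic.  Returns ``converged=False`` rather than raising when
    the optimizer stalls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("x and y must have equal length")
    if robust not in ("median", "ols"):
        raise ConfigError(f"unknown robust mode: {robust!r}")
    if x_max_conc is not None:
        if hormone is None:
            raise DataError("x_max_conc given but no per-cell hormone values")
        keep = np.asarray(hormone, dtype=float) < x_max_conc
        x, y = x[keep], y[keep]
    finite = np.isfinite(x) & np.isfinite(y) & (y > 0 if log10_response else True)
    x, y = x[finite], y[finite]
    if len(x) < 50:
        raise DataError(f"fit_hill requires >= 50 points, got {len(x)}")
    pos = x[x > 0]
    if len(pos) == 0:
        raise DataError("fit_hill: no positive predictor values")
    floor = np.quantile(pos, x_floor_quantile)
    x = np.maximum(x, floor)
    lx = np.log(x)
    if np.ptp(lx) < math.log(10.0):
        raise DataError("fit_hill: predictor must span at least one decade")
    yy = np.log10(y) if log10_response else y

    p0 = _ols_seed(lx, yy)
    p_ls, ls_ok = _ls_fit(lx, yy, p0)
    if robust == "ols":
        r = hill_log10(np.exp(lx), *p_ls) - yy
        scale = 1.4826 * float(np.median(np.abs(r - np.median(r))))
        return _package(p_ls, scale, len(yy), ls_ok, "ols")

    obj = _lms_objective(lx, yy)
    starts = [p_ls, p0,
              p_ls * np.array([1.0, 1.0, 1.0, 1.5]) + np.array([0, 0, 0.3, 0]),
              p_ls * np.array([1.0, 1.0, 1.0, 0.67]) + np.array([0, 0, -0.3, 0]),
              p_ls + np.array([0.1, -0.1, 0.0, 0.0])]
    best, best_val, any_ok = None, np.inf, False
    for s in starts:
        res = optimize.minimize(obj, s, method="Nelder-Mead",
                                options=dict(maxiter=2000, xatol=1e-6,
                                             fatol=1e-10))
        if res.fun < best_val:
            best, best_val = res.x, float(res.fun)
            any_ok = any_ok or bool(res.success)
    # reweighted least squares on the LMS inliers restores efficiency while
    # keeping the high breakdown point
    scale = 1.4826 * math.sqrt(best_val) if math.isfinite(best_val) else math.nan
    converged = any_ok and math.isfinite(best_val)
    if math.isfinite(scale):
        r = hill_log10(np.exp(lx), *best) - yy
        inlier = np.abs(r) <= max(2.5 * scale, 1e-12)
        if inlier.sum() >= 50:
            refit, ok = _ls_fit(lx[inlier], yy[inlier], best)
            r_in = hill_log10(np.exp(lx[inlier]), *refit) - yy[inlier]
            scale = 1.4826 * float(np.median(np.abs(r_in - np.median(r_in))))
            best, converged = refit, converged and ok
    return _package(best, scale, len(yy), converged, "lms")


def _package(p: np.ndarray, scale: float, n: int, ok: bool,
             loss: str) -> HillFitResult:
    c, d, log_K, h = (float(v) for v in p)
    if d < c:   # enforce the activation orientation of the asymptotes
        c, d = d, c
        h = abs(h)
    return HillFitResult(c=c, d=d, log_K=log_K, h=abs(h),
                         residual_scale=float(scale), n_points=int(n),
                         converged=bool(ok), loss=loss)


# ---------------------------------------------------------------------------
# Replicate aggregation
# ---------------------------------------------------------------------------

class FitSummary(NamedTuple):
    per_construct: pd.DataFrame     # mean/sd of h and K per construct
    halfmax_ratio: float            # ratio of mean K (first / second construct)
    p_h: float                      # Welch p-value comparing h
    p_logK: float                   # Welch p-value comparing log K
    flags: tuple


def summarize_fits(fits: Sequence[tuple[str, object, HillFitResult]],
                   ratio_order: Optional[tuple[str, str]] = None) -> FitSummary:
    """Aggregate per-strain-day fits into per-construct statistics.

    ``fits`` is a sequence of (construct, day, HillFitResult).  Returns the
    mean and sd of the Hill coefficient and half-max level per construct,
    the ratio of mean half-max levels between the two constructs of
    ``ratio_order`` (default: the two constructs in input order), and Welch
    two-sample p-values comparing h and log K.  A construct with a single
    fit is flagged (sd undefined).
    """
    if len(fits) == 0:
        raise DataError("summarize_fits: no fits given")
    df = pd.DataFrame(
        [dict(construct=cstr, day=day, h=f.h, K=f.K, log_K=f.log_K)
         for cstr, day, f in fits])
    rows, flags = [], []
    for cstr, grp in df.groupby("construct", sort=False):
        if len(grp) < 2:
            flags.append(f"{cstr}: single fit, sd undefined")
        rows.append(dict(construct=cstr, n=len(grp),
                         h_mean=grp.h.mean(),
                         h_sd=grp.h.std(ddof=1) if len(grp) > 1 else math.nan,
                         K_mean=grp.K.mean(),
                         K_sd=grp.K.std(ddof=1) if len(grp) > 1 else math.nan))
    per = pd.DataFrame(rows).set_index("construct")

    constructs = list(per.index)
    ratio = math.nan
    p_h = p_logK = math.nan
    if ratio_order is None and len(constructs) >= 2:
        ratio_order = (constructs[0], constructs[1])
    if ratio_order is not None:
        a, b = ratio_order
        if a in per.index and b in per.index:
            ratio = float(per.loc[a, "K_mean"] / per.loc[b, "K_mean"])
            ga, gb = df[df.construct == a], df[df.construct == b]
            if len(ga) > 1 and len(gb) > 1:
                p_h = float(stats.ttest_ind(ga.h, gb.h, equal_var=False).pvalue)
                p_logK = float(stats.ttest_ind(ga.log_K, gb.log_K,
                                               equal_var=False).pvalue)
    return FitSummary(per_construct=per, halfmax_ratio=ratio,
                      p_h=p_h, p_logK=p_logK, flags=tuple(flags))
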