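"""Hill concentration–response model: evaluation, fitting and IC50 intervals.

The four-point summary of an MTT concentration–response experiment used
throughout this package is the three-parameter Hill (log-logistic) model

    E(A) = E_max / (1 + (10**logIC50 / A) ** h)

where ``E`` is percent inhibition of viability at concentration ``A`` (µM),
``E_max`` the maximal inhibition, ``logIC50`` the log10 of the
half-maximal concentration and ``h > 0`` the Hill slope.  Fitting is
nonlinear least squares on log10 concentration; zero-concentration wells
are used for normalization only and never enter the fit.  IC50 confidence
limits come from a nonparametric bootstrap (wells resampled within each
concentration) or, as a fallback, an asymptotic Wald interval on logIC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FitOptions",
    "HillFit",
    "NoDoseEffectError",
    "BootstrapError",
    "hill_response",
    "fit_hill",
    "fit_hill_global",
    "ic50_confidence",
    "ic50_confidence_fixed_shape",
    "fold_potency_change",
]


class NoDoseEffectError(ValueError):
    """Responses show no dose effect; the Hill model is unidentifiable."""


class BootstrapError(RuntimeError):
    """Too many bootstrap refits failed to trust the percentile interval."""


@dataclass
class FitOptions:
    """Options controlling the Hill fit and its confidence limits.

    ``n_boot = 0`` switches the confidence-limit method from the default
    percentile bootstrap to the asymptotic Wald interval on logIC50.
    ``bounds`` maps parameter names (``emax``, ``log_ic50``, ``hill_slope``)
    to (lo, hi) pairs; unspecified parameters keep their defaults
    (E_max ≤ 120% so that plate noise nominally exceeding full inhibition
    stays representable; slope in [0.05, 10]).
    """

    fix_emax_at: float | None = None
    loss: str = "least_squares"  # or "robust_soft_l1"
    n_boot: int = 1000
    seed: int = 0
    max_iter: int = 5000
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def cl_method(self) -> str:
        return "bootstrap" if self.n_boot > 0 else "asymptotic"

    def scipy_loss(self) -> str:
        if self.loss == "least_squares":
            return "linear"
        if self.loss == "robust_soft_l1":
            return "soft_l1"
        raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class HillFit:
    """Fitted Hill parameters with IC50 confidence limits and diagnostics."""

    emax: float
    log_ic50: float
    hill_slope: float
    ic50_cl: tuple[float, float]
    n_points: int
    rss: float
    converged: bool
    cl_method: str = "bootstrap"

    @property
    def ic50(self) -> float:
        """Half-maximal inhibitory concentration, µM (= 10**log_ic50)."""
        return 10.0 ** self.log_ic50

    @classmethod
    def from_ic50(
        cls,
        ic50: float,
        emax: float = 100.0,
        hill_slope: float = 1.0,
        ic50_cl: tuple[float, float] | None = None,
    ) -> "HillFit":
        """Wrap a known IC50 (e.g. a published table value) as a converged fit."""
        if ic50 <= 0:
            raise ValueError("ic50 must be positive")
        return cls(
            emax=emax,
            log_ic50=math.log10(ic50),
            hill_slope=hill_slope,
            ic50_cl=ic50_cl if ic50_cl is not None else (ic50, ic50),
            n_points=0,
            rss=0.0,
            converged=True,
            cl_method="asymptotic",
        )

    def predict(self, conc) -> np.ndarray:
        return hill_response(conc, self.emax, self.log_ic50, self.hill_slope)


def hill_response(conc, emax: float, log_ic50: float, hill_slope: float):
    """Percent inhibition at concentration ``conc`` (µM) under the Hill model.

    Evaluates ``E_max / (1 + (10**log_ic50 / A) ** h)`` elementwise; the
    removable singularity at ``A = 0`` is taken as the limit 0.  Negative
    concentrations and non-positive slopes are rejected.
    """
    if hill_slope <= 0:
        raise ValueError("hill_slope must be positive for inhibitory responses")
    a = np.asarray(conc, dtype=float)
    if np.any(a < 0):
        raise ValueError("concentrations must be non-negative")
    out = np.zeros_like(a)
    nz = a > 0
    # evaluated in log space to avoid overflow at extreme conc/IC50 ratios
    with np.errstate(over="ignore"):
        out[nz] = emax / (1.0 + 10.0 ** (hill_slope * (log_ic50 - np.log10(a[nz]))))
    return out if out.ndim else float(out)


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1]
    if isinstance(data, tuple) and len(data) == 2:
        return np.asarray(data[0], float), np.asarray(data[1], float)
    raise ValueError("data must be (conc, inhibition) pairs or a (conc, inhibition) tuple")


def _param_bounds(options: FitOptions, logc: np.ndarray) -> dict[str, tuple[float, float]]:
    bounds = {
        "emax": (1e-6, 120.0),
        "log_ic50": (logc.min() - 2.0, logc.max() + 2.0),
        "hill_slope": (0.05, 10.0),
    }
    bounds.update(options.bounds)
    return bounds


def _initial_guess(logc: np.ndarray, resp: np.ndarray, bounds) -> np.ndarray:
    emax0 = float(np.clip(np.max(resp) * 1.05, *bounds["emax"]))
    half = emax0 / 2.0
    order = np.argsort(logc)
    lc, r = logc[order], resp[order]
    above = np.nonzero(r >= half)[0]
    log_ic50_0 = lc[above[0]] if len(above) else float(np.median(lc))
    log_ic50_0 = float(np.clip(log_ic50_0, *bounds["log_ic50"]))
    return np.array([emax0, log_ic50_0, 1.0])


def _fit_core(logc: np.ndarray, resp: np.ndarray, options: FitOptions, p0=None):
    """Least-squares Hill fit on log10 concentration; returns (params, rss, ok)."""
    bounds = _param_bounds(options, logc)
    fixed_emax = options.fix_emax_at

    if fixed_emax is None:
        def residuals(p):
            emax, l50, slope = p
            return emax / (1.0 + 10.0 ** (slope * (l50 - logc))) - resp

        full_p0 = _initial_guess(logc, resp, bounds) if p0 is None else np.asarray(p0)
        lo = [bounds["emax"][0], bounds["log_ic50"][0], bounds["hill_slope"][0]]
        hi = [bounds["emax"][1], bounds["log_ic50"][1], bounds["hill_slope"][1]]
        free_p0 = np.clip(full_p0, lo, hi)
    else:
        def residuals(p):
            l50, slope = p
            return fixed_emax / (1.0 + 10.0 ** (slope * (l50 - logc))) - resp

        guess = _initial_guess(logc, resp, bounds) if p0 is None else np.asarray(p0)
        lo = [bounds["log_ic50"][0], bounds["hill_slope"][0]]
        hi = [bounds["log_ic50"][1], bounds["hill_slope"][1]]
        free_p0 = np.clip(guess[-2:], lo, hi)

    res = least_squares(
        residuals,
        free_p0,
        bounds=(lo, hi),
        loss=options.scipy_loss(),
        max_nfev=options.max_iter,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if fixed_emax is None:
        params = res.x
    else:
        params = np.concatenate([[fixed_emax], res.x])
    rss = float(np.sum(res.fun ** 2))
    ok = bool(res.success and np.all(np.isfinite(params)))
    return params, rss, ok, res


def fit_hill(data, options: FitOptions | None = None, compute_cl: bool = True) -> HillFit:
    """Fit the Hill model to well-level (concentration, % inhibition) points.

    Requires at least four distinct non-zero concentrations; conc = 0 wells
    are silently dropped (they belong to normalization, and the model is
    undefined at zero).  All-zero responses raise :class:`NoDoseEffectError`
    rather than returning an unidentifiable fit.  Non-convergence is
    reported through ``converged = False``, never silently.
    """
    options = options or FitOptions()
    conc, resp = _as_xy(data)
    if not np.all(np.isfinite(resp)):
        raise ValueError("responses must be finite")
    mask = conc > 0
    conc, resp = conc[mask], resp[mask]
    if len(np.unique(conc)) < 4:
        raise ValueError("need >= 4 distinct non-zero concentrations to fit")
    if np.max(resp) <= 1e-9:
        raise NoDoseEffectError("no dose effect: responses never rise above zero")

    logc = np.log10(conc)
    params, rss, ok, res = _fit_core(logc, resp, options)
    fit = HillFit(
        emax=float(params[0]),
        log_ic50=float(params[1]),
        hill_slope=float(params[2]),
        ic50_cl=(float("nan"), float("nan")),
        n_points=len(resp),
        rss=rss,
        converged=ok,
        cl_method=options.cl_method,
    )
    if not ok:
        return fit
    if compute_cl:
        fit.ic50_cl = ic50_confidence((conc, resp), fit, options)
    else:
        fit.ic50_cl = (fit.ic50, fit.ic50)
    return fit


def fit_hill_global(datasets, options: FitOptions | None = None) -> list[HillFit]:
    """Global Hill fit: one E_max and slope shared across several datasets.

    ``datasets`` is a sequence of (conc, inhibition) point sets — typically
    the same compound measured under different exposure schedules or
    modulator levels, where the curve shape is common and only the potency
    (logIC50) shifts.  Sharing the shape parameters pools their estimation
    across all points, which stabilizes IC50s of conditions whose curves
    are only partially sampled (e.g. a weakly potent compound whose IC50
    sits near the top of the tested range).  Returns one :class:`HillFit`
    per dataset carrying the shared E_max/slope, its own logIC50, its own
    RSS, and the global convergence flag; confidence limits are left to
    :func:`ic50_confidence_fixed_shape`.
    """
    options = options or FitOptions()
    if not datasets:
        raise ValueError("need at least one dataset")
    prepared = []
    for data in datasets:
        conc, resp = _as_xy(data)
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        mask = conc > 0
        conc, resp = conc[mask], resp[mask]
        if len(np.unique(conc)) < 4:
            raise ValueError("need >= 4 distinct non-zero concentrations per dataset")
        if np.max(resp) <= 1e-9:
            raise NoDoseEffectError("no dose effect in one dataset")
        prepared.append((np.log10(conc), resp))

    # individual prefits seed the shared shape and per-dataset potency
    prefits = []
    for logc, resp in prepared:
        try:
            params, _, ok, _ = _fit_core(logc, resp, options)
        except Exception:
            params, ok = None, False
        prefits.append(params if ok else None)
    all_logc = np.concatenate([lc for lc, _ in prepared])
    bounds = _param_bounds(options, all_logc)
    good = [p for p in prefits if p is not None]
    emax0 = float(np.median([p[0] for p in good])) if good else 90.0
    slope0 = float(np.median([p[2] for p in good])) if good else 1.0
    l50_0 = [
        p[1] if p is not None else float(np.median(lc))
        for p, (lc, _) in zip(prefits, prepared)
    ]

    k = len(prepared)
    fixed_emax = options.fix_emax_at

    def residuals(p):
        if fixed_emax is None:
            emax, slope = p[0], p[1]
            l50s = p[2:]
        else:
            emax, slope = fixed_emax, p[0]
            l50s = p[1:]
        return np.concatenate(
            [
                emax / (1.0 + 10.0 ** (slope * (l50s[i] - lc))) - r
                for i, (lc, r) in enumerate(prepared)
            ]
        )

    l50_lo = [max(lc.min() - 2.0, bounds["log_ic50"][0]) for lc, _ in prepared]
    l50_hi = [min(lc.max() + 2.0, bounds["log_ic50"][1]) for lc, _ in prepared]
    if fixed_emax is None:
        p0 = np.array([np.clip(emax0, *bounds["emax"]), np.clip(slope0, *bounds["hill_slope"]), *np.clip(l50_0, l50_lo, l50_hi)])
        lo = [bounds["emax"][0], bounds["hill_slope"][0], *l50_lo]
        hi = [bounds["emax"][1], bounds["hill_slope"][1], *l50_hi]
    else:
        p0 = np.array([np.clip(slope0, *bounds["hill_slope"]), *np.clip(l50_0, l50_lo, l50_hi)])
        lo = [bounds["hill_slope"][0], *l50_lo]
        hi = [bounds["hill_slope"][1], *l50_hi]

    res = least_squares(
        residuals,
        p0,
        bounds=(lo, hi),
        loss=options.scipy_loss(),
        max_nfev=options.max_iter,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if fixed_emax is None:
        emax, slope, l50s = float(res.x[0]), float(res.x[1]), res.x[2:]
    else:
        emax, slope, l50s = float(fixed_emax), float(res.x[0]), res.x[1:]
    ok = bool(res.success and np.all(np.isfinite(res.x)))

    fits = []
    for (lc, r), l50 in zip(prepared, l50s):
        pred = emax / (1.0 + 10.0 ** (slope * (l50 - lc)))
        fit = HillFit(
            emax=emax,
            log_ic50=float(l50),
            hill_slope=slope,
            ic50_cl=(float("nan"), float("nan")),
            n_points=len(r),
            rss=float(np.sum((pred - r) ** 2)),
            converged=ok,
            cl_method=options.cl_method,
        )
        fit.ic50_cl = (fit.ic50, fit.ic50)
        fits.append(fit)
    return fits


def _fit_l50_only(logc, resp, emax, slope, l50_0, lo, hi):
    res = least_squares(
        lambda p: emax / (1.0 + 10.0 ** (slope * (p[0] - logc))) - resp,
        np.array([np.clip(l50_0, lo, hi)]),
        bounds=([lo], [hi]),
        xtol=1e-12,
        ftol=1e-12,
    )
    return float(res.x[0]), bool(res.success)


def ic50_confidence_fixed_shape(
    data, fit: HillFit, options: FitOptions | None = None
) -> tuple[float, float]:
    """Bootstrap 95% CL on IC50 holding the shared curve shape fixed.

    Companion to :func:`fit_hill_global`: wells are resampled within each
    concentration and only logIC50 is refit at the fitted E_max/slope.
    ``n_boot = 0`` falls back to the one-parameter asymptotic interval.
    """
    options = options or FitOptions()
    conc, resp = _as_xy(data)
    mask = conc > 0
    conc, resp = conc[mask], resp[mask]
    logc = np.log10(conc)
    lo_b, hi_b = logc.min() - 2.0, logc.max() + 2.0

    if options.n_boot <= 0:
        # 1-parameter Wald interval from the slope of the residual surface
        eps = 1e-5
        def pred(l50):
            return fit.emax / (1.0 + 10.0 ** (fit.hill_slope * (l50 - logc)))
        g = (pred(fit.log_ic50 + eps) - pred(fit.log_ic50 - eps)) / (2 * eps)
        dof = max(len(resp) - 1, 1)
        s2 = float(np.sum((pred(fit.log_ic50) - resp) ** 2)) / dof
        denom = float(g @ g)
        se = math.sqrt(s2 / denom) if denom > 0 else float("inf")
        return (10.0 ** (fit.log_ic50 - 1.96 * se), 10.0 ** (fit.log_ic50 + 1.96 * se))

    rng = np.random.default_rng(options.seed)
    groups = [np.nonzero(conc == c)[0] for c in np.unique(conc)]
    ic50s = []
    failures = 0
    for _ in range(options.n_boot):
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in groups])
        try:
            l50, ok = _fit_l50_only(
                logc[idx], resp[idx], fit.emax, fit.hill_slope, fit.log_ic50, lo_b, hi_b
            )
        except Exception:
            ok = False
        if ok:
            ic50s.append(10.0 ** l50)
        else:
            failures += 1
    frac = failures / options.n_boot
    if frac > 0.20:
        raise BootstrapError(f"{frac:.0%} of bootstrap refits failed (> 20%)")
    lo, hi = np.percentile(ic50s, [2.5, 97.5])
    return (min(float(lo), fit.ic50), max(float(hi), fit.ic50))


def _asymptotic_cl(res, fixed_emax: bool, n: int) -> tuple[float, float]:
    """Wald interval on logIC50 from the least-squares Jacobian, back-transformed."""
    J = res.jac
    p = J.shape[1]
    dof = max(n - p, 1)
    s2 = float(np.sum(res.fun ** 2)) / dof
    cov = s2 * np.linalg.pinv(J.T @ J)
    i = 0 if fixed_emax else 1  # position of log_ic50 among free params
    se = math.sqrt(max(cov[i, i], 0.0))
    l50 = res.x[i]
    return (10.0 ** (l50 - 1.96 * se), 10.0 ** (l50 + 1.96 * se))


def ic50_confidence(data, fit: HillFit, options: FitOptions | None = None) -> tuple[float, float]:
    """95% confidence limits on the fitted IC50 (µM).

    With ``options.n_boot > 0``: nonparametric bootstrap — wells are
    resampled with replacement within each concentration (preserving the
    design), the model is refit, and the 2.5/97.5 percentiles of the
    replicate IC50s are taken.  More than 20% failed refits aborts with
    the failure fraction.  With ``n_boot = 0``: asymptotic Wald interval.
    The interval always brackets the point estimate.
    """
    options = options or FitOptions()
    if not fit.converged:
        raise ValueError("cannot compute confidence limits for a non-converged fit")
    conc, resp = _as_xy(data)
    mask = conc > 0
    conc, resp = conc[mask], resp[mask]
    logc = np.log10(conc)
    p0 = np.array([fit.emax, fit.log_ic50, fit.hill_slope])

    if options.n_boot <= 0:
        _, _, _, res = _fit_core(logc, resp, options, p0=p0)
        lo, hi = _asymptotic_cl(res, options.fix_emax_at is not None, len(resp))
        return (min(lo, fit.ic50), max(hi, fit.ic50))

    rng = np.random.default_rng(options.seed)
    groups = [np.nonzero(conc == c)[0] for c in np.unique(conc)]
    ic50s = []
    failures = 0
    for _ in range(options.n_boot):
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in groups])
        try:
            params, _, ok, _ = _fit_core(logc[idx], resp[idx], options, p0=p0)
        except Exception:
            ok = False
        if ok:
            ic50s.append(10.0 ** params[1])
        else:
            failures += 1
    frac = failures / options.n_boot
    if frac > 0.20:
        raise BootstrapError(f"{frac:.0%} of bootstrap refits failed (> 20%)")
    lo, hi = np.percentile(ic50s, [2.5, 97.5])
    return (min(float(lo), fit.ic50), max(float(hi), fit.ic50))


def fold_potency_change(fit_ref: HillFit, fit_alt: HillFit) -> float:
    """Fold change in potency between two fits: IC50(ref) / IC50(alt).

    Values above 1 mean the alternative condition (e.g. longer exposure)
    made the drug more potent.
    """
    if not (fit_ref.converged and fit_alt.converged):
        raise ValueError("both fits must have converged")
    if fit_ref.ic50 <= 0 or fit_alt.ic50 <= 0:
        raise ValueError("IC50 values must be positive")
    return fit_ref.ic50 / fit_alt.ic50
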