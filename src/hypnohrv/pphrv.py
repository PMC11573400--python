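"""History-dependent inverse-Gaussian (HDIG) point-process HRV model.

The waiting time from the last R peak u_k to the next beat is modelled as
inverse Gaussian with shape theta_{p+1} and mean

    mu(H_{u_k}, theta) = theta_0 + sum_{j=1..p} theta_j * RR_{k-j},

an order-p autoregression on the preceding RR intervals (p = 9 by
default).  The time-varying parameter vector theta(t) is tracked on a
fine grid (0.05 s production resolution) by local maximum likelihood: at
each grid time the exponentially forgetting-weighted log-likelihood of
the intervals ending inside a trailing window is maximized by Newton's
method, warm-started from the previous step, including the
right-censoring (survivor) term of the interval still open at t.  The
fit pauses over masked irregular segments and resumes shortly after.

From the fitted parameters one obtains instantaneous moments
(mu, sigma^2 = mu^3/shape), the beat-domain AR spectrum mapped to Hz by
the instantaneous mean RR, the VLF/LF/HF band powers with their
normalized variants, and a time-rescaling Kolmogorov-Smirnov
goodness-of-fit statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr
from scipy.integrate import cumulative_trapezoid

from .ecg import BeatSeries, LABEL_NORMAL

LOG_2PI = math.log(2.0 * math.pi)

#: Spectral band edges in Hz.
VLF_BAND = (0.01, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

DEFAULT_ORDER = 9
DEFAULT_DELTA = 0.05
DEFAULT_WINDOW_S = 90.0
DEFAULT_FORGETTING = 0.98  # weight decay per second
DEFAULT_RESUME_S = 5.0


class FitError(RuntimeError):
    """Local-likelihood fit failed globally (too many flagged steps)."""


class SpectrumError(ValueError):
    """AR polynomial unstable at a step: spectrum undefined."""


@dataclass(frozen=True)
class HDIGParams:
    """theta = (theta_0 .. theta_p) plus the inverse-Gaussian shape."""

    theta: np.ndarray
    shape: float

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", th)
        if self.shape <= 0:
            raise ValueError(f"IG shape must be positive, got {self.shape}")

    @property
    def order(self) -> int:
        return self.theta.size - 1


# ---------------------------------------------------------------------------
# Inverse-Gaussian primitives

def _ig_logpdf(w, mu, lam):
    w = np.asarray(w, dtype=float)
    return (0.5 * (np.log(lam) - LOG_2PI - 3.0 * np.log(w))
            - lam * (w - mu) ** 2 / (2.0 * mu ** 2 * w))


def ig_density(t: float, u_k: float, mu: float, shape: float) -> float:
    """Inverse-Gaussian density of the waiting time t - u_k (1/seconds)."""
    if t <= u_k:
        raise ValueError("t must exceed the last event time u_k")
    if mu <= 0 or shape <= 0:
        raise ValueError("mu and shape must be positive")
    return float(np.exp(_ig_logpdf(t - u_k, mu, shape)))


def _ig_logsf(w, mu, lam):
    """log survivor of the IG: log(1 - CDF(w; mu, lam)), numerically stable."""
    w = np.asarray(w, dtype=float)
    s = np.sqrt(lam / w)
    a = s * (w / mu - 1.0)
    b = -s * (w / mu + 1.0)
    la = log_ndtr(-a)
    lb = 2.0 * lam / mu + log_ndtr(b)  # exponent is always <= la
    diff = lb - la
    diff = np.minimum(diff, -1e-300)
    return la + np.log1p(-np.exp(diff))


def _ig_logsf_grad(w: float, mu: float, lam: float) -> tuple[float, float]:
    """Analytic (d/dmu, d/dlam) of the IG log-survivor at w."""
    s = math.sqrt(lam / w)
    a = s * (w / mu - 1.0)
    b = -s * (w / mu + 1.0)
    c = 2.0 * lam / mu
    # S and the exp(c)*Phi(b), exp(c)*phi(b) products computed in log space
    t2 = math.exp(min(c + float(log_ndtr(b)), 700.0))
    S = float(ndtr(-a)) - t2
    S = max(S, 1e-300)
    pdf_a = math.exp(-0.5 * a * a) / math.sqrt(2 * math.pi)
    epb = math.exp(c - 0.5 * b * b) / math.sqrt(2 * math.pi)  # exp(c)*phi(b)
    da_dmu = -s * w / mu ** 2
    db_dmu = s * w / mu ** 2
    dc_dmu = -2.0 * lam / mu ** 2
    dS_dmu = -pdf_a * da_dmu - (t2 * dc_dmu + epb * db_dmu)
    da_dl = a / (2.0 * lam)
    db_dl = b / (2.0 * lam)
    dc_dl = 2.0 / mu
    dS_dl = -pdf_a * da_dl - (t2 * dc_dl + epb * db_dl)
    return dS_dmu / S, dS_dl / S


def conditional_mean(history, theta) -> float:
    """mu = theta_0 + sum_j theta_j * RR_{k-j}; history is most-recent-first.

    Raises when the regression yields a non-positive mean (the caller
    flags the step invalid / schedules a re-fit).
    """
    history = np.asarray(history, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if history.size != theta.size - 1:
        raise ValueError(
            f"history must hold exactly p={theta.size - 1} intervals, "
            f"got {history.size}")
    if np.any(history <= 0):
        raise ValueError("RR history must be positive")
    mu = float(theta[0] + theta[1:] @ history)
    if mu <= 0:
        raise ValueError(f"non-positive conditional mean {mu:.4f}")
    return mu


# ---------------------------------------------------------------------------
# Design matrix and window bookkeeping

def _design(times: np.ndarray, p: int):
    """Interval design for an event series.

    Row k describes the fully observed interval ending at ``ends[k]``:
    regressors ``X[k] = [1, RR_{-1}, ..., RR_{-p}]`` (most recent first),
    target ``w[k]`` the interval length.
    """
    rr = np.diff(times)
    n = rr.size - p
    if n <= 0:
        raise ValueError(f"need more than p+1={p + 1} beats")
    hist = np.lib.stride_tricks.sliding_window_view(rr[:-1], p)[:, ::-1]
    X = np.column_stack([np.ones(n), hist])
    return X, rr[p:], times[p + 1:]


def _interval_weights(times: np.ndarray, labels: np.ndarray,
                      mask: tuple[tuple[float, float], ...], p: int) -> np.ndarray:
    """Base weight per design row: 0 when the interval touches a mask/label."""
    n_int = times.size - 1
    ok = np.ones(n_int, dtype=bool)
    bad_beat = labels != LABEL_NORMAL
    ok &= ~(bad_beat[:-1] | bad_beat[1:])
    for a, b in mask:
        ok &= ~((times[:-1] < b) & (times[1:] > a))
    return ok[p:].astype(float)


def local_loglik(
    params: HDIGParams,
    beats: BeatSeries,
    t_now: float,
    window_s: float = DEFAULT_WINDOW_S,
    forgetting: float = DEFAULT_FORGETTING,
) -> float:
    """Forgetting-weighted local log-likelihood at time ``t_now``.

    Sums the weighted IG log-density of every fully observed interval
    ending inside ``(t_now - window_s, t_now]`` plus the weighted
    log-survivor of the interval still open at ``t_now`` (zero when
    ``t_now`` coincides with the last beat).  Masked intervals carry zero
    weight.  Raises when fewer than p+1 beats precede ``t_now``.
    """
    p = params.order
    times = beats.times
    if np.searchsorted(times, t_now, side="right") < p + 1:
        raise ValueError("warm-up: insufficient history before t_now")
    X, w, ends = _design(times, p)
    base = _interval_weights(times, beats.labels, beats.mask, p)
    sel = (ends > t_now - window_s) & (ends <= t_now)
    wt = base[sel] * forgetting ** (t_now - ends[sel])
    mu = X[sel] @ params.theta
    if np.any(mu <= 0):
        return -np.inf
    ll = float(np.sum(wt * _ig_logpdf(w[sel], mu, params.shape)))
    j = int(np.searchsorted(times, t_now, side="right")) - 1
    tau = t_now - times[j]
    if tau > 0 and j >= p + 1:
        hist = np.diff(times)[j - p:j][::-1]
        mu_c = float(params.theta[0] + params.theta[1:] @ hist)
        if mu_c <= 0:
            return -np.inf
        if beats.labels[j] == LABEL_NORMAL and not beats.in_mask(t_now):
            ll += float(_ig_logsf(tau, mu_c, params.shape))
    return ll


# ---------------------------------------------------------------------------
# Local maximum-likelihood fit

@dataclass
class HDIGFit:
    """Parameter trajectories from :func:`fit_hdig` plus diagnostics."""

    t: np.ndarray
    theta: np.ndarray          # (n_steps, p+1)
    shape: np.ndarray          # (n_steps,)
    mu: np.ndarray             # (n_steps,) conditional mean at t (s)
    sigma2: np.ndarray         # (n_steps,) mu^3/shape (s^2)
    valid: np.ndarray          # (n_steps,) bool
    converged: np.ndarray      # (n_steps,) bool
    order: int
    delta: float
    window_s: float
    forgetting: float
    settings: dict = field(default_factory=dict)

    def params_at(self, t: float) -> HDIGParams:
        """Parameters of the last grid step at or before ``t``."""
        i = int(np.searchsorted(self.t, t, side="right")) - 1
        i = max(i, 0)
        return HDIGParams(theta=self.theta[i], shape=float(self.shape[i]))

    @property
    def n_flagged(self) -> int:
        return int((~self.converged).sum())


def _newton_step(theta, lam, X, w, wt, cx, tau, cwt):
    """One local-likelihood objective/gradient/Hessian evaluation.

    Returns (loglik, grad, hess) over params beta = [theta, lam].
    ``cx``/``tau``/``cwt`` describe the censoring term (cwt 0 disables it).
    """
    q = theta.size
    mu = X @ theta
    if np.any(mu <= 0) or lam <= 0:
        return -np.inf, None, None
    ll = float(np.sum(wt * _ig_logpdf(w, mu, lam)))
    resid = w - mu
    inv3 = mu ** -3
    g_theta = X.T @ (wt * lam * resid * inv3)
    gsq = resid ** 2 / (w * mu ** 2)
    g_lam = float(np.sum(wt * (0.5 / lam - 0.5 * gsq)))
    col = wt * lam * (3.0 * w - 2.0 * mu) * mu ** -4
    H_tt = -(X * col[:, None]).T @ X
    H_tl = X.T @ (wt * resid * inv3)
    H_ll = float(np.sum(-0.5 * wt / lam ** 2))

    if cwt > 0.0:
        mu_c = float(cx @ theta)
        if mu_c <= 0:
            return -np.inf, None, None
        ll += cwt * float(_ig_logsf(tau, mu_c, lam))
        dmu, dlam = _ig_logsf_grad(tau, mu_c, lam)
        g_theta += cwt * dmu * cx
        g_lam += cwt * dlam
        # Hessian block: central difference of the analytic gradient
        hm = 1e-5 * mu_c
        hl = 1e-5 * lam
        dmu_p, dlam_p = _ig_logsf_grad(tau, mu_c + hm, lam)
        dmu_m, dlam_m = _ig_logsf_grad(tau, mu_c - hm, lam)
        l_mm = (dmu_p - dmu_m) / (2 * hm)
        l_ml = (dlam_p - dlam_m) / (2 * hm)
        _, dlam_p2 = _ig_logsf_grad(tau, mu_c, lam + hl)
        _, dlam_m2 = _ig_logsf_grad(tau, mu_c, lam - hl)
        l_ll = (dlam_p2 - dlam_m2) / (2 * hl)
        H_tt += cwt * l_mm * np.outer(cx, cx)
        H_tl += cwt * l_ml * cx
        H_ll += cwt * l_ll

    grad = np.empty(q + 1)
    grad[:q] = g_theta
    grad[q] = g_lam
    hess = np.empty((q + 1, q + 1))
    hess[:q, :q] = H_tt
    hess[:q, q] = H_tl
    hess[q, :q] = H_tl
    hess[q, q] = H_ll
    return ll, grad, hess


def _maximize(theta0, lam0, X, w, wt, cx, tau, cwt, tol, max_iter):
    """Damped Newton with backtracking; returns (theta, lam, converged)."""
    theta = theta0.copy()
    lam = lam0
    ll, grad, hess = _newton_step(theta, lam, X, w, wt, cx, tau, cwt)
    if not np.isfinite(ll):
        return theta0, lam0, False
    q = theta.size
    for _ in range(max_iter):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol:
            return theta, lam, True
        damp = 0.0
        step = None
        for _ in range(8):
            try:
                step = np.linalg.solve(hess - damp * np.eye(q + 1), -grad)
            except np.linalg.LinAlgError:
                step = None
            if step is not None and float(step @ grad) > 0:
                break
            damp = 10.0 * damp if damp else 1e-6 * max(1.0, abs(hess[q, q]))
            step = None
        if step is None:
            return theta, lam, False
        scale = 1.0
        for _ in range(30):
            th_new = theta + scale * step[:q]
            lam_new = lam + scale * step[q]
            ll_new, g_new, h_new = _newton_step(
                th_new, lam_new, X, w, wt, cx, tau, cwt)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            return theta, lam, False
        if abs(ll_new - ll) < 1e-14 * max(1.0, abs(ll)) and scale < 1.0:
            return theta, lam, float(np.linalg.norm(grad)) < 1e2 * tol
        theta, lam, ll, grad, hess = th_new, lam_new, ll_new, g_new, h_new
    return theta, lam, float(np.linalg.norm(grad)) < tol


def fit_hdig(
    beats: BeatSeries,
    order: int = DEFAULT_ORDER,
    delta: float = DEFAULT_DELTA,
    window_s: float = DEFAULT_WINDOW_S,
    forgetting: float = DEFAULT_FORGETTING,
    resume_after_s: float = DEFAULT_RESUME_S,
    t_start: float | None = None,
    t_end: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
    max_flagged_frac: float = 0.20,
) -> HDIGFit:
    """Track HDIG parameters on a regular grid by local maximum likelihood.

    At each grid time the forgetting-weighted likelihood of the trailing
    window is maximized by damped Newton, warm-started from the previous
    step.  Inside mask intervals (and for ``resume_after_s`` afterwards)
    the fit pauses: parameters are frozen and the step marked invalid.
    Non-converged steps fall back to the previous parameters and are
    flagged; more than ``max_flagged_frac`` flagged steps raises
    :class:`FitError`.

    The grid starts as soon as p+2 history-complete intervals exist (the
    early partial window is well-defined thanks to the forgetting
    weights), so stage runs near sleep onset still receive estimates.
    """
    p = order
    times = beats.times
    if times.size < p + 3:
        raise ValueError(f"need at least p+3={p + 3} beats for warm-up")
    X_all, w_all, ends = _design(times, p)
    base = _interval_weights(times, beats.labels, beats.mask, p)
    rr = np.diff(times)

    lo0 = min(p + 1, ends.size - 1)
    t0 = t_start if t_start is not None else ends[lo0]
    t0 = math.ceil(t0 / delta) * delta
    t1 = t_end if t_end is not None else float(times[-1])
    grid = np.arange(t0, t1 + 1e-9, delta)
    if grid.size == 0:
        raise ValueError("empty fitting grid")

    # initialization: OLS AR(p) on the first window, shape by moments
    span = times[0] + max(window_s, ends[lo0] - times[0])
    init_sel = ends <= span
    if init_sel.sum() < p + 2:
        init_sel = np.ones(ends.size, dtype=bool)
    Xi, wi = X_all[init_sel], w_all[init_sel]
    theta, *_ = np.linalg.lstsq(Xi, wi, rcond=None)
    resid_var = float(np.var(wi - Xi @ theta)) or 1e-8
    lam = float(np.clip(np.mean(wi) ** 3 / resid_var, 1.0, 1e8))
    if np.any(Xi @ theta <= 0):  # fall back to intercept-only start
        theta = np.zeros(p + 1)
        theta[0] = float(np.mean(wi))

    # pause bookkeeping: inside a mask or within resume_after_s of its end
    def paused(t: float) -> bool:
        for a, b in beats.mask:
            if a <= t < b + resume_after_s:
                return True
        return False

    n = grid.size
    thetas = np.empty((n, p + 1))
    lams = np.empty(n)
    mus = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    converged = np.ones(n, dtype=bool)
    attempted = 0
    flagged = 0

    for i, t in enumerate(grid):
        if paused(t):
            thetas[i], lams[i] = theta, lam
            continue
        lo = int(np.searchsorted(ends, t - window_s, side="right"))
        hi = int(np.searchsorted(ends, t, side="right"))
        if hi - lo < p + 3:  # need more observations than free parameters
            thetas[i], lams[i] = theta, lam
            continue
        sl = slice(lo, hi)
        wt = base[sl] * forgetting ** (t - ends[sl])
        if wt.sum() <= 0:
            thetas[i], lams[i] = theta, lam
            continue
        j = int(np.searchsorted(times, t, side="right")) - 1
        tau = t - times[j]
        cwt = 0.0
        cx = np.empty(0)
        if tau > 0 and j >= p and beats.labels[j] == LABEL_NORMAL:
            hist = rr[j - p:j][::-1]
            cx = np.concatenate([[1.0], hist])
            cwt = 1.0
        attempted += 1
        th_new, lam_new, ok = _maximize(
            theta, lam, X_all[sl], w_all[sl], wt, cx, tau, cwt, tol, max_iter)
        if ok:
            theta, lam = th_new, lam_new
        else:
            flagged += 1
            converged[i] = False
        # report a dof-corrected shape: the weighted-ML residual variance is
        # biased low by tr[(X'WX)^-1 X'W^2X]/sum(w) (exact for the WLS
        # analogue with exponential weights), inflating the shape
        wsum = float(wt.sum())
        Xw = X_all[sl]
        A = Xw.T @ (wt[:, None] * Xw)
        B = Xw.T @ ((wt ** 2)[:, None] * Xw)
        try:
            tr = float(np.trace(np.linalg.solve(A, B)))
        except np.linalg.LinAlgError:
            tr = p + 1.0
        dof_corr = max(wsum - tr, 1.0) / wsum
        thetas[i], lams[i] = theta, lam * dof_corr
        if j >= p:
            mu_t = float(np.concatenate([[1.0], rr[j - p:j][::-1]]) @ theta)
            if mu_t > 0:
                mus[i] = mu_t
                valid[i] = ok
    if attempted and flagged / attempted > max_flagged_frac:
        raise FitError(
            f"{flagged}/{attempted} grid steps failed to converge")
    fit = HDIGFit(
        t=grid, theta=thetas, shape=lams, mu=mus,
        sigma2=np.where(np.isfinite(mus), mus ** 3 / lams, np.nan),
        valid=valid, converged=converged, order=p, delta=delta,
        window_s=window_s, forgetting=forgetting,
        settings={
            "order": p, "delta": delta, "window_s": window_s,
            "forgetting": forgetting, "resume_after_s": resume_after_s,
            "tol": tol, "max_iter": max_iter,
            "n_steps": int(n), "n_flagged": int(flagged),
        },
    )
    return fit


def instantaneous_moments(params: HDIGParams, history) -> tuple[float, float]:
    """(mu, sigma^2) at a step: mu from the AR regression, sigma^2 = mu^3/shape."""
    mu = conditional_mean(history, params.theta)
    return mu, mu ** 3 / params.shape


# ---------------------------------------------------------------------------
# Spectra and band powers

def _check_stable(theta_ar: np.ndarray) -> None:
    if theta_ar.size == 0 or not np.any(theta_ar):
        return
    poles = np.roots(np.concatenate([[1.0], -theta_ar]))
    if poles.size and np.max(np.abs(poles)) >= 1.0 - 1e-10:
        raise SpectrumError("AR polynomial has poles on/outside the unit circle")


def _phi_basis(order: int, n_phi: int = 1024):
    """Fixed beat-domain frequency grid and complex AR basis e^{-i2*pi*phi*j}."""
    phi = np.linspace(0.0, 0.5, n_phi)
    j = np.arange(1, order + 1)
    return phi, np.exp(-2j * np.pi * np.outer(phi, j))


def instantaneous_spectrum(
    params: HDIGParams,
    mu_t: float,
    f_grid: np.ndarray | None = None,
    sigma2_ms2: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided RR power spectral density in ms^2/Hz on ``f_grid``.

    The AR transfer function is evaluated in the beat domain,
    S_beat(phi) = sigma_w^2 / |1 - sum_j theta_j e^{-i 2 pi phi j}|^2,
    and mapped to Hz by f = phi / mu_t with the density rescaled by mu_t
    so band integrals are conserved.  The innovation variance sigma_w^2 is
    chosen so that the total integrated power over (0, Nyquist) equals the
    instantaneous variance mu^3/shape (in ms^2).  Raises
    :class:`SpectrumError` for unstable AR polynomials.
    """
    theta_ar = params.theta[1:]
    _check_stable(theta_ar)
    if mu_t <= 0:
        raise ValueError("mu_t must be positive")
    if sigma2_ms2 is None:
        sigma2_ms2 = mu_t ** 3 / params.shape * 1e6
    phi, basis = _phi_basis(theta_ar.size)
    denom = np.abs(1.0 - basis @ theta_ar) ** 2
    norm = np.trapezoid(1.0 / denom, phi)
    sw2 = sigma2_ms2 / norm
    if f_grid is None:
        f_grid = np.arange(VLF_BAND[0], HF_BAND[1] + 1e-12, 0.002)
    phi_f = np.asarray(f_grid, dtype=float) * mu_t
    jj = np.arange(1, theta_ar.size + 1)
    denom_f = np.abs(1.0 - np.exp(-2j * np.pi * np.outer(phi_f, jj)) @ theta_ar) ** 2
    return np.asarray(f_grid, dtype=float), sw2 * mu_t / denom_f


def band_powers(S: np.ndarray, f_grid: np.ndarray,
                total_power: float | None = None) -> dict[str, float]:
    """Integrate a PSD into VLF/LF/HF powers and normalized indices.

    Trapezoid integrals on the provided grid; by default total power is
    the 0.01-0.4 Hz integral, so lfn + hfn = 1 by construction.  Passing
    ``total_power`` (e.g. the full 0-Nyquist integral) switches the
    normalization denominator to (total_power - vlf).  A zero HF power
    yields a missing (NaN) LF/HF ratio, never infinity.
    """
    f = np.asarray(f_grid, dtype=float)
    S = np.asarray(S, dtype=float)

    def band(lo, hi):
        sel = (f >= lo - 1e-12) & (f <= hi + 1e-12)
        return float(np.trapezoid(S[sel], f[sel]))

    vlf = band(*VLF_BAND)
    lf = band(*LF_BAND)
    hf = band(*HF_BAND)
    total = (vlf + lf + hf) if total_power is None else float(total_power)
    denom = total - vlf
    lfn = lf / denom if denom > 0 else np.nan
    hfn = hf / denom if denom > 0 else np.nan
    lfhf = lf / hf if hf > 0 else np.nan
    return {"vlf": vlf, "lf": lf, "hf": hf, "lfn": lfn, "hfn": hfn, "lfhf": lfhf}


@dataclass
class InstantaneousHRV:
    """Time-gridded instantaneous HRV trajectories.

    mu in seconds, sigma2 in s^2, band powers in ms^2; ``valid`` is False
    inside masks, during warm-up and at unstable/non-converged steps.
    """

    t: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    vlf: np.ndarray
    lf: np.ndarray
    hf: np.ndarray
    lfn: np.ndarray
    hfn: np.ndarray
    lfhf: np.ndarray
    valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "mu": self.mu, "sigma2": self.sigma2,
             "vlf": self.vlf, "lf": self.lf, "hf": self.hf,
             "lfn": self.lfn, "hfn": self.hfn, "lfhf": self.lfhf,
             "valid": self.valid})


def hrv_from_fit(fit: HDIGFit, chunk: int = 512) -> InstantaneousHRV:
    """Derive instantaneous band powers for every valid step of a fit.

    Evaluates the AR spectrum once per step on a fixed beat-domain grid
    and integrates the bands after mapping edges by the step's mean RR
    (change of variable f = phi/mu; band integrals are identical to the
    Hz-domain ones).  Steps with unstable AR polynomials are invalidated.
    """
    n = fit.t.size
    p = fit.order
    phi, basis = _phi_basis(p)
    out = {k: np.full(n, np.nan) for k in ("vlf", "lf", "hf", "lfn", "hfn", "lfhf")}
    valid = fit.valid.copy()
    idx = np.flatnonzero(fit.valid)
    edges_hz = np.array([VLF_BAND[0], VLF_BAND[1], LF_BAND[1], HF_BAND[1]])
    for a in range(0, idx.size, chunk):
        ii = idx[a:a + chunk]
        theta_blk = fit.theta[ii, 1:]
        denom = np.abs(1.0 - basis @ theta_blk.T) ** 2  # (n_phi, m)
        cum = cumulative_trapezoid(1.0 / denom, phi, axis=0, initial=0.0)
        for col, i in enumerate(ii):
            theta_ar = fit.theta[i, 1:]
            poles = np.roots(np.concatenate([[1.0], -theta_ar]))
            if poles.size and np.max(np.abs(poles)) >= 1.0 - 1e-10:
                valid[i] = False
                continue
            mu_t = fit.mu[i]
            sigma2_ms2 = fit.sigma2[i] * 1e6
            sw2 = sigma2_ms2 / cum[-1, col]
            phi_edges = np.clip(edges_hz * mu_t, phi[0], phi[-1])
            ce = np.interp(phi_edges, phi, cum[:, col])
            vlf = sw2 * (ce[1] - ce[0])
            lf = sw2 * (ce[2] - ce[1])
            hf = sw2 * (ce[3] - ce[2])
            denom_n = lf + hf
            out["vlf"][i] = vlf
            out["lf"][i] = lf
            out["hf"][i] = hf
            out["lfn"][i] = lf / denom_n if denom_n > 0 else np.nan
            out["hfn"][i] = hf / denom_n if denom_n > 0 else np.nan
            out["lfhf"][i] = lf / hf if hf > 0 else np.nan
    return InstantaneousHRV(
        t=fit.t, mu=fit.mu, sigma2=fit.sigma2, valid=valid, **out)


# ---------------------------------------------------------------------------
# Goodness of fit by time rescaling

@dataclass(frozen=True)
class GofResult:
    ks_distance: float
    within_95_band: bool
    band: float
    n: int


def ks_rescaling_gof(beats: BeatSeries, fit: HDIGFit) -> GofResult:
    """Time-rescaling KS goodness of fit.

    Each observed interval is rescaled by the model's integrated
    conditional intensity, Lambda_k = -log S(w_k; mu_k, shape_k), giving
    z_k = 1 - exp(-Lambda_k), uniform on (0, 1) under a correct model.
    Returns the KS distance of z against uniform and whether it lies
    within the 95% band 1.36/sqrt(n).
    """
    if beats.times.size < 20:
        raise ValueError("insufficient beats for goodness of fit (< 20)")
    p = fit.order
    X, w, ends = _design(beats.times, p)
    base = _interval_weights(beats.times, beats.labels, beats.mask, p)
    z = []
    for k in range(w.size):
        if base[k] == 0 or ends[k] < fit.t[0] or ends[k] > fit.t[-1]:
            continue
        i = int(np.searchsorted(fit.t, ends[k], side="right")) - 1
        if not fit.valid[i]:
            continue
        mu_k = float(X[k] @ fit.theta[i])
        if mu_k <= 0:
            continue
        lam_k = float(fit.shape[i])
        z.append(1.0 - math.exp(float(_ig_logsf(w[k], mu_k, lam_k))))
    if len(z) < 20:
        raise ValueError("insufficient beats for goodness of fit (< 20)")
    z = np.sort(np.asarray(z))
    n = z.size
    up = np.arange(1, n + 1) / n - z
    lo = z - np.arange(0, n) / n
    ks = float(max(up.max(), lo.max()))
    band = 1.36 / math.sqrt(n)
    return GofResult(ks_distance=ks, within_95_band=ks <= band, band=band, n=n)
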