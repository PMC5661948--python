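"""Exponential nucleotide-decay fits and half-lives with 95% bounds.

Two models for HPLC time courses of nucleotide concentration (mM):

* ``atp_fixed_asymptote``: conc(t) = 2 + b·exp(−t/τ) — the asymptote is
  pinned at 2 mM (the floor ATP does not drop below in cell-free extract).
* ``adp_free_asymptote``: conc(t) = d + b·exp(−t/τ) — the asymptote d is
  fitted because none can be pinned for ADP.

τ > 0 is the decay time constant in minutes and half-life = ln(2)·τ.  (An
equivalent parameterization writes exp(t/c) with negative c; here c = −τ,
which keeps the half-life positive by construction.)  Fits use
Levenberg–Marquardt least squares; confidence bounds are linearized
(covariance-based, Student-t) at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

__all__ = ["DecayFitResult", "FitError", "fit_decay", "simulate_decay",
           "MODELS", "ATP_FIXED", "ADP_FREE"]

ATP_FIXED = "atp_fixed_asymptote"
ADP_FREE = "adp_free_asymptote"
MODELS = (ATP_FIXED, ADP_FREE)

FIXED_ASYMPTOTE_MM = 2.0


class FitError(RuntimeError):
    """Raised when the decay fit fails to converge."""


@dataclass(frozen=True)
class DecayFitResult:
    """Fitted decay parameters with per-parameter 95% confidence bounds.

    ``half_life`` is ln(2)·τ in minutes; it is NaN (and ``decaying`` False)
    when the fitted amplitude b is not positive, i.e. the data do not decay.
    """

    model: str
    b: float
    tau: float
    d: float
    half_life: float
    decaying: bool
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    residual_norm: float = float("nan")
    n_points: int = 0

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.d + self.b * np.exp(-t / self.tau)


def _model_conc(t, b, tau, d):
    return d + b * np.exp(-t / tau)


def fit_decay(times, conc, model: str) -> DecayFitResult:
    """Levenberg–Marquardt fit of conc(t) = asymptote + b·exp(−t/τ).

    Requires ≥3 points for the fixed-asymptote model, ≥4 for the free one;
    initial guesses come from the data (b ≈ conc(0) − asymptote, τ ≈ half
    the time span).  95% bounds use the linearized covariance with a
    Student-t quantile at n − k degrees of freedom.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    t = np.asarray(times, dtype=float)
    y = np.asarray(conc, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and conc must be 1-D arrays of equal length")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    min_pts = 3 if model == ATP_FIXED else 4
    if len(t) < min_pts:
        raise ValueError(f"{model} needs at least {min_pts} time points")

    span = float(t.max() - t.min()) or 1.0
    d0 = FIXED_ASYMPTOTE_MM if model == ATP_FIXED else float(y.min())
    b0 = float(y[np.argmin(t)]) - d0
    if abs(b0) < 1e-12:
        b0 = 1e-3

    params = lmfit.Parameters()
    params.add("b", value=b0)
    params.add("tau", value=span / 2.0, min=1e-9)
    params.add("d", value=d0, vary=(model == ADP_FREE))

    def residual(p):
        return _model_conc(t, p["b"].value, p["tau"].value, p["d"].value) - y

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        norm = float(np.linalg.norm(result.residual)) if result.residual is not None else float("nan")
        raise FitError(f"decay fit did not converge (residual norm {norm:.4g}): "
                       f"{result.message}")

    b = float(result.params["b"].value)
    tau = float(result.params["tau"].value)
    d = float(result.params["d"].value)
    decaying = b > 0

    dof = max(result.ndata - result.nvarys, 1)
    tq = stats.t.ppf(0.975, dof)
    ci95: dict[str, tuple[float, float]] = {}
    for name in ("b", "tau", "d"):
        par = result.params[name]
        if par.vary and par.stderr is not None and np.isfinite(par.stderr):
            ci95[name] = (par.value - tq * par.stderr, par.value + tq * par.stderr)
    if "tau" in ci95 and decaying:
        lo, hi = ci95["tau"]
        ci95["half_life"] = (math.log(2) * lo, math.log(2) * hi)

    return DecayFitResult(
        model=model,
        b=b,
        tau=tau,
        d=d,
        half_life=math.log(2) * tau if decaying else float("nan"),
        decaying=decaying,
        ci95=ci95,
        residual_norm=float(np.linalg.norm(result.residual)),
        n_points=int(result.ndata),
    )


def simulate_decay(model: str, b: float, tau: float, d: float | None = None,
                   noise_sd: float = 0.0, times=None,
                   seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Generate a synthetic concentration time course (curve + Gaussian
    noise), as a stand-in for an HPLC measurement series."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if model == ATP_FIXED:
        d = FIXED_ASYMPTOTE_MM
    elif d is None:
        raise ValueError("free-asymptote model requires d")
    t = np.linspace(0.0, 120.0, 10) if times is None else np.asarray(times, dtype=float)
    y = _model_conc(t, b, tau, d)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return t, y
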