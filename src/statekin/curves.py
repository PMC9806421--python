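"""Nonlinear least-squares fits of the empirical availability and time-course
models used throughout the analysis.

Two model families are provided, each as a scikit-learn-style estimator with
a thin functional wrapper:

* :class:`BoltzmannFit` -- steady-state availability versus conditioning
  voltage,

      I(V) = i_max * [ i_res + (1 - i_res) / (1 + exp(z (V - V_0.5) / 24)) ]

  with ``i_res`` the residual availability resistant to inactivation, ``z``
  the apparent valence (elementary charges), ``V_0.5`` the midpoint (mV) and
  a fixed thermal slope constant of 24 mV per elementary charge.  The sign
  of the exponent is chosen so that availability decreases with
  depolarization for z > 0.  ``i_max`` is an optional overall amplitude
  (fixed to 1 for pre-normalized data).

* :class:`ExponentialFit` -- single / double / squared exponential time
  courses,

      single:  I(t) = A exp(-t/tau) + B
      double:  I(t) = A exp(-t/tau) + A2 exp(-t/tau2) + B     (tau2 > tau)
      squared: I(t) = A exp(-(t/tau)^2) + B

  The squared form is the kinetic signature of an inhibitor whose
  concentration ramps linearly in time (an indirectly generated blocker); a
  directly applied blocker at fixed concentration gives the single form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SLOPE_CONST",
    "BoltzmannParams",
    "ExpFitParams",
    "FitError",
    "BoltzmannFit",
    "ExponentialFit",
    "eval_boltzmann",
    "fit_boltzmann",
    "normalize_to_fit_max",
    "fit_exponential",
    "compare_forms",
    "FormComparison",
]

#: Fixed thermal slope constant, mV per elementary charge.
SLOPE_CONST = 24.0


class FitError(RuntimeError):
    """Raised when a fit fails to converge or the data are degenerate.

    Carries the last parameter iterate in ``last_params`` when available.
    """

    def __init__(self, message: str, last_params: dict | None = None):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class BoltzmannParams:
    """Fitted Boltzmann availability parameters."""

    i_res: float
    z: float
    v_half: float
    i_max: float = 1.0
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.i_res < 1.0):
            raise ValueError(f"i_res must be in [0, 1), got {self.i_res}")
        if self.z <= 0:
            raise ValueError(f"z must be > 0, got {self.z}")

    @property
    def predicted_max(self) -> float:
        """Value at the hyperpolarized asymptote (V -> -inf)."""
        return self.i_max

    def __call__(self, V):
        return eval_boltzmann(self, V)


@dataclass(frozen=True)
class ExpFitParams:
    """Fitted exponential time-course parameters.

    For the double form, (A, tau) is the fast component and (A2, tau2) the
    slow one (tau2 > tau).  ``rss`` is the residual sum of squares.
    """

    form: Literal["single", "double", "squared"]
    A: float
    B: float
    tau: float
    A2: float = 0.0
    tau2: float = float("nan")
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    converged: bool = True
    collapsed_from_double: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.form == "double" and not (self.tau2 > self.tau):
            raise ValueError("double form requires tau2 > tau")

    @property
    def asymptote(self) -> float:
        """The t -> infinity level."""
        return self.B

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.form == "single":
            return self.A * np.exp(-t / self.tau) + self.B
        if self.form == "squared":
            return self.A * np.exp(-((t / self.tau) ** 2)) + self.B
        return (self.A * np.exp(-t / self.tau)
                + self.A2 * np.exp(-t / self.tau2) + self.B)


def eval_boltzmann(params: BoltzmannParams, V) -> np.ndarray | float:
    """Evaluate the Boltzmann availability function at voltage(s) V (mV)."""
    V = np.asarray(V, dtype=float)
    e = np.exp(np.clip(params.z * (V - params.v_half) / SLOPE_CONST, -700, 700))
    out = params.i_max * (params.i_res + (1.0 - params.i_res) / (1.0 + e))
    return float(out) if out.ndim == 0 else out


def _stderr_from_jac(res, n: int, names: list[str]) -> dict:
    """Parameter standard errors from the least-squares Jacobian."""
    p = len(names)
    if n <= p:
        return {}
    try:
        JTJ = res.jac.T @ res.jac
        cov = np.linalg.inv(JTJ) * (2 * res.cost) / (n - p)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return dict(zip(names, se))
    except np.linalg.LinAlgError:
        return {}


class BoltzmannFit:
    """Least-squares Boltzmann availability fit (sklearn-style estimator).

    Parameters
    ----------
    fit_i_res : bool
        Fit the residual availability (else fixed at ``i_res0``).
    fit_i_max : bool
        Fit an overall amplitude (use for unnormalized peak currents);
        default False fixes i_max = 1 for pre-normalized data.

    Fitted attributes: ``v_half_``, ``z_``, ``i_res_``, ``i_max_``,
    ``stderr_``, ``rss_``, ``converged_``, ``params_``.
    """

    def __init__(self, fit_i_res: bool = True, fit_i_max: bool = False,
                 i_res0: float = 0.0, max_nfev: int = 2000):
        self.fit_i_res = fit_i_res
        self.fit_i_max = fit_i_max
        self.i_res0 = i_res0
        self.max_nfev = max_nfev

    # -- minimal sklearn plumbing ------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"fit_i_res": self.fit_i_res, "fit_i_max": self.fit_i_max,
                "i_res0": self.i_res0, "max_nfev": self.max_nfev}

    def set_params(self, **params) -> "BoltzmannFit":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------------
    @staticmethod
    def _initial_guess(V: np.ndarray, y: np.ndarray, fit_i_max: bool):
        lo, hi = float(y.min()), float(y.max())
        i_max0 = hi if fit_i_max else 1.0
        span = hi - lo
        # midpoint: voltage where y crosses half range (data sorted by V)
        half = lo + span / 2
        order = np.argsort(V)
        Vs, ys = V[order], y[order]
        below = np.where(ys <= half)[0]
        v50 = float(Vs[below[0]]) if below.size else float(Vs[len(Vs) // 2])
        # steepness from the 10-90% width: w = slope * ln(81)
        hi_t = lo + 0.9 * span
        lo_t = lo + 0.1 * span
        iv = np.interp  # monotone-ish decreasing data: interp on reversed axis
        v_hi = float(iv(-hi_t, -ys, Vs))
        v_lo = float(iv(-lo_t, -ys, Vs))
        width = max(abs(v_lo - v_hi), 1.0)
        z0 = float(np.clip(SLOPE_CONST * math.log(81.0) / width, 0.2, 19.0))
        i_res_0 = float(np.clip(lo / i_max0, 0.0, 0.9))
        return v50, z0, i_res_0, i_max0

    def fit(self, V, y, sample_weight=None) -> "BoltzmannFit":
        V = np.asarray(V, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if V.size != y.size:
            raise ValueError("V and y must have the same length")
        if V.size < 5:
            raise FitError("need at least 5 points spanning the transition")
        if not (np.all(np.isfinite(V)) and np.all(np.isfinite(y))):
            raise FitError("non-finite values in input")
        if np.ptp(y) < 1e-12:
            raise FitError("degenerate flat data: no transition to fit")
        w = np.ones_like(y) if sample_weight is None else np.sqrt(
            np.asarray(sample_weight, dtype=float).ravel())

        v50, z0, ir0, imax0 = self._initial_guess(V, y, self.fit_i_max)
        names = ["v_half", "z"]
        p0 = [v50, z0]
        lo = [V.min() - 100.0, 1e-3]
        hi = [V.max() + 100.0, 20.0]
        if self.fit_i_res:
            names.append("i_res")
            p0.append(ir0)
            lo.append(0.0)
            hi.append(1.0 - 1e-9)
        if self.fit_i_max:
            names.append("i_max")
            p0.append(imax0)
            lo.append(1e-12)
            hi.append(np.inf)

        def unpack(p):
            d = dict(zip(names, p))
            return (d["v_half"], d["z"],
                    d.get("i_res", self.i_res0), d.get("i_max", 1.0))

        def resid(p):
            vh, z, ir, im = unpack(p)
            e = np.exp(np.clip(z * (V - vh) / SLOPE_CONST, -700, 700))
            return w * (im * (ir + (1 - ir) / (1 + e)) - y)

        res = least_squares(resid, p0, bounds=(lo, hi), max_nfev=self.max_nfev,
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        vh, z, ir, im = unpack(res.x)
        if not res.success:
            raise FitError(
                f"Boltzmann fit did not converge: {res.message}",
                last_params=dict(zip(names, res.x)),
            )
        self.v_half_ = float(vh)
        self.z_ = float(z)
        self.i_res_ = float(ir)
        self.i_max_ = float(im)
        self.rss_ = float(2 * res.cost)
        self.stderr_ = _stderr_from_jac(res, V.size, names)
        self.converged_ = True
        self.params_ = BoltzmannParams(
            i_res=self.i_res_, z=self.z_, v_half=self.v_half_, i_max=self.i_max_,
            stderr=self.stderr_, rss=self.rss_, converged=True,
        )
        return self

    def predict(self, V):
        if not hasattr(self, "params_"):
            raise FitError("estimator is not fitted")
        return eval_boltzmann(self.params_, V)


def fit_boltzmann(V, I_norm, weights=None, fit_i_max: bool = False,
                  fit_i_res: bool = True) -> BoltzmannParams:
    """Fit the Boltzmann availability function; see :class:`BoltzmannFit`."""
    est = BoltzmannFit(fit_i_res=fit_i_res, fit_i_max=fit_i_max)
    est.fit(V, I_norm, sample_weight=weights)
    return est.params_


def normalize_to_fit_max(I, params: BoltzmannParams) -> np.ndarray:
    """Divide currents by the fit-predicted maximum (the value the fitted
    Boltzmann attains at the hyperpolarized asymptote)."""
    if not params.converged:
        raise FitError("cannot normalize to a non-converged fit")
    m = params.predicted_max
    if m <= 0:
        raise ValueError(f"fit-predicted maximum is not positive: {m}")
    return np.asarray(I, dtype=float) / m


# ---------------------------------------------------------------------------
# Exponential time courses
# ---------------------------------------------------------------------------

class ExponentialFit:
    """Least-squares single / double / squared exponential fit.

    Fitted attributes: ``A_``, ``B_``, ``tau_`` (fast), ``A2_``, ``tau2_``
    (slow; double form), ``rss_``, ``stderr_``, ``converged_``, ``params_``.
    A double fit whose two time constants collapse (within 5%) is refitted
    as a single exponential and flagged ``collapsed_from_double``.
    """

    def __init__(self, form: str = "single", fix_offset: float | None = None,
                 max_nfev: int = 5000, tau_max: float | None = None):
        if form not in ("single", "double", "squared"):
            raise ValueError(f"unknown form {form!r}")
        self.form = form
        self.fix_offset = fix_offset
        self.max_nfev = max_nfev
        # upper bound on the time constants; default 10x the observation
        # window, tighten (e.g. to the window itself) when the asymptote
        # must not be extrapolated from slower-than-observable components
        self.tau_max = tau_max

    def get_params(self, deep: bool = True) -> dict:
        return {"form": self.form, "fix_offset": self.fix_offset,
                "max_nfev": self.max_nfev, "tau_max": self.tau_max}

    def set_params(self, **params) -> "ExponentialFit":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _tau0(t: np.ndarray, y: np.ndarray) -> float:
        """Crude time-scale guess: time to cover half the dynamic range."""
        y0, y1 = y[0], y[-1]
        half = (y0 + y1) / 2
        sgn = 1.0 if y0 >= y1 else -1.0
        idx = np.where(sgn * (y - half) <= 0)[0]
        t_half = float(t[idx[0]]) if idx.size else float(t[-1] / 3)
        return max(t_half / math.log(2), float(t[1] - t[0]) / 10, 1e-9)

    def fit(self, t, y) -> "ExponentialFit":
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        min_n = 6 if self.form == "double" else 4
        if t.size != y.size:
            raise ValueError("t and y must have the same length")
        if t.size < min_n:
            raise FitError(f"need at least {min_n} points for the {self.form} form")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise FitError("t must be non-negative and strictly increasing")
        if not np.all(np.isfinite(y)):
            raise FitError("non-finite values in input")

        t_max = float(t[-1])
        tau_hi = 10 * t_max if self.tau_max is None else float(self.tau_max)
        tau0 = min(self._tau0(t, y), tau_hi / 2)
        B0 = float(y[-1]) if self.fix_offset is None else float(self.fix_offset)
        A0 = float(y[0]) - B0

        names: list[str]
        if self.form == "double":
            # split amplitudes at the point where the fast phase (set by the
            # half-range time scale) is complete, so a small slow tail on top
            # of a large fast component still seeds both components sensibly
            t_split = min(20 * tau0, t_max / 4)
            i_split = int(np.searchsorted(t, t_split))
            y_mid = float(y[min(max(i_split, 1), y.size - 1)])
            A2_0 = float(y[-1]) - y_mid if self.fix_offset is None else \
                float(self.fix_offset) - y_mid
            A2_0 = -A2_0  # amplitude convention: y = A2*exp(-t/tau2) + ...
            Af_0 = A0 - A2_0
            tau2_0 = float(np.clip(math.sqrt(max(t_split, 1e-9) * t_max),
                                   tau0 * 8, tau_hi * 0.9))
            names = ["A", "tau", "A2", "tau2"]
            p0 = [Af_0, max(tau0 / 3, 1e-9), A2_0, tau2_0]
            lo = [-np.inf, 1e-12, -np.inf, 1e-12]
            hi = [np.inf, tau_hi, np.inf, tau_hi]
        else:
            names = ["A", "tau"]
            p0 = [A0, tau0]
            lo = [-np.inf, 1e-12]
            hi = [np.inf, tau_hi]
        if self.fix_offset is None:
            names.append("B")
            p0.append(B0)
            lo.append(-np.inf)
            hi.append(np.inf)

        def model(p):
            d = dict(zip(names, p))
            B = d.get("B", self.fix_offset if self.fix_offset is not None else 0.0)
            if self.form == "single":
                return d["A"] * np.exp(-t / d["tau"]) + B
            if self.form == "squared":
                return d["A"] * np.exp(-((t / d["tau"]) ** 2)) + B
            return (d["A"] * np.exp(-t / d["tau"])
                    + d["A2"] * np.exp(-t / d["tau2"]) + B)

        res = least_squares(lambda p: model(p) - y, p0, bounds=(lo, hi),
                            max_nfev=self.max_nfev,
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not res.success:
            raise FitError(f"{self.form} exponential fit did not converge: "
                           f"{res.message}",
                           last_params=dict(zip(names, res.x)))
        d = dict(zip(names, res.x))
        B = float(d.get("B", self.fix_offset or 0.0))
        rss = float(2 * res.cost)
        stderr = _stderr_from_jac(res, t.size, names)

        collapsed = False
        if self.form == "double":
            tau_a, tau_b = float(d["tau"]), float(d["tau2"])
            amp_a, amp_b = abs(float(d["A"])), abs(float(d["A2"]))
            degenerate = (abs(tau_a - tau_b) / max(tau_a, tau_b) < 0.05
                          or min(amp_a, amp_b)
                          < 1e-6 + 1e-3 * (amp_a + amp_b))
            if degenerate:
                single = ExponentialFit("single", fix_offset=self.fix_offset).fit(t, y)
                self.params_ = ExpFitParams(
                    form="single", A=single.params_.A, B=single.params_.B,
                    tau=single.params_.tau, stderr=single.params_.stderr,
                    rss=single.params_.rss, converged=True,
                    collapsed_from_double=True,
                )
                collapsed = True
            else:
                # order the components fast -> slow
                (Af, tf), (As, ts) = sorted(
                    [(float(d["A"]), tau_a), (float(d["A2"]), tau_b)],
                    key=lambda c: c[1],
                )
                self.params_ = ExpFitParams(
                    form="double", A=Af, tau=tf, A2=As, tau2=ts, B=B,
                    stderr=stderr, rss=rss, converged=True,
                )
        else:
            self.params_ = ExpFitParams(
                form=self.form, A=float(d["A"]), B=B, tau=float(d["tau"]),
                stderr=stderr, rss=rss, converged=True,
            )
        p = self.params_
        self.A_, self.B_, self.tau_ = p.A, p.B, p.tau
        self.A2_, self.tau2_ = p.A2, p.tau2
        self.rss_, self.stderr_, self.converged_ = p.rss, p.stderr, True
        self.collapsed_ = collapsed
        return self

    def predict(self, t):
        if not hasattr(self, "params_"):
            raise FitError("estimator is not fitted")
        return self.params_(t)


def fit_exponential(t, y, form: str = "single",
                    fix_offset: float | None = None) -> ExpFitParams:
    """Fit an exponential time course; see :class:`ExponentialFit`."""
    est = ExponentialFit(form=form, fix_offset=fix_offset)
    est.fit(t, y)
    return est.params_


@dataclass(frozen=True)
class FormComparison:
    """Single- versus squared-exponential model discrimination."""

    single: ExpFitParams
    squared: ExpFitParams
    aicc_single: float
    aicc_squared: float
    aicc_const: float
    preferred: str  # "single" | "squared" | "inconclusive"


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def compare_forms(t, y, fix_offset: float | None = None) -> FormComparison:
    """Fit single and squared exponentials and flag the preferred form.

    Small-sample corrected AIC decides; if neither form improves on an
    offset-only (constant) description by more than 2 AICc units the result
    is flagged "inconclusive" (pure noise around a constant).
    """
    t = np.asarray(t, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    single = fit_exponential(t, y, "single", fix_offset)
    squared = fit_exponential(t, y, "squared", fix_offset)
    n = t.size
    k = 2 if fix_offset is not None else 3
    a1 = _aicc(single.rss, n, k)
    a2 = _aicc(squared.rss, n, k)
    rss_const = float(np.sum((y - y.mean()) ** 2))
    a0 = _aicc(rss_const, n, 1)
    if min(a1, a2) > a0 - 2.0:
        preferred = "inconclusive"
    else:
        preferred = "single" if a1 < a2 else "squared"
    return FormComparison(single=single, squared=squared, aicc_single=a1,
                          aicc_squared=a2, aicc_const=a0, preferred=preferred)
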