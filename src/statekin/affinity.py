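"""Inference of relative per-state association constants of the inhibitor.

Two steps, composable end-to-end:

1. **Repriming decomposition** (:func:`decompose_states`): a double-pulse
   recovery curve I2/I1con(dt) at holding potential V_h, fitted with a
   double exponential of total asymptote T, is decomposed into resting (R),
   fast-inactivated (FI) and slow-inactivated (SI) components.  The resting
   fraction is 1/T; the FI component is the part of the curve between the
   resting level (I2/I1con = 1) and the asymptote of the faster exponential
   (operationalized as T minus the slow component's amplitude); the SI
   component is the remainder up to T.  Fractions are the components
   divided by T.

2. **Affinity solve** (:func:`solve_affinity`): the onset rate of
   inhibition at each holding potential is modelled as proportional to
   F_R k_R + F_FI k_FI + F_SI k_SI (law of mass action over the unbound
   state fractions).  One linear equation per holding potential yields the
   lumped per-state products q_S = [X] C k_S; only the ratios k_FI/k_R and
   k_SI/k_R are identifiable and are invariant to any common rescaling of
   the input rates.

:class:`StateAffinitySolver` wraps the solve as a scikit-learn-style
estimator; :func:`recover_ratios_end_to_end` closes the loop on fully
synthetic data (simulate, fit, decompose, solve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channel import ChannelModel, InhibitorSchedule
from .curves import ExpFitParams, ExponentialFit, FitError, fit_exponential
from .protocols import repriming_protocol, run_protocol, simulate_inhibition_diary

__all__ = [
    "RecoveryCurve",
    "StateFractions",
    "AffinitySolution",
    "decompose_states",
    "build_affinity_system",
    "AffinitySystem",
    "solve_affinity",
    "StateAffinitySolver",
    "simulate_recovery_curve",
    "recover_ratios_end_to_end",
    "EndToEndResult",
]


@dataclass(frozen=True)
class RecoveryCurve:
    """A repriming (double-pulse recovery) curve at one holding potential."""

    V_h: float
    times: np.ndarray
    i2_over_i1con: np.ndarray
    fit: ExpFitParams | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.i2_over_i1con, dtype=float)
        if t.size != y.size:
            raise ValueError("times and i2_over_i1con must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("recovery times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("I2/I1con values must be >= 0")

    def fitted(self) -> "RecoveryCurve":
        """Return a copy with a (double, falling back to single) exponential
        fit of the recovery attached."""
        if self.fit is not None:
            return self
        # time constants are bounded by the observation window: the
        # asymptote T must not rest on slower-than-observable components
        tau_max = float(np.asarray(self.times)[-1])
        try:
            est = ExponentialFit("double", tau_max=tau_max).fit(
                self.times, self.i2_over_i1con)
        except FitError:
            est = ExponentialFit("single", tau_max=tau_max).fit(
                self.times, self.i2_over_i1con)
        return RecoveryCurve(self.V_h, self.times, self.i2_over_i1con,
                             est.params_)


@dataclass(frozen=True)
class StateFractions:
    """R/FI/SI components (in I2/I1con units) and fractions at one V_h."""

    V_h: float
    T: float
    component_R: float
    component_FI: float
    component_SI: float
    F_R: float
    F_FI: float
    F_SI: float

    def __post_init__(self) -> None:
        for c in (self.component_R, self.component_FI, self.component_SI):
            if c < -1e-12:
                raise ValueError("components must be >= 0")
        s = self.F_R + self.F_FI + self.F_SI
        if abs(s - 1.0) > 1e-3:
            raise ValueError(f"fractions sum to {s}, not 1")
        if abs(self.F_R - 1.0 / self.T) > 1e-6:
            raise ValueError("F_R must equal 1/T")

    @property
    def row(self) -> np.ndarray:
        return np.array([self.F_R, self.F_FI, self.F_SI])

    @classmethod
    def from_fractions(cls, V_h: float, F_R: float, F_FI: float,
                       F_SI: float) -> "StateFractions":
        """Build directly from fractions (e.g. a published table row)."""
        T = 1.0 / F_R
        return cls(V_h=V_h, T=T, component_R=1.0, component_FI=F_FI * T,
                   component_SI=F_SI * T, F_R=F_R, F_FI=F_FI, F_SI=F_SI)


def decompose_states(curve: RecoveryCurve,
                     fast_slow_split_s: float = 0.05) -> StateFractions:
    """Decompose a fitted repriming curve into R/FI/SI fractions.

    Requires the fitted total asymptote T >= 1 (the fully reprimed current
    can not be smaller than the pre-drug reference elicited from the holding
    potential; T < 1 indicates a normalization fault).

    Components are classified by absolute timescale: repriming of
    fast-inactivated channels completes within milliseconds while recovery
    from slow inactivation takes hundreds of milliseconds to seconds, so
    any fitted component slower than ``fast_slow_split_s`` is attributed to
    the slow-inactivated pool.  (Pure relative ordering would mislabel a
    curve that contains only a slow phase, e.g. at strongly hyperpolarized
    holding potentials where no channels are fast-inactivated.)
    """
    curve = curve.fitted()
    fit = curve.fit
    assert fit is not None
    if not fit.converged:
        raise FitError("recovery fit did not converge")
    T = fit.asymptote
    if T < 1.0 - 1e-9:
        raise ValueError(
            f"total asymptote T={T:.4f} < 1: more current after recovery than "
            "the pre-drug reference implies a normalization fault"
        )
    # recovery curves rise, so component amplitudes are negative
    components = [(fit.tau, -fit.A)]
    if fit.form == "double":
        components.append((fit.tau2, -fit.A2))
    slow_amplitude = sum(a for tau, a in components
                         if tau > fast_slow_split_s)
    fast_asymptote = T - max(slow_amplitude, 0.0)
    component_R = 1.0
    component_FI = max(0.0, fast_asymptote - 1.0)
    component_SI = max(0.0, T - max(fast_asymptote, 1.0))
    return StateFractions(
        V_h=curve.V_h,
        T=T,
        component_R=component_R,
        component_FI=component_FI,
        component_SI=component_SI,
        F_R=component_R / T,
        F_FI=component_FI / T,
        F_SI=component_SI / T,
    )


@dataclass(frozen=True)
class AffinitySystem:
    """The linear system F q = r over the lumped products q_S = [X] C k_S."""

    coefficients: np.ndarray  # rows [F_R, F_FI, F_SI], one per V_h
    rates: np.ndarray         # inhibition rates (1/s), one per V_h
    V_h: tuple[float, ...]
    condition_number: float


def build_affinity_system(entries) -> AffinitySystem:
    """Assemble one linear equation per holding potential.

    ``entries`` is a sequence of (StateFractions, inhibition_rate) pairs;
    at least 3 are required and the fraction rows must not be collinear.
    """
    entries = list(entries)
    if len(entries) < 3:
        raise ValueError(f"need >= 3 holding potentials, got {len(entries)}")
    F = np.array([sf.row for sf, _ in entries], dtype=float)
    r = np.array([float(rate) for _, rate in entries])
    vhs = tuple(sf.V_h for sf, _ in entries)
    rank = np.linalg.matrix_rank(F, tol=1e-10)
    if rank < 3:
        # name the dependency: find a row expressible from the others
        for i in range(len(entries)):
            others = np.delete(F, i, axis=0)
            if np.linalg.matrix_rank(others, tol=1e-10) == rank:
                raise ValueError(
                    f"fraction rows are rank-deficient (rank {rank}): row for "
                    f"V_h={vhs[i]} mV is linearly dependent on the others"
                )
        raise ValueError(f"fraction rows are rank-deficient (rank {rank})")
    cond = float(np.linalg.cond(F[:, :3] if F.shape[0] == 3 else F))
    return AffinitySystem(coefficients=F, rates=r, V_h=vhs,
                          condition_number=cond)


@dataclass(frozen=True)
class AffinitySolution:
    """Lumped products q_S and the identifiable state-affinity ratios."""

    q_R: float
    q_FI: float
    q_SI: float
    ratio_FI: float  # k_FI / k_R
    ratio_SI: float  # k_SI / k_R
    residual_norm: float
    condition_number: float
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @property
    def q(self) -> np.ndarray:
        return np.array([self.q_R, self.q_FI, self.q_SI])


class StateAffinitySolver:
    """Solve F q = r for the lumped per-state association products.

    Exactly-determined (3 equation) systems are solved directly; systems
    with more holding potentials by ordinary least squares.  Negative
    solved rates are reported with a validity warning, not clipped; set
    ``nonnegative=True`` for a non-negativity-constrained least-squares
    variant (off by default to keep the unconstrained solve primary).

    Fitted attributes: ``q_``, ``ratio_FI_``, ``ratio_SI_``, ``residual_``,
    ``condition_number_``, ``solution_``.
    """

    def __init__(self, nonnegative: bool = False):
        self.nonnegative = nonnegative

    def get_params(self, deep: bool = True) -> dict:
        return {"nonnegative": self.nonnegative}

    def set_params(self, **params) -> "StateAffinitySolver":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, F, rates) -> "StateAffinitySolver":
        F = np.asarray(F, dtype=float)
        r = np.asarray(rates, dtype=float).ravel()
        if F.shape[0] != r.size or F.shape[1] != 3:
            raise ValueError("coefficient matrix must be (n, 3) with n rates")
        warns: list[str] = []
        if self.nonnegative:
            from scipy.optimize import nnls
            q, rnorm = nnls(F, r)
            residual = float(rnorm)
        elif F.shape[0] == 3:
            if abs(np.linalg.det(F)) < 1e-14:
                raise np.linalg.LinAlgError("singular 3x3 affinity system")
            q = np.linalg.solve(F, r)
            residual = 0.0
        else:
            q, res, rank, _ = np.linalg.lstsq(F, r, rcond=None)
            if rank < 3:
                raise np.linalg.LinAlgError("rank-deficient affinity system")
            residual = float(np.sqrt(res[0])) if res.size else float(
                np.linalg.norm(F @ q - r))
        if np.any(q < 0):
            warns.append(
                "negative solved rate(s) "
                f"{dict(zip(('q_R', 'q_FI', 'q_SI'), np.round(q, 6)))}; "
                "reported unclipped"
            )
        if q[0] == 0:
            raise ZeroDivisionError("q_R = 0: affinity ratios are undefined")
        self.q_ = q
        self.ratio_FI_ = float(q[1] / q[0])
        self.ratio_SI_ = float(q[2] / q[0])
        self.residual_ = residual
        self.condition_number_ = float(np.linalg.cond(F))
        self.solution_ = AffinitySolution(
            q_R=float(q[0]), q_FI=float(q[1]), q_SI=float(q[2]),
            ratio_FI=self.ratio_FI_, ratio_SI=self.ratio_SI_,
            residual_norm=residual, condition_number=self.condition_number_,
            warnings=tuple(warns),
        )
        return self


def solve_affinity(system: AffinitySystem,
                   nonnegative: bool = False) -> AffinitySolution:
    """Solve an assembled affinity system; see :class:`StateAffinitySolver`."""
    solver = StateAffinitySolver(nonnegative=nonnegative)
    solver.fit(system.coefficients, system.rates)
    return solver.solution_


# ---------------------------------------------------------------------------
# End-to-end synthetic recovery
# ---------------------------------------------------------------------------

#: Log-spaced repriming recovery durations (s) used by the synthetic loop.
DEFAULT_RECOVERY_TIMES = tuple(np.geomspace(2e-4, 8.0, 48))


def simulate_recovery_curve(
    model: ChannelModel,
    V_h: float,
    recovery_times=DEFAULT_RECOVERY_TIMES,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> RecoveryCurve:
    """Simulate the drug-free double-pulse repriming protocol at one V_h."""
    proto = repriming_protocol(V_h, recovery_times)
    fam = run_protocol(model, proto, noise_sd=noise_sd, seed=seed)
    return RecoveryCurve(V_h=V_h, times=fam.axis_values,
                         i2_over_i1con=fam.peaks_norm)


@dataclass(frozen=True)
class EndToEndResult:
    solution: AffinitySolution
    fractions: tuple[StateFractions, ...]
    diary_taus: tuple[float, ...]
    rates: tuple[float, ...]
    true_ratio_FI: float
    true_ratio_SI: float


def recover_ratios_end_to_end(
    model: ChannelModel,
    seed: int = 0,
    v_holds=(-60.0, -80.0, -100.0),
    noise_sd: float = 0.0,
    schedule: InhibitorSchedule | None = None,
    diary_duration: float = 1600.0,
    test_interval: float = 2.0,
    recovery_times=DEFAULT_RECOVERY_TIMES,
    diary_k_off: float = 1e-5,
    n_replicates: int = 6,
    diary_dt: float = 0.5,
) -> EndToEndResult:
    """Simulate, fit, decompose and solve: the full synthetic pipeline.

    For each holding potential, (a) the drug-free double-pulse repriming
    protocol is simulated and decomposed into R/FI/SI state fractions, and
    (b) an inhibition diary under a linearly ramping inhibitor is simulated
    and fitted with the squared exponential.  Under the ramp x(t) = rho*t
    the survival of unbound channels is exp(-k_eff rho t^2 / 2), so the
    rate entering the affinity system is taken as 1/tau^2 (the common
    factor rho/2 cancels in the ratios).

    The diary uses the slow-unbinding regime in which the onset analysis is
    valid: ``diary_k_off`` far below 1/tau_onset, and a ramp slow enough
    that the binding hazard stays well under the gating relaxation rates
    (the quasi-equilibrium assumption behind the state-fraction model).

    With measurement noise, ``n_replicates`` independent replicates are
    simulated per holding potential; state fractions are averaged and the
    median inhibition rate is used, mirroring the use of median rates and
    multi-cell averages in practice.  Noise-free runs use one replicate.

    Returns the estimated solution alongside the generator's true ratios.
    """
    if schedule is None:
        schedule = InhibitorSchedule(shape="ramp", onset_time=0.0,
                                     ramp_rate=2.5e-6, plateau=1.0)
    from dataclasses import replace as _replace
    diary_model = _replace(model, k_off=diary_k_off)

    n_reps = n_replicates if noise_sd > 0 else 1
    n_pulses = int(round(diary_duration / test_interval))
    entries = []
    med_taus = []
    children = np.random.SeedSequence(seed).spawn(2 * len(v_holds) * n_reps)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in children]
    for i, vh in enumerate(v_holds):
        curves = []
        taus = []
        for r in range(n_reps):
            s_rec, s_diary = child_seeds[2 * (i * n_reps + r):
                                         2 * (i * n_reps + r) + 2]
            curve = simulate_recovery_curve(model, vh, recovery_times,
                                            noise_sd=noise_sd, seed=s_rec)
            curves.append(curve.i2_over_i1con)
            diary = simulate_inhibition_diary(
                diary_model, vh, schedule, test_interval=test_interval,
                n_pulses=n_pulses, seed=s_diary, noise_sd=noise_sd,
                dt=diary_dt,
            )
            t_on, y_on = diary.onset_series()
            taus.append(fit_exponential(t_on, y_on, "squared").tau)
        # replicate curves are averaged pointwise before the fit, the way
        # multi-cell recovery curves are averaged before display/fitting
        mean_curve = RecoveryCurve(vh, np.asarray(recovery_times, dtype=float),
                                   np.mean(curves, axis=0))
        fractions = decompose_states(mean_curve)
        tau_med = float(np.median(taus))
        med_taus.append(tau_med)
        entries.append((fractions, 1.0 / tau_med**2))

    system = build_affinity_system(entries)
    solution = solve_affinity(system)
    k = model.k_assoc
    return EndToEndResult(
        solution=solution,
        fractions=tuple(sf for sf, _ in entries),
        diary_taus=tuple(med_taus),
        rates=tuple(system.rates),
        true_ratio_FI=k["FI"] / k["R"],
        true_ratio_SI=k["SI"] / k["R"],
    )
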