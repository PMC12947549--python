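"""Terminal stress relaxation of dynamic networks under competition.

Relaxation time tau is extracted three ways that agree for networks
dominated by a single dissociative exchange process:

* crossover of storage and loss moduli in a frequency sweep
  (tau = 1/omega_c; exact for a single-mode Maxwell element),
* Kohlrausch-Williams-Watts (stretched-exponential) fit of the stress
  relaxation curve  G(t)/G0 = exp(-(t/tau)^beta),  0 < beta <= 1,
* the single-element Maxwell fit, i.e. KWW with beta fixed at 1.

The dependence of tau on competitor concentration is described by a
Langmuir-type decay with a single fitted parameter tau_min:
competitor binding lowers the fraction of elastically active chains
nu_e, and tau interpolates between its uninhibited value tau0 (full
occupancy of cross-linking sites by the network) and an asymptotic
floor tau_min as nu_e -> 0.  The default "occupancy" variant

    tau([C]) = tau0 - (tau0 - tau_min) * (1 - nu_e([C]) / nu_e(0))

guarantees tau(0) = tau0 and tau -> tau_min with vanishing nu_e; an
"as_printed" variant using the bracket 2*nu_e/N_XL (clipped to [0, 1])
is retained for comparison with the literature form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .binding import BindingSystem, NetworkSpec
from .elasticity import Convention, predict_titration
from .errors import ConvergenceError, ValidationError

__all__ = [
    "FrequencySweep",
    "StressRelaxationCurve",
    "CrossoverResult",
    "KWWFit",
    "LangmuirDecayModel",
    "crossover_tau",
    "fit_kww",
    "fit_maxwell",
    "tau_decay",
    "fit_tau_min",
]


@dataclass(frozen=True)
class FrequencySweep:
    """Small-amplitude oscillatory shear sweep: G'(omega), G''(omega)."""

    omega: np.ndarray       # rad/s, strictly increasing
    g_storage: np.ndarray   # Pa
    g_loss: np.ndarray      # Pa

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        gs = np.asarray(self.g_storage, dtype=float)
        gl = np.asarray(self.g_loss, dtype=float)
        if not (omega.shape == gs.shape == gl.shape) or omega.ndim != 1:
            raise ValidationError("omega, g_storage, g_loss must be equal-length 1-D arrays")
        if np.any(omega <= 0) or np.any(np.diff(omega) <= 0):
            raise ValidationError("omega must be strictly increasing and > 0")
        if np.any(gs < 0) or np.any(gl < 0):
            raise ValidationError("moduli must be >= 0")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "g_storage", gs)
        object.__setattr__(self, "g_loss", gl)


@dataclass(frozen=True)
class StressRelaxationCurve:
    """Relaxation modulus G(t); g0 defaults to the first sample."""

    time: np.ndarray   # s
    g_t: np.ndarray    # Pa (or already normalized)
    g0: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        g = np.asarray(self.g_t, dtype=float)
        if t.shape != g.shape or t.ndim != 1:
            raise ValidationError("time and g_t must be equal-length 1-D arrays")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("time must be strictly increasing and >= 0")
        if np.any(g < 0):
            raise ValidationError("g_t must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "g_t", g)

    @property
    def normalized(self) -> np.ndarray:
        g0 = self.g0 if self.g0 is not None else self.g_t[0]
        if g0 <= 0:
            raise ValidationError("g0 must be > 0 to normalize")
        return self.g_t / g0


@dataclass(frozen=True)
class CrossoverResult:
    """Location of the G' = G'' crossover, or its absence."""

    found: bool
    omega_c: float | None = None
    tau: float | None = None


def crossover_tau(sweep: FrequencySweep) -> CrossoverResult:
    """Locate the lowest-frequency G'/G'' crossover; tau = 1/omega_c.

    Interpolation is log-linear in both frequency and modulus, the
    coordinates in which a Maxwell element is exactly straight
    (log G' - log G'' = log(omega tau)).  The root of log G' - log G''
    around the lowest-frequency sign change is located by a local
    straight-line regression over a few neighbouring points, which is
    exact on noiseless Maxwell data and averages down point noise on
    measured sweeps.  A sweep without a sign change returns
    ``found=False`` rather than raising: gels probed above their
    terminal regime simply show G' > G'' everywhere.
    """
    with np.errstate(divide="ignore"):
        delta = np.log(sweep.g_storage) - np.log(sweep.g_loss)
    finite = np.isfinite(delta)
    if not np.any(finite):
        return CrossoverResult(found=False)
    logw = np.log(sweep.omega)

    exact = np.flatnonzero(finite & (delta == 0.0))
    exact_logw = logw[exact[0]] if exact.size else np.inf

    bracket = None  # lowest-frequency strict sign change
    for i in range(len(delta) - 1):
        if not (finite[i] and finite[i + 1]):
            continue
        if delta[i] == 0.0 or delta[i + 1] == 0.0:
            continue
        if np.sign(delta[i]) != np.sign(delta[i + 1]):
            bracket = i
            break

    if bracket is None:
        if exact.size:
            omega_c = float(np.exp(exact_logw))
            return CrossoverResult(found=True, omega_c=omega_c,
                                   tau=1.0 / omega_c)
        return CrossoverResult(found=False)

    i = bracket
    frac = delta[i] / (delta[i] - delta[i + 1])
    estimate = logw[i] + frac * (logw[i + 1] - logw[i])

    # regression window: the contiguous run around the bracket where
    # G'/G'' stays within a factor e^2 of unity (|delta| <= 2), roughly
    # a decade either side of the crossover where near-Maxwellian
    # sweeps are log-linear
    lo = i
    while lo > 0 and finite[lo - 1] and abs(delta[lo - 1]) <= 2.0:
        lo -= 1
    hi = i + 1
    while hi < len(delta) - 1 and finite[hi + 1] and abs(delta[hi + 1]) <= 2.0:
        hi += 1
    window = np.arange(lo, hi + 1)
    window = window[finite[window]]
    if window.size >= 3:
        slope, intercept = np.polyfit(logw[window], delta[window], 1)
        if slope != 0.0:
            root = -intercept / slope
            if logw[window[0]] <= root <= logw[window[-1]]:
                estimate = root
    crossing = min(estimate, exact_logw)
    omega_c = float(np.exp(crossing))
    return CrossoverResult(found=True, omega_c=omega_c, tau=1.0 / omega_c)


@dataclass(frozen=True)
class KWWFit:
    """Stretched-exponential fit parameters and residual."""

    tau_kww: float
    beta: float
    g0_fit: float
    rss: float


def _kww_initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # log(-log y) = beta*log t - beta*log tau for the noiseless curve
    mask = (y > 1e-12) & (y < 1.0 - 1e-12) & (t > 0)
    if mask.sum() >= 2:
        x = np.log(t[mask])
        z = np.log(-np.log(y[mask]))
        beta, intercept = np.polyfit(x, z, 1)
        if 0.05 <= beta <= 1.5:
            tau = float(np.exp(-intercept / beta))
            return max(tau, 1e-9), float(np.clip(beta, 0.05, 1.0))
    # fall back to the 1/e crossing
    idx = int(np.argmin(np.abs(y - np.exp(-1.0))))
    return max(float(t[idx]), 1e-9), 0.9


def fit_kww(curve: StressRelaxationCurve,
            fix_beta: float | None = None) -> KWWFit:
    """Least-squares KWW fit of a stress relaxation curve.

    Fits ``G(t) = g0_fit * exp(-(t/tau)^beta)`` with bounds tau > 0,
    beta in (0, 1]; ``fix_beta=1`` yields the single-element Maxwell
    fit.  Requires at least 5 points spanning one decade of decay.
    """
    t, g = curve.time, curve.g_t
    if len(t) < 5:
        raise ValidationError("need at least 5 points for a KWW fit")
    y = curve.normalized
    if np.min(y) > 0.1 * np.max(y):
        raise ValidationError(
            "relaxation curve must span at least one decade of decay")
    g0_scale = curve.g0 if curve.g0 is not None else g[0]
    tau0, beta0 = _kww_initial_guess(t, y)

    if fix_beta is not None:
        if not 0.0 < fix_beta <= 1.0:
            raise ValidationError("fix_beta must lie in (0, 1]")

        def model(tt, tau, amp):
            return amp * np.exp(-np.power(tt / tau, fix_beta))

        p0 = [tau0, 1.0]
        bounds = ([1e-12, 1e-12], [np.inf, np.inf])
    else:
        def model(tt, tau, beta, amp):
            return amp * np.exp(-np.power(tt / tau, beta))

        p0 = [tau0, beta0, 1.0]
        bounds = ([1e-12, 1e-6, 1e-12], [np.inf, 1.0, np.inf])

    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError as exc:
        resid = float(np.sum((model(t, *p0) - y) ** 2))
        raise ConvergenceError(f"KWW fit failed to converge: {exc}",
                               residual=resid) from exc
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    if fix_beta is not None:
        tau, amp = popt
        beta = float(fix_beta)
    else:
        tau, beta, amp = popt
    return KWWFit(tau_kww=float(tau), beta=float(beta),
                  g0_fit=float(amp * g0_scale), rss=rss)


def fit_maxwell(curve: StressRelaxationCurve) -> KWWFit:
    """Single-element Maxwell fit (KWW with beta fixed at 1)."""
    return fit_kww(curve, fix_beta=1.0)


@dataclass(frozen=True)
class LangmuirDecayModel:
    """Langmuir-type interpolation of tau between tau0 and tau_min."""

    tau0: float
    tau_min: float
    variant: str = "occupancy"

    def __post_init__(self) -> None:
        if self.variant not in ("occupancy", "as_printed"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if not self.tau0 > self.tau_min >= 0.0:
            raise ValidationError(
                f"need tau0 > tau_min >= 0, got tau0={self.tau0}, tau_min={self.tau_min}")


def tau_decay(model: LangmuirDecayModel, nu_e: np.ndarray | float,
              network: NetworkSpec | None = None,
              nu_e0: float | None = None) -> np.ndarray:
    """Relaxation time(s) for active-chain density/ies ``nu_e`` (M).

    occupancy (default): fraction of lost chains 1 - nu_e/nu_e(0) drives
    tau from tau0 down to tau_min; ``nu_e0`` defaults to the largest
    supplied value (the uninhibited condition of the series).

    as_printed: tau = tau0 - (tau0 - tau_min) * (2 nu_e / n_xl), bracket
    clipped to [0, 1]; requires ``network`` for n_xl.
    """
    nu = np.atleast_1d(np.asarray(nu_e, dtype=float))
    if np.any(nu < 0):
        raise ValidationError("nu_e must be >= 0")
    if model.variant == "occupancy":
        ref = float(np.max(nu)) if nu_e0 is None else float(nu_e0)
        if ref <= 0:
            return np.full_like(nu, model.tau_min)
        lost = np.clip(1.0 - nu / ref, 0.0, 1.0)
        return model.tau0 - (model.tau0 - model.tau_min) * lost
    if network is None:
        raise ValidationError("as_printed variant requires a NetworkSpec")
    occ = np.clip(2.0 * nu / network.n_xl, 0.0, 1.0)
    return model.tau0 - (model.tau0 - model.tau_min) * occ


def fit_tau_min(conc: np.ndarray, tau_obs: np.ndarray,
                binding: BindingSystem, network: NetworkSpec, tau0: float,
                convention: Convention | str = Convention.BONDED_ARM,
                variant: str = "occupancy") -> tuple[LangmuirDecayModel, float]:
    """Fit the single free parameter tau_min of the Langmuir decay.

    nu_e at each concentration comes from the forward elasticity chain;
    tau0 is the measured uninhibited relaxation time.  Returns the
    fitted model and the residual sum of squares.
    """
    conc = np.asarray(conc, dtype=float)
    tau_obs = np.asarray(tau_obs, dtype=float)
    if conc.shape != tau_obs.shape or conc.size < 2:
        raise ValidationError("need >= 2 (conc, tau) observations")
    if np.unique(conc).size < 2:
        raise ValidationError("degenerate data: all concentrations identical")
    if tau0 <= 0:
        raise ValidationError("tau0 must be > 0")

    preds = predict_titration(binding, network, conc, convention=convention)
    nu = np.array([pr.nu_e for pr in preds])
    nu0 = predict_titration(binding, network, [0.0], convention=convention)[0].nu_e

    def rss(tau_min: float) -> float:
        m = LangmuirDecayModel(tau0=tau0, tau_min=tau_min, variant=variant)
        pred = tau_decay(m, nu, network=network, nu_e0=nu0)
        return float(np.sum((pred - tau_obs) ** 2))

    res = minimize_scalar(rss, bounds=(0.0, tau0 * (1 - 1e-12)),
                          method="bounded",
                          options={"xatol": tau0 * 1e-10})
    tau_min = float(res.x)
    return (LangmuirDecayModel(tau0=tau0, tau_min=tau_min, variant=variant),
            float(res.fun))
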