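"""Forward models for 1:1 binding under partial mass-transport limitation.

The working model is the quasi-steady-state (QSS) reduction of the
two-compartment transport/binding system.  With the surface-compartment
analyte balance set to zero, complex formation in response units obeys a
single ODE:

    dR/dt = (ka·[A0]·(Rmax − R) − kd·R) / (1 + ka·(Rmax − R)/kM)

where ka (1/M/s) and kd (1/s) are the association/dissociation rate
constants, [A0] the active bulk analyte concentration (M; zero during the
dissociation phase), Rmax the saturating response (RU) and kM the
mass-transport coefficient rescaled to RU/(M·s).  As kM → ∞ the model
collapses to the ideal Langmuir binding curve, for which closed forms exist
and serve as test oracles.

The unreduced two-compartment system is kept as an independent reference:

    hdiff·d[As]/dt = kM_linear·([A0] − [As]) − (binding flux)
    dAB/dt         = ka·[As]·(Bmax − AB) − kd·AB

with [As] the surface-compartment analyte concentration and AB the complex
density; it is integrated with a stiff solver and used to validate the QSS
approximation, never for inference.

Curves are evaluated by classical fixed-step fourth-order Runge-Kutta with
the data timestamps as integration knots (no interpolation error at
likelihood evaluation points).  The inner kernel is numba-compiled because
posterior sampling evaluates on the order of 10^5 curves per fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

__all__ = [
    "KineticState",
    "PhaseGrid",
    "TwoCompartmentState",
    "qss_rate",
    "predict_sensorgram",
    "equilibrium_response",
    "langmuir_closed_form",
    "two_compartment_rhs",
    "solve_two_compartment",
]

#: Tolerated overshoot of R above Rmax, relative to Rmax, before a state is
#: declared outside the model domain.
RMAX_OVERSHOOT_TOL = 1e-9

#: Default RK4 substeps between consecutive data timestamps.
DEFAULT_RK4_SUBSTEPS = 4


class ModelDomainError(ValueError):
    """Model evaluated outside its domain (e.g. R > Rmax beyond tolerance)."""


class IntegrationError(RuntimeError):
    """Non-finite state encountered during ODE integration."""


@dataclass(frozen=True)
class KineticState:
    """Kinetic/measurement parameter vector θ for one sensorgram.

    Concentrations are molar internally; the sampler-facing nM scale is
    converted in :mod:`sprbayes.inference` only.

    Attributes
    ----------
    ka : float
        Association rate constant (1/M/s).
    kd : float
        Dissociation rate constant (1/s).
    A0 : float
        Active bulk analyte concentration (M).
    Rmax : float
        Saturating response (RU).
    R0 : float
        Response at the start of the dissociation phase (RU).  A free
        parameter, not pinned to the association endpoint.
    sigma2 : float
        Measurement-noise variance (RU²).
    """

    ka: float
    kd: float
    A0: float
    Rmax: float
    R0: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self):
        for name in ("ka", "kd", "A0", "Rmax", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.R0 < 0:
            raise ValueError("R0 must be nonnegative")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant kd/ka (M)."""
        return self.kd / self.ka


@dataclass(frozen=True)
class PhaseGrid:
    """Ordered timestamps split into association and dissociation phases.

    Association covers ``[0, injection_stop)``, dissociation
    ``[injection_stop, end]``; the dissociation clock restarts at zero so
    the initial condition R0 applies exactly at ``injection_stop``.
    """

    times: np.ndarray
    injection_stop: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("times must be a nonempty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def assoc_times(self) -> np.ndarray:
        """Association-phase timestamps (phase clock = absolute time)."""
        return self.times[self.times < self.injection_stop]

    @property
    def diss_times(self) -> np.ndarray:
        """Dissociation-phase timestamps on the restarted phase clock."""
        return self.times[self.times >= self.injection_stop] - self.injection_stop


@dataclass(frozen=True)
class TwoCompartmentState:
    """State/parameters of the unreduced two-compartment reference system."""

    As: float          # surface-compartment analyte concentration (M)
    AB: float          # complex density, response-scaled (RU)
    Bmax: float        # total ligand, response-scaled (RU)
    A0_bulk: float     # bulk analyte concentration (M)
    hdiff: float       # diffusion-layer height (m)
    kM_linear: float   # transport coefficient (m/s)
    response_scale: float = 1.0   # RU per (mol/m^2) of complex

    def __post_init__(self):
        if self.hdiff <= 0:
            raise ValueError("hdiff must be strictly positive")
        if self.As < 0:
            raise ValueError("As must be nonnegative")
        if not 0 <= self.AB <= self.Bmax * (1 + 1e-12):
            raise ValueError("require 0 <= AB <= Bmax")


# ---------------------------------------------------------------------------
# QSS rate and RK4 kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _qss_rate(R, ka, kd, A0, Rmax, kM):
    free = Rmax - R
    if free < 0.0:
        free = 0.0   # denominator guard for tiny numerical overshoot
    return (ka * A0 * (Rmax - R) - kd * R) / (1.0 + ka * free / kM)


@njit(cache=True)
def _integrate_phase(out, t, R_init, ka, kd, A0, Rmax, kM, substeps):
    """Fixed-step RK4 from phase clock 0 to each timestamp in ``t``.

    Returns 0 on success, 1 if the state went non-finite.
    """
    R = R_init
    t_prev = 0.0
    for i in range(t.shape[0]):
        dt_total = t[i] - t_prev
        if dt_total > 0.0:
            h = dt_total / substeps
            for _ in range(substeps):
                k1 = _qss_rate(R, ka, kd, A0, Rmax, kM)
                k2 = _qss_rate(R + 0.5 * h * k1, ka, kd, A0, Rmax, kM)
                k3 = _qss_rate(R + 0.5 * h * k2, ka, kd, A0, Rmax, kM)
                k4 = _qss_rate(R + h * k3, ka, kd, A0, Rmax, kM)
                R = R + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not np.isfinite(R):
                return 1
        out[i] = R
        t_prev = t[i]
    return 0


@njit(cache=True)
def _predict_curve(t_assoc, t_diss, ka, kd, A0, Rmax, R0, kM, substeps):
    """Predict the two-phase sensorgram; NaN-filled on integration failure."""
    n_a = t_assoc.shape[0]
    n_d = t_diss.shape[0]
    out = np.empty(n_a + n_d)
    status = 0
    if n_a > 0:
        status = _integrate_phase(out[:n_a], t_assoc, 0.0, ka, kd, A0, Rmax, kM, substeps)
    if status == 0 and n_d > 0:
        status = _integrate_phase(out[n_a:], t_diss, R0, ka, kd, 0.0, Rmax, kM, substeps)
    if status != 0:
        out[:] = np.nan
    return out


@njit(cache=True)
def _loglik_kernel(t_assoc, y_assoc, t_diss, y_diss,
                   ka, kd, A0, Rmax, R0, sigma2, kM, substeps):
    """Gaussian log-likelihood of a two-phase sensorgram in one call.

    Returns -inf on integration failure or if the initial condition R0
    exceeds Rmax beyond tolerance (proposals outside the model domain are
    rejected rather than raising).
    """
    if R0 > Rmax * (1.0 + RMAX_OVERSHOOT_TOL):
        return -np.inf
    n = t_assoc.shape[0] + t_diss.shape[0]
    ssr = 0.0
    tmp_a = np.empty(t_assoc.shape[0])
    if t_assoc.shape[0] > 0:
        if _integrate_phase(tmp_a, t_assoc, 0.0, ka, kd, A0, Rmax, kM, substeps) != 0:
            return -np.inf
        for i in range(t_assoc.shape[0]):
            d = y_assoc[i] - tmp_a[i]
            ssr += d * d
    tmp_d = np.empty(t_diss.shape[0])
    if t_diss.shape[0] > 0:
        if _integrate_phase(tmp_d, t_diss, R0, ka, kd, 0.0, Rmax, kM, substeps) != 0:
            return -np.inf
        for i in range(t_diss.shape[0]):
            d = y_diss[i] - tmp_d[i]
            ssr += d * d
    return -0.5 * ssr / sigma2 - 0.5 * n * np.log(2.0 * np.pi * sigma2)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def qss_rate(R: float, theta: KineticState, kM: float, phase: str = "association") -> float:
    """Instantaneous QSS binding rate dR/dt (RU/s) at response level R.

    During dissociation the bulk concentration is zero.  R may exceed Rmax
    only within a relative tolerance of 1e-9 (numerical overshoot); beyond
    that the state is outside the model domain.
    """
    if phase not in ("association", "dissociation"):
        raise ValueError(f"unknown phase {phase!r}")
    if R > theta.Rmax * (1 + RMAX_OVERSHOOT_TOL):
        raise ModelDomainError(f"R={R} exceeds Rmax={theta.Rmax} beyond tolerance")
    A0 = theta.A0 if phase == "association" else 0.0
    return float(_qss_rate(R, theta.ka, theta.kd, A0, theta.Rmax, kM))


def predict_sensorgram(
    theta: KineticState,
    kM: float,
    grid: PhaseGrid,
    rk4_substeps: int = DEFAULT_RK4_SUBSTEPS,
) -> np.ndarray:
    """Noise-free model curve r(t, θ) at every grid timestamp (RU).

    Association starts from R = 0 at phase clock zero; dissociation starts
    from the free parameter R0 at the injection stop.  Classical RK4 with
    ``rk4_substeps`` substeps between consecutive timestamps; timestamps
    are integration knots, so returned values carry no interpolation error.
    """
    if rk4_substeps < 1:
        raise ValueError("rk4_substeps must be >= 1")
    curve = _predict_curve(
        np.ascontiguousarray(grid.assoc_times, dtype=float),
        np.ascontiguousarray(grid.diss_times, dtype=float),
        theta.ka, theta.kd, theta.A0, theta.Rmax, theta.R0, kM,
        rk4_substeps,
    )
    if not np.all(np.isfinite(curve)):
        raise IntegrationError(f"non-finite state while integrating theta={theta}")
    return curve


def equilibrium_response(theta: KineticState) -> float:
    """Steady-state response Req = Rmax·A0/(A0 + KD) in RU.

    The unique root of the QSS rate numerator; independent of kM (transport
    changes the approach speed, not the equilibrium).
    """
    return theta.Rmax * theta.A0 / (theta.A0 + theta.kd / theta.ka)


def langmuir_closed_form(theta: KineticState, t, phase: str = "association"):
    """Ideal (kM → ∞) Langmuir binding curve, used as an analytic oracle.

    Association: Req·(1 − exp(−(ka·A0 + kd)·t)); dissociation: R0·exp(−kd·t)
    on the restarted phase clock.
    """
    t = np.asarray(t, dtype=float)
    if phase == "association":
        req = equilibrium_response(theta)
        return req * (1.0 - np.exp(-(theta.ka * theta.A0 + theta.kd) * t))
    if phase == "dissociation":
        return theta.R0 * np.exp(-theta.kd * t)
    raise ValueError(f"unknown phase {phase!r}")


def two_compartment_rhs(state: TwoCompartmentState, ka: float, kd: float):
    """Time derivatives (d[As]/dt in M/s, dAB/dt in RU/s) of the full system.

    The binding flux in RU/s is converted back to mol/(m²·s) through the
    response scale before entering the surface-compartment mass balance;
    with ``response_scale`` RU per mol/m², the flux divisor is
    ``hdiff · response_scale`` (and the QSS fixed point of this system
    reproduces the reduced single-ODE model exactly).
    """
    B = state.Bmax - state.AB
    dAB = ka * state.As * B - kd * state.AB            # RU/s
    # mol/(m^2 s) consumed by binding = dAB / response_scale; spread over
    # hdiff (m) of solution at 1000*As mol/m^3 per molar.
    dAs = (state.kM_linear * (state.A0_bulk - state.As)
           - dAB / (1000.0 * state.response_scale)) / state.hdiff
    return dAs, dAB


def solve_two_compartment(
    theta: KineticState,
    grid: PhaseGrid,
    hdiff: float,
    kM_linear: float,
    response_scale: float,
    r0_continuous: bool = True,
) -> np.ndarray:
    """Integrate the unreduced two-compartment system over a two-phase grid.

    A stiff solver (LSODA) handles the fast surface-compartment relaxation
    (rate ~ kM_linear/hdiff).  The rescaled transport coefficient implied by
    the arguments is ``kM = kM_linear · 1000 · response_scale`` RU/(M·s).
    With ``r0_continuous`` the dissociation phase starts from the
    association endpoint state; otherwise from (As=0, AB=theta.R0).

    This is a validation reference for the QSS model, not an inference path.
    """
    if hdiff <= 0:
        raise ValueError("hdiff must be strictly positive")

    def rhs(t, y, A0_bulk):
        As, AB = y
        st = TwoCompartmentState(
            As=max(As, 0.0), AB=min(max(AB, 0.0), theta.Rmax), Bmax=theta.Rmax,
            A0_bulk=A0_bulk, hdiff=hdiff, kM_linear=kM_linear,
            response_scale=response_scale,
        )
        dAs, dAB = two_compartment_rhs(st, theta.ka, theta.kd)
        return [dAs, dAB]

    t_a = grid.assoc_times
    t_d = grid.diss_times
    out = np.empty(t_a.size + t_d.size)
    y_end = [0.0, 0.0]
    if t_a.size:
        sol = solve_ivp(rhs, (0.0, float(t_a[-1])), [0.0, 0.0], t_eval=t_a,
                        args=(theta.A0,), method="LSODA", rtol=1e-9, atol=1e-12)
        if not sol.success:
            raise IntegrationError(sol.message)
        out[:t_a.size] = sol.y[1]
        y_end = [sol.y[0, -1], sol.y[1, -1]]
    if t_d.size:
        if r0_continuous and t_a.size:
            # carry the association endpoint through the (short) gap to the
            # injection stop, then continue with zero bulk concentration
            gap = float(grid.injection_stop - grid.assoc_times[-1])
            if gap > 0:
                sol = solve_ivp(rhs, (0.0, gap), y_end, args=(theta.A0,),
                                method="LSODA", rtol=1e-9, atol=1e-12)
                if not sol.success:
                    raise IntegrationError(sol.message)
                y_end = [sol.y[0, -1], sol.y[1, -1]]
            y0 = y_end
        else:
            y0 = [0.0, theta.R0]
        sol = solve_ivp(rhs, (0.0, float(t_d[-1])) if t_d[-1] > 0 else (0.0, 1e-9),
                        y0, t_eval=t_d if t_d[-1] > 0 else None,
                        args=(0.0,), method="LSODA", rtol=1e-9, atol=1e-12)
        if not sol.success:
            raise IntegrationError(sol.message)
        if t_d[-1] > 0:
            out[t_a.size:] = sol.y[1]
        else:
            out[t_a.size:] = y0[1]
    return out
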