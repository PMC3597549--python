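"""Stochastic excitatory/inhibitory competition among competing chains.

Each chain admitted to the competition carries eight state variables:
excitation ``E`` and inhibition ``I`` (bounded in (0, 1) by a logistic
sigmoid), adaptation ``A``, an Ornstein-Uhlenbeck noise signal ``U``, and
four leaky-integrated event rates — successes ``S``, collisions ``C_k``
(per rival), input events ``R`` and rediscoveries ``X``.  The rates obey
``tau * dx/dt = -x + sum_i delta(t - t_i)`` so each registered occurrence
bumps the variable by ``1/tau`` (per-second units) and the long-run mean
equals the occurrence rate.

Excitation and inhibition follow

    tau_ei dE_j/dt = -E_j + sig( w_s*S_j/(R+k) + w_x*X_j/(R+k)
                                 - w_ie*I_j + w_se*E_j*(1-A_j) + w_n*U_j )
    tau_ei dI_j/dt = -I_j + sig( w_c/(R+k) * sum_k C_jk
                                 + w_a*A_j - w_ei*E_j )

with ``sig`` the standard logistic sigmoid and ``k`` a small constant
preventing division by zero.  The divisive ``R + k`` factor normalises
the success, rediscovery and collision drives across presentation rates.
Collisions inhibit a chain in proportion to the rival's current
excitation, successes and rediscoveries excite it, and the adapting
self-excitation term ``w_se*E*(1-A)`` (with the saturating adaptation
dynamics ``tau_a dA/dt = E(1-2A) - A``) stabilises a freshly dominant
chain and then slowly gives way, which shapes the phase-duration
distribution.  The chain's own excitation
enters its inhibitory population with a negative sign, which keeps the
local inhibition away from saturation while a chain is dominant and
makes the winner-take-all states deeply bistable.  Noise enters the
excitatory population only; all noise paths are independent.

Integration is forward Euler at 1 ms with exact exponential decay of the
rate variables and square-root-of-step scaling of the OU increment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

from .assembly import ClosedChain

__all__ = [
    "DynamicsParams",
    "DynamicalState",
    "CompetitionDynamics",
    "ou_step",
    "adaptation_step",
    "sigmoid",
]


@dataclass
class DynamicsParams:
    """Dynamical-system parameters (defaults are the published set).

    Time constants are stored in ms.  ``sigma_noise`` is the stationary
    standard deviation of the OU noise signal ``U``.
    """

    tau_ei: float = 50.0
    tau_success: float = 1000.0
    tau_collision: float = 1000.0
    tau_noise: float = 500.0
    tau_adapt: float = 5000.0
    tau_rate: float = 5000.0
    tau_rediscovery: float = 5000.0
    w_inh_to_exc: float = 8.1
    w_exc_to_inh: float = 1.0
    w_self_exc: float = 3.2
    w_success: float = 3.8
    w_collision: float = 3.0
    w_noise: float = 3.4
    w_adapt: float = 0.1
    w_rediscovery: float = 7.0
    denom_const: float = 0.1
    integration_step: float = 1.0     # ms
    sigma_noise: float = 0.30         # OU stationary sd (see docs/methods.md)
    readout_filter_tau: float = 500.0  # ms; low-pass on E for the readout
    noise_on: bool = True
    adaptation_on: bool = True
    rediscovery_on: bool = True

    def __post_init__(self) -> None:
        for name in ("tau_ei", "tau_success", "tau_collision", "tau_noise",
                     "tau_adapt", "tau_rate", "tau_rediscovery"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.denom_const <= 0:
            raise ValueError("denom_const must be > 0")
        if self.integration_step > self.tau_ei / 10.0:
            raise ValueError("integration_step must be <= tau_ei / 10")


@dataclass
class DynamicalState:
    """Snapshot of one chain's eight state variables."""

    E: float
    I: float
    A: float
    U: float
    S: float
    C: dict
    R: float
    X: float


def sigmoid(x: float) -> float:
    """Standard logistic sigmoid, mapping the reals onto (0, 1)."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def ou_step(u: float, dt: float, tau: float, sigma: float, xi: float) -> float:
    """One Euler-Maruyama step of the mean-reverting noise process.

    ``xi`` is a standard-normal draw; the increment uses sqrt-of-step
    scaling so the stationary standard deviation is ``sigma`` for any step
    size small relative to ``tau``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return u - u * (dt / tau) + sigma * math.sqrt(2.0 * dt / tau) * xi


def adaptation_step(a: float, e: float, dt: float, tau: float) -> float:
    """One Euler step of the saturating adaptation dynamics.

    ``tau dA/dt = E (1 - 2A) - A``: adaptation rises while excitation is
    high (saturating at the equilibrium ``E / (1 + 2E) <= 1/3``) and
    decays towards zero while excitation is low.  The cap keeps the
    adapted self-excitation of a long-dominant chain above the level a
    freshly admitted rival can muster, so admission alone cannot unseat
    the incumbent.
    """
    return a + (dt / tau) * (e * (1.0 - 2.0 * a) - a)


@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


@njit(cache=True)
def _integrate_segment(E, I, A, U, F, S, R0, X, C, noise, n_steps, dt,
                       tau_ei, tau_a, tau_u, tau_f,
                       dec_s, dec_c, dec_r, dec_x,
                       w_ie, w_ei, w_se, w_s, w_c, w_n, w_a, w_x, kappa,
                       sigma, adapt_on,
                       g0, decim, rec_E, rec_F, rec_slot0):
    n = E.shape[0]
    newE = np.empty(n)
    newI = np.empty(n)
    rec = rec_slot0
    r = R0
    for s in range(n_steps):
        if (g0 + s) % decim == 0:
            for j in range(n):
                rec_E[rec, j] = E[j]
                rec_F[rec, j] = F[j]
            rec += 1
        for j in range(n):
            coll = 0.0
            for k in range(n):
                coll += C[j, k]
            norm = r + kappa
            a_j = A[j] if adapt_on else 0.0
            drive_e = (w_s * S[j] / norm + w_x * X[j] / norm
                       - w_ie * I[j] + w_se * E[j] * (1.0 - a_j)
                       + w_n * U[j])
            drive_i = -w_ei * E[j] + w_c * coll / norm + w_a * a_j
            newE[j] = E[j] + (dt / tau_ei) * (-E[j] + _sigmoid(drive_e))
            newI[j] = I[j] + (dt / tau_ei) * (-I[j] + _sigmoid(drive_i))
        for j in range(n):
            if adapt_on:
                A[j] = A[j] + (dt / tau_a) * (E[j] * (1.0 - 2.0 * A[j]) - A[j])
            U[j] = U[j] - U[j] * (dt / tau_u) \
                + sigma * math.sqrt(2.0 * dt / tau_u) * noise[s, j]
            E[j] = newE[j]
            I[j] = newI[j]
            F[j] = F[j] + (dt / tau_f) * (E[j] - F[j])
            S[j] *= dec_s
            X[j] *= dec_x
            for k in range(n):
                C[j, k] *= dec_c
        r *= dec_r
    return rec, r


class CompetitionDynamics:
    """Integrates the per-chain state variables over a simulation.

    Chains are added when admitted to the competition (all state variables
    start at zero) and removed when they die.  Impulses are registered at
    event onsets via the ``register_*`` methods; ``advance_to`` integrates
    the continuous dynamics between impulses and records decimated traces
    of ``E`` and its low-pass filtered version used by the readout.
    """

    def __init__(self, params: DynamicsParams, rng: np.random.Generator,
                 duration_ms: float, record_dt: float = 10.0):
        self.params = params
        self.rng = rng
        self.duration_ms = float(duration_ms)
        self.record_dt = float(record_dt)
        self.dt = params.integration_step
        self.decim = max(1, int(round(self.record_dt / self.dt)))
        self.n_samples = int(math.floor(duration_ms / self.record_dt)) + 1
        self.sample_times = np.arange(self.n_samples) * self.record_dt

        self.t = 0.0
        self._gstep = 0
        self.chains: list[ClosedChain] = []
        self._E: list[float] = []
        self._I: list[float] = []
        self._A: list[float] = []
        self._U: list[float] = []
        self._F: list[float] = []
        self._S: list[float] = []
        self._R: float = 0.0  # shared input-event rate
        self._X: list[float] = []
        self._C: np.ndarray = np.zeros((0, 0))
        # per-chain traces keyed by chain id
        self.trace_E: dict[int, np.ndarray] = {}
        self.trace_F: dict[int, np.ndarray] = {}
        self.history: list[ClosedChain] = []

    # -- population --------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.chains)

    def add_chain(self, chain: ClosedChain, t: Optional[float] = None) -> None:
        """Admit a chain; all dynamical variables are initialised to zero."""
        self.chains.append(chain)
        self.history.append(chain)
        for lst in (self._E, self._I, self._A, self._U, self._F,
                    self._S, self._X):
            lst.append(0.0)
        n = self.n
        C = np.zeros((n, n))
        C[:n - 1, :n - 1] = self._C
        self._C = C
        self.trace_E[chain.id] = np.full(self.n_samples, np.nan)
        self.trace_F[chain.id] = np.full(self.n_samples, np.nan)

    def remove_chain(self, chain: ClosedChain, t: Optional[float] = None) -> None:
        i = self.chains.index(chain)
        self.chains.pop(i)
        for lst in (self._E, self._I, self._A, self._U, self._F,
                    self._S, self._X):
            lst.pop(i)
        self._C = np.delete(np.delete(self._C, i, axis=0), i, axis=1)

    def state_of(self, chain: ClosedChain) -> DynamicalState:
        i = self.chains.index(chain)
        return DynamicalState(
            E=self._E[i], I=self._I[i], A=self._A[i], U=self._U[i],
            S=self._S[i],
            C={c.id: self._C[i, j] for j, c in enumerate(self.chains) if j != i},
            R=self._R, X=self._X[i])

    def set_state(self, chain: ClosedChain, **kwargs) -> None:
        """Override state variables (used to probe the attractor landscape)."""
        i = self.chains.index(chain)
        arrays = {"E": self._E, "I": self._I, "A": self._A, "U": self._U,
                  "F": self._F, "S": self._S, "X": self._X}
        for name, value in kwargs.items():
            if name == "R":  # shared across chains
                self._R = float(value)
            else:
                arrays[name][i] = float(value)

    # -- impulses (registered at event onsets) ------------------------------
    def register_success(self, chain: ClosedChain, t: float) -> None:
        i = self.chains.index(chain)
        self._S[i] += 1000.0 / self.params.tau_success

    def register_collision(self, c1: ClosedChain, c2: ClosedChain, t: float) -> None:
        """Record a mutual prediction of the same event.

        Both directed rates are bumped, each weighted by the *rival's*
        excitation at the collision instant, so the inhibitory effect of a
        collision on a chain is proportional to how excited the other
        chain currently is.
        """
        i = self.chains.index(c1)
        j = self.chains.index(c2)
        bump = 1000.0 / self.params.tau_collision
        self._C[i, j] += bump * self._E[j]
        self._C[j, i] += bump * self._E[i]

    def register_input_event(self, t: float) -> None:
        self._R += 1000.0 / self.params.tau_rate

    def register_rediscovery(self, chain: ClosedChain, t: float) -> None:
        if not self.params.rediscovery_on:
            return
        i = self.chains.index(chain)
        self._X[i] += 1000.0 / self.params.tau_rediscovery

    # listener aliases used by ChainAssembler
    on_success = register_success
    on_collision = register_collision
    on_rediscovery = register_rediscovery

    def on_input_event(self, t: float) -> None:
        self.register_input_event(t)

    def on_admitted(self, chain: ClosedChain, t: float) -> None:
        self.add_chain(chain, t)

    def on_removed(self, chain: ClosedChain, t: float) -> None:
        self.remove_chain(chain, t)

    # -- integration ---------------------------------------------------------
    def advance_to(self, t_target: float) -> None:
        """Integrate the dynamics from the current time up to ``t_target``."""
        if t_target < self.t - 1e-9:
            raise ValueError("cannot integrate backwards")
        n_steps = int(round((t_target - self.t) / self.dt))
        if n_steps <= 0:
            return
        p = self.params
        n = self.n
        dt = self.dt
        if n == 0:
            self._R *= math.exp(-n_steps * dt / p.tau_rate)
            self._gstep += n_steps
            self.t += n_steps * dt
            return
        E = np.array(self._E)
        I = np.array(self._I)
        A = np.array(self._A)
        U = np.array(self._U)
        F = np.array(self._F)
        S = np.array(self._S)
        X = np.array(self._X)
        C = self._C.copy()
        sigma = p.sigma_noise if p.noise_on else 0.0
        noise = (self.rng.standard_normal((n_steps, n)) if sigma > 0.0
                 else np.zeros((n_steps, n)))
        first_g = ((self._gstep + self.decim - 1) // self.decim) * self.decim
        last_g = self._gstep + n_steps - 1
        n_rec = 0 if first_g > last_g else (last_g - first_g) // self.decim + 1
        rec_E = np.empty((n_rec, n))
        rec_F = np.empty((n_rec, n))
        _, self._R = _integrate_segment(
            E, I, A, U, F, S, self._R, X, C, noise, n_steps, dt,
            p.tau_ei, p.tau_adapt, p.tau_noise, p.readout_filter_tau,
            math.exp(-dt / p.tau_success), math.exp(-dt / p.tau_collision),
            math.exp(-dt / p.tau_rate), math.exp(-dt / p.tau_rediscovery),
            p.w_inh_to_exc, p.w_exc_to_inh, p.w_self_exc, p.w_success,
            p.w_collision, p.w_noise, p.w_adapt, p.w_rediscovery,
            p.denom_const, sigma, p.adaptation_on,
            self._gstep, self.decim, rec_E, rec_F, 0)
        # scatter recorded samples into per-chain traces
        if n_rec:
            first = math.ceil(self._gstep / self.decim)
            idx = np.arange(first, first + n_rec)
            idx = idx[idx < self.n_samples]
            for j, chain in enumerate(self.chains):
                self.trace_E[chain.id][idx] = rec_E[:len(idx), j]
                self.trace_F[chain.id][idx] = rec_F[:len(idx), j]
        self._E, self._I, self._A, self._U, self._F = \
            list(E), list(I), list(A), list(U), list(F)
        self._S, self._X = list(S), list(X)
        self._C = C
        self._gstep += n_steps
        self.t += n_steps * dt

    def finalize(self) -> None:
        """Record the final sample at the end of the stimulus."""
        self.advance_to(self.duration_ms)
        g = self._gstep
        if g % self.decim == 0 and g // self.decim < self.n_samples:
            i = g // self.decim
            for j, chain in enumerate(self.chains):
                self.trace_E[chain.id][i] = self._E[j]
                self.trace_F[chain.id][i] = self._F[j]
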