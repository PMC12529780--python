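"""Magnetic-field rotational sampling (HRS) of RDCs.

The magnetic-field direction is represented by a two-united-atom molecule
(two CH3-like particles of 15.035 u joined by a rigid 0.153 nm bond) whose
rotation is propagated by Langevin stochastic dynamics.  A flat-bottom
restraint on the exponentially-memory-averaged coupling of every restrained
RDC biases the orientation distribution of this vector toward one that
reproduces the target couplings, without assuming any functional form for
the distribution.  Reported RDC values use the plain arithmetic time
average of P2 over all sampled orientations of all runs; the exponentially
damped average enters only the restraining forces, and the two are never
mixed.

Energies are in kJ/mol, couplings in Hz, the force constant in
kJ mol^-1 Hz^-2, lengths in nm and times in ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from rdcsampler.core_rdc import BOND_CLASSES, CONSTANTS, RDCTarget, legendre_p2
from rdcsampler.structure_io import RDCVector

__all__ = [
    "RestraintParams",
    "SimParams",
    "MFVState",
    "HRSResult",
    "restraint_energy",
    "restraint_force_dD",
    "update_exp_average",
    "p2_gradient",
    "mfv_force",
    "init_state",
    "langevin_step",
    "run_hrs",
]

_SHAKE_TOL = 1e-5  # relative bond-length precision enforced every step
_SHAKE_MAX_ITER = 1000


@dataclass
class RestraintParams:
    """Flat-bottom restraint parameters.

    K: force constant (kJ mol^-1 Hz^-2); dD_fb: flat-bottom half-width (Hz);
    dD_h: width of the harmonic band before the potential turns linear (Hz);
    tau_theta: memory relaxation time of the exponential average (ps).
    """

    K: float = 100.0
    dD_fb: float = 2.0
    dD_h: float = 1.0
    tau_theta: float = 10000.0

    def __post_init__(self):
        if self.K < 0 or self.dD_fb < 0 or self.dD_h <= 0 or self.tau_theta <= 0:
            raise ValueError("invalid restraint parameters")


@dataclass
class SimParams:
    """Stochastic-dynamics parameters for the magnetic-field vector."""

    dt: float = 0.002  # ps
    T: float = 308.0  # K
    gamma_friction: float = 2.4  # ps^-1
    n_steps: int = 5_000_000
    n_runs: int = 3
    seed: int = 0
    mass: float = 15.035  # u
    bond: float = 0.153  # nm

    def __post_init__(self):
        if self.dt <= 0 or self.T <= 0 or self.mass <= 0 or self.bond <= 0:
            raise ValueError("invalid simulation parameters")


@dataclass
class MFVState:
    """Positions/velocities of the two particles plus per-restraint averages."""

    r1: np.ndarray
    r2: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    p_bar: np.ndarray  # exponential averages of P2, one per restrained RDC
    step: int = 0

    @property
    def unit_vector(self) -> np.ndarray:
        d = self.r1 - self.r2
        return d / np.linalg.norm(d)

    @property
    def bond_length(self) -> float:
        return float(np.linalg.norm(self.r1 - self.r2))


def restraint_energy(d_bar, d0, params: RestraintParams):
    """Flat-bottom restraint energy in kJ/mol (vectorized over restraints).

    Zero for |d_bar - d0| <= dD_fb, half-harmonic over the next dD_h, and
    linear beyond, continuous with continuous first derivative at both
    junctions.
    """
    x = np.abs(np.asarray(d_bar, dtype=float) - d0) - params.dD_fb
    e = np.where(
        x <= 0.0,
        0.0,
        np.where(
            x <= params.dD_h,
            0.5 * params.K * x ** 2,
            params.K * params.dD_h * (x - 0.5 * params.dD_h),
        ),
    )
    return float(e) if np.ndim(d_bar) == 0 and np.ndim(d0) == 0 else e


def restraint_force_dD(d_bar, d0, params: RestraintParams):
    """Generalized force -dV/d(d_bar) in kJ mol^-1 Hz^-1 (vectorized)."""
    dev = np.asarray(d_bar, dtype=float) - d0
    x = np.abs(dev) - params.dD_fb
    mag = np.where(
        x <= 0.0,
        0.0,
        np.where(x <= params.dD_h, params.K * x, params.K * params.dD_h),
    )
    f = -np.sign(dev) * mag
    return float(f) if np.ndim(d_bar) == 0 and np.ndim(d0) == 0 else f


def update_exp_average(p_bar_prev, p_now, dt: float, tau: float):
    """Discrete exponential-memory average update (asymptotic form).

    ``p_bar_n = p_n (1 - exp(-dt/tau)) + exp(-dt/tau) p_bar_{n-1}``; the
    caller initializes ``p_bar_0`` to the first evaluated value.  This bare
    recursion carries an initialization weight ``exp(-t/tau)``; the engine
    itself restrains the weight-normalized average (NormalizedExpAverage),
    which this recursion approaches once t >> tau.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    w = math.exp(-dt / tau)
    return np.asarray(p_now) * (1.0 - w) + w * np.asarray(p_bar_prev)


class NormalizedExpAverage:
    """Exponential-memory running average with proper weight normalization.

    Implements the continuous definition
    ``P_bar(t) = (tau (1 - e^(-t/tau)))^-1 int_0^t e^(-(t-t')/tau) P(t') dt'``
    in discrete form: ``S_n = P_n + w S_{n-1}``, ``W_n = 1 + w W_{n-1}``,
    ``P_bar = S_n / W_n`` with ``w = exp(-dt/tau)``.  For t << tau this is
    the plain running mean of the history (no dead time from the arbitrary
    initial orientation); for t >> tau it coincides with the bare
    exponential recursion of ``update_exp_average``.
    """

    def __init__(self, p0, dt: float, tau: float):
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.w = math.exp(-dt / tau)
        self.s = np.array(p0, dtype=float, copy=True)
        self.wsum = 1.0

    def update(self, p_now) -> np.ndarray:
        self.s *= self.w
        self.s += p_now
        self.wsum = 1.0 + self.w * self.wsum
        return self.value

    @property
    def value(self) -> np.ndarray:
        return self.s / self.wsum


def p2_gradient(u_mfv: np.ndarray, u_rdc: np.ndarray, bond: float) -> np.ndarray:
    """Gradient of P2(cos theta) with respect to particle h1.

    ``dP/dr_h1 = 3 cos(theta) (u_rdc - cos(theta) u_mfv) / bond`` for the
    rigid magnetic-field vector; the gradient with respect to h2 is the
    negative.  ``u_rdc`` may be a single vector (3,) or a stack (N, 3).
    """
    u_rdc = np.asarray(u_rdc, dtype=float)
    single = u_rdc.ndim == 1
    uk = u_rdc[None, :] if single else u_rdc
    c = uk @ u_mfv
    g = 3.0 * c[:, None] * (uk - c[:, None] * u_mfv[None, :]) / bond
    return g[0] if single else g


def _restraint_arrays(vectors: Sequence[RDCVector],
                      targets: Sequence[RDCTarget]):
    """Split inputs into (all, restrained) arrays used by the engine."""
    if len(vectors) != len(targets):
        raise ValueError("vectors and targets must be index-aligned")
    u_all = np.array([v.u for v in vectors])
    dcr_all = np.array([BOND_CLASSES[v.bond_class].dc_r_hz for v in vectors])
    mask = np.array([t.restrained for t in targets], dtype=bool)
    d0 = np.array([t.d0 for t in targets])
    return u_all, dcr_all, d0, mask


def mfv_force(state: MFVState, vectors: Sequence[RDCVector],
              targets: Sequence[RDCTarget], params: RestraintParams,
              dt: float) -> Tuple[np.ndarray, np.ndarray]:
    """Restraining force on the two particles from the current averages.

    ``f_h1 = sum_k f_k Dc_k R_k (1 - exp(-dt/tau)) dP_k/dr_h1`` over the
    restrained RDCs, with f_k the flat-bottom generalized force evaluated
    at the exponentially averaged coupling; ``f_h2 = -f_h1``.
    """
    u_all, dcr_all, d0, mask = _restraint_arrays(vectors, targets)
    u_r, dcr_r, d0_r = u_all[mask], dcr_all[mask], d0[mask]
    if state.p_bar.shape != d0_r.shape:
        raise ValueError("state carries averages for a different restraint set")
    d_bar = dcr_r * state.p_bar
    fk = restraint_force_dD(d_bar, d0_r, params)
    dweight = 1.0 - math.exp(-dt / params.tau_theta)
    grad = p2_gradient(state.unit_vector, u_r, float(np.linalg.norm(state.r1 - state.r2)))
    f1 = (fk * dcr_r * dweight) @ grad
    return f1, -f1


def init_state(vectors: Sequence[RDCVector], targets: Sequence[RDCTarget],
               sim: SimParams, rng: np.random.Generator) -> MFVState:
    """Initial state: bond along +z, Maxwell velocities, averages at first P."""
    _, _, _, mask = _restraint_arrays(vectors, targets)
    u_r = np.array([v.u for v in vectors])[mask]
    half = 0.5 * sim.bond
    r1 = np.array([0.0, 0.0, half])
    r2 = np.array([0.0, 0.0, -half])
    sigma_v = math.sqrt(CONSTANTS.kB * sim.T / sim.mass)
    v1 = rng.normal(0.0, sigma_v, 3)
    v2 = rng.normal(0.0, sigma_v, 3)
    u_mfv = (r1 - r2) / sim.bond
    _rattle(v1, v2, u_mfv)
    p_bar = legendre_p2(u_r @ u_mfv) if mask.any() else np.empty(0)
    return MFVState(r1, r2, v1, v2, np.atleast_1d(p_bar).astype(float), 0)


def _shake(r1: np.ndarray, r2: np.ndarray, bond: float) -> None:
    """Iteratively restore |r1 - r2| = bond (in place)."""
    for _ in range(_SHAKE_MAX_ITER):
        d = r1 - r2
        dist = math.sqrt(float(d @ d))
        err = abs(dist - bond) / bond
        if err <= _SHAKE_TOL:
            return
        corr = 0.5 * (dist - bond) / dist * d
        r1 -= corr
        r2 += corr
    raise RuntimeError("SHAKE failed to converge within 1000 iterations")


def _rattle(v1: np.ndarray, v2: np.ndarray, u: np.ndarray) -> None:
    """Remove the bond-direction component of the relative velocity."""
    vr = float((v1 - v2) @ u)
    v1 -= 0.5 * vr * u
    v2 += 0.5 * vr * u


def _ou_coeffs(sim: SimParams) -> Tuple[float, float]:
    c1 = math.exp(-sim.gamma_friction * sim.dt)
    c2 = math.sqrt((1.0 - c1 * c1) * CONSTANTS.kB * sim.T / sim.mass)
    return c1, c2


def _step_core(r1, r2, v1, v2, f1, f2, dt, m, c1, c2, bond, xi) -> None:
    """Kick / drift / exact OU thermostat / drift, then SHAKE + RATTLE.

    Operates in place on the four coordinate arrays; ``xi`` holds six
    standard normal deviates for the thermostat.
    """
    half_dt = 0.5 * dt
    v1 += (half_dt / m) * f1
    v2 += (half_dt / m) * f2
    r1 += half_dt * v1
    r2 += half_dt * v2
    v1 *= c1
    v1 += c2 * xi[:3]
    v2 *= c1
    v2 += c2 * xi[3:]
    r1 += half_dt * v1
    r2 += half_dt * v2
    _shake(r1, r2, bond)
    d = r1 - r2
    u = d / math.sqrt(float(d @ d))
    _rattle(v1, v2, u)


def langevin_step(state: MFVState, force: Tuple[np.ndarray, np.ndarray],
                  sim: SimParams, rng: np.random.Generator) -> MFVState:
    """One constrained Langevin step (kick / drift / thermostat / drift).

    The force is evaluated by the caller at the current positions and held
    through the step; the Ornstein-Uhlenbeck velocity update is exact at any
    dt, so the force-free stationary distribution has Maxwell velocities at
    T and an isotropic bond orientation.  SHAKE restores the bond length and
    the velocity is projected onto the constraint surface afterwards.
    """
    c1, c2 = _ou_coeffs(sim)
    _step_core(state.r1, state.r2, state.v1, state.v2, force[0], force[1],
               sim.dt, sim.mass, c1, c2, sim.bond, rng.standard_normal(6))
    state.step += 1
    return state


@dataclass
class HRSResult:
    """Outcome of a set of magnetic-field-vector SD runs."""

    reported_d: np.ndarray  # Hz, plain time average over all runs, all targets
    per_run_d: np.ndarray  # (n_runs, n_targets) Hz
    traj: np.ndarray  # sampled mfv unit vectors, concatenated over runs
    trace_times: np.ndarray  # ps
    trace_d: np.ndarray  # (n_snapshots, n_targets) running plain averages, Hz
    seeds: List[int] = field(default_factory=list)

    @property
    def run_spread(self) -> np.ndarray:
        """Per-target standard deviation of the reported value across runs."""
        return self.per_run_d.std(axis=0, ddof=1)


def _mean_p_from_moment(m2: np.ndarray, u_all: np.ndarray) -> np.ndarray:
    """Plain-average P2 per target from the orientation second moment.

    mean_t P2(u_k . u(t)) = 3/2 u_k^T <u u^T> u_k - 1/2 exactly, so the
    engine only accumulates the 3x3 second moment.
    """
    return 1.5 * np.einsum("ki,ij,kj->k", u_all, m2, u_all) - 0.5


def run_hrs(vectors: Sequence[RDCVector], targets: Sequence[RDCTarget],
            restraint_params: Optional[RestraintParams] = None,
            sim_params: Optional[SimParams] = None,
            traj_stride: int = 20, trace_stride: int = 10000) -> HRSResult:
    """Run n_runs independent SD simulations and report averaged RDCs.

    Restraining forces act only on the restrained targets; RDC values are
    reported for every target from the plain arithmetic mean of P2 over all
    sampled steps of all runs.  Runs differ only by their seed
    (``seed + run_index``).
    """
    params = restraint_params or RestraintParams()
    sim = sim_params or SimParams()
    u_all, dcr_all, d0, mask = _restraint_arrays(vectors, targets)
    u_r, dcr_r, d0_r = u_all[mask], dcr_all[mask], d0[mask]
    n_restr = int(mask.sum())
    restrained = params.K > 0.0 and n_restr > 0
    dweight = 1.0 - math.exp(-sim.dt / params.tau_theta)
    ew = math.exp(-sim.dt / params.tau_theta)

    m2_total = np.zeros((3, 3))
    per_run_d = np.empty((sim.n_runs, len(targets)))
    traj_chunks = []
    trace_times = []
    trace_d = []
    seeds = [sim.seed + i for i in range(sim.n_runs)]

    c1, c2 = _ou_coeffs(sim)
    dt, m, bond = sim.dt, sim.mass, sim.bond
    chunk = 8192
    for run_idx, run_seed in enumerate(seeds):
        rng = np.random.default_rng(run_seed)
        state = init_state(vectors, targets, sim, rng)
        r1, r2, v1, v2 = state.r1, state.r2, state.v1, state.v2
        m2_run = np.zeros((3, 3))
        n_take = sim.n_steps // traj_stride
        traj = np.empty((n_take, 3))
        taken = 0
        # weight-normalized exponential memory average (Eq.-12/14 form):
        # s/wsum, with s and wsum updated recursively
        s_avg = state.p_bar.copy()
        wsum = 1.0
        u_buf = np.empty((chunk, 3))
        kd = dcr_r * dweight
        n = 0
        next_trace = trace_stride
        while n < sim.n_steps:
            n_sub = min(chunk, sim.n_steps - n)
            xi = rng.standard_normal((n_sub, 6))
            for j in range(n_sub):
                if restrained:
                    d = r1 - r2
                    u_mfv = d / math.sqrt(float(d @ d))
                    c = u_r @ u_mfv
                    if n + j > 0:
                        s_avg *= ew
                        s_avg += 1.5 * c * c - 0.5
                        wsum = 1.0 + ew * wsum
                    # flat-bottom generalized force, inlined from
                    # restraint_force_dD for the hot loop
                    dev = dcr_r * (s_avg / wsum) - d0_r
                    x = np.abs(dev) - params.dD_fb
                    mag = params.K * np.minimum(np.maximum(x, 0.0), params.dD_h)
                    fk = -np.sign(dev) * mag
                    coef = fk * kd * (3.0 * c)
                    f1 = (coef @ u_r - float(coef @ c) * u_mfv) / bond
                    _step_core(r1, r2, v1, v2, f1, -f1, dt, m, c1, c2, bond,
                               xi[j])
                else:
                    _step_core(r1, r2, v1, v2, _ZERO3, _ZERO3, dt, m, c1, c2,
                               bond, xi[j])
                d = r1 - r2
                u_buf[j] = d / math.sqrt(float(d @ d))
            m2_run += u_buf[:n_sub].T @ u_buf[:n_sub]
            idx0 = (-(n + 1)) % traj_stride  # first sampled step in chunk
            sampled = u_buf[idx0:n_sub:traj_stride]
            traj[taken:taken + sampled.shape[0]] = sampled
            taken += sampled.shape[0]
            n += n_sub
            if run_idx == 0 and (n >= next_trace or n == sim.n_steps):
                trace_times.append(n * sim.dt)
                trace_d.append(dcr_all * _mean_p_from_moment(m2_run / n, u_all))
                while next_trace <= n:
                    next_trace += trace_stride
        state.p_bar = s_avg / wsum
        state.step = sim.n_steps
        m2_total += m2_run
        per_run_d[run_idx] = dcr_all * _mean_p_from_moment(m2_run / sim.n_steps, u_all)
        traj_chunks.append(traj[:taken])

    m2_total /= sim.n_runs * sim.n_steps
    reported = dcr_all * _mean_p_from_moment(m2_total, u_all)
    return HRSResult(
        reported_d=reported,
        per_run_d=per_run_d,
        traj=np.concatenate(traj_chunks),
        trace_times=np.array(trace_times),
        trace_d=np.array(trace_d) if trace_d else np.empty((0, len(targets))),
        seeds=seeds,
    )


_ZERO3 = np.zeros(3)
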