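"""Bilinear neural dynamics, balloon hemodynamics and the 7T BOLD equation.

The neural model is the deterministic one-state bilinear form

    dx/dt = (A + sum_j u_j B(j)) x + C u

where A is the latent coupling (Hz), B(j) the modulation of coupling by input
channel j and C the driving influence of inputs on nodes.  Each node's
activity enters a standard balloon model (vasodilatory signal s, inflow f,
venous volume v, deoxyhemoglobin q) whose states map to percent BOLD signal
change through the static observation equation with field-strength-specific
constants (7 Tesla values by default).

Integration is fixed-step RK4 on a microtime grid (default 16 steps per
volume).  Flow, volume and dHb are integrated in log space so they remain
positive.  The batched entry point integrates many parameter sets against a
shared input, which is what makes finite-difference Jacobians cheap during
model inversion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

#: default microtime resolution (steps per acquired volume)
MICRO_PER_VOLUME = 16


@dataclass
class HemodynamicConfig:
    """Balloon-model and BOLD-equation constants for one node.

    The observation constants default to the 7T values (echo time 0.026 s,
    intra/extra-vascular ratio 0.026, intravascular relaxation rate 340 1/s,
    frequency offset 197.9 Hz, resting O2 extraction 0.34).  The dynamic
    balloon constants (signal decay, autoregulation, transit time, stiffness)
    take the conventional values of the standard formulation.
    """

    echo_time: float = 0.026  # s
    intra_extra_ratio: float = 0.026
    intravascular_relaxation: float = 340.0  # 1/s
    frequency_offset: float = 197.9  # Hz
    resting_o2_extraction: float = 0.34
    signal_decay: float = 0.64  # kappa, 1/s
    autoregulation: float = 0.32  # gamma, 1/s
    transit_time: float = 2.0  # tau, s
    stiffness: float = 0.32  # alpha (Grubb exponent)
    neurovascular_efficacy: float = 1.0
    resting_volume_fraction: float = 4.0  # V0, percent of voxel volume

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"hemodynamic constant {name} must be positive, got {value}")

    def bold_constants(self) -> tuple[float, float, float]:
        """k1, k2, k3 of the static BOLD equation."""
        te, e0 = self.echo_time, self.resting_o2_extraction
        k1 = 4.3 * self.frequency_offset * e0 * te
        k2 = self.intra_extra_ratio * self.intravascular_relaxation * e0 * te
        k3 = 1.0 - self.intra_extra_ratio
        return k1, k2, k3


@dataclass
class BilinearParams:
    """Coupling matrices plus hemodynamics of one generative model.

    ``A`` is target x source in Hz; ``B`` stacks one n x n matrix per input
    channel; ``C`` is n x m.  The diagonal of A must be strictly negative
    (intrinsic decay), which inversion guarantees by the -0.5*exp(a_ii)
    parameterization of self-connections.
    """

    A: np.ndarray
    B: np.ndarray  # (m, n, n)
    C: np.ndarray  # (n, m)
    hemo: HemodynamicConfig = field(default_factory=HemodynamicConfig)
    nodes: list[str] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.B.ndim != 3 or self.B.shape[1:] != (n, n):
            raise ValueError("B must have shape (m, n, n)")
        m = self.B.shape[0]
        if self.C.shape != (n, m):
            raise ValueError(f"C must have shape ({n}, {m})")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A must be strictly negative")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[0]

    def max_real_eigenvalue(self) -> float:
        return float(np.max(np.real(np.linalg.eigvals(self.A))))

    def is_stable(self) -> bool:
        return self.max_real_eigenvalue() < 0

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(), "B": self.B.tolist(), "C": self.C.tolist(),
            "hemo": asdict(self.hemo), "nodes": self.nodes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BilinearParams":
        return cls(A=np.asarray(d["A"]), B=np.asarray(d["B"]), C=np.asarray(d["C"]),
                   hemo=HemodynamicConfig(**d["hemo"]), nodes=d.get("nodes"))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "BilinearParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def neural_derivative(x: np.ndarray, u: np.ndarray, params: BilinearParams) -> np.ndarray:
    """Instantaneous rate of change of node activity, (A + sum u_j B(j)) x + C u."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.shape != (params.n_nodes,):
        raise ValueError(f"x must have shape ({params.n_nodes},)")
    if u.shape != (params.n_inputs,):
        raise ValueError(f"u must have shape ({params.n_inputs},)")
    a_eff = params.A + np.tensordot(u, params.B, axes=1)
    return a_eff @ x + params.C @ u


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _neural_rk4(A, Bm, C, U, dt):  # pragma: no cover - compiled
    """Neural trajectory only. U is (S, m); returns x at S+1 grid points."""
    n = A.shape[0]
    S = U.shape[0]
    m = C.shape[1]
    traj = np.zeros((S + 1, n))
    x = np.zeros(n)
    aeff = np.zeros((n, n))
    drive = np.zeros(n)
    k1 = np.zeros(n); k2 = np.zeros(n); k3 = np.zeros(n); k4 = np.zeros(n)
    xt = np.zeros(n)
    for s in range(S):
        for i in range(n):
            drive[i] = 0.0
            for j in range(n):
                aeff[i, j] = A[i, j]
        for jm in range(m):
            uj = U[s, jm]
            if uj != 0.0:
                for i in range(n):
                    drive[i] += C[i, jm] * uj
                    for j in range(n):
                        aeff[i, j] += uj * Bm[jm, i, j]
        for i in range(n):
            acc = drive[i]
            for j in range(n):
                acc += aeff[i, j] * x[j]
            k1[i] = acc
        for i in range(n):
            xt[i] = x[i] + 0.5 * dt * k1[i]
        for i in range(n):
            acc = drive[i]
            for j in range(n):
                acc += aeff[i, j] * xt[j]
            k2[i] = acc
        for i in range(n):
            xt[i] = x[i] + 0.5 * dt * k2[i]
        for i in range(n):
            acc = drive[i]
            for j in range(n):
                acc += aeff[i, j] * xt[j]
            k3[i] = acc
        for i in range(n):
            xt[i] = x[i] + dt * k3[i]
        for i in range(n):
            acc = drive[i]
            for j in range(n):
                acc += aeff[i, j] * xt[j]
            k4[i] = acc
        for i in range(n):
            x[i] = x[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        traj[s + 1] = x
    return traj


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def _balloon_rhs(x_i, sv, lf, lv, lq, kappa, gamma, tau, ialpha, e0, eff):  # pragma: no cover
    # clamp log-states so trial parameter sets that diverge cannot produce
    # overflow; divergence is caught separately and rejected
    if lf > 20.0: lf = 20.0
    elif lf < -20.0: lf = -20.0
    if lv > 20.0: lv = 20.0
    elif lv < -20.0: lv = -20.0
    if lq > 20.0: lq = 20.0
    elif lq < -20.0: lq = -20.0
    f = math.exp(lf)
    v = math.exp(lv)
    q = math.exp(lq)
    ds = eff * x_i - kappa * sv - gamma * (f - 1.0)
    dlf = sv / f
    fv = math.exp(ialpha * lv)  # v ** (1/alpha), computed from the log state
    dlv = (f - fv) / (tau * v)
    # oxygen extraction E(f) = 1 - (1 - E0)^(1/f), via exp(log(1-E0)/f)
    ex = 1.0 - math.exp(math.log(1.0 - e0) / f)
    dlq = (f * ex / e0 - fv * q / v) / (tau * q)
    return ds, dlf, dlv, dlq


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def _balloon_bold(xtraj, dt, sample_every, kappa, gamma, tau, ialpha, e0, eff,
                  bk1, bk2, bk3, v0):  # pragma: no cover - compiled
    """Integrate balloon states driven by a fixed neural trajectory.

    xtraj is (S+1, n) on the microtime grid; neural drive is treated as
    piecewise constant per step (left value).  Returns BOLD at every
    ``sample_every``-th grid point, including t=0.
    """
    S = xtraj.shape[0] - 1
    n = xtraj.shape[1]
    n_out = S // sample_every + 1
    out = np.zeros((n_out, n))
    sv = np.zeros(n); lf = np.zeros(n); lv = np.zeros(n); lq = np.zeros(n)
    for s in range(S):
        for i in range(n):
            xi = xtraj[s, i]
            a1, b1, c1, d1 = _balloon_rhs(xi, sv[i], lf[i], lv[i], lq[i],
                                          kappa[i], gamma[i], tau[i], ialpha[i], e0[i], eff[i])
            a2, b2, c2, d2 = _balloon_rhs(xi, sv[i] + 0.5 * dt * a1, lf[i] + 0.5 * dt * b1,
                                          lv[i] + 0.5 * dt * c1, lq[i] + 0.5 * dt * d1,
                                          kappa[i], gamma[i], tau[i], ialpha[i], e0[i], eff[i])
            a3, b3, c3, d3 = _balloon_rhs(xi, sv[i] + 0.5 * dt * a2, lf[i] + 0.5 * dt * b2,
                                          lv[i] + 0.5 * dt * c2, lq[i] + 0.5 * dt * d2,
                                          kappa[i], gamma[i], tau[i], ialpha[i], e0[i], eff[i])
            a4, b4, c4, d4 = _balloon_rhs(xi, sv[i] + dt * a3, lf[i] + dt * b3,
                                          lv[i] + dt * c3, lq[i] + dt * d3,
                                          kappa[i], gamma[i], tau[i], ialpha[i], e0[i], eff[i])
            sv[i] += dt / 6.0 * (a1 + 2 * a2 + 2 * a3 + a4)
            lf[i] += dt / 6.0 * (b1 + 2 * b2 + 2 * b3 + b4)
            lv[i] += dt / 6.0 * (c1 + 2 * c2 + 2 * c3 + c4)
            lq[i] += dt / 6.0 * (d1 + 2 * d2 + 2 * d3 + d4)
        if (s + 1) % sample_every == 0:
            k = (s + 1) // sample_every
            for i in range(n):
                lv_s = lv[i]; lq_s = lq[i]
                if lv_s > 20.0: lv_s = 20.0
                elif lv_s < -20.0: lv_s = -20.0
                if lq_s > 20.0: lq_s = 20.0
                elif lq_s < -20.0: lq_s = -20.0
                v = math.exp(lv_s); q = math.exp(lq_s)
                out[k, i] = v0 * (bk1[i] * (1.0 - q) + bk2[i] * (1.0 - q / v)
                                  + bk3[i] * (1.0 - v))
    return out


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def _joint_rhs(Y, aeff, drive, kappa, gamma, tau, ialpha, e0, eff, dY):  # pragma: no cover
    """Joint RHS over state rows (x, s, lf, lv, lq), shape (5, n)."""
    n = Y.shape[1]
    for i in range(n):
        acc = drive[i]
        for j in range(n):
            acc += aeff[i, j] * Y[0, j]
        dY[0, i] = acc
        ds, dlf, dlv, dlq = _balloon_rhs(Y[0, i], Y[1, i], Y[2, i], Y[3, i], Y[4, i],
                                         kappa[i], gamma[i], tau[i], ialpha[i], e0[i], eff[i])
        dY[1, i] = ds
        dY[2, i] = dlf
        dY[3, i] = dlv
        dY[4, i] = dlq


@njit(cache=True, fastmath={'contract', 'reassoc', 'nsz', 'arcp'})
def _full_rk4_batch(A, Bm, C, U, dt, sample_every, kappa, gamma, tau, ialpha, e0, eff,
                    bk1, bk2, bk3, v0):  # pragma: no cover - compiled
    """Joint neural + balloon RK4 for a batch of parameter sets.

    A (B,n,n), Bm (B,m,n,n), C (B,n,m) against a shared input U (S,m), treated
    as piecewise constant over each microtime step.  Returns BOLD
    (B, S//sample_every + 1, n); the first sample is rest (0).  Effective
    coupling and drive are rebuilt only at steps where some input is nonzero.
    """
    nb = A.shape[0]
    n = A.shape[1]
    m = C.shape[2]
    S = U.shape[0]
    n_out = S // sample_every + 1
    out = np.zeros((nb, n_out, n))
    for b in range(nb):
        Y = np.zeros((5, n))
        Yt = np.zeros((5, n))
        K1 = np.zeros((5, n)); K2 = np.zeros((5, n)); K3 = np.zeros((5, n)); K4 = np.zeros((5, n))
        aeff = np.zeros((n, n))
        drive = np.zeros(n)
        base = True
        for i in range(n):
            drive[i] = 0.0
            for j in range(n):
                aeff[i, j] = A[b, i, j]
        for s in range(S):
            active = False
            for jm in range(m):
                if U[s, jm] != 0.0:
                    active = True
                    break
            if active or not base:
                for i in range(n):
                    drive[i] = 0.0
                    for j in range(n):
                        aeff[i, j] = A[b, i, j]
                if active:
                    for jm in range(m):
                        uj = U[s, jm]
                        if uj != 0.0:
                            for i in range(n):
                                drive[i] += C[b, i, jm] * uj
                                for j in range(n):
                                    aeff[i, j] += uj * Bm[b, jm, i, j]
                base = not active
            _joint_rhs(Y, aeff, drive, kappa, gamma, tau, ialpha, e0, eff, K1)
            for r in range(5):
                for i in range(n):
                    Yt[r, i] = Y[r, i] + 0.5 * dt * K1[r, i]
            _joint_rhs(Yt, aeff, drive, kappa, gamma, tau, ialpha, e0, eff, K2)
            for r in range(5):
                for i in range(n):
                    Yt[r, i] = Y[r, i] + 0.5 * dt * K2[r, i]
            _joint_rhs(Yt, aeff, drive, kappa, gamma, tau, ialpha, e0, eff, K3)
            for r in range(5):
                for i in range(n):
                    Yt[r, i] = Y[r, i] + dt * K3[r, i]
            _joint_rhs(Yt, aeff, drive, kappa, gamma, tau, ialpha, e0, eff, K4)
            diverged = False
            for r in range(5):
                for i in range(n):
                    Y[r, i] += dt / 6.0 * (K1[r, i] + 2.0 * K2[r, i] + 2.0 * K3[r, i] + K4[r, i])
                    if not np.isfinite(Y[r, i]) or abs(Y[r, i]) > 500.0:
                        diverged = True
            if diverged:
                for k in range((s + 1) // sample_every, n_out):
                    for i in range(n):
                        out[b, k, i] = np.nan
                break
            if (s + 1) % sample_every == 0:
                k = (s + 1) // sample_every
                for i in range(n):
                    lv_s = Y[3, i]; lq_s = Y[4, i]
                    if lv_s > 20.0: lv_s = 20.0
                    elif lv_s < -20.0: lv_s = -20.0
                    if lq_s > 20.0: lq_s = 20.0
                    elif lq_s < -20.0: lq_s = -20.0
                    v = math.exp(lv_s); q = math.exp(lq_s)
                    out[b, k, i] = v0 * (bk1[i] * (1.0 - q) + bk2[i] * (1.0 - q / v)
                                         + bk3[i] * (1.0 - v))
    return out


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------

def _hemo_arrays(hemo: HemodynamicConfig, n: int):
    k1, k2, k3 = hemo.bold_constants()
    rep = lambda x: np.full(n, float(x))
    return (rep(hemo.signal_decay), rep(hemo.autoregulation), rep(hemo.transit_time),
            rep(1.0 / hemo.stiffness), rep(hemo.resting_o2_extraction),
            rep(hemo.neurovascular_efficacy), rep(k1), rep(k2), rep(k3),
            float(hemo.resting_volume_fraction))


def integrate_states(params: BilinearParams, U: np.ndarray, dt: float) -> np.ndarray:
    """Neural trajectory x(t) on the microtime grid (S+1 points, from rest).

    Emits a warning and proceeds if the latent coupling is unstable (the
    trajectory is still defined; it will grow until inputs stop).
    """
    U = np.ascontiguousarray(U, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if U.ndim != 2 or U.shape[1] != params.n_inputs:
        raise ValueError("U must be (steps, n_inputs)")
    if not params.is_stable():
        import warnings
        warnings.warn(
            f"unstable A (max real eigenvalue {params.max_real_eigenvalue():.3f} >= 0); "
            "integration proceeds but may diverge", RuntimeWarning)
    return _neural_rk4(np.ascontiguousarray(params.A), np.ascontiguousarray(params.B),
                       np.ascontiguousarray(params.C), U, float(dt))


def hemodynamic_bold(xtraj: np.ndarray, hemo: HemodynamicConfig, dt: float,
                     sample_every: int = 1) -> np.ndarray:
    """Percent-BOLD trajectory from a neural trajectory (S+1, n)."""
    xtraj = np.ascontiguousarray(xtraj, dtype=float)
    if not np.all(np.isfinite(xtraj)):
        raise ValueError("neural trajectory must be finite")
    n = xtraj.shape[1]
    kappa, gamma, tau, ialpha, e0, eff, bk1, bk2, bk3, v0 = _hemo_arrays(hemo, n)
    return _balloon_bold(xtraj, float(dt), int(sample_every),
                         kappa, gamma, tau, ialpha, e0, eff, bk1, bk2, bk3, v0)


def simulate_bold(params: BilinearParams, U: np.ndarray, dt: float,
                  sample_every: int = MICRO_PER_VOLUME) -> np.ndarray:
    """Clean BOLD (volumes x nodes) for one parameter set.

    ``U`` is the microtime input array (steps, m); the output has
    ``steps // sample_every + 1`` rows (the first row is rest, BOLD = 0).
    """
    y = simulate_bold_batch(params.A[None], params.B[None], params.C[None],
                            U, params.hemo, dt, sample_every)
    return y[0]


def simulate_bold_batch(A: np.ndarray, B: np.ndarray, C: np.ndarray, U: np.ndarray,
                        hemo: HemodynamicConfig, dt: float,
                        sample_every: int = MICRO_PER_VOLUME) -> np.ndarray:
    """Batched clean BOLD for stacked parameter sets against a shared input."""
    A = np.ascontiguousarray(A, dtype=float)
    B = np.ascontiguousarray(B, dtype=float)
    C = np.ascontiguousarray(C, dtype=float)
    U = np.ascontiguousarray(U, dtype=float)
    n = A.shape[1]
    kappa, gamma, tau, ialpha, e0, eff, bk1, bk2, bk3, v0 = _hemo_arrays(hemo, n)
    return _full_rk4_batch(A, B, C, U, float(dt), int(sample_every),
                           kappa, gamma, tau, ialpha, e0, eff, bk1, bk2, bk3, v0)


def build_inputs(onsets_per_channel: list[np.ndarray], n_steps: int, dt: float,
                 mean_center: bool = False) -> np.ndarray:
    """Microtime stick-function inputs from per-channel event onsets.

    Zero-duration events become unit-area impulses: height 1/dt in the single
    microtime bin containing the onset.  ``mean_center`` removes each
    channel's temporal mean; it is off by default because a tonic negative
    drive can push the balloon model outside its domain (negative flow)
    during stimulus-free periods -- centering only reparameterizes the
    latent coupling by ubar*B, which is negligible at these event rates.
    """
    m = len(onsets_per_channel)
    U = np.zeros((n_steps, m))
    for j, onsets in enumerate(onsets_per_channel):
        for t in np.atleast_1d(np.asarray(onsets, dtype=float)):
            k = int(np.floor(t / dt))
            if not 0 <= k < n_steps:
                raise ValueError(f"event at {t:.3f} s falls outside the run")
            U[k, j] += 1.0 / dt
    if mean_center:
        U = U - U.mean(axis=0, keepdims=True)
    return U


def sample_bold(y_clean: np.ndarray, noise_sd: float | np.ndarray = 0.0,
                drift: np.ndarray | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Observed volumes: clean samples plus white noise and additive drift."""
    y = np.array(y_clean, dtype=float, copy=True)
    if drift is not None:
        drift = np.asarray(drift, dtype=float)
        if drift.shape != y.shape:
            raise ValueError("drift must match the sampled series shape")
        y += drift
    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (y.shape[1],))
    if np.any(noise_sd > 0):
        if rng is None:
            rng = np.random.default_rng()
        y += rng.standard_normal(y.shape) * noise_sd[None, :]
    return y


def cosine_drift(n_volumes: int, n_basis: int, coeffs: np.ndarray) -> np.ndarray:
    """Slow drift as a combination of low-order cosines (one node's series)."""
    t = np.arange(n_volumes)
    basis = np.stack([np.cos(np.pi * (k + 1) * (t + 0.5) / n_volumes)
                      for k in range(n_basis)], axis=1)
    return basis @ np.asarray(coeffs, dtype=float)
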