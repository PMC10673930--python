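"""Variational-Laplace inversion of bilinear hemodynamic models.

The observation model is y = h(theta) + X beta + e, where h is the bilinear
neural model pushed through the balloon observation equations, X holds
drift/mean confounds per node and e is white Gaussian noise with one
log-precision hyperparameter per node.  A Gaussian posterior over the free
parameters is fitted by Gauss-Newton ascent on the variational free energy F
with Levenberg-Marquardt damping; F is the model-evidence approximation used
for all subsequent model comparison.

Free parameters are the unmasked A/B/C entries (self-connections on a log
scale, A_ii = -0.5 exp(a_ii), so estimation cannot destabilize the
intrinsic decay), the confound coefficients, and the noise log-precisions.
Hemodynamic constants are held fixed at their configured values.  Jacobians
are obtained by batched finite differences through the compiled integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import forward as fw
from .glm import dct_highpass_basis, DEFAULT_HP_CUTOFF
from .space import ModelSpec

SELF_SCALE = 0.5  # A_ii = -SELF_SCALE * exp(a_ii)


class ParamLayout:
    """Mapping between the free parameter vector and the A/B/C matrices."""

    def __init__(self, a_mask: np.ndarray, b_masks: np.ndarray, c_mask: np.ndarray,
                 nodes: list[str] | None = None):
        a_mask = np.asarray(a_mask, dtype=bool)
        b_masks = np.asarray(b_masks, dtype=bool)
        c_mask = np.asarray(c_mask, dtype=bool)
        n = a_mask.shape[0]
        m = b_masks.shape[0]
        if b_masks.shape != (m, n, n) or c_mask.shape != (n, m):
            raise ValueError("inconsistent mask shapes")
        self.n_nodes, self.n_inputs = n, m
        self.a_mask, self.b_masks, self.c_mask = a_mask, b_masks, c_mask
        self.nodes = nodes or [f"node{i + 1}" for i in range(n)]
        entries: list[tuple] = []
        for i in range(n):
            for j in range(n):
                if i != j and a_mask[i, j]:
                    entries.append(("a", i, j))
        for i in range(n):
            entries.append(("a_self", i, i))
        for jm in range(m):
            for i in range(n):
                for j in range(n):
                    if i != j and b_masks[jm, i, j]:
                        entries.append(("b", jm, i, j))
        for i in range(n):
            for jm in range(m):
                if c_mask[i, jm]:
                    entries.append(("c", i, jm))
        self.entries = entries

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "ParamLayout":
        return cls(spec.a_mask.allowed, spec.b_masks, spec.c_mask,
                   nodes=list(spec.a_mask.nodes))

    @property
    def size(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        out = []
        for e in self.entries:
            if e[0] == "a":
                out.append(f"a[{self.nodes[e[1]]}<-{self.nodes[e[2]]}]")
            elif e[0] == "a_self":
                out.append(f"a_self[{self.nodes[e[1]]}]")
            elif e[0] == "b":
                out.append(f"b{e[1] + 1}[{self.nodes[e[2]]}<-{self.nodes[e[3]]}]")
            else:
                out.append(f"c[{self.nodes[e[1]]}<-u{e[2] + 1}]")
        return out

    def matrices_batch(self, thetas: np.ndarray):
        """Stacked (A, B, C) for a batch of free vectors (P, p)."""
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        P = thetas.shape[0]
        n, m = self.n_nodes, self.n_inputs
        A = np.zeros((P, n, n))
        B = np.zeros((P, m, n, n))
        C = np.zeros((P, n, m))
        for k, e in enumerate(self.entries):
            col = thetas[:, k]
            if e[0] == "a":
                A[:, e[1], e[2]] = col
            elif e[0] == "a_self":
                A[:, e[1], e[1]] = -SELF_SCALE * np.exp(col)
            elif e[0] == "b":
                B[:, e[1], e[2], e[3]] = col
            else:
                C[:, e[1], e[2]] = col
        return A, B, C

    def to_params(self, theta: np.ndarray, hemo: fw.HemodynamicConfig | None = None
                  ) -> fw.BilinearParams:
        A, B, C = self.matrices_batch(theta[None])
        return fw.BilinearParams(A=A[0], B=B[0], C=C[0],
                                 hemo=hemo or fw.HemodynamicConfig(), nodes=self.nodes)

    def from_params(self, params: fw.BilinearParams) -> np.ndarray:
        theta = np.empty(self.size)
        for k, e in enumerate(self.entries):
            if e[0] == "a":
                theta[k] = params.A[e[1], e[2]]
            elif e[0] == "a_self":
                theta[k] = np.log(-params.A[e[1], e[1]] / SELF_SCALE)
            elif e[0] == "b":
                theta[k] = params.B[e[1], e[2], e[3]]
            else:
                theta[k] = params.C[e[1], e[2]]
        return theta


@dataclass
class PriorSpec:
    """Diagonal Gaussian prior over a free parameter vector."""

    mean: np.ndarray
    var: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if np.any(self.var < 0):
            raise ValueError("prior variances must be non-negative")

    @property
    def cov(self) -> np.ndarray:
        return np.diag(self.var)


def default_priors(layout: ParamLayout,
                   a_var: float = 0.25, self_var: float = 1.0 / 16,
                   b_var: float = 0.25, c_var: float = 0.25) -> PriorSpec:
    """Zero-mean shrinkage priors on the free coupling parameters.

    The zero self-connection prior mean corresponds to -0.5 Hz intrinsic
    decay under the exponential parameterization.
    """
    var = np.empty(layout.size)
    for k, e in enumerate(layout.entries):
        var[k] = {"a": a_var, "a_self": self_var, "b": b_var, "c": c_var}[e[0]]
    return PriorSpec(mean=np.zeros(layout.size), var=var, names=layout.names())


@dataclass
class InversionResult:
    """Gaussian posterior, free energy and diagnostics of one inversion."""

    mean: np.ndarray  # posterior mean over (dcm params, confound betas)
    cov: np.ndarray
    free_energy: float
    lambdas: np.ndarray  # per-node noise log-precisions
    layout: ParamLayout
    n_confounds: int
    explained_variance: float
    iterations: int
    converged: bool
    f_trajectory: list[float] = field(default_factory=list)

    @property
    def n_dcm(self) -> int:
        return self.layout.size

    def dcm_mean(self) -> np.ndarray:
        return self.mean[: self.n_dcm]

    def dcm_cov(self) -> np.ndarray:
        return self.cov[: self.n_dcm, : self.n_dcm]

    def to_params(self, hemo: fw.HemodynamicConfig | None = None) -> fw.BilinearParams:
        return self.layout.to_params(self.dcm_mean(), hemo=hemo)


def default_confounds(n_volumes: int, t_volume: float,
                      hp_cutoff: float = DEFAULT_HP_CUTOFF) -> np.ndarray:
    """Cosine high-pass set plus a mean column for one run."""
    dct = dct_highpass_basis(n_volumes, t_volume, hp_cutoff)
    return np.hstack([dct, np.ones((n_volumes, 1))])


def _pack_priors(priors: PriorSpec, n_nodes: int, n_conf: int,
                 beta_var: float = 16.0) -> tuple[np.ndarray, np.ndarray]:
    mean = np.concatenate([priors.mean, np.zeros(n_nodes * n_conf)])
    var = np.concatenate([priors.var, np.full(n_nodes * n_conf, beta_var)])
    return mean, var


def variational_laplace(
    layout: ParamLayout,
    y: np.ndarray,
    U: np.ndarray,
    dt: float,
    priors: PriorSpec | None = None,
    confounds: np.ndarray | None = None,
    hemo: fw.HemodynamicConfig | None = None,
    micro: int = fw.MICRO_PER_VOLUME,
    max_iter: int = 128,
    f_tol: float = 0.05,
    n_converged: int = 4,
    fd_step: float = 1e-3,
    lambda_fixed: np.ndarray | None = None,
    lambda_prior: tuple[float, float] = (0.0, 16.0),
    pinned_var: float = 1e-8,
    theta_init: np.ndarray | None = None,
    project_confounds: bool = False,
) -> InversionResult:
    """Fit one model to one run's node time-series.

    ``y`` is (volumes, nodes) and ``U`` the matching microtime inputs
    (volumes*micro, inputs); passing lists of per-run arrays fits all runs
    jointly with shared coupling parameters (each run simulated from rest,
    with its own confound block).  Parameters whose prior variance is below
    ``pinned_var`` are held at their prior mean (used by reduced models).
    Non-convergence within ``max_iter`` flags the result rather than raising.
    """
    runs_y = [np.asarray(a, float) for a in (y if isinstance(y, (list, tuple)) else [y])]
    runs_U = [np.asarray(a, float) for a in (U if isinstance(U, (list, tuple)) else [U])]
    if len(runs_y) != len(runs_U):
        raise ValueError("need one input array per run")
    if any(a.size == 0 for a in runs_y):
        raise ValueError("empty data")
    n = runs_y[0].shape[1]
    if n != layout.n_nodes:
        raise ValueError("data columns must match layout nodes")
    for a, u in zip(runs_y, runs_U):
        if u.shape[0] != a.shape[0] * micro:
            raise ValueError("U rows must equal volumes * micro")
    hemo = hemo or fw.HemodynamicConfig()
    priors = priors if priors is not None else default_priors(layout)
    if confounds is None:
        runs_X = [default_confounds(a.shape[0], dt * micro) for a in runs_y]
    else:
        runs_X = [np.asarray(a, float) for a in
                  (confounds if isinstance(confounds, (list, tuple)) else [confounds])]
    # block-diagonal confound matrix across runs
    T = sum(a.shape[0] for a in runs_y)
    K_conf = sum(x.shape[1] for x in runs_X)
    X = np.zeros((T, K_conf))
    r0 = c0 = 0
    for x in runs_X:
        X[r0:r0 + x.shape[0], c0:c0 + x.shape[1]] = x
        r0 += x.shape[0]
        c0 += x.shape[1]
    y = np.vstack(runs_y)
    if project_confounds:
        # profile out the confound coefficients exactly: both data and model
        # predictions live in the confound-orthogonal subspace
        Q, _ = np.linalg.qr(X)
        projector = lambda M: M - Q @ (Q.T @ M)
        y = projector(y)
        X = np.zeros((T, 0))
        K = 0
        T_eff = T - K_conf  # effective dof per node for noise updates
    else:
        projector = None
        K = K_conf
        T_eff = T
    p = layout.size
    p_tot = p + n * K

    mu0, var0 = _pack_priors(priors, n, K)
    free = var0 > pinned_var
    pi0 = np.zeros(p_tot)
    pi0[free] = 1.0 / var0[free]
    P0 = np.diag(pi0)  # infinite-precision (pinned) dims handled by exclusion

    theta = mu0.copy()
    if theta_init is not None:
        theta[:p] = np.where(free[:p], np.asarray(theta_init, float), theta[:p])
    lam0, lam_var = lambda_prior
    if lambda_fixed is not None:
        lam = np.asarray(lambda_fixed, dtype=float).copy()
    else:
        lam = np.log(2.0 / np.maximum(y.var(axis=0), 1e-12))

    idx_free = np.flatnonzero(free)
    idx_dcm_free = idx_free[idx_free < p]

    def _simulate_runs(batch_theta: np.ndarray) -> np.ndarray:
        """(P, T_total, n) clean predictions of a batch of coupling vectors."""
        A, B, C = layout.matrices_batch(batch_theta)
        parts = []
        for yr, Ur in zip(runs_y, runs_U):
            parts.append(fw.simulate_bold_batch(A, B, C, Ur, hemo, dt,
                                                sample_every=micro)[:, : yr.shape[0], :])
        sims = np.concatenate(parts, axis=1)
        if projector is not None:
            Z = np.tensordot(sims, Q, axes=([1], [0]))  # (P, n, K_conf)
            sims = sims - np.einsum('pnk,tk->ptn', Z, Q)
        return sims

    def predict(th: np.ndarray) -> np.ndarray:
        sim = _simulate_runs(th[None, :p])[0]
        beta = th[p:].reshape(n, K)
        return sim + X @ beta.T

    def jacobian(th: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (pred at th, J (T, n, p_tot)) over free dims only (others 0)."""
        batch = np.tile(th[:p], (idx_dcm_free.size + 1, 1))
        for bi, k in enumerate(idx_dcm_free):
            batch[bi + 1, k] += fd_step
        sims = _simulate_runs(batch)
        J = np.zeros((T, n, p_tot))
        for bi, k in enumerate(idx_dcm_free):
            col = (sims[bi + 1] - sims[0]) / fd_step
            # a perturbation that destabilizes the dynamics carries no usable
            # local gradient; treat that direction as flat for this iteration
            if not np.all(np.isfinite(col)):
                col = np.zeros_like(col)
            J[:, :, k] = col
        for i in range(n):
            J[:, i, p + i * K: p + (i + 1) * K] = X
        beta = th[p:].reshape(n, K)
        pred = sims[0] + X @ beta.T
        return pred, J

    def free_energy(e: np.ndarray, th: np.ndarray, H_free: np.ndarray,
                    lam_: np.ndarray) -> float:
        sse = (e ** 2).sum(axis=0)
        acc = float(np.sum(-0.5 * np.exp(lam_) * sse + 0.5 * T_eff * lam_))
        acc -= 0.5 * T_eff * n * np.log(2 * np.pi)
        d = (th - mu0)[idx_free]
        acc -= 0.5 * float(d @ (pi0[idx_free] * d))
        sign, logdet_h = np.linalg.slogdet(H_free)
        acc += 0.5 * (float(np.sum(np.log(pi0[idx_free]))) - logdet_h)
        if lambda_fixed is None:
            acc -= 0.5 * float(np.sum((lam_ - lam0) ** 2)) / lam_var
            acc += 0.5 * n * (np.log(1.0 / lam_var) - np.log(0.5 * T_eff + 1.0 / lam_var))
        return acc

    def assemble(J: np.ndarray, e: np.ndarray, th: np.ndarray, lam_: np.ndarray):
        Jf = J[:, :, idx_free]
        H = np.zeros((idx_free.size, idx_free.size))
        g = np.zeros(idx_free.size)
        w = np.exp(lam_)
        for i in range(n):
            Ji = Jf[:, i, :]
            H += w[i] * (Ji.T @ Ji)
            g += w[i] * (Ji.T @ e[:, i])
        H += np.diag(pi0[idx_free])
        g -= pi0[idx_free] * (th - mu0)[idx_free]
        return H, g

    pred, J = jacobian(theta)
    e = y - pred
    H, g = assemble(J, e, theta, lam)
    F = free_energy(e, theta, H, lam)
    traj = [F]
    rho = 1.0 / 128
    n_small = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        accepted = False
        for _ in range(12):
            Hd = H + rho * np.diag(np.diag(H))
            try:
                step = np.linalg.solve(Hd, g)
            except np.linalg.LinAlgError:
                rho *= 8
                continue
            th_try = theta.copy()
            th_try[idx_free] += step
            pred_try = predict(th_try)
            e_try = y - pred_try
            H_try, _ = assemble(J, e_try, th_try, lam)
            F_try = free_energy(e_try, th_try, H_try, lam)
            if np.isfinite(F_try) and F_try > F:
                accepted = True
                rho = max(rho / 2, 1.0 / 512)
                break
            rho *= 8
            if rho > 1e8:
                break
        if not accepted:
            break
        theta = th_try
        # refresh Jacobian at the accepted point, update hyperparameters
        pred, J = jacobian(theta)
        e = y - pred
        if lambda_fixed is None:
            H_cur, _ = assemble(J, e, theta, lam)
            S = np.linalg.inv(H_cur)
            Jf = J[:, :, idx_free]
            for i in range(n):
                Ji = Jf[:, i, :]
                tr = float(np.sum((Ji @ S) * Ji))
                sse = float((e[:, i] ** 2).sum())
                if not (np.isfinite(tr) and np.isfinite(sse)):
                    continue
                lam_hat = np.log(T_eff / max(sse + tr, 1e-12))
                lam[i] += np.clip(lam_hat - lam[i], -2.0, 2.0)
        H, g = assemble(J, e, theta, lam)
        F_new = free_energy(e, theta, H, lam)
        dF = F_new - traj[-1]
        traj.append(F_new)
        F = F_new
        n_small = n_small + 1 if abs(dF) < f_tol else 0
        if n_small >= n_converged:
            converged = True
            break

    S_free = np.linalg.inv(H)
    cov = np.zeros((p_tot, p_tot))
    cov[np.ix_(idx_free, idx_free)] = S_free
    cov[~free, ~free] = 0.0
    ev = 1.0 - float(e.var()) / max(float(y.var()), 1e-300)
    return InversionResult(mean=theta, cov=cov, free_energy=F, lambdas=lam.copy(),
                           layout=layout, n_confounds=K, explained_variance=ev,
                           iterations=it, converged=converged, f_trajectory=traj)


def predict_bold(result: InversionResult, U: np.ndarray, dt: float,
                 confounds: np.ndarray | None = None,
                 n_volumes: int | None = None,
                 hemo: fw.HemodynamicConfig | None = None,
                 micro: int = fw.MICRO_PER_VOLUME) -> np.ndarray:
    """Fitted BOLD at the posterior mean (forward simulation + confound fit)."""
    hemo = hemo or fw.HemodynamicConfig()
    layout = result.layout
    p = layout.size
    T = U.shape[0] // micro if n_volumes is None else n_volumes
    A, B, C = layout.matrices_batch(result.mean[None, :p])
    sim = fw.simulate_bold_batch(A, B, C, U, hemo, dt, sample_every=micro)[0][:T]
    K = result.n_confounds
    X = confounds if confounds is not None else default_confounds(T, dt * micro)
    beta = result.mean[p:].reshape(layout.n_nodes, K)
    return sim + X @ beta.T
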