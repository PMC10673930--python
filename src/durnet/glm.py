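"""Mass-univariate GLM, duration contrasts and winner-take-all labeling.

Six condition regressors per run (one per S1 duration at stimulus offset,
plus S2 onset and response onset, all zero-duration events convolved with the
canonical HRF), discrete-cosine high-pass confounds per run (cutoff
0.0083 Hz by default) and per-run mean columns.  Runs are concatenated into a
single design.  Voxels are labeled by the duration contrast with the largest
t-statistic, provided it clears the threshold (3.13); a region qualifies as a
region of interest only when each of the four duration labels reaches the
minimum cluster size (20 voxels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .design import TimingConfig

DEFAULT_T_THRESHOLD = 3.13
DEFAULT_MIN_CLUSTER = 20
DEFAULT_HP_CUTOFF = 0.0083  # Hz

CONDITIONS = ("s1_offset_d1", "s1_offset_d2", "s1_offset_d3", "s1_offset_d4",
              "s2_onset", "response_onset")


def canonical_hrf(dt: float, length: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    Positive lobe peaking near 5 s, undershoot centered near 15 s with a
    1:6 amplitude ratio — the conventional parameterization.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length + dt / 2, dt)
    a1, a2, ratio = 6.0, 16.0, 1.0 / 6.0

    def gpdf(x, a):
        out = np.zeros_like(x)
        pos = x > 0
        out[pos] = np.exp((a - 1) * np.log(x[pos]) - x[pos] - gammaln(a))
        return out

    h = gpdf(t, a1) - ratio * gpdf(t, a2)
    return h / h.max()


def dct_highpass_basis(n_volumes: int, t_volume: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift columns with frequencies below the cutoff.

    Returns (n_volumes, K); K = 0 when the cutoff admits nothing beyond the
    constant (which is carried by the run-mean column instead).
    """
    run_len = n_volumes * t_volume
    k_max = int(np.floor(2.0 * run_len * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (k) * (2 * t + 1) / (2 * n_volumes))
            for k in range(1, k_max + 1)]
    return np.stack(cols, axis=1) if cols else np.zeros((n_volumes, 0))


@dataclass
class DesignMatrix:
    X: np.ndarray  # (total volumes, regressors)
    labels: list[str]
    condition_columns: dict[str, int]
    n_runs: int
    volumes_per_run: int

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    def contrast_vector(self, condition: str) -> np.ndarray:
        c = np.zeros(self.X.shape[1])
        c[self.condition_columns[condition]] = 1.0
        return c


def build_design_matrix(events_per_run: list[pd.DataFrame], timing: TimingConfig,
                        hp_cutoff: float = DEFAULT_HP_CUTOFF,
                        micro: int = 16) -> DesignMatrix:
    """Concatenated-run design with HRF-convolved condition regressors.

    Condition sticks are laid out on a microtime grid, convolved with the
    canonical HRF sampled at that resolution, then downsampled to volume
    times.  High-pass cosines and a mean column are added per run and are
    zero outside their run (honest concatenation).
    """
    if not events_per_run or any(ev.empty for ev in events_per_run):
        raise ValueError("each run needs a non-empty event table")
    n_dur = len(timing.s1_durations)
    cond_names = [f"s1_offset_d{j + 1}" for j in range(n_dur)] + ["s2_onset", "response_onset"]
    dt = timing.t_volume / micro
    T = timing.volumes_per_run
    hrf = canonical_hrf(dt)
    n_runs = len(events_per_run)

    cond_blocks = []
    for ev in events_per_run:
        block = np.zeros((T, len(cond_names)))
        for ci, name in enumerate(cond_names):
            onsets = ev.loc[ev.trial_type == name, "onset"].to_numpy(dtype=float)
            sticks = np.zeros(T * micro)
            for t in onsets:
                k = int(np.floor(t / dt))
                if not 0 <= k < sticks.size:
                    raise ValueError(f"event at {t:.3f} s outside run bounds")
                sticks[k] += 1.0
            conv = np.convolve(sticks, hrf)[: sticks.size]
            block[:, ci] = conv[::micro]
        cond_blocks.append(block)
    cond = np.vstack(cond_blocks)

    dct = dct_highpass_basis(T, timing.t_volume, hp_cutoff)
    K = dct.shape[1]
    conf = np.zeros((n_runs * T, n_runs * (K + 1)))
    labels_conf = []
    for r in range(n_runs):
        rows = slice(r * T, (r + 1) * T)
        cols = slice(r * (K + 1), r * (K + 1) + K)
        conf[rows, cols] = dct
        conf[rows, r * (K + 1) + K] = 1.0
        labels_conf += [f"run{r}_dct{k + 1}" for k in range(K)] + [f"run{r}_mean"]

    X = np.hstack([cond, conf])
    labels = list(cond_names) + labels_conf
    condition_columns = {name: i for i, name in enumerate(cond_names)}
    return DesignMatrix(X=X, labels=labels, condition_columns=condition_columns,
                        n_runs=n_runs, volumes_per_run=T)


@dataclass
class TStatMap:
    t: np.ndarray  # (voxels, contrasts)
    dof: int
    contrast_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dof <= 0:
            raise ValueError("dof must be positive")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("t-map must be finite")


def fit_glm(ts: np.ndarray, design: DesignMatrix,
            contrasts: dict[str, np.ndarray] | None = None
            ) -> tuple[np.ndarray, TStatMap]:
    """Ordinary least squares per voxel; t = c'beta / se(c'beta).

    ``ts`` is (volumes, voxels); returns (betas (regressors, voxels), t-map).
    Defaults to one contrast per S1-duration condition.
    """
    X = design.X
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    if ts.shape[0] != X.shape[0]:
        raise ValueError(f"time-series rows ({ts.shape[0]}) must match design rows "
                         f"({X.shape[0]})")
    if contrasts is None:
        contrasts = {name: design.contrast_vector(name)
                     for name in design.condition_columns if name.startswith("s1_offset")}
    beta, *_ = np.linalg.lstsq(X, ts, rcond=None)
    resid = ts - X @ beta
    dof = ts.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    names = list(contrasts)
    tmat = np.empty((ts.shape[1], len(names)))
    for ci, name in enumerate(names):
        c = np.asarray(contrasts[name], dtype=float)
        var_c = c @ xtx_inv @ c
        se = np.sqrt(np.maximum(sigma2 * var_c, 1e-300))
        tmat[:, ci] = (c @ beta) / se
    return beta, TStatMap(t=tmat, dof=int(dof), contrast_names=names)


@dataclass
class DurationClusters:
    """Per-voxel winner-take-all duration labels within one region."""

    labels: np.ndarray  # (voxels,), 0 = unassigned, 1..n_durations
    counts: np.ndarray  # per-duration voxel counts
    qualifies: bool  # all durations reach the minimum cluster size
    region: str = ""


def winner_take_all(tmap: TStatMap, threshold: float = DEFAULT_T_THRESHOLD,
                    min_cluster: int = DEFAULT_MIN_CLUSTER,
                    region: str = "") -> DurationClusters:
    """Label each voxel by its argmax duration contrast, thresholded.

    Ties break toward the lower duration index (measure-zero with continuous
    statistics).  "Cluster size" is a per-label voxel count: synthetic voxels
    carry no spatial geometry.
    """
    t = tmap.t
    win = np.argmax(t, axis=1)
    tbest = t[np.arange(t.shape[0]), win]
    labels = np.where(tbest >= threshold, win + 1, 0)
    n_con = t.shape[1]
    counts = np.bincount(labels, minlength=n_con + 1)[1:]
    return DurationClusters(labels=labels, counts=counts,
                            qualifies=bool(np.all(counts >= min_cluster)),
                            region=region)


def extract_eigenvariate(ts: np.ndarray, confounds: np.ndarray | None = None) -> np.ndarray:
    """First principal-component summary series of a voxel set.

    Optionally residualizes confound columns first ("adjusted to effects of
    interest").  The summary is the first left singular vector scaled by its
    singular value over sqrt(n_voxels), sign-aligned with the mean signal.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    if ts.shape[1] < 1 or not np.any(ts):
        raise ValueError("need at least one voxel with signal")
    Y = ts - ts.mean(axis=0, keepdims=True)
    if confounds is not None and confounds.size:
        Q, _ = np.linalg.qr(confounds - confounds.mean(axis=0, keepdims=True))
        Y = Y - Q @ (Q.T @ Y)
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    y = U[:, 0] * s[0] / np.sqrt(ts.shape[1])
    if y @ Y.mean(axis=1) < 0:
        y = -y
    return y
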