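"""BOLD normalization and cross-validated duration tuning curves.

A duration-selective cluster's response to each presented S1 duration is read
out at the 2nd volume after stimulus offset, after a two-stage normalization:
(1) voxel signals are converted to percent signal change around a per-voxel
baseline (the voxel's mean over runs), voxel-averaged, run-averaged and
scaled by the temporal standard deviation of the run-wise voxel-averaged
series; (2) each cluster's curve is divided by its response at the preferred
duration, which is therefore exactly 1.  Circularity is avoided by defining
clusters on one half of the runs and measuring the curve on the other half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SplitPlan:
    """Disjoint, exhaustive half-splits of the run list."""

    iterations: list[tuple[tuple[int, ...], tuple[int, ...]]]  # (select, measure)
    seed: int


def make_split_plan(n_runs: int = 18, n_iterations: int = 18, seed: int = 0) -> SplitPlan:
    """Random distinct 50/50 splits (select half, measure half)."""
    if n_runs % 2:
        raise ValueError("n_runs must be even for half splits")
    half = n_runs // 2
    n_possible = math.comb(n_runs, half)
    if n_iterations > n_possible:
        raise ValueError(f"only {n_possible} distinct half-splits exist; "
                         f"{n_iterations} requested")
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    iters = []
    while len(iters) < n_iterations:
        perm = rng.permutation(n_runs)
        select = tuple(sorted(int(r) for r in perm[:half]))
        if select in seen:
            continue
        seen.add(select)
        measure = tuple(sorted(int(r) for r in perm[half:]))
        iters.append((select, measure))
    return SplitPlan(iterations=iters, seed=seed)


def normalize_bold(runs_x_time: np.ndarray, baseline: np.ndarray | None = None
                   ) -> np.ndarray:
    """Normalized cluster response series from per-run voxel data.

    ``runs_x_time`` has shape (n_runs, n_volumes, n_voxels).  Per voxel the
    baseline MB is its mean signal across runs (and volumes); the percent
    signal change (x - MB)/MB is voxel-averaged per run, run-averaged, and
    divided by the mean across runs of the temporal standard deviation of
    each run's voxel-averaged series.  (The printed formula's "std" axis is
    read as time; this function is the single place that choice lives.)
    """
    x = np.asarray(runs_x_time, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (runs, volumes, voxels)")
    mb = x.mean(axis=(0, 1)) if baseline is None else np.asarray(baseline, float)
    if np.any(mb == 0):
        raise ValueError("zero baseline MB; percent signal change undefined")
    psc = (x - mb[None, None, :]) / mb[None, None, :]
    run_mean = psc.mean(axis=2)  # (runs, volumes)
    sd = run_mean.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero temporal variance in a run; normalization undefined")
    return run_mean.mean(axis=0) / sd.mean()


@dataclass
class TuningCurve:
    region: str
    cluster: int  # preferred-duration label, 1-based
    response: np.ndarray  # normalized response per presented duration
    iteration: int = 0

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)


def responses_at_offset(norm_series: np.ndarray, events: pd.DataFrame,
                        t_volume: float, n_durations: int,
                        align_offset: int = 2) -> np.ndarray:
    """Mean normalized response per S1 duration, read ``align_offset`` volumes
    after each stimulus offset (offset volume found by flooring offset/TR)."""
    T = norm_series.shape[0]
    out = np.empty(n_durations)
    for j in range(n_durations):
        onsets = events.loc[events.trial_type == f"s1_offset_d{j + 1}", "onset"].to_numpy()
        if onsets.size == 0:
            raise ValueError(f"no trials for duration {j + 1}")
        vals = []
        for t in onsets:
            k = int(np.floor(t / t_volume)) + align_offset
            if k < T:
                vals.append(norm_series[k])
        if not vals:
            raise ValueError(f"all duration-{j + 1} probes fall outside the run")
        out[j] = float(np.mean(vals))
    return out


def extract_tuning(voxel_runs: np.ndarray, events_per_run: list[pd.DataFrame],
                   labels: np.ndarray, t_volume: float, n_durations: int,
                   measure_runs: tuple[int, ...] | None = None,
                   align_offset: int = 2, region: str = "",
                   iteration: int = 0) -> list[TuningCurve]:
    """Tuning curves of every labeled cluster in one region.

    ``voxel_runs`` is (runs, volumes, voxels); ``labels`` assigns each voxel
    its winner-take-all duration (0 = unassigned, typically derived from the
    *other* half of the runs).  The response at each presented duration is
    averaged over that duration's trials in the measurement runs; the second
    normalization divides by the preferred-duration response (exactly 1).
    """
    runs = range(voxel_runs.shape[0]) if measure_runs is None else measure_runs
    runs = tuple(runs)
    curves = []
    for cluster in range(1, n_durations + 1):
        vox = np.flatnonzero(labels == cluster)
        if vox.size == 0:
            continue
        sub = voxel_runs[np.ix_(runs, range(voxel_runs.shape[1]), vox)]
        mb = sub.mean(axis=(0, 1))
        if np.any(mb == 0):
            raise ValueError("zero baseline MB; percent signal change undefined")
        run_mean = ((sub - mb) / mb).mean(axis=2)  # (runs, volumes)
        sd = run_mean.std(axis=1, ddof=0).mean()
        if sd == 0:
            raise ValueError("zero temporal variance; normalization undefined")
        per_run = [responses_at_offset(run_mean[ri] / sd, events_per_run[run],
                                       t_volume, n_durations, align_offset)
                   for ri, run in enumerate(runs)]
        resp = np.mean(per_run, axis=0)
        pref = resp[cluster - 1]
        if pref == 0:
            raise ValueError("zero response at preferred duration; cannot normalize")
        curves.append(TuningCurve(region=region, cluster=cluster,
                                  response=resp / pref, iteration=iteration))
    return curves


def curves_to_frame(curves: list[TuningCurve], durations: tuple[float, ...]) -> pd.DataFrame:
    """Tidy table (region, cluster, presented_duration, iteration, response)."""
    rows = []
    for c in curves:
        for j, r in enumerate(c.response):
            rows.append((c.region, c.cluster, durations[j], c.iteration, r))
    return pd.DataFrame(rows, columns=["region", "cluster", "presented_duration",
                                       "iteration", "response"])
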