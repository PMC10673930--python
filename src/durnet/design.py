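"""Experiment designs, ground-truth networks and synthetic cohorts.

Emulates the duration-discrimination protocol: each run presents every
combination of S1 duration x orientation exactly once (16 trial types with
the default 4 x 4 design); S2 is shorter or longer than S1 by a fixed Weber
fraction; inter-stimulus and inter-trial intervals are drawn uniformly from a
4-5.2 s grid in 0.08 s steps; events are logged at S1 offset (duration zero),
S2 onset and response onset.  BOLD is generated from a ground-truth bilinear
network through the balloon observation model, sampled at the volume time,
and corrupted with white noise and slow cosine drift.  Orientation is
generated but carries no signal (it was task-irrelevant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forward as fw
from . import space as sp

EVENT_COLUMNS = ["onset", "duration", "trial_type", "orientation", "run"]


@dataclass
class TimingConfig:
    """Trial timing and acquisition geometry of one study."""

    n_runs: int = 18
    volumes_per_run: int = 169
    t_volume: float = 1.368  # s
    isi_min: float = 4.0
    isi_max: float = 5.2
    isi_step: float = 0.08
    response_period: float = 2.0
    s1_durations: tuple[float, ...] = (0.2, 0.4, 0.6, 1.0)
    orientations: tuple[float, ...] = (36.0, 72.0, 108.0, 144.0)
    weber_fraction: float = 0.5
    start_pad: float = 2.0  # quiet period before the first trial, s

    def __post_init__(self) -> None:
        if self.isi_min >= self.isi_max:
            raise ValueError("isi_min must be < isi_max")
        ratio = (self.isi_max - self.isi_min) / self.isi_step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("isi_step must divide (isi_max - isi_min) exactly")
        if any(d <= 0 for d in self.s1_durations):
            raise ValueError("all S1 durations must be positive")
        if not 0 < self.weber_fraction < 1:
            raise ValueError("weber_fraction must lie in (0, 1)")
        if self.n_runs < 1 or self.volumes_per_run < 1 or self.t_volume <= 0:
            raise ValueError("run geometry must be positive")

    @property
    def run_length(self) -> float:
        return self.volumes_per_run * self.t_volume

    @property
    def n_trial_types(self) -> int:
        return len(self.s1_durations) * len(self.orientations)

    @property
    def isi_grid(self) -> np.ndarray:
        n = int(round((self.isi_max - self.isi_min) / self.isi_step)) + 1
        return self.isi_min + self.isi_step * np.arange(n)


class RunOverflowError(ValueError):
    """The drawn trial sequence does not fit in the run."""

    def __init__(self, needed: float, available: float):
        self.needed = needed
        self.available = available
        super().__init__(
            f"trial sequence needs {needed:.2f} s but the run offers only "
            f"{available:.2f} s ({needed - available:.2f} s short)")


def assign_s2_duration(s1: float, weber: float, direction: str) -> float:
    """Comparison duration: S1 scaled down or up by the Weber fraction."""
    if s1 <= 0:
        raise ValueError("s1 must be positive")
    if not 0 < weber < 1:
        raise ValueError("weber fraction must lie strictly in (0, 1); "
                         "0 would make the discrimination degenerate")
    if direction == "shorter":
        return s1 * (1.0 - weber)
    if direction == "longer":
        return s1 * (1.0 + weber)
    raise ValueError(f"direction must be 'shorter' or 'longer', got {direction!r}")


def generate_trial_sequence(timing: TimingConfig, run: int, seed: int) -> pd.DataFrame:
    """Event table of one run (deterministic in ``(run, seed)``).

    Every S1 duration x orientation pair occurs exactly once, in random
    order.  Per trial the sequence is S1 -> ISI -> S2 -> response cue -> ITI,
    with ISI/ITI drawn from the allowed grid.  S1 offset, S2 onset and
    response onset are logged as zero-duration events.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(run)]))
    trial_types = [(d, o) for d in timing.s1_durations for o in timing.orientations]
    order = rng.permutation(len(trial_types))
    grid = timing.isi_grid
    rows = []
    t = timing.start_pad
    d_index = {d: i + 1 for i, d in enumerate(timing.s1_durations)}
    for ti in order:
        s1_dur, orient = trial_types[ti]
        s1_onset = t
        s1_offset = s1_onset + s1_dur
        isi = float(rng.choice(grid))
        s2_onset = s1_offset + isi
        direction = "shorter" if rng.random() < 0.5 else "longer"
        s2_dur = assign_s2_duration(s1_dur, timing.weber_fraction, direction)
        resp_onset = s2_onset + s2_dur
        iti = float(rng.choice(grid))
        rows.append((s1_offset, 0.0, f"s1_offset_d{d_index[s1_dur]}", orient, run))
        rows.append((s2_onset, 0.0, "s2_onset", orient, run))
        rows.append((resp_onset, 0.0, "response_onset", orient, run))
        t = resp_onset + timing.response_period + iti
    needed = rows[-1][0] + timing.response_period
    if needed > timing.run_length:
        raise RunOverflowError(needed, timing.run_length)
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS).sort_values("onset", kind="stable")
    return df.reset_index(drop=True)


def s1_onsets_by_duration(events: pd.DataFrame, n_durations: int) -> list[np.ndarray]:
    """Per-duration-channel S1-offset onset times of one run's events.

    With a single channel (region-level analyses, where the stimulus input is
    duration-unspecific) all S1 offsets feed that channel.
    """
    if n_durations == 1:
        mask = events.trial_type.str.startswith("s1_offset")
        return [events.loc[mask, "onset"].to_numpy()]
    return [events.loc[events.trial_type == f"s1_offset_d{j + 1}", "onset"].to_numpy()
            for j in range(n_durations)]


def onsets_for_channels(events: pd.DataFrame, channels: tuple[str, ...]) -> list[np.ndarray]:
    """Onset times per named input channel.

    Channel names: ``s1_all`` (every S1 offset), ``s1_d<j>`` (one duration),
    ``s2`` (S2 onsets), ``response`` (response onsets).
    """
    out = []
    for ch in channels:
        if "+" in ch:
            parts = onsets_for_channels(events, tuple(ch.split("+")))
            out.append(np.sort(np.concatenate(parts)))
            continue
        if ch == "s1_all":
            mask = events.trial_type.str.startswith("s1_offset")
        elif ch.startswith("s1_d"):
            mask = events.trial_type == f"s1_offset_{ch[3:]}"
        elif ch == "s2":
            mask = events.trial_type == "s2_onset"
        elif ch == "response":
            mask = events.trial_type == "response_onset"
        else:
            raise ValueError(f"unknown input channel {ch!r}")
        out.append(events.loc[mask, "onset"].to_numpy())
    return out


@dataclass
class GroundTruth:
    """Generative model of a cohort: coupling, tuning gains and nuisance levels."""

    params: fw.BilinearParams
    region_graph: sp.AMask
    hypothesis_a: tuple[str, str]  # (between, within)
    hypothesis_b: tuple[str, str]
    hypothesis_c: str
    cluster_amplitudes: np.ndarray  # (n_clusters, n_durations) drive gain
    n_clusters: int
    input_channels: tuple[str, ...] | None = None  # None: per-duration S1 channels
    snr: float = 1.0
    drift_amplitude: float = 0.2  # percent signal, per cosine coefficient scale
    between_subject_sd: float = 0.1  # Hz, additive on free A/B/C entries
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return self.params.n_nodes


def _tuned_amplitudes(n_clusters: int, n_durations: int, falloff: float = 0.5) -> np.ndarray:
    """Drive gain of cluster c under duration d: geometric falloff in |c - d|."""
    c = np.arange(n_clusters)[:, None]
    d = np.arange(n_durations)[None, :]
    return falloff ** np.abs(c - d).astype(float)


def make_ground_truth_network(
    hypothesis_a: tuple[str, str] = ("independent", "independent"),
    hypothesis_b: tuple[str, str] = ("dependent", "dependent"),
    hypothesis_c: str = "dependent",
    region_graph: sp.AMask | None = None,
    n_clusters: int = 4,
    seed: int = 0,
    between_strength: float = 0.15,
    within_strength: float = 0.08,
    modulation_strength: float = 0.1,
    drive_strength: float = 0.35,
    self_decay: float = 0.5,
    snr: float = 1.0,
    drive_regions: str = "c_mask",
    tuning_falloff: float = 0.5,
    hemo: fw.HemodynamicConfig | None = None,
    driven_region_index: int | None = None,
) -> GroundTruth:
    """Ground-truth bilinear network respecting the requested hypothesis masks.

    Nonzero entries are placed where the masks allow, with small seeded
    jitter around the configured strengths; self-connections are fixed at
    ``-self_decay``.  ``drive_regions`` selects where inputs enter: the
    hypothesis C mask (the driven region only) or ``"all"`` — duration-tuned
    drive of every cluster in every region, the configuration used when the
    voxelwise selection stage itself is under study.  Raises if the resulting
    coupling is unstable.
    """
    region_graph = sp.region_graph_peblike() if region_graph is None else region_graph
    rng = np.random.default_rng(seed)
    spec = sp.make_model_spec(hypothesis_a[0], hypothesis_a[1],
                              hypothesis_b[0], hypothesis_b[1], hypothesis_c,
                              region_mask=region_graph, n_clusters=n_clusters,
                              driven_region_index=driven_region_index)
    n = spec.a_mask.n_nodes
    m = n_clusters  # one input channel per S1 duration
    jitter = lambda shape: 1.0 + 0.2 * rng.standard_normal(shape)

    # strengths are shared per (target cluster, source region) across the
    # allowed source clusters, so the total coupling mass a cluster receives
    # from a region does not depend on the specificity hypothesis (and the
    # dynamics stay stable under the independent expansion)
    A = np.zeros((n, n))
    nr = region_graph.n_nodes
    for it in range(n):
        for rs in range(nr):
            srcs = [rs * n_clusters + cs for cs in range(n_clusters)
                    if spec.a_mask.allowed[it, rs * n_clusters + cs]
                    and it != rs * n_clusters + cs]
            if not srcs:
                continue
            same_region = (it // n_clusters) == rs
            strength = within_strength if same_region else between_strength
            for js in srcs:
                A[it, js] = strength / len(srcs) * jitter(())
    np.fill_diagonal(A, -self_decay)

    B = np.where(spec.b_masks, modulation_strength * jitter((m, n, n)), 0.0)

    amplitudes = _tuned_amplitudes(n_clusters, m, falloff=tuning_falloff)
    C = np.zeros((n, m))
    if drive_regions == "all":
        for r in range(nr):
            for c in range(n_clusters):
                C[r * n_clusters + c, :] = drive_strength * amplitudes[c, :]
    else:
        C = np.where(spec.c_mask, drive_strength, 0.0)
        # grade the allowed entries by the tuning falloff of |cluster - input|
        for node in range(n):
            c = node % n_clusters
            C[node, :] *= amplitudes[c, :]

    params = fw.BilinearParams(A=A, B=B, C=C,
                               hemo=hemo or fw.HemodynamicConfig(),
                               nodes=list(spec.a_mask.nodes))
    lam = params.max_real_eigenvalue()
    if lam >= -0.08:
        raise ValueError(f"requested strengths give unstable (or nearly unstable) "
                         f"dynamics (max real eigenvalue {lam:.4f} >= -0.08)")
    return GroundTruth(params=params, region_graph=region_graph,
                       hypothesis_a=(spec.a_between, spec.a_within),
                       hypothesis_b=(spec.b_between, spec.b_within),
                       hypothesis_c=spec.c_level,
                       cluster_amplitudes=amplitudes,
                       n_clusters=n_clusters, snr=snr, seed=seed)


def region_level_ground_truth(
    region_graph: sp.AMask | None = None,
    seed: int = 0,
    coupling_strength: float = 0.2,
    drive_strength: float = 0.5,
    self_decay: float | tuple[float, ...] = (0.5, 0.65, 0.55, 0.45, 0.35),
    driven_regions: tuple[int, ...] = (0, 1),
    input_channels: tuple[str, ...] = ("s1_all", "s2"),
    drive_pattern: np.ndarray | None = None,
    snr: float = 1.0,
    hemo: fw.HemodynamicConfig | None = None,
) -> GroundTruth:
    """Region-level (one node per region) ground truth, e.g. the 5-node stage.

    Intrinsic decays default to region-specific values (regions differ in
    their intrinsic timescales), which also makes upstream sources
    dynamically distinguishable downstream.
    """
    region_graph = sp.region_graph_peblike() if region_graph is None else region_graph
    rng = np.random.default_rng(seed)
    n = region_graph.n_nodes
    off = region_graph.allowed & ~np.eye(n, dtype=bool)
    A = np.where(off, coupling_strength * (1.0 + 0.2 * rng.standard_normal((n, n))), 0.0)
    decays = np.asarray(self_decay, dtype=float)
    decays = (np.full(n, float(decays)) if decays.ndim == 0
              else np.resize(decays, n))
    np.fill_diagonal(A, -decays)
    n_inputs = len(input_channels)
    B = np.zeros((n_inputs, n, n))
    if drive_pattern is not None:
        C = np.asarray(drive_pattern, dtype=float) * drive_strength
        if C.shape != (n, n_inputs):
            raise ValueError("drive_pattern must be (n_regions, n_channels)")
    else:
        C = np.zeros((n, n_inputs))
        for ch, r in enumerate(driven_regions[:n_inputs]):
            C[r, ch] = drive_strength
    params = fw.BilinearParams(A=A, B=B, C=C, hemo=hemo or fw.HemodynamicConfig(),
                               nodes=list(region_graph.nodes))
    lam = params.max_real_eigenvalue()
    if lam >= -0.1:
        raise ValueError(f"dynamics unstable or nearly so (max real eigenvalue "
                         f"{lam:.4f} > -0.1); reduce coupling_strength")
    return GroundTruth(params=params, region_graph=region_graph,
                       hypothesis_a=("independent", "independent"),
                       hypothesis_b=("independent", "independent"),
                       hypothesis_c="independent",
                       cluster_amplitudes=np.ones((1, n_inputs)),
                       n_clusters=1, input_channels=tuple(input_channels),
                       snr=snr, seed=seed)


@dataclass
class Subject:
    """One synthetic subject: per-run events, node time-series, true params."""

    events: list[pd.DataFrame]
    timeseries: list[np.ndarray]  # per run, (volumes, nodes), observed
    clean: list[np.ndarray]  # noiseless sampled series
    params: fw.BilinearParams  # subject-level (jittered) truth
    inputs: list[np.ndarray]  # microtime input arrays per run


@dataclass
class SyntheticDataset:
    subjects: list[Subject]
    timing: TimingConfig
    truth: GroundTruth
    node_labels: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def n_first_level_units(self) -> int:
        return sum(len(s.timeseries) for s in self.subjects)

    def volumes_per_subject(self) -> int:
        return self.timing.n_runs * self.timing.volumes_per_run


def jitter_params(params: fw.BilinearParams, rel_sd: float, rng: np.random.Generator,
                  max_tries: int = 20, margin: float = 0.08) -> fw.BilinearParams:
    """Subject-level parameters: Gaussian jitter, sd = ``rel_sd`` x |entry|.

    Self-connections are jittered on their log scale.  Redraws (bounded) if a
    draw pushes the spectral abscissa above ``-margin`` (a nearly unstable
    subject would hold activity for minutes, which real cortex does not).
    """
    for _ in range(max_tries):
        A = params.A.copy()
        off = ~np.eye(A.shape[0], dtype=bool)
        free = off & (A != 0)
        A[free] *= 1.0 + rel_sd * rng.standard_normal(int(free.sum()))
        d = np.diag(params.A)
        np.fill_diagonal(A, d * np.exp(rel_sd * rng.standard_normal(A.shape[0])))
        B = params.B.copy()
        nz = params.B != 0
        B[nz] *= 1.0 + rel_sd * rng.standard_normal(int(nz.sum()))
        C = params.C.copy()
        nz = params.C != 0
        C[nz] *= 1.0 + rel_sd * rng.standard_normal(int(nz.sum()))
        cand = fw.BilinearParams(A=A, B=B, C=C, hemo=params.hemo, nodes=params.nodes)
        if cand.max_real_eigenvalue() < -margin:
            return cand
    raise RuntimeError("could not draw stable subject-level parameters")


def simulate_run(params: fw.BilinearParams, events: pd.DataFrame, timing: TimingConfig,
                 noise_sd: float | np.ndarray, drift_amplitude: float,
                 rng: np.random.Generator, mean_center: bool = False,
                 micro: int = fw.MICRO_PER_VOLUME):
    """One run's (clean, observed, U) given subject parameters and events."""
    dt = timing.t_volume / micro
    n_steps = timing.volumes_per_run * micro
    onsets = s1_onsets_by_duration(events, params.n_inputs)
    U = fw.build_inputs(onsets, n_steps, dt, mean_center=mean_center)
    y = fw.simulate_bold(params, U, dt)[: timing.volumes_per_run]
    n_basis = 3
    drift = np.stack(
        [fw.cosine_drift(timing.volumes_per_run, n_basis,
                         drift_amplitude * rng.standard_normal(n_basis))
         for _ in range(params.n_nodes)], axis=1)
    obs = fw.sample_bold(y, noise_sd=noise_sd, drift=drift, rng=rng)
    return y, obs, U


def build_cohort(n_subjects: int, timing: TimingConfig, truth: GroundTruth,
                 seed: int = 0, noise_sd: float | None = None,
                 mean_center: bool = False) -> SyntheticDataset:
    """Complete multi-subject node-level dataset.

    Per subject: parameters jittered around the ground truth (between-subject
    variability), per run a fresh trial sequence, forward-simulated BOLD,
    white noise and cosine drift.  ``noise_sd`` overrides the SNR-derived
    noise level (SNR = temporal sd of clean signal / noise sd, per node,
    averaged over the subject's runs).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    root = np.random.SeedSequence([int(seed), 0xC0B0])
    subj_seeds = root.spawn(n_subjects)
    subjects = []
    for si in range(n_subjects):
        rng = np.random.default_rng(subj_seeds[si])
        params = (jitter_params(truth.params, truth.between_subject_sd, rng)
                  if truth.between_subject_sd > 0 else truth.params)
        events_list, clean_list, inputs = [], [], []
        for run in range(timing.n_runs):
            ev = generate_trial_sequence(timing, run, seed=int(rng.integers(2 ** 31)))
            dt = timing.t_volume / fw.MICRO_PER_VOLUME
            n_steps = timing.volumes_per_run * fw.MICRO_PER_VOLUME
            onsets = (onsets_for_channels(ev, truth.input_channels)
                      if truth.input_channels is not None
                      else s1_onsets_by_duration(ev, params.n_inputs))
            U = fw.build_inputs(onsets, n_steps, dt, mean_center=mean_center)
            y = fw.simulate_bold(params, U, dt)[: timing.volumes_per_run]
            events_list.append(ev)
            clean_list.append(y)
            inputs.append(U)
        if noise_sd is None:
            signal_sd = np.mean([c.std(axis=0) for c in clean_list], axis=0)
            nsd = signal_sd / truth.snr if truth.snr > 0 else np.zeros_like(signal_sd)
        else:
            nsd = np.broadcast_to(np.asarray(noise_sd, float), (params.n_nodes,))
        obs_list = []
        n_basis = 3
        for y in clean_list:
            drift = np.stack(
                [fw.cosine_drift(timing.volumes_per_run, n_basis,
                                 truth.drift_amplitude * rng.standard_normal(n_basis))
                 for _ in range(params.n_nodes)], axis=1)
            obs_list.append(fw.sample_bold(y, noise_sd=nsd, drift=drift, rng=rng))
        subjects.append(Subject(events=events_list, timeseries=obs_list,
                                clean=clean_list, params=params, inputs=inputs))
    labels = list(truth.params.nodes or
                  [f"node{i + 1}" for i in range(truth.params.n_nodes)])
    return SyntheticDataset(subjects=subjects, timing=timing, truth=truth,
                            node_labels=labels)


def expand_to_voxels(node_series: np.ndarray, n_voxels_per_node: int,
                     voxel_noise_sd: float, rng: np.random.Generator,
                     baseline: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-level series: noisy copies of each node's signal on a baseline.

    Returns (volumes x total_voxels array, voxel -> node index map).  The
    additive baseline makes the series resemble raw scanner units so the
    percent-signal-change normalization has a meaningful denominator.
    """
    T, n = node_series.shape
    V = n * n_voxels_per_node
    out = np.empty((T, V))
    owner = np.empty(V, dtype=int)
    for i in range(n):
        sl = slice(i * n_voxels_per_node, (i + 1) * n_voxels_per_node)
        gain = 1.0 + 0.1 * rng.standard_normal(n_voxels_per_node)
        out[:, sl] = (baseline + node_series[:, i:i + 1] * gain[None, :]
                      + voxel_noise_sd * rng.standard_normal((T, n_voxels_per_node)))
        owner[sl] = i
    return out, owner


# -- TSV / JSON round-trip helpers -----------------------------------------

def write_events_tsv(events: pd.DataFrame, path: str) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_timeseries_tsv(ts: np.ndarray, labels: list[str], path: str) -> None:
    pd.DataFrame(ts, columns=labels).to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path: str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)
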