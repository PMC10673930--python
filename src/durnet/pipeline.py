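"""Configuration and orchestration of the full synthetic study.

Stages mirror the analysis: ``simulate`` (cohort generation), ``glm``
(voxelwise selection), ``tuning`` (cross-validated tuning curves), ``space``
(model enumeration), ``invert`` (first-level full-model inversions),
``compare`` (model-space scoring by Bayesian model reduction + family
inference), ``peb`` (group architecture discovery on the region level) and
``graph`` (metrics of the recovered architecture).  Every stage consumes and
produces serialized artifacts only — TSV for tables and time-series, JSON for
models, posteriors and results — so any stage can be re-run or audited in
isolation.  A manifest with content hashes makes end-to-end reproducibility
checkable from (config, seeds) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes, design as dg, forward as fw, glm as gm
from . import graph as gr, peb as pb, space as sp, tuning as tn
from .invert import ParamLayout, default_priors, variational_laplace

STAGES = ("simulate", "glm", "tuning", "space", "invert", "compare", "peb", "graph")


@dataclasses.dataclass
class PipelineConfig:
    """Validated, fully-defaulted configuration of one synthetic study."""

    timing: dg.TimingConfig
    n_subjects: int = 11
    regions: tuple[str, ...] = sp.REGIONS
    n_clusters: int = 4
    hypothesis_a: tuple[str, str] = ("independent", "independent")
    hypothesis_b: tuple[str, str] = ("dependent", "dependent")
    hypothesis_c: str = "dependent"
    snr: float = 1.0
    n_voxels_per_cluster: int = 30
    voxel_noise_sd: float = 1.0
    t_threshold: float = gm.DEFAULT_T_THRESHOLD
    min_cluster: int = gm.DEFAULT_MIN_CLUSTER
    hp_cutoff: float = gm.DEFAULT_HP_CUTOFF
    pp_threshold: float = pb.DEFAULT_PP_THRESHOLD
    pep_threshold: float = 0.90
    seed: int = 0
    out_dir: str = "durnet_out"

    def spawn_seed(self, tag: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{tag}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2 ** 31)


def validate_config(raw: dict | None) -> PipelineConfig:
    """Normalize a raw (JSON/YAML) mapping into a PipelineConfig.

    Unknown keys, unknown hypothesis levels and non-integer seeds raise
    structured errors; everything absent falls back to the study defaults.
    """
    raw = dict(raw or {})
    timing_raw = raw.pop("timing", {})
    try:
        timing = dg.TimingConfig(**timing_raw)
    except TypeError as exc:
        raise ValueError(f"invalid timing config: {exc}") from None
    for key in ("hypothesis_a", "hypothesis_b"):
        if key in raw:
            pair = tuple(raw[key])
            if len(pair) != 2:
                raise ValueError(f"{key} needs (between, within) levels")
            for lev in pair:
                if lev not in sp.LEVELS:
                    raise ValueError(f"unknown specificity level {lev!r} in {key}; "
                                     f"valid: {sp.LEVELS}")
            raw[key] = pair
    if "hypothesis_c" in raw and raw["hypothesis_c"] not in sp.LEVELS:
        raise ValueError(f"unknown specificity level {raw['hypothesis_c']!r}; "
                         f"valid: {sp.LEVELS}")
    if "seed" in raw and not isinstance(raw["seed"], (int, np.integer)):
        raise ValueError("seed must be an integer")
    if "regions" in raw:
        raw["regions"] = tuple(raw["regions"])
        unknown = set(raw["regions"]) - set(sp.REGIONS)
        if unknown:
            raise ValueError(f"unknown regions {sorted(unknown)}; valid: {sp.REGIONS}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"timing"}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    cfg = PipelineConfig(timing=timing, **raw)
    if cfg.n_clusters != len(cfg.timing.s1_durations):
        raise ValueError("n_clusters must equal the number of S1 durations "
                         "(one duration channel per cluster)")
    return cfg


def load_config(path: str | None) -> PipelineConfig:
    if path is None:
        return validate_config({})
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if path.endswith((".yml", ".yaml")) else json.loads(text)
    return validate_config(raw)


def _region_graph(cfg: PipelineConfig) -> sp.AMask:
    return sp.induced_subgraph(sp.region_graph_peblike(), list(cfg.regions))


def _ground_truth(cfg: PipelineConfig) -> dg.GroundTruth:
    return dg.make_ground_truth_network(
        hypothesis_a=cfg.hypothesis_a, hypothesis_b=cfg.hypothesis_b,
        hypothesis_c=cfg.hypothesis_c, region_graph=_region_graph(cfg),
        n_clusters=cfg.n_clusters, seed=cfg.spawn_seed("truth"),
        snr=cfg.snr, drive_regions="all",
        driven_region_index=_driven_index(cfg))


def _driven_index(cfg: PipelineConfig) -> int:
    return (list(cfg.regions).index(sp.DRIVEN_REGION)
            if sp.DRIVEN_REGION in cfg.regions else len(cfg.regions) - 1)


class MissingArtifactError(FileNotFoundError):
    pass


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"stage '{stage}' requires missing artifact {path.name}; "
            "run its producing stage first")
    return path


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in canonical order; return the manifest."""
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}; valid: {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = [st for st in STAGES if st in stages]
    for st in ordered:
        _STAGE_FUNCS[st](cfg, out)
    manifest = {"stages": ordered, "artifacts": {}}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["artifacts"][str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    truth = _ground_truth(cfg)
    ds = dg.build_cohort(cfg.n_subjects, cfg.timing, truth,
                         seed=cfg.spawn_seed("cohort"))
    (out / "config.json").write_text(json.dumps(
        {**dataclasses.asdict(cfg), "timing": dataclasses.asdict(cfg.timing)},
        default=str, indent=1))
    truth.params.save(str(out / "ground_truth_params.json"))
    (out / "ground_truth.json").write_text(json.dumps({
        "region_graph": truth.region_graph.to_dict(),
        "hypothesis_a": truth.hypothesis_a, "hypothesis_b": truth.hypothesis_b,
        "hypothesis_c": truth.hypothesis_c,
        "cluster_amplitudes": truth.cluster_amplitudes.tolist(),
        "snr": truth.snr, "seed": truth.seed}))
    for si, subj in enumerate(ds.subjects):
        for run in range(cfg.timing.n_runs):
            dg.write_events_tsv(subj.events[run],
                                str(out / f"events_sub{si:02d}_run{run:02d}.tsv"))
            dg.write_timeseries_tsv(subj.timeseries[run], ds.node_labels,
                                    str(out / f"bold_sub{si:02d}_run{run:02d}.tsv"))


def _load_subject_runs(cfg: PipelineConfig, out: Path, stage: str):
    events, series = [], []
    for si in range(cfg.n_subjects):
        ev_runs, ts_runs = [], []
        for run in range(cfg.timing.n_runs):
            ev = dg.read_events_tsv(str(_need(out / f"events_sub{si:02d}_run{run:02d}.tsv", stage)))
            ts, labels = dg.read_timeseries_tsv(
                str(_need(out / f"bold_sub{si:02d}_run{run:02d}.tsv", stage)))
            ev_runs.append(ev)
            ts_runs.append(ts)
        events.append(ev_runs)
        series.append(ts_runs)
    return events, series, labels


def _voxelize(cfg: PipelineConfig, series: list[list[np.ndarray]]):
    """Deterministic voxel expansion of node series (shared by glm/tuning)."""
    rng = np.random.default_rng(cfg.spawn_seed("voxels"))
    vox = []
    owner = None
    for ts_runs in series:
        runs = []
        for ts in ts_runs:
            v, owner = dg.expand_to_voxels(ts, cfg.n_voxels_per_cluster,
                                           cfg.voxel_noise_sd, rng)
            runs.append(v)
        vox.append(runs)
    return vox, owner


def _stage_glm(cfg: PipelineConfig, out: Path) -> None:
    events, series, labels = _load_subject_runs(cfg, out, "glm")
    vox, owner = _voxelize(cfg, series)
    n_dur = len(cfg.timing.s1_durations)
    frames = []
    for si in range(cfg.n_subjects):
        X = gm.build_design_matrix(events[si], cfg.timing, hp_cutoff=cfg.hp_cutoff)
        ts = np.vstack(vox[si])
        _, tmap = gm.fit_glm(ts, X)
        for ri, region in enumerate(cfg.regions):
            sel = np.flatnonzero(owner // cfg.n_clusters == ri)
            sub = gm.TStatMap(t=tmap.t[sel], dof=tmap.dof,
                              contrast_names=tmap.contrast_names)
            clusters = gm.winner_take_all(sub, threshold=cfg.t_threshold,
                                          min_cluster=cfg.min_cluster, region=region)
            frames.append(pd.DataFrame({
                "subject": si, "region": region, "voxel": sel,
                "true_cluster": owner[sel] % cfg.n_clusters + 1,
                "label": clusters.labels,
            }))
    pd.concat(frames).to_csv(out / "wta_labels.tsv", sep="\t", index=False)


def _stage_tuning(cfg: PipelineConfig, out: Path) -> None:
    events, series, labels = _load_subject_runs(cfg, out, "tuning")
    lab = pd.read_csv(_need(out / "wta_labels.tsv", "tuning"), sep="\t")
    vox, owner = _voxelize(cfg, series)
    n_dur = len(cfg.timing.s1_durations)
    plan = tn.make_split_plan(cfg.timing.n_runs, min(cfg.timing.n_runs, 18),
                              seed=cfg.spawn_seed("splits"))
    all_curves = []
    for si in range(cfg.n_subjects):
        voxel_runs = np.stack(vox[si])
        sub_lab = lab[lab.subject == si]
        for it, (select, measure) in enumerate(plan.iterations):
            for region in cfg.regions:
                reg = sub_lab[sub_lab.region == region]
                labels_vec = np.zeros(voxel_runs.shape[2], dtype=int)
                labels_vec[reg.voxel.to_numpy()] = reg.label.to_numpy()
                curves = tn.extract_tuning(voxel_runs, events[si], labels_vec,
                                           cfg.timing.t_volume, n_dur,
                                           measure_runs=measure, region=region,
                                           iteration=it)
                df = tn.curves_to_frame(curves, cfg.timing.s1_durations)
                df.insert(0, "subject", si)
                all_curves.append(df)
    pd.concat(all_curves).to_csv(out / "tuning_curves.tsv", sep="\t", index=False)


def _stage_space(cfg: PipelineConfig, out: Path) -> None:
    specs = sp.enumerate_model_space(region_mask=_region_graph(cfg),
                                     n_clusters=cfg.n_clusters,
                                     driven_region_index=_driven_index(cfg))
    sp.save_model_space(specs, str(out / "model_space.json"))
    cmasks = sp.enumerate_c_matrices(n_regions=len(cfg.regions))
    (out / "c_space.json").write_text(json.dumps(
        [m.astype(int).tolist() for m in cmasks]))


def _full_layout(cfg: PipelineConfig) -> ParamLayout:
    full = sp.make_model_spec("independent", "independent", "independent",
                              "independent", "independent",
                              region_mask=_region_graph(cfg),
                              n_clusters=cfg.n_clusters,
                              driven_region_index=_driven_index(cfg))
    return ParamLayout.from_spec(full)


INVERSION_MICRO = 8  # microtime steps per volume during estimation


def _stage_invert(cfg: PipelineConfig, out: Path) -> None:
    events, series, labels = _load_subject_runs(cfg, out, "invert")
    layout = _full_layout(cfg)
    priors = default_priors(layout)
    micro = INVERSION_MICRO
    dt = cfg.timing.t_volume / micro
    n_steps = cfg.timing.volumes_per_run * micro
    records = []
    for si in range(cfg.n_subjects):
        for run in range(cfg.timing.n_runs):
            U = fw.build_inputs(dg.s1_onsets_by_duration(events[si][run], cfg.n_clusters),
                                n_steps, dt)
            res = variational_laplace(layout, series[si][run], U, dt, priors=priors,
                                      micro=micro, max_iter=32,
                                      project_confounds=True)
            records.append({
                "subject": si, "run": run, "free_energy": res.free_energy,
                "explained_variance": res.explained_variance,
                "converged": bool(res.converged),
                "f_trajectory": [float(f) for f in res.f_trajectory],
                "mean": res.mean.tolist(), "cov": res.cov.tolist(),
                "lambdas": res.lambdas.tolist(),
                "n_confounds": res.n_confounds,
            })
    (out / "inversions.json").write_text(json.dumps(records))


def _load_inversions(cfg: PipelineConfig, out: Path, stage: str):
    layout = _full_layout(cfg)
    from .invert import InversionResult
    records = json.loads(_need(out / "inversions.json", stage).read_text())
    results = []
    for r in records:
        results.append(InversionResult(
            mean=np.asarray(r["mean"]), cov=np.asarray(r["cov"]),
            free_energy=r["free_energy"], lambdas=np.asarray(r["lambdas"]),
            layout=layout, n_confounds=r["n_confounds"],
            explained_variance=r["explained_variance"], iterations=0,
            converged=r["converged"]))
    return layout, results, records


def _stage_compare(cfg: PipelineConfig, out: Path) -> None:
    layout, results, records = _load_inversions(cfg, out, "compare")
    specs = sp.load_model_space(str(_need(out / "model_space.json", "compare")))
    priors = default_priors(layout)
    reduced = [bayes.reduce_priors(priors, _spec_keep(layout, s)) for s in specs]
    subjects = sorted({r["subject"] for r in records})
    lme = np.zeros((len(subjects), len(specs)))
    for res, rec in zip(results, records):
        lme[subjects.index(rec["subject"])] += bayes.score_model_space(res, priors, reduced)
    bms = bayes.rfx_bms(lme, seed=cfg.spawn_seed("bms"),
                        model_names=[s.name for s in specs])
    fam = bayes.family_inference(lme, [s.family for s in specs],
                                 seed=cfg.spawn_seed("family"))
    (out / "evidence.tsv").write_text(
        pd.DataFrame(lme, columns=[s.name for s in specs]).to_csv(sep="\t", index=False))
    (out / "bms.json").write_text(json.dumps({
        "models": bms.model_names,
        "pep": bms.protected_exceedance_prob.tolist(),
        "ep": bms.exceedance_prob.tolist(),
        "expected": bms.expected_prob.tolist(),
        "bor": bms.bayesian_omnibus_risk,
        "families": fam.model_names,
        "family_pep": fam.protected_exceedance_prob.tolist(),
        "family_expected": fam.expected_prob.tolist(),
        "pep_threshold": cfg.pep_threshold,
    }))


def _spec_keep(layout: ParamLayout, spec: sp.ModelSpec) -> np.ndarray:
    keep = np.empty(layout.size, dtype=bool)
    for k, e in enumerate(layout.entries):
        if e[0] == "a":
            keep[k] = spec.a_mask.allowed[e[1], e[2]]
        elif e[0] == "a_self":
            keep[k] = True
        elif e[0] == "b":
            keep[k] = spec.b_masks[e[1], e[2], e[3]]
        else:
            keep[k] = spec.c_mask[e[1], e[2]]
    return keep


def _stage_peb(cfg: PipelineConfig, out: Path) -> None:
    layout, results, _ = _load_inversions(cfg, out, "peb")
    priors = default_priors(layout)
    group = pb.fit_peb(results, priors)
    a_idx = np.array([i for i, e in enumerate(layout.entries) if e[0] == "a"])
    cand = np.zeros(layout.size, bool)
    cand[a_idx] = True
    pruned = pb.prune_parameters(group, threshold=cfg.pp_threshold, candidates=cand)
    strengths = pb.peb_bma(pruned)
    n = layout.n_nodes
    amat = np.zeros((n, n))
    for i, e in enumerate(layout.entries):
        if e[0] == "a":
            amat[e[1], e[2]] = strengths[i]
    surviving = sp.AMask(nodes=layout.nodes,
                         allowed=(amat != 0) | np.eye(n, dtype=bool))
    (out / "peb_result.json").write_text(json.dumps({
        "gamma": pruned.gamma, "free_energy": pruned.free_energy,
        "pp": pruned.pp.tolist(), "names": layout.names(),
        "group_a_matrix": amat.tolist(),
        "surviving_mask": surviving.to_dict(),
    }))


def _stage_graph(cfg: PipelineConfig, out: Path) -> None:
    peb_res = json.loads(_need(out / "peb_result.json", "graph").read_text())
    amat = np.asarray(peb_res["group_a_matrix"])
    g = gr.to_graph(amat, nodes=peb_res["surviving_mask"]["nodes"])
    gr.metrics_long(g).to_csv(out / "graph_metrics.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "glm": _stage_glm,
    "tuning": _stage_tuning,
    "space": _stage_space,
    "invert": _stage_invert,
    "compare": _stage_compare,
    "peb": _stage_peb,
    "graph": _stage_graph,
}
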