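"""Hypothesis-constrained connectivity model spaces.

The analysis distinguishes three *duration-specificity* levels for how the
duration-selective clusters of one brain region may talk to those of another
(or to each other within a region):

* ``independent`` — any cluster may connect to any cluster (PD unconstrained),
* ``neighboring``  — a cluster connects to the cluster with the same preferred
  duration (PD) and its immediate neighbors (PD +/- 1),
* ``dependent``    — a cluster connects only to the cluster sharing its PD.

These levels are applied separately to between-region and within-region
entries of the latent coupling matrix A, to the input modulations B and to the
driving inputs C, producing the 108-model space compared at the group level.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

#: canonical specificity levels, coded 1..3 (increasingly specific)
LEVELS = ("independent", "neighboring", "dependent")
LEVEL_CODE = {name: i + 1 for i, name in enumerate(LEVELS)}

#: the five regions of the duration network, in canonical order
REGIONS = ("CRB", "V1", "IPS", "SMA", "IFG")

#: region receiving the driving input in the cluster-level (20-node) space
DRIVEN_REGION = "IPS"


def _as_level(level: str | int) -> str:
    if isinstance(level, (int, np.integer)):
        if not 1 <= level <= 3:
            raise ValueError(f"level code must be 1..3, got {level}")
        return LEVELS[level - 1]
    if level not in LEVELS:
        raise ValueError(f"unknown specificity level {level!r}; valid: {LEVELS}")
    return level


@dataclass
class AMask:
    """Boolean connectivity mask over labeled nodes (target x source).

    Self-connections (diagonal) are always allowed; they carry the intrinsic
    decay of each node and are never subject to hypothesis constraints.
    """

    nodes: list[str]
    allowed: np.ndarray  # bool, shape (n, n), [target, source]

    def __post_init__(self) -> None:
        self.allowed = np.asarray(self.allowed, dtype=bool)
        n = len(self.nodes)
        if self.allowed.shape != (n, n):
            raise ValueError("mask shape must be square and match node labels")
        if not np.all(np.diag(self.allowed)):
            raise ValueError("self-connections must be allowed (diagonal True)")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_count(self) -> int:
        """Number of allowed directed off-diagonal edges."""
        off = self.allowed & ~np.eye(self.n_nodes, dtype=bool)
        return int(off.sum())

    def edges(self) -> list[tuple[str, str]]:
        """Directed off-diagonal edges as (source, target) label pairs."""
        out = []
        for t in range(self.n_nodes):
            for s in range(self.n_nodes):
                if t != s and self.allowed[t, s]:
                    out.append((self.nodes[s], self.nodes[t]))
        return out

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes), "allowed": self.allowed.astype(int).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AMask":
        return cls(nodes=list(d["nodes"]), allowed=np.asarray(d["allowed"], dtype=bool))


def region_graph_peblike() -> AMask:
    """The 5-region architecture found by the group-level PEB stage.

    Bidirectional coupling between cerebellum and V1 and between cerebellum
    and IFG; feedforward connections CRB->IPS, CRB->SMA, V1->SMA, IPS->SMA;
    feedback IFG->V1.  SMA is a pure sink.  9 directed edges in total.
    """
    n = len(REGIONS)
    idx = {r: i for i, r in enumerate(REGIONS)}
    allowed = np.eye(n, dtype=bool)
    edges = [
        ("CRB", "V1"), ("V1", "CRB"),
        ("CRB", "IFG"), ("IFG", "CRB"),
        ("CRB", "IPS"),
        ("CRB", "SMA"), ("V1", "SMA"), ("IPS", "SMA"),
        ("IFG", "V1"),
    ]
    for src, tgt in edges:
        allowed[idx[tgt], idx[src]] = True
    return AMask(nodes=list(REGIONS), allowed=allowed)


def fully_connected(nodes: list[str] | None = None) -> AMask:
    """All-to-all mask (used for the first-level full model of the PEB stage)."""
    nodes = list(REGIONS) if nodes is None else list(nodes)
    n = len(nodes)
    return AMask(nodes=nodes, allowed=np.ones((n, n), dtype=bool))


def induced_subgraph(mask: AMask, nodes: list[str]) -> AMask:
    """Induced sub-architecture over a subset of labeled nodes (order kept)."""
    idx = [mask.nodes.index(n) for n in nodes]
    return AMask(nodes=list(nodes), allowed=mask.allowed[np.ix_(idx, idx)])


def cluster_pair_allowed(c_t: int, c_s: int, level: str) -> bool:
    """Whether cluster pair (target PD rank, source PD rank) is allowed.

    Duration ranks are ordinal (no wraparound): rank 0's neighbors are {0, 1}.
    """
    level = _as_level(level)
    if level == "independent":
        return True
    if level == "neighboring":
        return abs(c_t - c_s) <= 1
    return c_t == c_s


def expand_to_clusters(
    region_mask: AMask,
    level_between: str | int,
    level_within: str | int,
    n_clusters: int = 4,
) -> AMask:
    """Expand a region-level mask to the cluster level under specificity levels.

    Each region is replaced by ``n_clusters`` duration-selective clusters.  For
    every allowed region edge r->s the admitted cluster pairs follow
    ``level_between``; within-region off-diagonal pairs follow
    ``level_within`` ("dependent" within a region means self-connections only,
    since each cluster has a distinct preferred duration).
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    lb, lw = _as_level(level_between), _as_level(level_within)
    nr = region_mask.n_nodes
    nodes = [f"{r}_c{c + 1}" for r in region_mask.nodes for c in range(n_clusters)]
    n = nr * n_clusters
    allowed = np.eye(n, dtype=bool)
    for rt in range(nr):
        for rs in range(nr):
            if not region_mask.allowed[rt, rs]:
                continue
            for ct in range(n_clusters):
                for cs in range(n_clusters):
                    it, js = rt * n_clusters + ct, rs * n_clusters + cs
                    if it == js:
                        continue
                    if rt == rs:
                        ok = cluster_pair_allowed(ct, cs, lw) and ct != cs \
                            if lw != "dependent" else False
                    else:
                        ok = cluster_pair_allowed(ct, cs, lb)
                    if ok:
                        allowed[it, js] = True
    return AMask(nodes=nodes, allowed=allowed)


def enumerate_c_matrices(n_regions: int = 5, max_driven: int = 2) -> list[np.ndarray]:
    """All region-level driving-input masks with 1..max_driven driven regions.

    Each mask is a boolean vector over regions, applied identically to all
    input channels.  Defaults give the 15 combinations of the C-matrix search.
    """
    if max_driven < 1:
        raise ValueError("max_driven must be >= 1")
    if max_driven > n_regions:
        raise ValueError("max_driven cannot exceed n_regions")
    masks = []
    for k in range(1, max_driven + 1):
        for combo in itertools.combinations(range(n_regions), k):
            m = np.zeros(n_regions, dtype=bool)
            m[list(combo)] = True
            masks.append(m)
    return masks


def c_cluster_mask(
    level: str | int,
    n_regions: int = 5,
    n_clusters: int = 4,
    driven_region_index: int | None = None,
) -> np.ndarray:
    """Cluster-level C mask (nodes x inputs) under a specificity level.

    Input channel j (the j-th S1 duration) may drive clusters of the driven
    region: its PD-matched cluster (dependent), PD +/- 1 (neighboring) or all
    clusters (independent).  Other regions are never directly driven.
    """
    level = _as_level(level)
    if driven_region_index is None:
        driven_region_index = REGIONS.index(DRIVEN_REGION) if n_regions == len(REGIONS) else n_regions - 1
    n = n_regions * n_clusters
    mask = np.zeros((n, n_clusters), dtype=bool)
    for c in range(n_clusters):
        for j in range(n_clusters):
            if cluster_pair_allowed(c, j, level):
                mask[driven_region_index * n_clusters + c, j] = True
    return mask


def b_cluster_masks(
    a_mask: AMask,
    region_mask: AMask,
    level_between: str | int,
    level_within: str | int,
    n_clusters: int = 4,
) -> np.ndarray:
    """Cluster-level B masks, one per input channel, shape (m, n, n).

    Input j may modulate an A-allowed connection only when both endpoint
    clusters lie within the level's PD distance of j (dependent: both equal j;
    neighboring: within +/-1 of j; independent: any).  Between- and
    within-region entries follow their own levels.  Modulation of
    self-connections is never allowed.
    """
    lb, lw = _as_level(level_between), _as_level(level_within)
    nr, nc = region_mask.n_nodes, n_clusters
    n = nr * nc
    masks = np.zeros((nc, n, n), dtype=bool)
    for j in range(nc):
        for it in range(n):
            for js in range(n):
                if it == js or not a_mask.allowed[it, js]:
                    continue
                rt, ct = divmod(it, nc)
                rs, cs = divmod(js, nc)
                level = lw if rt == rs else lb
                if cluster_pair_allowed(ct, j, level) and cluster_pair_allowed(cs, j, level):
                    masks[j, it, js] = True
    return masks


@dataclass
class ModelSpec:
    """One hypothesis-constrained model of the cluster-level space.

    Levels are stored by name; ``family`` is the C-level label, the partition
    used for family inference.  Masks are the concrete boolean structures on
    which priors are placed (masked-out entries are fixed at zero).
    """

    a_between: str
    a_within: str
    b_between: str
    b_within: str
    c_level: str
    a_mask: AMask
    b_masks: np.ndarray  # (m, n, n) bool
    c_mask: np.ndarray  # (n, m) bool
    family: str = field(default="")
    enforce_nesting: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if not self.family:
            self.family = self.c_level
        if self.enforce_nesting:
            if LEVEL_CODE[self.b_between] < LEVEL_CODE[self.a_between]:
                raise ValueError("B between-level must be at least as specific as A's")
            if LEVEL_CODE[self.b_within] < LEVEL_CODE[self.a_within]:
                raise ValueError("B within-level must be at least as specific as A's")
        a = self.a_mask.allowed
        if np.any(self.b_masks & ~a[None, :, :]):
            raise ValueError("B mask must be a subset of the A mask")

    @property
    def name(self) -> str:
        code = {lev: str(LEVEL_CODE[lev]) for lev in LEVELS}
        return ("Ab{}Aw{}Bb{}Bw{}C{}".format(
            code[self.a_between], code[self.a_within],
            code[self.b_between], code[self.b_within], code[self.c_level]))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "levels": {
                "a_between": self.a_between, "a_within": self.a_within,
                "b_between": self.b_between, "b_within": self.b_within,
                "c_level": self.c_level,
            },
            "family": self.family,
            "a_mask": self.a_mask.to_dict(),
            "b_masks": self.b_masks.astype(int).tolist(),
            "c_mask": self.c_mask.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        lv = d["levels"]
        return cls(
            a_between=lv["a_between"], a_within=lv["a_within"],
            b_between=lv["b_between"], b_within=lv["b_within"],
            c_level=lv["c_level"],
            a_mask=AMask.from_dict(d["a_mask"]),
            b_masks=np.asarray(d["b_masks"], dtype=bool),
            c_mask=np.asarray(d["c_mask"], dtype=bool),
            family=d.get("family", ""),
        )


def make_model_spec(
    a_between: str | int,
    a_within: str | int,
    b_between: str | int,
    b_within: str | int,
    c_level: str | int,
    region_mask: AMask | None = None,
    n_clusters: int = 4,
    driven_region_index: int | None = None,
    enforce_nesting: bool = True,
) -> ModelSpec:
    """Build the concrete masks of one hypothesis combination."""
    region_mask = region_graph_peblike() if region_mask is None else region_mask
    ab, aw = _as_level(a_between), _as_level(a_within)
    bb, bw = _as_level(b_between), _as_level(b_within)
    cl = _as_level(c_level)
    a_mask = expand_to_clusters(region_mask, ab, aw, n_clusters=n_clusters)
    b_masks = b_cluster_masks(a_mask, region_mask, bb, bw, n_clusters=n_clusters)
    c_mask = c_cluster_mask(cl, n_regions=region_mask.n_nodes,
                            n_clusters=n_clusters,
                            driven_region_index=driven_region_index)
    return ModelSpec(ab, aw, bb, bw, cl, a_mask, b_masks, c_mask,
                     enforce_nesting=enforce_nesting)


def enumerate_model_space(
    region_mask: AMask | None = None,
    n_clusters: int = 4,
    driven_region_index: int | None = None,
    nested_only: bool = True,
) -> list[ModelSpec]:
    """Enumerate the hypothesis space Ab^i Aw^j Bb^k Bw^m C^n.

    i, j, n range over 1..3; k >= i and m >= j (a modulation cannot be less
    specific than the connection it rides on).  With the nesting constraints
    this yields 108 models in 3 equal C-level families; lifting them
    (``nested_only=False``) yields the full 3^5 = 243 combinations.
    """
    region_mask = region_graph_peblike() if region_mask is None else region_mask
    specs = []
    for i in range(1, 4):
        for j in range(1, 4):
            k_range = range(i, 4) if nested_only else range(1, 4)
            for k in k_range:
                m_range = range(j, 4) if nested_only else range(1, 4)
                for m in m_range:
                    for n in range(1, 4):
                        specs.append(make_model_spec(
                            i, j, k, m, n,
                            region_mask=region_mask, n_clusters=n_clusters,
                            driven_region_index=driven_region_index,
                            enforce_nesting=nested_only))
    return specs


def family_partition(specs: list[ModelSpec]) -> dict[str, str]:
    """Map model name -> family label (the C specificity level)."""
    return {s.name: s.family for s in specs}


def save_model_space(specs: list[ModelSpec], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in specs], fh)


def load_model_space(path: str) -> list[ModelSpec]:
    with open(path) as fh:
        return [ModelSpec.from_dict(d) for d in json.load(fh)]
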