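"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three generators: Poisson window coverage over the three window classes
(with sample-specific diploid calibration and female mismapping
background), infinite-sites mutations dropped on a known genealogy, and
patriline pedigrees with known generation-interval distributions. All are
pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coverage import (
    FEMALE,
    LABEL_MCY,
    LABEL_NONMSY,
    LABEL_SCY,
    MALE,
    SampleProfile,
    WindowRecord,
)
from .phylogeny import ANCESTRAL, DERIVED, CladeTree, HaploMatrix, Node
from .rates import PedigreeLink


@dataclass(frozen=True)
class SimCoverageParams:
    n_males: int = 10
    n_females: int = 5
    c_range: tuple[float, float] = (20.0, 40.0)
    background: float = 0.3
    window_size: int = 50
    n_windows_per_class: int = 2000
    mcY_copies: int = 3
    overdispersion: float = 0.0  # gamma-Poisson mixing CV^2; 0 = pure Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 1 or self.n_females < 1 or self.n_windows_per_class < 1:
            raise ValueError("counts must be >= 1")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0 < self.c_range[0] <= self.c_range[1]):
            raise ValueError("need 0 < c_low <= c_high")
        if not (0 <= self.background < self.c_range[0] / 2):
            raise ValueError("background must satisfy 0 <= b < c_low / 2")
        if self.mcY_copies < 3:
            raise ValueError(
                "mcY copy number must be >= 3 so expected relative coverage "
                "clears the scY cutoff unambiguously"
            )
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


def simulate_coverage(
    params: SimCoverageParams,
) -> tuple[list[WindowRecord], list[SampleProfile], list[str]]:
    """Per-window Poisson coverage for the three window classes.

    Expected coverages: nonMSY -> c (everyone); scY -> c/2 for males and
    the background for females; mcY -> copies*c/2 for males, background for
    females. Returns windows on one synthetic contig per class, profiles
    (with the true c and b), and truth labels aligned with the windows.
    """
    rng = np.random.default_rng(params.seed)
    profiles: list[SampleProfile] = []
    for i in range(params.n_males):
        c = float(rng.uniform(*params.c_range))
        profiles.append(SampleProfile(f"male{i + 1}", MALE, c))
    for j in range(params.n_females):
        c = float(rng.uniform(*params.c_range))
        profiles.append(SampleProfile(f"female{j + 1}", FEMALE, c, params.background))

    def draw(mean: float, size: int) -> np.ndarray:
        if mean == 0:
            return np.zeros(size)
        if params.overdispersion > 0:
            shape = 1.0 / params.overdispersion
            lam = rng.gamma(shape, mean / shape, size=size)
            return rng.poisson(lam).astype(float)
        return rng.poisson(mean, size=size).astype(float)

    windows: list[WindowRecord] = []
    labels: list[str] = []
    w = params.window_size
    for label in (LABEL_SCY, LABEL_MCY, LABEL_NONMSY):
        contig = f"sim_{label}"
        cov = {}
        for p in profiles:
            if label == LABEL_NONMSY:
                mean = p.c
            elif p.is_male:
                half = p.c / 2.0
                mean = half if label == LABEL_SCY else params.mcY_copies * half
            else:
                mean = params.background
            cov[p.sample_id] = draw(mean, params.n_windows_per_class)
        for k in range(params.n_windows_per_class):
            windows.append(
                WindowRecord(
                    contig,
                    k * w,
                    (k + 1) * w,
                    {sid: float(cov[sid][k]) for sid in cov},
                )
            )
            labels.append(label)
    return windows, profiles, labels


# ---------------------------------------------------------------------------
# infinite-sites genealogies


@dataclass(frozen=True)
class SimTreeParams:
    n_leaves: int = 10
    mean_mutations_per_branch: float = 3.0
    branch_lengths: Mapping[str, float] | None = None  # branch label -> expectation
    outgroup_mutations: int = 0
    topology: object | None = None  # None = random coalescent; "star"; nested tuples
    outgroup_id: str = "outgroup"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("need at least one leaf")
        if self.mean_mutations_per_branch < 0 or self.outgroup_mutations < 0:
            raise ValueError("expected mutation counts must be >= 0")
        if self.branch_lengths is not None and any(
            v < 0 for v in self.branch_lengths.values()
        ):
            raise ValueError("expected mutation counts must be >= 0")


def _leaf_names(n: int) -> list[str]:
    return [f"L{i + 1}" for i in range(n)]


def _build_topology(params: SimTreeParams, rng: np.random.Generator) -> Node:
    names = _leaf_names(params.n_leaves)
    leaves = [Node(nm, members=(nm,)) for nm in names]
    if params.topology == "star" or params.n_leaves == 1:
        return Node("ingroup", children=leaves) if len(leaves) > 1 else leaves[0]
    if params.topology is not None:

        def from_nested(t: object, counter: list[int]) -> Node:
            if isinstance(t, str):
                return Node(t, members=(t,))
            counter[0] += 1
            return Node(
                f"n{counter[0]}", children=[from_nested(c, counter) for c in t]
            )

        root = from_nested(params.topology, [0])
        root.label = "ingroup"
        return root
    # random coalescent topology: repeatedly join two random lineages
    pool = leaves[:]
    counter = 0
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False).tolist())
        counter += 1
        parent = Node(f"n{counter}", children=[pool[i], pool[j]])
        pool = [p for t, p in enumerate(pool) if t not in (i, j)] + [parent]
    pool[0].label = "ingroup"
    return pool[0]


def _branch_label(node: Node) -> str:
    if node.is_leaf:
        return node.label
    return "clade:" + ",".join(sorted(lf.label for lf in node.leaves()))


def simulate_infinite_sites(
    params: SimTreeParams,
) -> tuple[HaploMatrix, CladeTree]:
    """Drop Poisson mutation counts on a known genealogy.

    Each mutation creates a new site derived exactly in the branch's
    descendant leaves, so the matrix passes the four-gamete test by
    construction. ``outgroup_mutations`` extra sites go on the ingroup stem
    (derived in every ingroup leaf); the outgroup row is all-ancestral.
    Branch expectations can be overridden per branch label (leaf name, or
    ``clade:`` plus the sorted leaf names).
    """
    rng = np.random.default_rng(params.seed)
    mrca = _build_topology(params, rng)
    root = Node("root", children=[Node(params.outgroup_id,
                                       members=(params.outgroup_id,)), mrca])
    tree = CladeTree(root, params.outgroup_id)

    leaf_names = _leaf_names(params.n_leaves)
    leaf_idx = {nm: i for i, nm in enumerate(leaf_names)}
    sites: list[str] = []
    cols: list[np.ndarray] = []
    counter = 0

    def add_sites(node: Node, n_mut: int) -> None:
        nonlocal counter
        col = np.zeros(params.n_leaves, dtype=np.int8)
        for lf in node.leaves():
            col[leaf_idx[lf.label]] = DERIVED
        for _ in range(n_mut):
            counter += 1
            sid = f"s{counter:04d}"
            node.mutations.append(sid)
            sites.append(sid)
            cols.append(col)

    add_sites(mrca, params.outgroup_mutations)
    for node in mrca.walk():
        if node is mrca:
            continue
        label = _branch_label(node)
        expect = params.mean_mutations_per_branch
        if params.branch_lengths is not None and label in params.branch_lengths:
            expect = params.branch_lengths[label]
        add_sites(node, int(rng.poisson(expect)))

    n_rows = params.n_leaves + 1
    states = np.full((n_rows, len(sites)), ANCESTRAL, dtype=np.int8)
    for j, col in enumerate(cols):
        states[:-1, j] = col  # outgroup is the last, all-ancestral row
    matrix = HaploMatrix(
        leaf_names + [params.outgroup_id], sites, states, params.outgroup_id
    )
    return matrix, tree


# ---------------------------------------------------------------------------
# pedigrees


def simulate_pedigree(
    n_tips: int,
    interval_mean: float,
    interval_sd: float,
    founder_birth: int = 1680,
    founder_id: str = "founder",
    seed: int = 0,
) -> list[PedigreeLink]:
    """Patriline tree rooted at one founder with known interval statistics.

    Each new individual attaches as a son to a uniformly chosen existing
    male; father-son intervals are truncated-normal (minimum 2 years), so
    the graph is acyclic by construction.
    """
    if n_tips < 1:
        raise ValueError("need at least one tip")
    if not (interval_mean > interval_sd >= 0):
        raise ValueError("need interval_mean > interval_sd >= 0")
    rng = np.random.default_rng(seed)
    births = {founder_id: founder_birth}
    ids = [founder_id]
    links: list[PedigreeLink] = []
    for i in range(n_tips):
        father = ids[int(rng.integers(len(ids)))]
        while True:
            interval = rng.normal(interval_mean, interval_sd) if interval_sd else interval_mean
            if interval >= 2:
                break
        son = f"M{i + 1:04d}"
        son_birth = int(round(births[father] + interval))
        links.append(PedigreeLink(father, son, births[father], son_birth))
        births[son] = son_birth
        ids.append(son)
    return links
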