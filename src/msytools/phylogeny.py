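"""Haplotype matrices, perfect-phylogeny genealogies and flank liftover.

Allelic states are coded as small ints: 0 = ancestral, 1 = derived,
-1 = missing. Under the infinite-sites assumption (verified with the
four-gamete test) the genealogy is a perfect phylogeny: every variant
maps to exactly one branch, and the tree length equals the number of
polymorphic sites. An exhaustive Fitch maximum-parsimony search over all
topologies is provided as an independent oracle for small matrices.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

ANCESTRAL = 0
DERIVED = 1
MISSING = -1


class IncompatibleMatrixError(ValueError):
    """Raised when a matrix violates the infinite-sites assumption."""

    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs = pairs
        super().__init__(
            f"matrix is not infinite-sites compatible; offending site pairs: {pairs}"
        )


@dataclass
class HaploMatrix:
    """Samples x variants allelic-state matrix with a designated outgroup."""

    samples: list[str]
    sites: list[str]
    states: np.ndarray  # int8, shape (n_samples, n_sites)
    outgroup_id: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.samples), len(self.sites)):
            raise ValueError("states shape does not match samples x sites")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if self.outgroup_id is not None and self.outgroup_id not in self.samples:
            raise ValueError(f"outgroup {self.outgroup_id!r} not among samples")

    def row(self, sample_id: str) -> np.ndarray:
        return self.states[self.samples.index(sample_id)]

    def copy(self) -> "HaploMatrix":
        return HaploMatrix(
            list(self.samples), list(self.sites), self.states.copy(), self.outgroup_id
        )

    def drop_samples(self, ids: Iterable[str]) -> "HaploMatrix":
        drop = set(ids)
        keep = [i for i, s in enumerate(self.samples) if s not in drop]
        og = self.outgroup_id if self.outgroup_id not in drop else None
        return HaploMatrix(
            [self.samples[i] for i in keep], list(self.sites), self.states[keep], og
        )


@dataclass(frozen=True)
class Haplotype:
    id: str
    member_samples: tuple[str, ...]
    defining_sites: frozenset[str]


def polarize(
    matrix: HaploMatrix,
    outgroup_id: str,
    secondary_outgroup_id: str | None = None,
) -> HaploMatrix:
    """Recode states so the outgroup reads ancestral at every retained site.

    Sites where the outgroup is missing fall back to the secondary outgroup
    when given; otherwise they are dropped with a warning.
    """
    if outgroup_id not in matrix.samples:
        raise ValueError(f"outgroup {outgroup_id!r} not among samples")
    og = matrix.row(outgroup_id)
    og2 = (
        matrix.row(secondary_outgroup_id)
        if secondary_outgroup_id is not None
        else None
    )
    keep_cols: list[int] = []
    flip: list[bool] = []
    for j in range(len(matrix.sites)):
        anc = og[j]
        if anc == MISSING and og2 is not None:
            anc = og2[j]
        if anc == MISSING:
            logger.warning(
                "site %s dropped: outgroup state missing and no fallback",
                matrix.sites[j],
            )
            continue
        keep_cols.append(j)
        flip.append(anc == DERIVED)
    states = matrix.states[:, keep_cols].copy()
    flip_arr = np.asarray(flip, dtype=bool)
    obs = states != MISSING
    states[:, flip_arr] = np.where(
        obs[:, flip_arr], 1 - states[:, flip_arr], MISSING
    ).astype(np.int8)
    return HaploMatrix(
        list(matrix.samples),
        [matrix.sites[j] for j in keep_cols],
        states,
        outgroup_id,
    )


def collapse_haplotypes(matrix: HaploMatrix) -> list[Haplotype]:
    """Partition samples into maximal identical-state groups.

    Missing entries are wildcards: a sample joins the first group whose
    every member agrees with it at all mutually observed sites, which makes
    the assignment deterministic in input order.
    """
    groups: list[list[int]] = []
    S = matrix.states
    for i in range(len(matrix.samples)):
        for g in groups:
            ok = True
            for m in g:
                a, b = S[i], S[m]
                obs = (a != MISSING) & (b != MISSING)
                if np.any(a[obs] != b[obs]):
                    ok = False
                    break
            if ok:
                g.append(i)
                break
        else:
            groups.append([i])
    out: list[Haplotype] = []
    for n, g in enumerate(groups, start=1):
        # consensus derived sites (any member observed derived)
        sub = S[g]
        derived = frozenset(
            matrix.sites[j]
            for j in range(len(matrix.sites))
            if np.any(sub[:, j] == DERIVED)
        )
        out.append(
            Haplotype(f"HT{n}", tuple(matrix.samples[i] for i in g), derived)
        )
    return out


def four_gamete_check(
    matrix: HaploMatrix,
) -> tuple[bool, list[tuple[str, str]]]:
    """Infinite-sites compatibility: no site pair may show all four gametes.

    Missing entries are wildcards (rows missing at either site are ignored
    for that pair).
    """
    S = matrix.states
    bad: list[tuple[str, str]] = []
    n_sites = len(matrix.sites)
    for j, k in itertools.combinations(range(n_sites), 2):
        a, b = S[:, j], S[:, k]
        obs = (a != MISSING) & (b != MISSING)
        g = set(zip(a[obs].tolist(), b[obs].tolist()))
        if len(g) == 4:
            bad.append((matrix.sites[j], matrix.sites[k]))
    return (not bad), bad


# ---------------------------------------------------------------------------
# trees


@dataclass
class Node:
    """Tree node; ``mutations`` are the variant ids on the branch above it."""

    label: str
    children: list["Node"] = field(default_factory=list)
    mutations: list[str] = field(default_factory=list)
    members: tuple[str, ...] = ()  # leaf: samples carried by this haplotype

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]

    def walk(self) -> Iterable["Node"]:
        yield self
        for ch in self.children:
            yield from ch.walk()


class CladeTree:
    """Rooted genealogy whose branches carry mutation lists."""

    def __init__(self, root: Node, outgroup_id: str | None = None):
        self.root = root
        self.outgroup_id = outgroup_id

    def nodes(self) -> list[Node]:
        return list(self.root.walk())

    @property
    def tree_length(self) -> int:
        return sum(len(n.mutations) for n in self.root.walk())

    def branch_mutation_counts(self) -> dict[str, int]:
        return {n.label: len(n.mutations) for n in self.root.walk()}

    def branch_mutations(self) -> dict[str, list[str]]:
        return {n.label: list(n.mutations) for n in self.root.walk()}

    def find_clade(self, leaf_labels: Iterable[str]) -> Node | None:
        want = frozenset(leaf_labels)
        for n in self.root.walk():
            if frozenset(lf.label for lf in n.leaves()) == want:
                return n
        return None

    def clades(self) -> set[frozenset[str]]:
        return {
            frozenset(lf.label for lf in n.leaves())
            for n in self.root.walk()
            if not n.is_leaf
        }

    def to_newick(self, counts: bool = True) -> str:
        def fmt(n: Node) -> str:
            dist = f":{len(n.mutations)}" if counts else ""
            if n.is_leaf:
                return f"{n.label}{dist}"
            inner = ",".join(fmt(c) for c in n.children)
            return f"({inner}){n.label}{dist}"

        return fmt(self.root) + ";"


def build_perfect_phylogeny(matrix: HaploMatrix) -> CladeTree:
    """Build the (unique) perfect phylogeny of a polarized matrix.

    Sites with identical derived sample sets stack on one branch; the tree
    is rooted at the outgroup, stem mutations (derived in every ingroup
    sample) sit on the branch from the root to the ingroup ancestor, and
    internal branches without a supporting mutation do not exist, so
    multifurcations arise naturally. Missing entries are treated as
    ancestral when forming derived sets (run imputation first to keep them
    rare). Raises :class:`IncompatibleMatrixError` on four-gamete failures.
    """
    ok, bad = four_gamete_check(matrix)
    if not ok:
        raise IncompatibleMatrixError(bad)
    if matrix.outgroup_id is None:
        raise ValueError("matrix has no outgroup; cannot root the tree")

    ingroup = matrix.drop_samples([matrix.outgroup_id])
    haps = collapse_haplotypes(ingroup)
    # haplotype-level consensus states, missing -> ancestral
    hap_states = np.zeros((len(haps), len(matrix.sites)), dtype=np.int8)
    idx = {s: i for i, s in enumerate(ingroup.samples)}
    for h, hap in enumerate(haps):
        rows = ingroup.states[[idx[s] for s in hap.member_samples]]
        hap_states[h] = np.any(rows == DERIVED, axis=0).astype(np.int8)

    all_haps = frozenset(range(len(haps)))
    site_sets: dict[frozenset[int], list[str]] = {}
    for j, site in enumerate(matrix.sites):
        ds = frozenset(np.nonzero(hap_states[:, j] == DERIVED)[0].tolist())
        if not ds:
            logger.warning("site %s is invariant in the ingroup; not placed", site)
            continue
        site_sets.setdefault(ds, []).append(site)

    root = Node("root")
    og_leaf = Node(matrix.outgroup_id, members=(matrix.outgroup_id,))
    stem_sites = site_sets.pop(all_haps, [])
    if len(haps) == 1:  # single ingroup haplotype: the stem is its branch
        mrca = Node(haps[0].id, mutations=stem_sites, members=haps[0].member_samples)
        root.children = [og_leaf, mrca]
        return CladeTree(root, matrix.outgroup_id)
    mrca = Node("ingroup", mutations=stem_sites)
    root.children = [og_leaf, mrca]

    node_sets: list[tuple[frozenset[int], Node]] = [(all_haps, mrca)]
    counter = itertools.count(1)
    for ds in sorted(site_sets, key=lambda s: (-len(s), sorted(s))):
        # smallest existing clade containing ds is its parent (laminar family)
        parent_set, parent = min(
            ((ps, pn) for ps, pn in node_sets if ds <= ps),
            key=lambda t: len(t[0]),
        )
        if len(ds) == 1:
            (h,) = ds
            node = Node(
                haps[h].id, mutations=site_sets[ds], members=haps[h].member_samples
            )
        else:
            node = Node(f"n{next(counter)}", mutations=site_sets[ds])
        parent.children.append(node)
        node_sets.append((ds, node))

    # attach leaves for haplotypes not yet represented by a singleton set
    placed = {ds for ds, _ in node_sets if len(ds) == 1}
    for h, hap in enumerate(haps):
        if frozenset([h]) in placed:
            continue
        _, parent = min(
            ((ps, pn) for ps, pn in node_sets if h in ps),
            key=lambda t: len(t[0]),
        )
        parent.children.append(Node(hap.id, members=hap.member_samples))
    return CladeTree(root, matrix.outgroup_id)


def branch_mutation_counts(tree: CladeTree) -> dict[str, int]:
    return tree.branch_mutation_counts()


# ---------------------------------------------------------------------------
# exhaustive maximum-parsimony oracle


def _enumerate_unrooted(n_taxa: int) -> Iterable[dict[int, list[int]]]:
    """Yield adjacency maps of all unrooted binary topologies on taxa 0..n-1.

    Internal nodes are numbered from ``n_taxa`` upward.
    """
    base = {0: [n_taxa], 1: [n_taxa], 2: [n_taxa], n_taxa: [0, 1, 2]}

    def edges(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
        return [(u, v) for u in adj for v in adj[u] if u < v]

    def grow(adj: dict[int, list[int]], taxon: int, next_internal: int):
        if taxon == n_taxa:
            yield adj
            return
        for u, v in edges(adj):
            new = {k: list(vs) for k, vs in adj.items()}
            w = next_internal
            new[u].remove(v)
            new[v].remove(u)
            new[u].append(w)
            new[v].append(w)
            new[w] = [u, v, taxon]
            new[taxon] = [w]
            yield from grow(new, taxon + 1, next_internal + 1)

    if n_taxa == 2:
        yield {0: [1], 1: [0]}
        return
    yield from grow(base, 3, n_taxa + 1)


def mp_length_exhaustive(matrix: HaploMatrix, max_taxa: int = 8) -> int:
    """Minimum Fitch parsimony length over all topologies (test oracle).

    States are bitmask-encoded (ancestral=1, derived=2, missing=both) and
    Fitch counting is vectorised over sites. Limited to ``max_taxa`` taxa.
    """
    n = len(matrix.samples)
    if n > max_taxa:
        raise ValueError(f"exhaustive search limited to {max_taxa} taxa, got {n}")
    if n < 2:
        raise ValueError("need at least two taxa")
    S = matrix.states
    masks = np.where(S == ANCESTRAL, 1, np.where(S == DERIVED, 2, 3)).astype(np.uint8)
    m = len(matrix.sites)
    if m == 0:
        return 0

    best = None
    for adj in _enumerate_unrooted(n):
        # root at taxon 0's neighbour, iterative postorder Fitch
        length = 0
        root = adj[0][0]
        stack = [(root, 0, False)]
        states: dict[int, np.ndarray] = {}
        while stack:
            node, parent, done = stack.pop()
            kids = [x for x in adj[node] if x != parent]
            if node < n:
                states[node] = masks[node]
                continue
            if not done:
                stack.append((node, parent, True))
                for k in kids:
                    stack.append((k, node, False))
                continue
            acc = states[kids[0]]
            for k in kids[1:]:
                inter = acc & states[k]
                union = acc | states[k]
                empty = inter == 0
                length += int(empty.sum())
                acc = np.where(empty, union, inter).astype(np.uint8)
            states[node] = acc
        # fold in taxon 0, the leaf the tree was rooted next to
        length += int(((states[root] & masks[0]) == 0).sum())
        if best is None or length < best:
            best = length
    return int(best)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    matrix: HaploMatrix, n_replicates: int = 100, seed: int = 0
) -> dict[frozenset[str], float]:
    """Clade support by site-resampling with perfect-phylogeny rebuilds."""
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    m = len(matrix.sites)
    for _ in range(n_replicates):
        cols = rng.integers(0, m, size=m)
        rep = HaploMatrix(
            list(matrix.samples),
            [f"r{i}" for i in range(m)],
            matrix.states[:, cols],
            matrix.outgroup_id,
        )
        for clade in build_perfect_phylogeny(rep).clades():
            counts[clade] = counts.get(clade, 0) + 1
    return {c: k / n_replicates for c, k in counts.items()}


# ---------------------------------------------------------------------------
# liftover and STR arithmetic


@dataclass(frozen=True)
class LiftoverResult:
    variant_id: str
    status: str  # unique | absent | ambiguous
    target_contig: str | None = None
    target_pos: int | None = None  # 1-based position of the gap start
    strand: str | None = None


def liftover_by_flank(
    variant_id: str,
    left_flank: str,
    right_flank: str,
    gap_len: int,
    target: Mapping[str, str],
) -> LiftoverResult:
    """Place a variant on another assembly by exact flank identity.

    The pattern ``left_flank + <gap_len bases> + right_flank`` is searched on
    both strands of every target contig; a unique hit yields the 1-based
    coordinate of the gap start on the forward strand. Mismatch-tolerant
    rescue is deliberately not attempted.
    """
    if not left_flank or not right_flank:
        raise ValueError("flanks must be non-empty")
    left = left_flank.upper()
    right = right_flank.upper()
    hits: set[tuple[str, int, str]] = set()
    for contig, seq in target.items():
        fwd = seq.upper()
        for strand in "+-":
            if strand == "+":
                a, b = left, right
            else:
                a, b = reverse_complement(right), reverse_complement(left)
            start = fwd.find(a)
            while start != -1:
                gap0 = start + len(a)
                if fwd[gap0 + gap_len : gap0 + gap_len + len(b)] == b:
                    hits.add((contig, gap0 + 1, strand))
                start = fwd.find(a, start + 1)
    # a palindromic pattern matches the same locus on both strands: dedup
    loci = {(c, p) for c, p, _ in hits}
    if not loci:
        return LiftoverResult(variant_id, "absent")
    if len(loci) > 1:
        return LiftoverResult(variant_id, "ambiguous")
    contig, pos, strand = sorted(hits)[0]
    return LiftoverResult(variant_id, "unique", contig, pos, strand)


def str_allele_length(
    ref_amplicon_len: int, repeat_unit_len: int, repeat_delta: int
) -> int:
    """Amplicon length of an STR allele differing by ``repeat_delta`` units."""
    length = ref_amplicon_len + repeat_unit_len * repeat_delta
    if length <= 0:
        raise ValueError("resulting amplicon length must be positive")
    return length
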