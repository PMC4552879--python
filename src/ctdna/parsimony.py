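"""Maximum-parsimony sample tree from binary mutation presence/absence.

Samples (normal, primary tumor, metastasis, plasma) are the taxa; each
somatic mutation is a binary character (present/absent per sample).  The
matched normal is the all-absent outgroup.  With 3–8 samples the space of
unrooted binary topologies is enumerated exhaustively; each is scored with
Fitch's small-parsimony algorithm and the minimum-length tree is returned,
rooted at the normal for reporting.  Branch lengths are the number of
mutations whose state changes on that branch under a Fitch backtrace that
prefers the ancestral (absent) state at ties — mutations are gained on the
path toward the leaves, losses are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .model import (
    ValidationError,
    VariantKey,
    VariantTable,
)

MAX_SAMPLES = 8

_ABSENT, _PRESENT, _BOTH = 1, 2, 3  # bitmask state sets for Fitch passes


@dataclass
class MutationMatrix:
    """samples × variants presence matrix; normal first, all-absent."""

    samples: list[str]
    characters: np.ndarray  # shape (n_characters, n_samples), dtype uint8
    keys: list[VariantKey]
    nonsynonymous_only: bool

    def __post_init__(self) -> None:
        self.characters = np.asarray(self.characters, dtype=np.uint8)
        if self.characters.ndim != 2 or self.characters.shape[1] != len(
            self.samples
        ):
            raise ValidationError("characters must be (n_characters, n_samples)")
        if len(self.keys) != self.characters.shape[0]:
            raise ValidationError("one key per character required")
        if len(set(self.keys)) != len(self.keys):
            raise ValidationError("duplicate character coordinates")
        if self.characters.size and self.characters[:, 0].any():
            raise ValidationError("normal (first) row must be all-absent")
        if self.characters.size and (~self.characters.any(axis=1)).any():
            raise ValidationError("all-absent characters are not allowed")


def build_mutation_matrix(
    calls: dict[str, set[VariantKey]],
    table: VariantTable,
    nonsynonymous_only: bool = True,
) -> MutationMatrix:
    """Assemble the binary character matrix from per-sample call sets.

    The normal sample is prepended as the all-absent outgroup.  When
    ``nonsynonymous_only`` is set, characters are restricted to variants
    annotated as nonsynonymous.
    """
    case_ids = [s for s in table.case_ids if s in calls]
    if len(case_ids) < 2:
        raise ValidationError(
            f"need >= 2 non-normal samples with calls, got {case_ids}"
        )
    samples = [table.normal_id] + case_ids
    by_key = table.by_key()
    keys = sorted(set().union(*(calls[s] for s in case_ids)))
    if nonsynonymous_only:
        keys = [k for k in keys if by_key[k].annotation.nonsynonymous]
    if not keys:
        raise ValidationError("no characters remain after filtering")
    chars = np.zeros((len(keys), len(samples)), dtype=np.uint8)
    for i, key in enumerate(keys):
        for j, sid in enumerate(case_ids, start=1):
            if key in calls[sid]:
                chars[i, j] = 1
    return MutationMatrix(
        samples=samples,
        characters=chars,
        keys=keys,
        nonsynonymous_only=nonsynonymous_only,
    )


@dataclass
class TreeNode:
    """Rooted tree node; ``length`` is the mutation count on the edge above."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass
class SampleTree:
    """A parsimony tree rooted at the normal sample for reporting."""

    root: TreeNode
    total_length: int

    def newick(self) -> str:
        return to_newick(self)


# -- topology enumeration ----------------------------------------------------
#
# Rooting an unrooted binary tree at the normal leaf identifies unrooted
# topologies over n samples with rooted binary topologies over the n-1
# case samples; the latter are enumerated by stepwise leaf insertion
# ((2n-5)!! topologies, fine for <= 8 samples).

_Topo = object  # nested: str (leaf) or tuple of two sub-topologies


def _enumerate_rooted(leaves: list[str]):
    if len(leaves) == 1:
        yield leaves[0]
        return
    if len(leaves) == 2:
        yield (leaves[0], leaves[1])
        return
    first, rest = leaves[0], leaves[1:]
    for sub in _enumerate_rooted(rest):
        yield from _insert_on_each_edge(sub, first)
    # also the topology where `first` attaches at the root
    for sub in _enumerate_rooted(rest):
        yield (first, sub)


def _insert_on_each_edge(topo, leaf):
    if isinstance(topo, str):
        yield (leaf, topo)
        return
    a, b = topo
    for new_a in _insert_on_each_edge(a, leaf):
        yield (new_a, b)
    for new_b in _insert_on_each_edge(b, leaf):
        yield (a, new_b)
    yield (leaf, topo)


def _canonical(topo) -> str:
    """Topology-only canonical newick (children sorted by min leaf name)."""
    if isinstance(topo, str):
        return topo
    parts = sorted(_canonical(t) for t in topo)
    return "(" + ",".join(parts) + ")"


def _unique_rooted_topologies(leaves: list[str]) -> list:
    seen: dict[str, object] = {}
    for topo in _enumerate_rooted(sorted(leaves)):
        seen.setdefault(_canonical(topo), topo)
    return [seen[k] for k in sorted(seen)]


# -- Fitch scoring -----------------------------------------------------------


def _downpass(topo, states: dict[str, np.ndarray]):
    """Return (state-set vector over characters, change-count vector)."""
    if isinstance(topo, str):
        return states[topo], 0
    (sa, ca), (sb, cb) = _downpass(topo[0], states), _downpass(topo[1], states)
    inter = sa & sb
    union = sa | sb
    disjoint = inter == 0
    changes = ca + cb + disjoint.astype(np.int64)
    return np.where(disjoint, union, inter).astype(np.uint8), changes


def _leaf_states(matrix: MutationMatrix) -> dict[str, np.ndarray]:
    return {
        sid: np.where(matrix.characters[:, j] == 1, _PRESENT, _ABSENT).astype(
            np.uint8
        )
        for j, sid in enumerate(matrix.samples)
    }


def fitch_length(topology, matrix: MutationMatrix) -> int:
    """Total parsimony length of ``topology`` for all characters.

    ``topology`` is a nested tuple of pairs whose leaves are sample names
    and must span exactly the matrix's samples.  The tree is treated as
    rooted but the Fitch count is the unrooted parsimony length.
    """
    leaves = _topo_leaves(topology)
    if sorted(leaves) != sorted(matrix.samples):
        raise ValidationError(
            f"topology leaves {sorted(leaves)} do not match matrix samples "
            f"{sorted(matrix.samples)}"
        )
    if len(set(leaves)) != len(leaves):
        raise ValidationError("duplicate leaf in topology")
    if matrix.characters.shape[0] == 0:
        return 0
    _, changes = _downpass(topology, _leaf_states(matrix))
    return int(np.sum(changes)) if np.ndim(changes) else int(changes)


def _topo_leaves(topo) -> list[str]:
    if isinstance(topo, str):
        return [topo]
    out = []
    for t in topo:
        out.extend(_topo_leaves(t))
    return out


# -- backtrace with absent-preferring tie-break ------------------------------


def _assign(topo, parent_state: np.ndarray, states, node_sets) -> TreeNode:
    own_set = node_sets[id(topo)]
    # take the parent state where allowed; otherwise prefer absent
    state = np.where(
        (own_set & parent_state) != 0,
        parent_state,
        np.where((own_set & _ABSENT) != 0, _ABSENT, _PRESENT),
    ).astype(np.uint8)
    length = int(np.sum(state != parent_state))
    if isinstance(topo, str):
        return TreeNode(name=topo, length=length)
    node = TreeNode(length=length)
    node.children = [_assign(t, state, states, node_sets) for t in topo]
    return node


def _collect_sets(topo, states, node_sets) -> np.ndarray:
    if isinstance(topo, str):
        node_sets[id(topo)] = states[topo]
        return states[topo]
    sa = _collect_sets(topo[0], states, node_sets)
    sb = _collect_sets(topo[1], states, node_sets)
    inter = sa & sb
    own = np.where(inter == 0, sa | sb, inter).astype(np.uint8)
    node_sets[id(topo)] = own
    return own


def _score_rooted_at_normal(topo, matrix: MutationMatrix) -> SampleTree:
    """Build the reporting tree: root joins the normal leaf and ``topo``."""
    states = _leaf_states(matrix)
    node_sets: dict[int, np.ndarray] = {}
    _collect_sets(topo, states, node_sets)
    n_chars = matrix.characters.shape[0]
    # the root's effective state is the normal's (all absent): mutations are
    # gained below the root, never lost
    root_state = np.full(n_chars, _ABSENT, dtype=np.uint8)
    normal_leaf = TreeNode(name=matrix.samples[0], length=0)
    case_subtree = _assign(topo, root_state, states, node_sets)
    root = TreeNode(children=[normal_leaf, case_subtree])
    total = _sum_lengths(root)
    return SampleTree(root=root, total_length=total)


def _sum_lengths(node: TreeNode) -> int:
    return node.length + sum(_sum_lengths(c) for c in node.children)


def best_tree(matrix: MutationMatrix) -> SampleTree:
    """Exhaustive-search maximum-parsimony tree over all samples.

    Ties between equally parsimonious topologies are broken by the
    lexicographic order of their canonical newick strings, so the result is
    deterministic and independent of sample input order.
    """
    n = len(matrix.samples)
    if not 3 <= n <= MAX_SAMPLES:
        raise ValidationError(
            f"exhaustive search supports 3-{MAX_SAMPLES} samples, got {n}; "
            "use dedicated phylogenetics software for larger cohorts"
        )
    case_samples = matrix.samples[1:]
    best = None
    for topo in _unique_rooted_topologies(case_samples):
        full = (matrix.samples[0], topo)
        length = fitch_length(full, matrix)
        cand_key = (length, _canonical(full))
        if best is None or cand_key < best[0]:
            best = (cand_key, topo)
    tree = _score_rooted_at_normal(best[1], matrix)
    # the backtrace preference is one optimal assignment, so edge counts sum
    # to the Fitch length
    assert tree.total_length == best[0][0]
    return tree


def to_newick(tree: SampleTree) -> str:
    """Serialize with integer branch lengths and canonical child order."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length}"
        parts = sorted(
            (min(c.leaf_names()), fmt(c)) for c in node.children
        )
        return "(" + ",".join(p for _, p in parts) + f"):{node.length}"

    root = tree.root
    parts = sorted((min(c.leaf_names()), fmt(c)) for c in root.children)
    return "(" + ",".join(p for _, p in parts) + ");"


def branch_lengths(tree: SampleTree) -> dict[frozenset[str], int]:
    """Map each branch (identified by the leaf set below it) to its length."""
    out: dict[frozenset[str], int] = {}

    def walk(node: TreeNode) -> None:
        if node is not tree.root:
            out[frozenset(node.leaf_names())] = node.length
        for c in node.children:
            walk(c)

    walk(tree.root)
    return out


def pairwise_splits(matrix: MutationMatrix) -> dict[tuple[str, str], int]:
    """Shared-mutation counts per sample pair (diagnostic helper)."""
    out = {}
    for (i, a), (j, b) in combinations(enumerate(matrix.samples), 2):
        out[(a, b)] = int(
            np.sum((matrix.characters[:, i] == 1) & (matrix.characters[:, j] == 1))
        )
    return out
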