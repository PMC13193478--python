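"""Phylogenetic tree handling and discrete-trait machinery.

The tree is held in a flat array representation (tips first, internal nodes
in postorder, root last) built on top of dendropy's Newick/NEXUS parsers.
All downstream stages — state-dependent diversification, multi-regime niche
evolution and the phylogenetic multilevel model — consume this structure.

Branch lengths are interpreted as millions of years (Myr); trees are expected
to be ultrametric (all root-to-tip path lengths equal) within a relative
tolerance, as produced by time calibration with rounding noise.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TraitTable",
    "MkParams",
    "RegimeMap",
    "read_newick",
    "prune_tips",
    "phylo_correlation",
    "mk_loglik",
    "fit_mk_ard",
    "stochastic_maps",
    "ancestral_marginals",
    "normalize_label",
]

ULTRAMETRIC_RTOL = 1e-6
REJECTION_CAP = 100_000


def normalize_label(label: str) -> str:
    """Canonical species label: strip, collapse whitespace to underscores."""
    return "_".join(str(label).strip().split())


@dataclass
class Phylogeny:
    """Rooted phylogeny with branch lengths, tips indexed ``0..n_tips-1``.

    ``parent[i]`` is the parent node index (-1 for the root) and
    ``edge_length[i]`` the length of the edge above node ``i`` (0 at the
    root). Internal nodes are ordered so that every parent has a higher
    index than its children; the root is the last node.
    """

    tip_labels: list[str]
    parent: np.ndarray
    edge_length: np.ndarray
    children: list[list[int]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.edge_length = np.asarray(self.edge_length, dtype=np.float64)
        if np.any(self.edge_length < 0):
            raise ValueError("negative branch length")
        n = self.parent.size
        if not self.children:
            ch: list[list[int]] = [[] for _ in range(n)]
            for i in range(n):
                if self.parent[i] >= 0:
                    ch[self.parent[i]].append(i)
            self.children = ch
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have a single root, found {roots.size}")

    # ------------------------------------------------------------------ basic
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def postorder(self) -> np.ndarray:
        """Node indices, every child before its parent."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return np.asarray(order[::-1], dtype=np.int64)

    @property
    def node_depth(self) -> np.ndarray:
        """Distance from the root to each node."""
        depth = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.edge_length[v]
        return depth

    @property
    def root_age(self) -> float:
        return float(self.node_depth[: self.n_tips].max())

    @property
    def node_age(self) -> np.ndarray:
        """Age (time before present) of each node, tips at ~0."""
        return self.root_age - self.node_depth

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.node_depth[: self.n_tips]
        return bool(np.ptp(d) <= rtol * max(d.max(), 1e-300))

    def normalize_depths(self) -> "Phylogeny":
        """Stretch terminal branches so all tips sit exactly at the root age.

        Repair for calibrated trees carrying rounding noise; raises if the
        adjustment would exceed 0.1% of tree height.
        """
        d = self.node_depth[: self.n_tips]
        h = d.max()
        if np.ptp(d) > 1e-3 * h:
            raise ValueError(
                "tree is far from ultrametric; depth normalization refused"
            )
        el = self.edge_length.copy()
        el[: self.n_tips] += h - d
        return Phylogeny(list(self.tip_labels), self.parent.copy(), el)

    # -------------------------------------------------------------- structure
    def tip_index(self, labels) -> np.ndarray:
        lut = {normalize_label(l): i for i, l in enumerate(self.tip_labels)}
        idx = []
        missing = []
        for l in labels:
            key = normalize_label(l)
            if key in lut:
                idx.append(lut[key])
            else:
                missing.append(l)
        if missing:
            raise KeyError(f"labels not found in tree: {missing[:10]}")
        return np.asarray(idx, dtype=np.int64)

    def mrca_depth_matrix(self) -> np.ndarray:
        """``M[i, j]`` = root-to-MRCA distance for tips i, j (diag = tip depth)."""
        n = self.n_tips
        depth = self.node_depth
        M = np.zeros((n, n))
        tipsets: dict[int, np.ndarray] = {}
        for v in self.postorder:
            if v < n:
                tipsets[v] = np.array([v], dtype=np.int64)
                M[v, v] = depth[v]
            else:
                kids = self.children[v]
                sets = [tipsets.pop(c) for c in kids]
                for a in range(len(sets)):
                    for b in range(a + 1, len(sets)):
                        M[np.ix_(sets[a], sets[b])] = depth[v]
                        M[np.ix_(sets[b], sets[a])] = depth[v]
                tipsets[v] = np.concatenate(sets)
        return M

    def mrca_index_matrix(self) -> np.ndarray:
        """``M[i, j]`` = node index of MRCA(tip i, tip j); diag = tip index."""
        n = self.n_tips
        M = np.zeros((n, n), dtype=np.int64)
        np.fill_diagonal(M, np.arange(n))
        tipsets: dict[int, np.ndarray] = {}
        for v in self.postorder:
            if v < n:
                tipsets[v] = np.array([v], dtype=np.int64)
            else:
                sets = [tipsets.pop(c) for c in self.children[v]]
                for a in range(len(sets)):
                    for b in range(a + 1, len(sets)):
                        M[np.ix_(sets[a], sets[b])] = v
                        M[np.ix_(sets[b], sets[a])] = v
                tipsets[v] = np.concatenate(sets)
        return M

    def patristic_distances(self) -> np.ndarray:
        d = self.node_depth[: self.n_tips]
        M = self.mrca_depth_matrix()
        return d[:, None] + d[None, :] - 2 * np.where(
            np.eye(self.n_tips, dtype=bool), d, M
        )

    def total_branch_length(self) -> float:
        return float(self.edge_length.sum())

    # --------------------------------------------------------------------- io
    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for v in self.postorder:
            if v < self.n_tips:
                s = self.tip_labels[v].replace(" ", "_")
            else:
                s = "(" + ",".join(parts.pop(c) for c in self.children[v]) + ")"
            if self.parent[v] >= 0:
                s += f":{self.edge_length[v]:.10g}"
            parts[v] = s
        return parts[self.root] + ";"

    def write_newick(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    leaves = [lf for lf in dtree.leaf_node_iter()]
    internals = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
    index = {}
    tip_labels = []
    for i, lf in enumerate(leaves):
        index[lf] = i
        tip_labels.append(normalize_label(lf.taxon.label if lf.taxon else f"t{i}"))
    for j, nd in enumerate(internals):
        index[nd] = len(leaves) + j
    n = len(leaves) + len(internals)
    parent = np.full(n, -1, dtype=np.int64)
    edge = np.zeros(n)
    for nd in dtree.preorder_node_iter():
        i = index[nd]
        if nd.parent_node is not None:
            parent[i] = index[nd.parent_node]
            if nd.edge.length is None:
                raise ValueError(
                    f"missing branch length above node {tip_labels[i] if i < len(leaves) else i}"
                )
            edge[i] = float(nd.edge.length)
    return Phylogeny(tip_labels, parent, edge)


def read_newick(path_or_string: str, schema: str = "newick") -> Phylogeny:
    """Read a rooted tree with branch lengths (Newick, or NEXUS read-only).

    Accepts a path or a literal Newick string. Non-ultrametric trees are
    accepted with a warning; downstream operations that require an
    ultrametric tree raise.
    """
    text = path_or_string
    if not path_or_string.strip().startswith("(") or schema == "nexus":
        with open(path_or_string) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            file=io.StringIO(text), schema=schema, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise ValueError(f"malformed {schema}: {exc}") from exc
    tree = _from_dendropy(dtree)
    if not tree.is_ultrametric():
        warnings.warn(
            "tree is not ultrametric within tolerance; "
            "use normalize_depths() if this is rounding noise",
            stacklevel=2,
        )
    return tree


def prune_tips(tree: Phylogeny, drop) -> Phylogeny:
    """Remove tips in ``drop``; collapse resulting unary internal nodes.

    Root-to-tip depths of retained tips are preserved exactly (the root node
    is kept even if it becomes unary, so patristic distances and tip depths
    are unchanged).
    """
    dropset = {normalize_label(d) for d in drop}
    unknown = dropset - {normalize_label(l) for l in tree.tip_labels}
    if unknown:
        raise KeyError(f"cannot drop unknown tips: {sorted(unknown)[:10]}")
    keep = [i for i, l in enumerate(tree.tip_labels) if normalize_label(l) not in dropset]
    if not keep:
        raise ValueError("pruning would remove every tip")

    alive = np.zeros(tree.n_nodes, dtype=bool)
    alive[keep] = True
    for v in tree.postorder:
        if v >= tree.n_tips:
            alive[v] = any(alive[c] for c in tree.children[v])

    # remap: walk from each surviving node to its nearest surviving ancestor,
    # accumulating branch lengths through dead/unary nodes
    root = tree.root
    nkeep = len(keep)
    surviving_internal = []
    for v in tree.postorder:
        if v >= tree.n_tips and alive[v]:
            live_kids = [c for c in tree.children[v] if alive[c]]
            if v == root or len(live_kids) >= 2:
                surviving_internal.append(v)
    new_index = {old: i for i, old in enumerate(keep)}
    for j, v in enumerate(surviving_internal):
        new_index[v] = nkeep + j
    n_new = nkeep + len(surviving_internal)
    parent = np.full(n_new, -1, dtype=np.int64)
    edge = np.zeros(n_new)
    for old, new in new_index.items():
        if old == root:
            continue
        length = tree.edge_length[old]
        p = tree.parent[old]
        while p != root and p not in new_index:
            length += tree.edge_length[p]
            p = tree.parent[p]
        parent[new] = new_index[p]
        edge[new] = length
    labels = [tree.tip_labels[i] for i in keep]
    return Phylogeny(labels, parent, edge)


def phylo_correlation(tree: Phylogeny, rtol: float = ULTRAMETRIC_RTOL) -> np.ndarray:
    """Phylogenetic correlation matrix: shared root-to-MRCA depth / root age.

    This is the Brownian-motion trait covariance standardized to unit
    diagonal; it is symmetric PSD by construction. Requires an ultrametric
    tree (otherwise the diagonal is not constant).
    """
    if not tree.is_ultrametric(rtol):
        raise ValueError(
            "phylo_correlation requires an ultrametric tree; "
            "call normalize_depths() to repair rounding noise"
        )
    C = tree.mrca_depth_matrix() / tree.root_age
    np.fill_diagonal(C, 1.0)
    return C


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

_HABIT_CODES = {
    "deciduous": 1, "evergreen": 0, "1": 1, "0": 0, 1: 1, 0: 0,
    "semideciduous": 0,  # partial leaf loss retains the soil-plant-atmosphere link
}


@dataclass
class TraitTable:
    """Per-species binary leaf habit (1 = deciduous, 0 = evergreen)."""

    species: list[str]
    habit: np.ndarray  # float; NaN = missing
    growth_form: list | None = None

    def __post_init__(self) -> None:
        self.species = [normalize_label(s) for s in self.species]
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species identifiers in trait table")
        self.habit = np.asarray(self.habit, dtype=np.float64)
        ok = np.isnan(self.habit) | np.isin(self.habit, [0.0, 1.0])
        if not ok.all():
            raise ValueError("habit must be coded 0/1 (or missing)")

    @classmethod
    def from_frame(cls, df) -> "TraitTable":
        def code(h):
            key = str(h).strip().lower()
            if key in _HABIT_CODES:
                return _HABIT_CODES[key]
            try:
                val = float(key)
            except ValueError:
                return np.nan
            return val if val in (0.0, 1.0) else np.nan

        habit = np.array([code(h) for h in df["habit"]], dtype=np.float64)
        gf = list(df["growth_form"]) if "growth_form" in df.columns else None
        return cls(list(df["species"]), habit, gf)

    def scored(self) -> "TraitTable":
        keep = ~np.isnan(self.habit)
        return TraitTable(
            [s for s, k in zip(self.species, keep) if k],
            self.habit[keep],
            [g for g, k in zip(self.growth_form, keep) if k]
            if self.growth_form is not None
            else None,
        )

    def states_for(self, tree: Phylogeny) -> np.ndarray:
        """Tip states aligned to tree tip order; raises on unmatched tips."""
        lut = dict(zip(self.species, self.habit))
        missing = [l for l in tree.tip_labels if normalize_label(l) not in lut]
        if missing:
            raise KeyError(
                f"{len(missing)} tree tips lack trait data (e.g. {missing[:5]}); "
                "prune them explicitly"
            )
        states = np.array([lut[normalize_label(l)] for l in tree.tip_labels])
        if np.isnan(states).any():
            raise ValueError("missing habit among matched tips; prune unscored species")
        return states.astype(np.int64)


@dataclass
class MkParams:
    """ARD transition rates (per Myr): q01 evergreen->deciduous, q10 reverse."""

    q01: float
    q10: float

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("transition rates must be >= 0")

    @property
    def stationary(self) -> np.ndarray:
        tot = self.q01 + self.q10
        if tot == 0:
            return np.array([0.5, 0.5])
        return np.array([self.q10 / tot, self.q01 / tot])


def mk_transition_matrix(q: MkParams, t: float) -> np.ndarray:
    """2-state transition probabilities, closed form of expm(Q t)."""
    r = q.q01 + q.q10
    if r == 0:
        return np.eye(2)
    e = np.exp(-r * t)
    p0, p1 = q.q10 / r, q.q01 / r
    return np.array(
        [[p0 + p1 * e, p1 * (1 - e)], [p0 * (1 - e), p1 + p0 * e]]
    )


def _root_pi(root_prior, q: MkParams) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "flat":
            return np.array([0.5, 0.5])
        if root_prior == "stationary":
            return q.stationary
        raise ValueError(f"unknown root prior {root_prior!r}")
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (2,) or pi.min() < 0 or not np.isclose(pi.sum(), 1.0):
        raise ValueError("root prior vector must be a length-2 probability vector")
    return pi


def _mk_partials(tree: Phylogeny, states: np.ndarray, q: MkParams):
    """Postorder conditional likelihoods with per-node log scaling."""
    n = tree.n_nodes
    L = np.zeros((n, 2))
    logscale = 0.0
    for v in tree.postorder:
        if v < tree.n_tips:
            L[v, int(states[v])] = 1.0
        else:
            part = np.ones(2)
            for c in tree.children[v]:
                P = mk_transition_matrix(q, tree.edge_length[c])
                part = part * (P @ L[c])
            s = part.sum()
            if s <= 0:
                return L, -np.inf
            L[v] = part / s
            logscale += np.log(s)
    return L, logscale


def mk_loglik(
    tree: Phylogeny, traits, q: MkParams, root_prior="flat"
) -> float:
    """Felsenstein-pruning log-likelihood of a binary trait under ARD Mk.

    ``traits`` may be a TraitTable or an int array in tip order.
    """
    states = traits.states_for(tree) if isinstance(traits, TraitTable) else np.asarray(traits)
    if not np.isin(states, [0, 1]).all():
        raise ValueError("tip states must be 0/1")
    L, logscale = _mk_partials(tree, states, q)
    if not np.isfinite(logscale):
        return -np.inf
    pi = _root_pi(root_prior, q)
    lik = float(pi @ L[tree.root])
    return np.log(lik) + logscale if lik > 0 else -np.inf


def fit_mk_ard(
    tree: Phylogeny,
    traits,
    root_prior="flat",
    n_starts: int = 3,
    seed: int = 0,
    bounds=(1e-9, 100.0),
):
    """ML fit of the 2-rate (all-rates-different) Mk model.

    Bounded quasi-Newton on log rates with seeded multi-start. Returns
    ``(MkParams, loglik)``. With all tips in one state the unused rate runs
    to the lower bound (warned).
    """
    from scipy.optimize import minimize

    states = traits.states_for(tree) if isinstance(traits, TraitTable) else np.asarray(traits)
    counts = np.bincount(states.astype(int), minlength=2)
    if counts.min() == 0:
        warnings.warn("all tips share one state; boundary Mk fit", stacklevel=2)
    elif counts.min() < 2:
        warnings.warn("fewer than 2 tips in one state; Mk fit weakly identified", stacklevel=2)

    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    def nll(logq):
        return -mk_loglik(tree, states, MkParams(*np.exp(logq)), root_prior)

    # crude parsimony-flavoured rate scale to seed the optimizer
    scale = max(1.0, counts.min()) / max(tree.total_branch_length(), 1e-9)
    rng = np.random.default_rng(seed)
    starts = [np.log([scale, scale])]
    for _ in range(n_starts - 1):
        starts.append(np.log(scale) + rng.uniform(-2, 2, size=2))
    best = None
    for x0 in starts:
        res = minimize(
            nll, np.clip(x0, lo, hi), method="L-BFGS-B", bounds=[(lo, hi)] * 2
        )
        if best is None or res.fun < best.fun:
            best = res
    q = MkParams(*np.exp(best.x))
    return q, -float(best.fun)


def ancestral_marginals(
    tree: Phylogeny, traits, q: MkParams, root_prior="flat"
) -> np.ndarray:
    """Marginal posterior state probabilities at every node (n_nodes x 2)."""
    states = traits.states_for(tree) if isinstance(traits, TraitTable) else np.asarray(traits)
    L, _ = _mk_partials(tree, states, q)
    pi = _root_pi(root_prior, q)
    n = tree.n_nodes
    D = np.zeros((n, 2))
    D[tree.root] = pi
    for v in tree.postorder[::-1]:
        kids = tree.children[v]
        msgs = {}
        for c in kids:
            P = mk_transition_matrix(q, tree.edge_length[c])
            msgs[c] = P @ L[c]
        for c in kids:
            above = D[v].copy()
            for s in kids:
                if s != c:
                    above = above * msgs[s]
            P = mk_transition_matrix(q, tree.edge_length[c])
            D[c] = above @ P
    post = L * D
    Z = post.sum(axis=1, keepdims=True)
    Z[Z == 0] = 1.0
    return post / Z


# ---------------------------------------------------------------------------
# stochastic character mapping
# ---------------------------------------------------------------------------


@dataclass
class RegimeMap:
    """One sampled trait history: per-edge regime segments, parent-to-child.

    ``segments[v]`` lists ``(duration, state)`` pairs along the edge above
    node ``v`` (empty at the root); durations sum to that edge's length and
    the final state is the state at node ``v``.
    """

    segments: list[list[tuple[float, int]]]
    node_state: np.ndarray

    def validate(self, tree: Phylogeny, atol: float = 1e-9) -> None:
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            tot = sum(d for d, _ in self.segments[v])
            if abs(tot - tree.edge_length[v]) > atol * max(1.0, tree.edge_length[v]):
                raise ValueError(f"segments on edge {v} do not sum to branch length")
            if self.segments[v] and self.segments[v][-1][1] != self.node_state[v]:
                raise ValueError(f"segment end state mismatch at node {v}")

    def time_in_state(self, state: int) -> float:
        return sum(
            d for segs in self.segments for d, s in segs if s == state
        )

    def n_transitions(self) -> int:
        count = 0
        for segs in self.segments:
            count += max(0, len(segs) - 1)
        return count


def _sample_bridge(rng, q: MkParams, t: float, a: int, b: int):
    """CTMC path on {0,1} from state a to b over duration t, by rejection."""
    rates = (q.q01, q.q10)
    for _ in range(REJECTION_CAP):
        path = []
        s, elapsed = a, 0.0
        while True:
            r = rates[s]
            dt = rng.exponential(1.0 / r) if r > 0 else np.inf
            if elapsed + dt >= t:
                path.append((t - elapsed, s))
                break
            path.append((dt, s))
            s = 1 - s
            elapsed += dt
        if s == b:
            return path
    raise RuntimeError(
        "stochastic map rejection cap exceeded; increase the cap or revisit q"
    )


def stochastic_maps(
    tree: Phylogeny,
    traits,
    q: MkParams,
    n_maps: int = 100,
    seed: int = 0,
    root_prior="flat",
) -> list[RegimeMap]:
    """Sample full trait histories consistent with the tips under Mk.

    Node states are drawn from their joint conditional distribution
    (pruning partials), then within-branch histories are filled in by
    endpoint-conditioned rejection sampling.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    states = traits.states_for(tree) if isinstance(traits, TraitTable) else np.asarray(traits)
    L, _ = _mk_partials(tree, states, q)
    pi = _root_pi(root_prior, q)
    rng = np.random.default_rng(seed)
    preorder = tree.postorder[::-1]
    maps: list[RegimeMap] = []
    for _ in range(n_maps):
        node_state = np.zeros(tree.n_nodes, dtype=np.int64)
        w = pi * L[tree.root]
        node_state[tree.root] = rng.choice(2, p=w / w.sum())
        segments: list[list[tuple[float, int]]] = [[] for _ in range(tree.n_nodes)]
        for v in preorder:
            for c in tree.children[v]:
                P = mk_transition_matrix(q, tree.edge_length[c])
                w = P[node_state[v]] * L[c]
                node_state[c] = rng.choice(2, p=w / w.sum())
                segments[c] = _sample_bridge(
                    rng, q, tree.edge_length[c], int(node_state[v]), int(node_state[c])
                )
        maps.append(RegimeMap(segments, node_state))
    return maps
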