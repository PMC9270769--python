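"""Spatial sampling, ground-truth phylogeny reconstruction and tree statistics.

A simulated biopsy picks a set S of alive cells, either uniformly at random
or as a circular/spherical region.  Because every division retires the
parent label and mints two daughter labels, the birth records define a full
binary genealogy of all cells that ever existed; scrolling those records
backwards from the sampled leaves, keeping only events ancestral to S, and
collapsing pass-through (degree-2) ancestors yields the ground-truth
phylogenetic tree, with branch lengths equal to time differences between
the incident events.  The root retains the stem edge from the founding of
the samples' least recent common ancestor down to the first coalescence.

The module also provides the tree-balance statistics used to characterise
spatial constraints on the genealogies: the Sackin index normalised by its
Yule (pure-birth) expectation, the maximum-likelihood Aldous beta-splitting
parameter, and a logistic fit of the growth curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .dynamics import EventLog, SimulationResult

__all__ = [
    "SamplingScheme",
    "PhyloNode",
    "PhyloTree",
    "sample_cells",
    "reconstruct_phylogeny",
    "to_newick",
    "parse_newick",
    "sackin_index",
    "yule_sackin_expectation",
    "beta_split",
    "fit_logistic",
    "simulate_yule_tree",
]


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingScheme:
    """Biopsy specification: ``random_n`` cells, or a ball in R^D."""

    mode: str = "random_n"
    n: int | None = None
    center: tuple | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("random_n", "ball"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.mode == "random_n" and (self.n is None or self.n < 1):
            raise ValueError("random_n sampling requires n >= 1")
        if self.mode == "ball":
            if self.center is None or self.radius is None or self.radius <= 0:
                raise ValueError("ball sampling requires a center and a positive radius")


def sample_cells(
    result: SimulationResult,
    scheme: SamplingScheme,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[int]:
    """Return the list S of sampled cell labels."""
    if rng is None:
        rng = np.random.default_rng(seed)
    g = result.graph
    alive_nodes = np.nonzero(g.state)[0]
    if len(alive_nodes) == 0:
        raise ValueError("no alive cells to sample (population extinct)")
    if scheme.mode == "random_n":
        if scheme.n > len(alive_nodes):
            raise ValueError(
                f"requested {scheme.n} cells but only {len(alive_nodes)} are alive"
            )
        chosen = rng.choice(alive_nodes, size=scheme.n, replace=False)
    else:
        center = np.asarray(scheme.center, dtype=float)
        d2 = ((g.coords[alive_nodes] - center) ** 2).sum(axis=1)
        chosen = alive_nodes[d2 <= scheme.radius**2]
        if len(chosen) == 0:
            raise ValueError(
                f"empty biopsy ball (radius {scheme.radius}); {len(alive_nodes)} cells alive"
            )
    return [int(lab) for lab in g.cell_label[chosen]]


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

@dataclass(eq=False)
class PhyloNode:
    name: str | None = None
    length: float = 0.0  # branch length to the parent
    children: list = field(default_factory=list)
    time: float | None = None  # absolute event time (simulation units)
    annotations: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Rooted tree; the root may carry a single child (the retained stem)."""

    root: PhyloNode

    def leaves(self) -> list[PhyloNode]:
        out: list[PhyloNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(node.children)
        return out

    def leaf_names(self) -> set[str]:
        return {leaf.name for leaf in self.leaves()}

    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_nodes(self) -> list[PhyloNode]:
        out: list[PhyloNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.children:
                out.append(node)
                stack.extend(node.children)
        return out

    def first_bifurcation(self) -> PhyloNode:
        """Skip unifurcations at the root (the stem) down to the first split."""
        node = self.root
        while len(node.children) == 1:
            node = node.children[0]
        return node

    def depths_from(self, start: PhyloNode) -> dict[int, float]:
        """Path length (branch-length sum) from ``start`` to every descendant."""
        depths = {id(start): 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            for child in node.children:
                depths[id(child)] = depths[id(node)] + child.length
                stack.append(child)
        return depths

    def normalise_depth(self) -> "PhyloTree":
        """Rescale branch lengths so the maximum root-to-leaf depth is 1."""
        depths = self.depths_from(self.root)
        dmax = max(depths[id(leaf)] for leaf in self.leaves())
        if dmax <= 0:
            raise ValueError("cannot normalise a zero-depth tree")
        stack = [self.root]
        while stack:
            node = stack.pop()
            node.length /= dmax
            if node.time is not None:
                node.time /= dmax
            stack.extend(node.children)
        return self


def reconstruct_phylogeny(log: EventLog, samples: list[int],
                          sampling_time: float) -> PhyloTree:
    """Build the ground-truth phylogeny of the sampled cells from the log.

    Scrolls the birth records backwards: only events ancestral to a sampled
    cell are kept; ancestors through which a single sampled lineage passes
    are collapsed, accumulating branch length, and driver-mutation events on
    collapsed chains are kept as edge annotations.  The tree's internal
    nodes are exactly the coalescences between sampled lineages; the root
    is the founding event of the samples' least recent common ancestor
    (retaining the stem edge down to the first coalescence).
    """
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise ValueError("sample list contains duplicate labels")
    if not samples:
        raise ValueError("sample list is empty")

    parent_of: dict[int, int] = {}
    birth_time: dict[int, float] = {lab: 0.0 for lab, _, _ in log.initial}
    division_time: dict[int, float] = {}
    children_of: dict[int, tuple[int, int]] = {}
    for t, pa, d1, d2, *_ in log.births:
        parent_of[d1] = pa
        parent_of[d2] = pa
        birth_time[d1] = t
        birth_time[d2] = t
        division_time[pa] = t
        children_of[pa] = (d1, d2)
    driver_of: dict[int, list[tuple[int, float]]] = {}
    for t, lab, sp, adv in log.drivers:
        driver_of.setdefault(lab, []).append((sp, adv))

    for s in samples:
        if s not in birth_time:
            raise ValueError(f"sampled label {s} does not appear in the event log")
        if s in division_time:
            raise ValueError(f"sampled label {s} divided before sampling (not alive)")

    # backward scroll: count sampled descendants of every ancestral label
    n_desc: dict[int, int] = {}
    for s in samples:
        lab = s
        while True:
            n_desc[lab] = n_desc.get(lab, 0) + 1
            if lab not in parent_of:
                break
            lab = parent_of[lab]

    # LCA: walk up from any sample; the first label subtending all of S
    lca = samples[0]
    while n_desc[lca] < len(samples):
        lca = parent_of[lca]

    def build(label: int) -> PhyloNode:
        """Subtree below ``label``, collapsing single-lineage chains."""
        start_time = birth_time[label]
        annotations: dict = {}
        # follow the chain of pass-through ancestors
        while True:
            if label in driver_of:
                annotations.setdefault("drivers", []).extend(driver_of[label])
            if label not in children_of:  # a sampled leaf
                node = PhyloNode(name=str(label), time=sampling_time,
                                 length=sampling_time - start_time,
                                 annotations=annotations)
                return node
            d1, d2 = children_of[label]
            kept = [d for d in (d1, d2) if n_desc.get(d, 0) > 0]
            if len(kept) == 2:
                t_split = division_time[label]
                node = PhyloNode(time=t_split, length=t_split - start_time,
                                 children=[build(d1), build(d2)],
                                 annotations=annotations)
                return node
            label = kept[0]  # degree-2 ancestor: collapse through it

    if len(samples) == 1:
        leaf = build(lca)
        root = PhyloNode(time=birth_time[lca], length=0.0, children=[leaf])
        return PhyloTree(root=root)

    top = build(lca)
    # retain the stem: a degree-1 root at the LCA's founding time
    root = PhyloNode(time=birth_time[lca], length=0.0, children=[top])
    return PhyloTree(root=root)


# --------------------------------------------------------------------------
# Newick
# --------------------------------------------------------------------------

def _newick_node(node: PhyloNode) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.15g}"
    inner = ",".join(_newick_node(c) for c in node.children)
    return f"({inner}):{node.length:.15g}"


def to_newick(tree: PhyloTree) -> str:
    """Serialise to standard Newick with branch lengths.

    The root's (zero-length) stem origin is the outermost node; one-leaf
    trees serialise as ``(label:length);``.
    """
    root = tree.root
    if root.is_leaf:
        return f"{root.name}:{root.length:.15g};"
    inner = ",".join(_newick_node(c) for c in root.children)
    return f"({inner});"


def parse_newick(text: str) -> PhyloTree:
    """Minimal Newick reader (labels + branch lengths), for round trips."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_node() -> PhyloNode:
        nonlocal pos
        node = PhyloNode()
        if s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if s[pos] != ")":
                raise ValueError(f"expected ')' at position {pos}")
            pos += 1
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError("trailing characters in Newick string")
    return PhyloTree(root=root)


# --------------------------------------------------------------------------
# balance statistics
# --------------------------------------------------------------------------

def yule_sackin_expectation(n: int) -> float:
    """Expected Sackin index of a Yule tree with n leaves: 2n * sum_{k=2..n} 1/k."""
    return 2.0 * n * sum(1.0 / k for k in range(2, n + 1))


def sackin_index(tree: PhyloTree, normalised: bool = False) -> float:
    """Sum of leaf depths in edge counts, measured below the first bifurcation.

    The retained root stem (a unifurcation) is excluded; with
    ``normalised=True`` the raw index is divided by the Yule (pure-birth)
    expectation for the same number of leaves.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("Sackin index requires >= 2 leaves")
    start = tree.first_bifurcation()
    # edge-count depths
    total = 0
    stack = [(start, 0)]
    while stack:
        node, depth = stack.pop()
        if node.is_leaf:
            total += depth
        else:
            for child in node.children:
                stack.append((child, depth + 1))
    if not normalised:
        return float(total)
    return total / yule_sackin_expectation(len(leaves))


def _beta_loglik(beta: float, splits: list[tuple[int, int]]) -> float:
    """Log-likelihood of internal splits under Aldous' beta-splitting model."""
    ll = 0.0
    by_n: dict[int, list[int]] = {}
    for a, b in splits:
        by_n.setdefault(a + b, []).append(a)
    for n, lefts in by_n.items():
        i = np.arange(1, n)
        logw = (special.gammaln(beta + i + 1) + special.gammaln(beta + n - i + 1)
                - special.gammaln(i + 1) - special.gammaln(n - i + 1))
        lognorm = special.logsumexp(logw)
        counts = np.bincount(lefts, minlength=n)[1:n]
        ll += float(counts @ (logw - lognorm))
    return ll


def beta_split(tree_or_splits, bounds: tuple[float, float] = (-1.999, 10.0)):
    """Maximum-likelihood beta of Aldous' beta-splitting model.

    Accepts a tree (its internal splits are collected below the first
    bifurcation) or a pre-collected list of (left, right) leaf-count
    splits, e.g. pooled over an ensemble.  Yule trees correspond to
    beta = 0.  Returns ``(beta_hat, at_boundary)``.
    """
    if isinstance(tree_or_splits, PhyloTree):
        tree = tree_or_splits
        if tree.n_leaves() < 3:
            raise ValueError("beta-split requires >= 3 leaves")
        splits = collect_splits(tree)
    else:
        splits = list(tree_or_splits)
    res = optimize.minimize_scalar(
        lambda b: -_beta_loglik(b, splits), bounds=bounds, method="bounded",
        options={"xatol": 1e-5},
    )
    beta_hat = float(res.x)
    at_boundary = (beta_hat - bounds[0] < 1e-3) or (bounds[1] - beta_hat < 1e-3)
    return beta_hat, at_boundary


def collect_splits(tree: PhyloTree) -> list[tuple[int, int]]:
    """(left, right) leaf counts of every bifurcating internal node."""
    counts: dict[int, int] = {}

    def count(node: PhyloNode) -> int:
        if node.is_leaf:
            counts[id(node)] = 1
            return 1
        c = sum(count(ch) for ch in node.children)
        counts[id(node)] = c
        return c

    count(tree.root)
    splits = []
    stack = [tree.first_bifurcation()]
    while stack:
        node = stack.pop()
        if len(node.children) == 2:
            splits.append((counts[id(node.children[0])], counts[id(node.children[1])]))
        stack.extend(node.children)
    return splits


def simulate_yule_tree(n: int, rng: np.random.Generator) -> PhyloTree:
    """Pure-birth tree with n leaves: split a uniformly chosen leaf, n-1 times.

    Branch lengths are exponential inter-split times (rate = #lineages),
    though only the topology matters for the balance statistics.
    """
    root = PhyloNode(time=0.0)
    leaves = [root]
    t = 0.0
    while len(leaves) < n:
        t += rng.exponential(1.0 / len(leaves))
        k = int(rng.integers(len(leaves)))
        node = leaves[k]
        node.time = t
        c1, c2 = PhyloNode(time=t), PhyloNode(time=t)
        node.children = [c1, c2]
        leaves[k] = c1
        leaves.append(c2)
    for i, leaf in enumerate(leaves):
        leaf.name = f"L{i}"
    # assign lengths from times (leaves extend to the final time)
    t_end = t + rng.exponential(1.0 / n)

    def set_lengths(node: PhyloNode, parent_time: float) -> None:
        if node.is_leaf:
            node.time = t_end
            node.length = t_end - parent_time
        else:
            node.length = node.time - parent_time
            for ch in node.children:
                set_lengths(ch, node.time)

    set_lengths(root, 0.0)
    return PhyloTree(root=root)


# --------------------------------------------------------------------------
# growth-curve fit
# --------------------------------------------------------------------------

def fit_logistic(dynamics, min_points: int = 5):
    """Least-squares logistic fit N(t) = K / (1 + exp(-r (t - t0))).

    ``dynamics`` is either the per-subpopulation table produced by the
    simulation (summed over subpopulations) or a (t, N) pair of arrays.
    Returns ``(K, r, t0)``; raises RuntimeError with diagnostics on
    non-convergence, and flags a degenerate (flat) trace by returning
    r = 0 with K equal to the constant population.
    """
    if hasattr(dynamics, "columns"):
        tot = dynamics.groupby("time")["cell_count"].sum()
        t = tot.index.to_numpy(dtype=float)
        n = tot.to_numpy(dtype=float)
    else:
        t, n = (np.asarray(a, dtype=float) for a in dynamics)
    if len(t) < min_points:
        raise ValueError(f"logistic fit requires >= {min_points} time points")
    if np.ptp(n) == 0:
        return float(n[0]), 0.0, float(np.median(t))

    def logistic(tt, K, r, t0):
        return K / (1.0 + np.exp(-np.clip(r * (tt - t0), -500, 500)))

    k0 = max(n.max(), 1.0)
    r0 = 4.0 / max(np.ptp(t), 1e-9)
    t0_0 = float(t[np.argmin(np.abs(n - k0 / 2))])
    try:
        popt, _ = optimize.curve_fit(
            logistic, t, n, p0=[k0, r0, t0_0],
            bounds=([1e-9, 1e-9, t.min() - np.ptp(t)],
                    [np.inf, np.inf, t.max() + np.ptp(t)]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"logistic fit did not converge (n={len(t)}, N in [{n.min()}, {n.max()}]): {err}"
        ) from err
    return float(popt[0]), float(popt[1]), float(popt[2])
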