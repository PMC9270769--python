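"""Independent brute-force oracles used by the tests.

Everything here deliberately avoids the package's optimized code paths:
the naive Gillespie recomputes the feasible event set at every step, the
genealogy oracle builds the complete binary genealogy of all cells before
pruning, and the adjacency oracle is an O(n^2) pairwise-distance scan.
"""

from __future__ import annotations

import numpy as np


def brute_force_adjacency(coords: np.ndarray, J: float) -> set:
    """All unordered pairs at Euclidean distance strictly below J."""
    n = len(coords)
    edges = set()
    for i in range(n):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        for off in np.nonzero(d < J)[0]:
            edges.add((i, i + 1 + int(off)))
    return edges


def naive_contact_gillespie(neighbors, alpha, beta, t_max, rng,
                            initial_node) -> int:
    """Doob-Gillespie for the contact process, re-enumerating every event.

    Events: per cell, death at rate beta and one birth event per EMPTY
    neighbour at rate alpha / degree (the parent proposes a uniformly
    chosen neighbour, succeeding only if it is empty).  Returns the final
    cell count at t_max.
    """
    n = len(neighbors)
    occupied = np.zeros(n, dtype=bool)
    occupied[initial_node] = True
    t = 0.0
    while True:
        events = []  # (rate, kind, node, target)
        for i in np.nonzero(occupied)[0]:
            i = int(i)
            events.append((beta, "death", i, -1))
            deg = len(neighbors[i])
            for j in neighbors[i]:
                if not occupied[j]:
                    events.append((alpha / deg, "birth", i, int(j)))
        if not events:
            return 0
        rates = np.array([e[0] for e in events])
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        if t >= t_max:
            return int(occupied.sum())
        k = rng.choice(len(events), p=rates / total)
        _, kind, i, j = events[k]
        if kind == "death":
            occupied[i] = False
        else:
            occupied[j] = True


def prune_full_genealogy(initial, births, samples, sampling_time):
    """Ground-truth phylogeny by building the FULL genealogy, then pruning.

    ``initial``: list of (label, node, subpop); ``births``: list of
    (time, parent, d1, d2, ...).  Returns a canonical nested representation
    ``(children_tuple_or_name, branch_length)`` with children sorted by
    their smallest leaf label, and the root as a (stem, root_time) wrapper:
    ``("ROOT", [child_repr])`` is avoided — the caller gets the canonical
    form of the stem child plus the stem length.
    """
    children = {}
    parent_of = {}
    birth_time = {lab: 0.0 for lab, _, _ in initial}
    for rec in births:
        t, pa, d1, d2 = rec[0], rec[1], rec[2], rec[3]
        children[pa] = (d1, d2, t)
        parent_of[d1] = pa
        parent_of[d2] = pa
        birth_time[d1] = t
        birth_time[d2] = t

    samples = list(samples)

    def path_labels(label):
        out = {label}
        while label in parent_of:
            label = parent_of[label]
            out.add(label)
        return out

    common = set.intersection(*(path_labels(s) for s in samples))
    lca = max(common, key=lambda lab: birth_time[lab])

    if len(samples) == 1:
        return (str(samples[0]), round(sampling_time - birth_time[lca], 9))

    sample_set = set(samples)

    def subtree(label):
        """Full-genealogy subtree; None if no sampled descendant."""
        if label in children:
            d1, d2, t = children[label]
            s1, s2 = subtree(d1), subtree(d2)
            if s1 is None and s2 is None:
                return None
            if s1 is None:
                return s2
            if s2 is None:
                return s1
            return ((s1, s2), t)
        return (label, sampling_time) if label in sample_set else None

    def to_canonical(node, parent_time):
        payload, t = node
        if isinstance(payload, tuple):
            kids = sorted(
                (to_canonical(c, t) for c in payload), key=lambda k: k[2]
            )
            min_leaf = kids[0][2]
            return (tuple((k[0], k[1]) for k in kids), round(t - parent_time, 9),
                    min_leaf)
        return (str(payload), round(t - parent_time, 9), int(payload))

    sub = subtree(lca)
    canonical = to_canonical(sub, birth_time[lca])
    return (canonical[0], canonical[1])


def canonical_from_phylo(tree):
    """Canonical nested form of a package PhyloTree (stem excluded)."""

    def conv(node, parent_time):
        if node.is_leaf:
            return (node.name, round(node.time - parent_time, 9), int(node.name))
        kids = sorted((conv(c, node.time) for c in node.children),
                      key=lambda k: k[2])
        return (tuple((k[0], k[1]) for k in kids),
                round(node.time - parent_time, 9), kids[0][2])

    root = tree.root
    assert len(root.children) == 1, "expected a stem under the root"
    c = conv(root.children[0], root.time)
    return (c[0], c[1])
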