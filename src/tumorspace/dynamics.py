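"""Spatial multi-type birth-death dynamics via an optimized Gillespie loop.

Cells live on a :class:`~tumorspace.spatial_graph.SpatialGraph`, one per
node.  Every cell of subpopulation ``i`` divides at rate ``alpha_i`` and
dies at rate ``beta``.  A division proposes a uniformly chosen neighbour of
the parent node as the target; whether the proposal succeeds depends on the
interaction rule:

* ``contact``     — succeeds only into an empty node;
* ``voter``       — may also displace ("kill") a resident of a *different*
                    subpopulation;
* ``hierarchical_voter`` — may displace a resident only if the parent's
                    birth rate is strictly greater (empty nodes are always
                    colonisable).

A proposal that violates the rule is a *phantom event*: it advances the
clock but changes no state.  Scheduling phantom and real events together
lets the loop draw waiting times from the total rate
``sum_cells(alpha_subpop + beta)`` without re-enumerating the feasible event
set after every event, which is what makes large lattices affordable; the
process remains statistically exact for the multi-type birth-death model.

Division retires the parent's label and mints two fresh labels, one per
daughter; labels are globally unique and never reused, and the ordered
record of (parent label, daughter labels, timestamp) triples is what the
phylogeny reconstruction consumes later.

With probability ``mu_dri`` per (non-phantom) division, one uniformly
chosen daughter acquires a new driver mutation and founds a new
subpopulation whose birth rate adds a positively-truncated Gaussian
advantage to the parent's rate.  Alternatively a driver mutational tree
with explicit per-subpopulation birth rates can be supplied, in which case
new subpopulations follow the tree's edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial_graph import SpatialGraph

__all__ = [
    "DynamicsParams",
    "BottleneckEvent",
    "DriverTree",
    "EventLog",
    "SimulationResult",
    "simulate",
    "attempt_birth",
    "sample_driver_advantage",
]

RULES = ("contact", "voter", "hierarchical_voter")

# total rate is recomputed from scratch at this stride to bound FP drift
_RATE_REFRESH_STRIDE = 10_000


@dataclass
class DynamicsParams:
    """Parameters of the spatial birth-death process.

    alpha : wild-type birth rate per unit time.
    beta : death rate per unit time (identical for all subpopulations).
    mu_dri : probability per non-phantom division that one daughter
        acquires a new driver mutation.
    driver_advantage_mean, driver_advantage_sd : parameters of the
        positively truncated Gaussian birth-rate advantage per driver.
    rule : interaction rule, one of contact | voter | hierarchical_voter.
    t_max : simulation horizon in time units.
    max_cells : optional cap on the population size.
    seed : RNG seed (ignored if an explicit Generator is passed to
        :func:`simulate`).
    """

    alpha: float = 0.4
    beta: float = 0.01
    mu_dri: float = 0.0
    driver_advantage_mean: float = 0.2
    driver_advantage_sd: float = 0.1
    rule: str = "contact"
    t_max: float = 100.0
    max_cells: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown interaction rule {self.rule!r}; choose from {RULES}")
        for name in ("alpha", "beta", "driver_advantage_mean", "driver_advantage_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.mu_dri <= 1.0:
            raise ValueError("mu_dri must be in [0, 1]")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


@dataclass(frozen=True)
class BottleneckEvent:
    """Scheduled mass-death event: at ``time`` only ``fraction`` survives."""

    time: float
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"bottleneck fraction must be in (0, 1], got {self.fraction}")


@dataclass
class DriverTree:
    """Driver mutational tree over subpopulation ids.

    Nodes are subpopulation ids with the driver-free wild type as root
    (id 1); each edge parent->child means the child clone carries the
    parent's drivers plus one more.  ``birth_rates`` gives alpha_i per
    subpopulation.  During a simulation new clones may only appear along
    unused edges of this tree, so the realised clonal structure is a
    subtree of the input.
    """

    edges: list
    birth_rates: dict
    root: int = 1

    def __post_init__(self) -> None:
        self.children: dict[int, list[int]] = {}
        seen = {self.root}
        for parent, child in self.edges:
            self.children.setdefault(parent, []).append(child)
            if child in seen:
                raise ValueError(f"driver tree is not a tree: node {child} repeated")
            seen.add(child)
        for parent, _ in self.edges:
            if parent not in seen:
                raise ValueError(f"driver tree edge from unknown node {parent}")
        missing = [i for i in seen if i not in self.birth_rates]
        if missing:
            raise ValueError(f"birth_rates missing for subpopulations {missing}")

    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("parent\tchild\tbirth_rate_child\n")
            for parent, child in self.edges:
                fh.write(f"{parent}\t{child}\t{self.birth_rates[child]:g}\n")


class EventLog:
    """Append-only record of the simulation's events.

    Birth records hold, per division event m: the parental label PA_m, the
    two daughter labels DA_m, the nodes occupied, the daughters'
    subpopulation ids and the timestamp T_m.  Phantom proposals are only
    counted, never recorded individually (they change no state).
    """

    def __init__(self) -> None:
        self.initial: list[tuple[int, int, int]] = []  # (label, node, subpop)
        # (time, parent_label, d1, d2, node_parent, node_target, subpop_d1, subpop_d2)
        self.births: list[tuple] = []
        self.deaths: list[tuple[float, int, str]] = []  # (time, label, cause)
        self.drivers: list[tuple[float, int, int, float]] = []  # (t, label, subpop, adv)
        self.n_phantom: int = 0
        self.n_labels: int = 0

    def mint_label(self) -> int:
        self.n_labels += 1
        return self.n_labels

    def add_initial(self, label: int, node: int, subpop: int) -> None:
        self.initial.append((label, node, subpop))

    def add_birth(self, time, parent, d1, d2, node_p, node_t, sp1, sp2) -> None:
        self.births.append((time, parent, d1, d2, node_p, node_t, sp1, sp2))

    def add_death(self, time: float, label: int, cause: str = "death") -> None:
        self.deaths.append((time, label, cause))

    def add_driver(self, time: float, label: int, subpop: int, advantage: float) -> None:
        self.drivers.append((time, label, subpop, advantage))

    # -- label bookkeeping invariants -------------------------------------
    @property
    def n_minted(self) -> int:
        return self.n_labels

    def check_label_conservation(self) -> bool:
        return self.n_labels == len(self.initial) + 2 * len(self.births)

    # -- text round trip ---------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("record\ttime\tf1\tf2\tf3\tf4\tf5\tf6\tf7\n")
            for label, node, sp in self.initial:
                fh.write(f"initial\t0\t{label}\t{node}\t{sp}\t\t\t\t\n")
            for t, pa, d1, d2, np_, nt, s1, s2 in self.births:
                fh.write(f"birth\t{t!r}\t{pa}\t{d1}\t{d2}\t{np_}\t{nt}\t{s1}\t{s2}\n")
            for t, label, cause in self.deaths:
                fh.write(f"death\t{t!r}\t{label}\t{cause}\t\t\t\t\t\n")
            for t, label, sp, adv in self.drivers:
                fh.write(f"driver\t{t!r}\t{label}\t{sp}\t{adv!r}\t\t\t\t\n")
            fh.write(f"meta\t0\t{self.n_phantom}\t{self.n_labels}\t\t\t\t\t\n")

    @classmethod
    def from_tsv(cls, path) -> "EventLog":
        log = cls()
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                kind = parts[0]
                if kind == "initial":
                    log.add_initial(int(parts[2]), int(parts[3]), int(parts[4]))
                elif kind == "birth":
                    log.add_birth(
                        float(parts[1]), int(parts[2]), int(parts[3]), int(parts[4]),
                        int(parts[5]), int(parts[6]), int(parts[7]), int(parts[8]),
                    )
                elif kind == "death":
                    log.add_death(float(parts[1]), int(parts[2]), parts[3])
                elif kind == "driver":
                    log.add_driver(float(parts[1]), int(parts[2]), int(parts[3]), float(parts[4]))
                elif kind == "meta":
                    log.n_phantom = int(parts[2])
                    log.n_labels = int(parts[3])
        return log


@dataclass
class SimulationResult:
    graph: SpatialGraph
    log: EventLog
    dynamics: pd.DataFrame  # columns: time, subpop_id, cell_count
    subpop_alphas: dict
    final_time: float
    status: str  # "t_max" | "extinct" | "max_cells" | "fixed"

    @property
    def alive_labels(self) -> np.ndarray:
        return self.graph.cell_label[self.graph.cell_label > 0]

    def n_alive(self) -> int:
        return int((self.graph.state > 0).sum())


def sample_driver_advantage(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Positively truncated Gaussian advantage, by rejection.

    Resampling (rather than clamping at 0) avoids an atom at zero
    advantage: every accepted driver strictly increases the birth rate.
    """
    if sd == 0.0:
        if mean <= 0:
            raise ValueError("zero-sd advantage requires a positive mean")
        return mean
    while True:
        draw = rng.normal(mean, sd)
        if draw > 0:
            return float(draw)


def attempt_birth(
    state: np.ndarray,
    parent_node: int,
    neighbors: np.ndarray,
    rule: str,
    rng: np.random.Generator,
    alpha_of_subpop,
) -> tuple[bool, int]:
    """Propose a division target and classify it.

    Picks the target uniformly among the parent's neighbours, then applies
    the rule's violation condition.  Returns ``(is_phantom, target_node)``.
    """
    target = int(neighbors[rng.integers(len(neighbors))])
    occupant = int(state[target])
    if occupant == 0:
        return False, target  # empty target is a valid birth under every rule
    if rule == "contact":
        return True, target
    if rule == "voter":
        return occupant == int(state[parent_node]), target
    # hierarchical voter: displacement needs strictly greater birth rate
    return alpha_of_subpop(occupant) >= alpha_of_subpop(int(state[parent_node])), target


def simulate(
    graph: SpatialGraph,
    params: DynamicsParams,
    bottlenecks: list[BottleneckEvent] | tuple = (),
    driver_tree: DriverTree | None = None,
    initial="center",
    rng: np.random.Generator | None = None,
    record_log: bool = True,
    record_every: int = 1,
    stop_when_monoclonal: bool = False,
) -> SimulationResult:
    """Run the optimized Gillespie simulation of the spatial BD process.

    Parameters
    ----------
    initial : "center" (one wild-type cell at the node nearest the graph
        centroid) or a mapping ``{node_id: subpopulation_id}``.
    record_log : if False, skip recording birth/death records (genealogy
        reconstruction becomes impossible; useful for pure-dynamics
        ensembles).
    record_every : record subpopulation counts every k-th state-changing
        event (plus the initial and final state).
    stop_when_monoclonal : stop once a single subpopulation remains and at
        least one division has occurred (fixation in voter-type runs).

    Returns a :class:`SimulationResult`; the input graph is not modified.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    bottlenecks = sorted(bottlenecks, key=lambda b: b.time)
    times = [b.time for b in bottlenecks]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("bottleneck times must be strictly increasing")
    if any(b.time >= params.t_max for b in bottlenecks):
        raise ValueError("bottleneck times must precede t_max")

    g = graph.copy_empty()
    state = g.state
    label_of = g.cell_label
    log = EventLog()

    # subpopulation registry
    alphas: dict[int, float] = {1: params.alpha}
    if driver_tree is not None:
        alphas[1] = float(driver_tree.birth_rates[driver_tree.root])
        tree_used: set[int] = {driver_tree.root}

    # initial occupancy
    if initial == "center":
        occupancy = {g.central_node(): 1}
    else:
        occupancy = {int(node): int(sp) for node, sp in dict(initial).items()}
    if not occupancy:
        raise ValueError("initial occupancy must contain at least one cell")
    for node, sp in occupancy.items():
        if sp < 1:
            raise ValueError("initial subpopulation ids must be >= 1")
        if sp not in alphas:
            if driver_tree is not None:
                alphas[sp] = float(driver_tree.birth_rates[sp])
                tree_used.add(sp)
            else:
                # explicit multi-type initial condition without a driver
                # tree: the extra clones are neutral (wild-type rate)
                alphas[sp] = params.alpha
        lab = log.mint_label()
        state[node] = sp
        label_of[node] = lab
        log.add_initial(lab, node, sp)

    # per-subpopulation occupied-node lists with O(1) swap-removal;
    # every cell of clone i carries the same rate alpha_i + beta, so the
    # event draw is: clone ~ n_i (alpha_i + beta), then uniform cell.
    members: dict[int, list[int]] = {}
    pos_in_list = np.full(g.n_nodes, -1, dtype=np.int64)
    for node, sp in occupancy.items():
        members.setdefault(sp, [])
        pos_in_list[node] = len(members[sp])
        members[sp].append(node)

    beta = params.beta
    total_rate = sum(len(nodes) * (alphas[sp] + beta) for sp, nodes in members.items())

    def add_cell(node: int, sp: int) -> None:
        nonlocal total_rate
        lst = members.setdefault(sp, [])
        pos_in_list[node] = len(lst)
        lst.append(node)
        total_rate += alphas[sp] + beta

    def remove_cell(node: int) -> None:
        nonlocal total_rate
        sp = int(state[node])
        lst = members[sp]
        i = pos_in_list[node]
        last = lst[-1]
        lst[i] = last
        pos_in_list[last] = i
        lst.pop()
        pos_in_list[node] = -1
        total_rate -= alphas[sp] + beta

    def n_cells() -> int:
        return sum(len(lst) for lst in members.values())

    # dynamics table rows: (time, subpop, count)
    dyn_rows: list[tuple[float, int, int]] = []

    def record_counts(time: float) -> None:
        for sp, lst in members.items():
            dyn_rows.append((time, sp, len(lst)))

    t = 0.0
    record_counts(t)
    next_bn = 0
    events_since_refresh = 0
    state_changes = 0
    n_births = 0
    status = "t_max"
    alpha_of = alphas.__getitem__

    while True:
        n_alive = n_cells()
        if n_alive == 0:
            status = "extinct"
            break
        if params.max_cells is not None and n_alive >= params.max_cells:
            status = "max_cells"
            break
        if stop_when_monoclonal and n_births > 0:
            nonempty = [sp for sp, lst in members.items() if lst]
            if len(nonempty) == 1:
                status = "fixed"
                break

        events_since_refresh += 1
        if events_since_refresh >= _RATE_REFRESH_STRIDE:
            total_rate = sum(len(lst) * (alphas[sp] + beta) for sp, lst in members.items())
            events_since_refresh = 0
        if total_rate <= 0:
            status = "extinct" if n_alive == 0 else "t_max"
            t = params.t_max
            break

        tau = rng.exponential(1.0 / total_rate)
        t_next = t + tau

        if next_bn < len(bottlenecks) and bottlenecks[next_bn].time <= t_next:
            # clock jumps to the bottleneck; the exponential is memoryless
            bn = bottlenecks[next_bn]
            next_bn += 1
            t = bn.time
            survivors = int(round(bn.fraction * n_alive))
            kill = n_alive - survivors
            if kill > 0:
                all_nodes = np.concatenate([np.array(lst, dtype=np.int64)
                                            for lst in members.values() if lst])
                victims = rng.choice(all_nodes, size=kill, replace=False)
                for node in victims:
                    node = int(node)
                    if record_log:
                        log.add_death(t, int(label_of[node]), "bottleneck")
                    remove_cell(node)
                    state[node] = 0
                    label_of[node] = 0
                record_counts(t)
            continue

        if t_next >= params.t_max:
            t = params.t_max
            break
        t = t_next

        # pick subpopulation proportional to n_i * (alpha_i + beta)
        u = rng.random() * total_rate
        acc = 0.0
        chosen_sp = None
        for sp, lst in members.items():
            if not lst:
                continue
            chosen_sp = sp  # FP-drift fallback: last non-empty clone
            acc += len(lst) * (alphas[sp] + beta)
            if u < acc:
                break
        lst = members[chosen_sp]
        node = lst[int(rng.integers(len(lst)))]
        a = alphas[chosen_sp]

        if rng.random() * (a + beta) < beta:
            # death
            if record_log:
                log.add_death(t, int(label_of[node]), "death")
            remove_cell(node)
            state[node] = 0
            label_of[node] = 0
            state_changes += 1
        else:
            nbrs = g.neighbors[node]
            if len(nbrs) == 0:
                log.n_phantom += 1
                continue
            phantom, target = attempt_birth(state, node, nbrs, params.rule, rng, alpha_of)
            if phantom:
                log.n_phantom += 1
                continue
            # displacement (voter rules): resident of the target dies
            if state[target] != 0:
                if record_log:
                    log.add_death(t, int(label_of[target]), "displaced")
                remove_cell(int(target))
                state[target] = 0
                label_of[target] = 0
            parent_label = int(label_of[node])
            parent_sp = chosen_sp
            remove_cell(node)
            d1 = log.mint_label()
            d2 = log.mint_label()
            sp1 = sp2 = parent_sp
            driver_rec = None
            if params.mu_dri > 0 and rng.random() < params.mu_dri:
                new_sp = None
                if driver_tree is not None:
                    unused = [c for c in driver_tree.children.get(parent_sp, [])
                              if c not in tree_used]
                    if unused:
                        new_sp = unused[0]
                        tree_used.add(new_sp)
                        advantage = driver_tree.birth_rates[new_sp] - alphas[parent_sp]
                        alphas[new_sp] = float(driver_tree.birth_rates[new_sp])
                else:
                    advantage = sample_driver_advantage(
                        params.driver_advantage_mean, params.driver_advantage_sd, rng
                    )
                    new_sp = max(alphas) + 1
                    alphas[new_sp] = alphas[parent_sp] + advantage
                if new_sp is not None:
                    if rng.random() < 0.5:
                        sp1 = new_sp
                        driver_rec = (t, d1, new_sp, advantage)
                    else:
                        sp2 = new_sp
                        driver_rec = (t, d2, new_sp, advantage)
            state[node] = sp1
            label_of[node] = d1
            add_cell(node, sp1)
            state[target] = sp2
            label_of[target] = d2
            add_cell(int(target), sp2)
            if record_log:
                log.add_birth(t, parent_label, d1, d2, int(node), int(target), sp1, sp2)
                if driver_rec is not None:
                    log.add_driver(*driver_rec)
            n_births += 1
            state_changes += 1

        if state_changes % record_every == 0:
            record_counts(t)

    record_counts(t)
    dynamics = pd.DataFrame(
        dyn_rows, columns=["time", "subpop_id", "cell_count"]
    ).drop_duplicates(subset=["time", "subpop_id"], keep="last").reset_index(drop=True)
    if status == "extinct":
        # extinction is reported, not silently ignored
        dynamics.attrs["extinct_at"] = t
    return SimulationResult(
        graph=g,
        log=log,
        dynamics=dynamics,
        subpop_alphas=dict(alphas),
        final_time=t,
        status=status,
    )
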