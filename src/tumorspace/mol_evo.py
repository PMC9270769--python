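"""Molecular evolution of genomes along the sampled-cell phylogeny.

Sequences evolve root-to-leaves: each child starts from its parent's
realised sequence, so mutations are heritable.  Three mutation engines are
provided:

* an infinite-sites model (every mutation hits a fresh site; no
  back-mutation or multiple hits), suitable for long genomes and low rates;
* finite-sites continuous-time Markov substitution models (JC69, F81, K80,
  HKY85, TN93, K81) run branch-by-branch with an exact Doob-Gillespie
  scheme over the whole sequence, optionally with indels whose lengths
  follow a Lavalette law — either jointly in the same Gillespie clock
  (exact, slow) or as an independent Poisson process per branch (default
  for large trees);
* a time-dependent trinucleotide (96-channel) substitution model driven by
  mutational-signature probability vectors with piecewise-constant
  activities, mixing a uniform background with the signature linear
  combination through a shrinkage coefficient xi.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampling_phylo import PhyloNode, PhyloTree

__all__ = [
    "Genome",
    "MutationRecord",
    "SubstitutionModel",
    "IndelModel",
    "SignatureModel",
    "generate_ancestral_genome",
    "simulate_isa",
    "build_rate_matrix",
    "evolve_branch",
    "evolve_tree",
    "simulate_independent_indels",
    "sample_indel_length",
    "lavalette_weights",
    "context_counts",
    "build_signature_rates",
    "evolve_branch_signatures",
    "evolve_tree_signatures",
    "replay_records",
    "read_signature_table",
    "write_sample_fasta",
    "write_mutation_table",
    "CHANNEL_LABELS",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMP = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G
_PURINES = (0, 2)  # A, G
_TRANSITION = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def _enc(s: str) -> np.ndarray:
    try:
        return np.array([_BASE_IDX[c] for c in s.upper()], dtype=np.int8)
    except KeyError as err:
        raise ValueError(f"non-ACGT character in sequence: {err}") from err


def _dec(a: np.ndarray) -> str:
    return "".join(BASES[int(i)] for i in a)


@dataclass
class Genome:
    """A nucleotide sequence stored as an int8 array over {A,C,G,T}->{0..3}."""

    seq: np.ndarray

    @classmethod
    def from_string(cls, s: str) -> "Genome":
        return cls(seq=_enc(s))

    def __str__(self) -> str:
        return _dec(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def composition(self) -> np.ndarray:
        """Empirical base frequencies (nu_A, nu_C, nu_G, nu_T)."""
        return np.bincount(self.seq, minlength=4) / len(self.seq)


@dataclass(frozen=True)
class MutationRecord:
    """One molecular event on a branch.

    ``position`` is 1-based in the coordinate frame of the sequence at the
    moment of the event; ``anc_position`` maps it back to the ancestral
    genome where possible (None inside inserted material).
    """

    kind: str  # "SNV" | "insertion" | "deletion"
    position: int
    ref: str
    alt: str
    time: float
    anc_position: int | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "SNV" and self.ref == self.alt:
            raise ValueError("SNV ref and alt must differ")


# --------------------------------------------------------------------------
# ancestral genome
# --------------------------------------------------------------------------

def generate_ancestral_genome(L: int, nu, rng: np.random.Generator | None = None,
                              seed: int | None = None) -> Genome:
    """Random genome of length L with bases drawn i.i.d. from nu=(A,C,G,T)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (4,):
        raise ValueError("nu must have 4 entries (A, C, G, T)")
    if np.any(nu < 0):
        raise ValueError("nucleotide frequencies must be non-negative")
    if abs(nu.sum() - 1.0) > 1e-9:
        raise ValueError(f"nucleotide frequencies must sum to 1, got {nu.sum()}")
    if L < 1:
        raise ValueError("genome length must be >= 1")
    return Genome(seq=rng.choice(4, size=L, p=nu).astype(np.int8))


# --------------------------------------------------------------------------
# infinite-sites model
# --------------------------------------------------------------------------

def simulate_isa(tree: PhyloTree, genome: Genome, mu_neut: float,
                 rng: np.random.Generator | None = None, seed: int | None = None):
    """Place neutral mutations on the tree under the infinite-sites model.

    Per branch, exponential waiting times at rate L * mu_neut accumulate
    until the branch length is exceeded; each mutation hits a globally
    unique site (no back-mutations, no multiple hits) and flips it to a
    uniformly chosen different base.  A sample's mutation list is the union
    over its root-to-leaf path.

    Returns ``(branch_counts, sample_records)`` where ``branch_counts`` maps
    each tree node to the mutation count of the branch above it and
    ``sample_records`` maps leaf names to their mutation lists.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if mu_neut < 0:
        raise ValueError("mu_neut must be >= 0")
    L = len(genome)
    rate = L * mu_neut
    used_sites: set[int] = set()

    def draw_site() -> int:
        if len(used_sites) >= L:
            raise RuntimeError(
                f"infinite-sites saturation: more than L={L} mutations requested"
            )
        if len(used_sites) > L // 2:  # dense regime: enumerate the free sites
            free = np.setdiff1d(np.arange(1, L + 1),
                                np.fromiter(used_sites, dtype=np.int64))
            site = int(rng.choice(free))
        else:
            while True:
                site = int(rng.integers(1, L + 1))
                if site not in used_sites:
                    break
        used_sites.add(site)
        return site

    branch_counts: dict = {}
    branch_records: dict = {}

    def visit(node: PhyloNode, t_path: float) -> None:
        records: list[MutationRecord] = []
        if node.length > 0 and rate > 0:
            t = rng.exponential(1.0 / rate)
            while t <= node.length:
                site = draw_site()
                ref = int(genome.seq[site - 1])
                alt = int(rng.choice([b for b in range(4) if b != ref]))
                records.append(MutationRecord(
                    kind="SNV", position=site, ref=BASES[ref], alt=BASES[alt],
                    time=t_path + t, anc_position=site,
                ))
                t += rng.exponential(1.0 / rate)
        branch_counts[node] = len(records)
        branch_records[node] = records
        for child in node.children:
            visit(child, t_path + node.length)

    visit(tree.root, 0.0)

    sample_records: dict[str, list[MutationRecord]] = {}

    def collect(node: PhyloNode, inherited: list) -> None:
        mine = inherited + branch_records[node]
        if node.is_leaf:
            sample_records[node.name] = mine
        for child in node.children:
            collect(child, mine)

    collect(tree.root, [])
    return branch_counts, sample_records


# --------------------------------------------------------------------------
# finite-sites substitution models
# --------------------------------------------------------------------------

@dataclass
class SubstitutionModel:
    """4x4 instantaneous rate matrix Q (rows/cols ordered A, C, G, T)."""

    name: str
    Q: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.shape != (4, 4):
            raise ValueError("Q must be 4x4")
        off = Q[~np.eye(4, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.any(np.abs(Q.sum(axis=1)) > 1e-9):
            raise ValueError("rows of Q must sum to 0")
        self.Q = Q

    @property
    def row_rates(self) -> np.ndarray:
        """Total leaving rate per base: -diag(Q)."""
        return -np.diag(self.Q)


def build_rate_matrix(name: str, **params) -> SubstitutionModel:
    """Construct Q for a named substitution model.

    Parameterisations (rates per unit time; ``freqs`` = equilibrium
    (pi_A, pi_C, pi_G, pi_T)):

    * ``JC69(rate)``             — q_xy = rate / 4 for all x != y.
    * ``K80(rate, kappa)``       — transitions kappa * rate/4, transversions rate/4.
    * ``F81(rate, freqs)``       — q_xy = rate * pi_y.
    * ``HKY85(rate, kappa, freqs)``   — q_xy = rate * pi_y * (kappa on transitions).
    * ``TN93(rate, kappa_AG, kappa_CT, freqs)`` — distinct purine/pyrimidine
      transition factors.
    * ``K81(rate, kappa1, kappa2)``   — three-substitution-type model:
      transitions rate*1/4, A<->T & C<->G rate*kappa1/4, A<->C & G<->T
      rate*kappa2/4.
    """
    name = name.upper()
    rate = float(params.get("rate", 1.0))
    if rate <= 0:
        raise ValueError("rate must be positive")

    def with_freqs():
        freqs = np.asarray(params.get("freqs", [0.25] * 4), dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0) or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("freqs must be 4 positive values summing to 1")
        return freqs

    Q = np.zeros((4, 4))
    if name == "JC69":
        Q[:] = rate / 4.0
    elif name == "K80":
        kappa = float(params.get("kappa", 1.0))
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        for x in range(4):
            for y in range(4):
                if x != y:
                    Q[x, y] = rate * (kappa if (x, y) in _TRANSITION else 1.0) / 4.0
    elif name == "F81":
        pi = with_freqs()
        for x in range(4):
            for y in range(4):
                if x != y:
                    Q[x, y] = rate * pi[y]
    elif name == "HKY85":
        kappa = float(params.get("kappa", 1.0))
        pi = with_freqs()
        for x in range(4):
            for y in range(4):
                if x != y:
                    Q[x, y] = rate * pi[y] * (kappa if (x, y) in _TRANSITION else 1.0)
    elif name == "TN93":
        k_ag = float(params.get("kappa_AG", 1.0))
        k_ct = float(params.get("kappa_CT", 1.0))
        pi = with_freqs()
        for x in range(4):
            for y in range(4):
                if x != y:
                    if (x, y) in ((0, 2), (2, 0)):
                        f = k_ag
                    elif (x, y) in ((1, 3), (3, 1)):
                        f = k_ct
                    else:
                        f = 1.0
                    Q[x, y] = rate * pi[y] * f
    elif name == "K81":
        k1 = float(params.get("kappa1", 1.0))  # A<->T, C<->G
        k2 = float(params.get("kappa2", 1.0))  # A<->C, G<->T
        for x in range(4):
            for y in range(4):
                if x == y:
                    continue
                if (x, y) in _TRANSITION:
                    f = 1.0
                elif (x, y) in ((0, 3), (3, 0), (1, 2), (2, 1)):
                    f = k1
                else:
                    f = k2
                Q[x, y] = rate * f / 4.0
    else:
        raise ValueError(f"unknown substitution model {name!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return SubstitutionModel(name=name, Q=Q)


# --------------------------------------------------------------------------
# indels
# --------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=64)
def _lavalette_cached(L_indel: int, a: float) -> np.ndarray:
    ls = np.arange(1, L_indel + 1, dtype=float)
    w = (ls * L_indel / (L_indel - ls + 1.0)) ** (-a)
    w /= w.sum()
    w.setflags(write=False)
    return w


def lavalette_weights(L_indel: int, a: float) -> np.ndarray:
    """Exactly enumerated, normalised Lavalette length probabilities.

    P(l) is proportional to [l * L_indel / (L_indel - l + 1)]^(-a) for
    l = 1..L_indel.
    """
    if L_indel < 1:
        raise ValueError("L_indel must be >= 1")
    if a <= 0:
        raise ValueError("Lavalette exponent a must be > 0")
    return _lavalette_cached(int(L_indel), float(a))


@dataclass
class IndelModel:
    """Indel process: rate per site per unit time, Lavalette lengths."""

    mu_indel: float
    L_indel: int
    a: float
    insertion_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mu_indel < 0:
            raise ValueError("mu_indel must be >= 0")
        if not 0.0 <= self.insertion_fraction <= 1.0:
            raise ValueError("insertion_fraction must be in [0, 1]")
        self.length_probs = lavalette_weights(self.L_indel, self.a)


def sample_indel_length(L_indel: int, a: float, rng: np.random.Generator) -> int:
    """Draw an indel length from the Lavalette law on 1..L_indel."""
    return int(rng.choice(np.arange(1, L_indel + 1), p=lavalette_weights(L_indel, a)))


# --------------------------------------------------------------------------
# per-branch Doob-Gillespie (finite sites, optional joint indels)
# --------------------------------------------------------------------------

def total_rate(seq: np.ndarray, model: SubstitutionModel,
               indels: IndelModel | None) -> float:
    """From-scratch total event rate of the whole sequence.

    The sum over sites of the site's substitution leaving rate plus the
    per-site indel rate; used both by the simulator and as the invariant
    check against incremental bookkeeping.
    """
    counts = np.bincount(seq, minlength=4)
    r = float(counts @ model.row_rates)
    if indels is not None:
        r += len(seq) * indels.mu_indel
    return r


def evolve_branch(
    seq: np.ndarray,
    model: SubstitutionModel,
    indels: IndelModel | None,
    t_b: float,
    rng: np.random.Generator,
    t_offset: float = 0.0,
    nu_insert=None,
    anc: np.ndarray | None = None,
    validate: bool = False,
):
    """Evolve a sequence for time ``t_b`` under the joint Gillespie scheme.

    The total rate sums, over every current site, the substitution leaving
    rate of its base plus the per-site indel rate; waiting times are
    exponential at that rate, the event is picked proportionally to its
    rate, and both the rate and the sequence are updated after each event
    (the sequence length changes after indels).

    Returns ``(new_seq, records, new_anc)`` where ``anc`` carries the
    ancestral coordinate of every current position (0 = inserted base).
    """
    if t_b < 0:
        raise ValueError("branch length must be >= 0")
    seq = seq.copy()
    if anc is None:
        anc = np.arange(1, len(seq) + 1, dtype=np.int64)
    else:
        anc = anc.copy()
    if nu_insert is None:
        nu_insert = np.full(4, 0.25)
    row = model.row_rates
    counts = np.bincount(seq, minlength=4).astype(np.int64)
    mu_i = 0.0 if indels is None else indels.mu_indel
    records: list[MutationRecord] = []

    sub_rate = float(counts @ row)
    t = 0.0
    while True:
        L = len(seq)
        R = sub_rate + L * mu_i
        if validate:  # incremental bookkeeping must equal Eq.-style recomputation
            scratch = total_rate(seq, model, indels)
            assert abs(R - scratch) <= 1e-9 * max(1.0, scratch), (R, scratch)
        if R <= 0:
            break
        t += rng.exponential(1.0 / R)
        if t > t_b:
            break
        if mu_i > 0 and rng.random() * R < L * mu_i:
            # ---- indel ----
            site = int(rng.integers(1, L + 1))
            length = sample_indel_length(indels.L_indel, indels.a, rng)
            if rng.random() < indels.insertion_fraction:
                ins = rng.choice(4, size=length, p=np.asarray(nu_insert)).astype(np.int8)
                records.append(MutationRecord(
                    kind="insertion", position=site, ref="-", alt=_dec(ins),
                    time=t_offset + t,
                    anc_position=int(anc[site - 1]) if anc[site - 1] > 0 else None,
                ))
                seq = np.concatenate([seq[:site], ins, seq[site:]])
                anc = np.concatenate([anc[:site], np.zeros(length, dtype=np.int64),
                                      anc[site:]])
                counts += np.bincount(ins, minlength=4)
            else:
                length = min(length, L - site + 1)
                removed = seq[site - 1: site - 1 + length]
                if length >= L:
                    raise RuntimeError(
                        f"deletion of length {length} would erase the whole "
                        f"sequence (L={L}) at branch time {t:.4g}"
                    )
                records.append(MutationRecord(
                    kind="deletion", position=site, ref=_dec(removed), alt="-",
                    time=t_offset + t,
                    anc_position=int(anc[site - 1]) if anc[site - 1] > 0 else None,
                ))
                counts -= np.bincount(removed, minlength=4)
                seq = np.delete(seq, slice(site - 1, site - 1 + length))
                anc = np.delete(anc, slice(site - 1, site - 1 + length))
            sub_rate = float(counts @ row)
        else:
            # ---- substitution: base class x ~ n_x * row_x, then y ~ q_xy
            u = rng.random() * sub_rate
            acc = 0.0
            x = 3
            for b in range(4):
                acc += counts[b] * row[b]
                if u < acc:
                    x = b
                    break
            qx = model.Q[x].copy()
            qx[x] = 0.0
            y = int(rng.choice(4, p=qx / qx.sum()))
            # uniform site among those currently holding base x (rejection)
            while True:
                k = int(rng.integers(len(seq)))
                if seq[k] == x:
                    break
            seq[k] = y
            counts[x] -= 1
            counts[y] += 1
            sub_rate += row[y] - row[x]
            records.append(MutationRecord(
                kind="SNV", position=k + 1, ref=BASES[x], alt=BASES[y],
                time=t_offset + t,
                anc_position=int(anc[k]) if anc[k] > 0 else None,
            ))
    return seq, records, anc


def evolve_tree(
    tree: PhyloTree,
    ancestral: Genome,
    model: SubstitutionModel,
    indels: IndelModel | None = None,
    mode: str = "independent",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    nu_insert=None,
):
    """Evolve the ancestral genome along every branch, root to leaves.

    ``mode="joint"`` runs substitutions and indels in one exact Gillespie
    clock per branch; ``mode="independent"`` (default) first places the
    substitutions, then adds indels as a separate per-branch Poisson
    process — much faster and equivalent at first order for small indel
    rates.

    Returns ``(sequences, sample_records)``: per-leaf genomes and per-leaf
    mutation lists (the union along the root-to-leaf path).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if mode not in ("joint", "independent"):
        raise ValueError(f"unknown mode {mode!r}")
    if nu_insert is None:
        nu_insert = ancestral.composition()

    joint_indels = indels if mode == "joint" else None
    node_seqs: dict[PhyloNode, np.ndarray] = {}
    node_anc: dict[PhyloNode, np.ndarray] = {}
    node_records: dict[PhyloNode, list] = {}

    def visit(node: PhyloNode, seq: np.ndarray, anc: np.ndarray, t_path: float) -> None:
        new_seq, recs, new_anc = evolve_branch(
            seq, model, joint_indels, node.length, rng,
            t_offset=t_path, nu_insert=nu_insert, anc=anc,
        )
        node_seqs[node] = new_seq
        node_anc[node] = new_anc
        node_records[node] = recs
        for child in node.children:
            visit(child, new_seq, new_anc, t_path + node.length)

    root_anc = np.arange(1, len(ancestral) + 1, dtype=np.int64)
    visit(tree.root, ancestral.seq, root_anc, 0.0)

    if mode == "independent" and indels is not None and indels.mu_indel > 0:
        node_seqs, indel_records = simulate_independent_indels(
            tree, node_seqs, indels, rng, nu_insert=nu_insert)
        for node, recs in indel_records.items():
            node_records[node] = sorted(node_records[node] + recs,
                                        key=lambda r: r.time)

    sequences: dict[str, Genome] = {}
    sample_records: dict[str, list] = {}

    def collect(node: PhyloNode, inherited: list) -> None:
        mine = inherited + node_records[node]
        if node.is_leaf:
            sequences[node.name] = Genome(seq=node_seqs[node])
            sample_records[node.name] = mine
        for child in node.children:
            collect(child, mine)

    collect(tree.root, [])
    return sequences, sample_records


def simulate_independent_indels(
    tree: PhyloTree,
    node_seqs: dict,
    indels: IndelModel,
    rng: np.random.Generator,
    nu_insert=None,
):
    """Overlay a per-branch Poisson indel process on substitution-only sequences.

    ``node_seqs`` maps every tree node to its substitution-pass sequence
    (all in the shared ancestral coordinate frame, since substitutions do
    not change length).  Indel operations accumulate along each root-to-leaf
    path and are replayed onto each node's substitution-pass sequence, so
    an ancestor's indel is inherited (with identical inserted content) by
    all its descendants.

    Returns ``(updated_node_seqs, per-branch indel records)``.
    """
    if nu_insert is None:
        nu_insert = np.full(4, 0.25)
    new_seqs: dict = {}
    branch_records: dict = {}

    def apply_ops(seq: np.ndarray, ops: list) -> np.ndarray:
        for kind, pos, payload in ops:
            if kind == "insertion":
                seq = np.concatenate([seq[:pos], payload, seq[pos:]])
            else:  # deletion: payload = length
                seq = np.delete(seq, slice(pos - 1, pos - 1 + payload))
        return seq

    def visit(node: PhyloNode, ops: list, t_path: float) -> None:
        seq_in = apply_ops(node_seqs[node], ops)
        L = len(seq_in)
        recs: list[MutationRecord] = []
        branch_ops: list = []
        if node.length > 0:
            n_events = rng.poisson(L * indels.mu_indel * node.length)
            times = np.sort(rng.uniform(0.0, node.length, size=n_events))
            seq = seq_in
            for t_ev in times:
                Lc = len(seq)
                site = int(rng.integers(1, Lc + 1))
                length = sample_indel_length(indels.L_indel, indels.a, rng)
                if rng.random() < indels.insertion_fraction:
                    ins = rng.choice(4, size=length,
                                     p=np.asarray(nu_insert)).astype(np.int8)
                    recs.append(MutationRecord(
                        kind="insertion", position=site, ref="-", alt=_dec(ins),
                        time=t_path + float(t_ev)))
                    branch_ops.append(("insertion", site, ins))
                    seq = np.concatenate([seq[:site], ins, seq[site:]])
                else:
                    length = min(length, Lc - site + 1)
                    if length >= Lc:
                        raise RuntimeError(
                            f"deletion would erase the whole sequence (L={Lc})")
                    recs.append(MutationRecord(
                        kind="deletion", position=site,
                        ref=_dec(seq[site - 1: site - 1 + length]), alt="-",
                        time=t_path + float(t_ev)))
                    branch_ops.append(("deletion", site, length))
                    seq = np.delete(seq, slice(site - 1, site - 1 + length))
        all_ops = ops + branch_ops
        new_seqs[node] = apply_ops(node_seqs[node], all_ops)
        branch_records[node] = recs
        for child in node.children:
            visit(child, all_ops, t_path + node.length)

    visit(tree.root, [], 0.0)
    return new_seqs, branch_records


def replay_records(seq: np.ndarray, records: list) -> np.ndarray:
    """Re-apply a branch's mutation records to its parent sequence.

    Used to verify heritability: the result must equal the child's realised
    sequence.  Records must be in event order.
    """
    seq = seq.copy()
    for rec in records:
        if rec.kind == "SNV":
            k = rec.position - 1
            if BASES[int(seq[k])] != rec.ref:
                raise ValueError(
                    f"replay mismatch at {rec.position}: sequence has "
                    f"{BASES[int(seq[k])]}, record says {rec.ref}"
                )
            seq[k] = _BASE_IDX[rec.alt]
        elif rec.kind == "insertion":
            ins = _enc(rec.alt)
            seq = np.concatenate([seq[:rec.position], ins, seq[rec.position:]])
        elif rec.kind == "deletion":
            length = len(rec.ref)
            if _dec(seq[rec.position - 1: rec.position - 1 + length]) != rec.ref:
                raise ValueError(f"replay deletion mismatch at {rec.position}")
            seq = np.delete(seq, slice(rec.position - 1, rec.position - 1 + length))
        else:
            raise ValueError(f"unknown record kind {rec.kind!r}")
    return seq


# --------------------------------------------------------------------------
# 96-channel mutational-signature model
# --------------------------------------------------------------------------

_SUB_CLASSES = [("C", "A"), ("C", "G"), ("C", "T"),
                ("T", "A"), ("T", "C"), ("T", "G")]

#: canonical channel labels in COSMIC order: substitution class-major,
#: flanks alphabetical, e.g. "A[C>A]A" ... "T[T>G]T".
CHANNEL_LABELS = [
    f"{n}[{k}>{m}]{p}"
    for (k, m) in _SUB_CLASSES
    for n in BASES
    for p in BASES
]
_CHANNEL_IDX = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}

# context id: pyr(C=0, T=1) * 16 + left * 4 + right  -> 32 folded contexts
_N_CTX = 32


def _channel_context(channel: int) -> int:
    cls, rest = divmod(channel, 16)
    left, right = divmod(rest, 4)
    pyr = 0 if cls < 3 else 1
    return pyr * 16 + left * 4 + right


_CTX_OF_CHANNEL = np.array([_channel_context(c) for c in range(96)])
# target base index (in pyrimidine-strand orientation) per channel
_ALT_OF_CHANNEL = np.array([_BASE_IDX[_SUB_CLASSES[c // 16][1]] for c in range(96)])


def _ctx_ids(seq: np.ndarray) -> np.ndarray:
    """Folded trinucleotide context id per position (-1 at the termini).

    Purine-centred trinucleotides are reverse-complemented onto the
    pyrimidine strand (the COSMIC convention).
    """
    L = len(seq)
    ctx = np.full(L, -1, dtype=np.int64)
    if L < 3:
        return ctx
    center = seq[1:-1]
    left = seq[:-2]
    right = seq[2:]
    is_pyr = (center == 1) | (center == 3)  # C or T
    pyr = np.where(is_pyr, np.where(center == 1, 0, 1),
                   np.where(_COMP[center] == 1, 0, 1))
    fl = np.where(is_pyr, left, _COMP[right])
    fr = np.where(is_pyr, right, _COMP[left])
    ctx[1:-1] = pyr * 16 + fl * 4 + fr
    return ctx


def context_counts(seq: np.ndarray) -> np.ndarray:
    """n_NKP: counts of the 32 folded trinucleotide contexts in a sequence."""
    ctx = _ctx_ids(seq)
    return np.bincount(ctx[ctx >= 0], minlength=_N_CTX)


@dataclass
class SignatureModel:
    """Time-dependent 96-channel substitution model.

    ``signatures`` maps names to 96-entry probability vectors in the
    canonical channel order; ``activities`` has one row per time interval
    delimited by ``change_times`` (so ``len(activities) ==
    len(change_times) + 1``) and one column per signature, each row summing
    to 1.  ``mu_avg`` is the average mutation rate per trinucleotide per
    unit time and ``xi`` in [0, 1] weighs the signature mixture against the
    uniform background P0.
    """

    signatures: dict
    mu_avg: float
    xi: float
    activities: np.ndarray = field(default=None)  # type: ignore[assignment]
    change_times: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must be in [0, 1]")
        if self.mu_avg < 0:
            raise ValueError("mu_avg must be >= 0")
        self.names = list(self.signatures)
        self.P = np.array([np.asarray(self.signatures[n], dtype=float)
                           for n in self.names])
        if self.P.shape[1] != 96:
            raise ValueError("each signature must have 96 channel probabilities")
        if np.any(self.P < 0) or np.any(np.abs(self.P.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("signature probability vectors must sum to 1")
        self.change_times = tuple(float(t) for t in self.change_times)
        if any(b <= a for a, b in zip(self.change_times, self.change_times[1:])):
            raise ValueError("change-point times must be strictly increasing")
        if self.activities is None:
            self.activities = np.full((1, len(self.names)), 1.0 / len(self.names))
        self.activities = np.atleast_2d(np.asarray(self.activities, dtype=float))
        if self.activities.shape != (len(self.change_times) + 1, len(self.names)):
            raise ValueError(
                "activities must have one row per interval "
                f"({len(self.change_times) + 1}) and one column per signature"
            )
        if np.any(np.abs(self.activities.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("activities must sum to 1 at every time")

    def activities_at(self, t: float) -> np.ndarray:
        return self.activities[bisect.bisect_right(self.change_times, t)]

    def channel_probs(self, t: float) -> np.ndarray:
        """(1-xi) P0 + xi sum_i A_i(t) P_i, per channel (sums to 1)."""
        mix = self.activities_at(t) @ self.P
        return (1.0 - self.xi) / 96.0 + self.xi * mix


def build_signature_rates(n_ctx: np.ndarray, model: SignatureModel,
                          t: float) -> np.ndarray:
    """Per-channel substitution rates R_{N[K>M]P} at time t.

    R = mu_avg * n_NKP * [(1 - xi) P0 + xi * sum_i A_i(t) P_i].
    """
    n_ctx = np.asarray(n_ctx)
    if n_ctx.shape != (_N_CTX,):
        raise ValueError(f"context counts must have {_N_CTX} entries")
    return model.mu_avg * n_ctx[_CTX_OF_CHANNEL] * model.channel_probs(t)


def evolve_branch_signatures(
    seq: np.ndarray,
    model: SignatureModel,
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
):
    """Gillespie SNV simulation under the signature model on [t_start, t_end].

    Times are absolute (the frame in which the activity change points are
    given).  When the clock crosses a change point the channel rates are
    rebuilt with the new activities; after each substitution the
    trinucleotide contexts of the +-1 window are updated.  Terminal bases
    lack a full trinucleotide context and are never substituted.
    """
    if t_end < t_start:
        raise ValueError("branch interval must have t_end >= t_start")
    if t_start < 0:
        raise ValueError(
            f"branch interval [{t_start}, {t_end}] starts before time 0, "
            "outside the covered activity timeline"
        )
    seq = seq.copy()
    ctx = _ctx_ids(seq)
    counts = np.bincount(ctx[ctx >= 0], minlength=_N_CTX)
    records: list[MutationRecord] = []
    t = t_start
    boundaries = [ct for ct in model.change_times if t_start < ct < t_end] + [t_end]
    b_idx = 0
    while t < t_end:
        boundary = boundaries[b_idx]
        rates = model.mu_avg * counts[_CTX_OF_CHANNEL] * model.channel_probs(t)
        R = float(rates.sum())
        if R <= 0:
            t = boundary
            b_idx += 1 if b_idx + 1 < len(boundaries) else 0
            if t >= t_end:
                break
            continue
        t_next = t + rng.exponential(1.0 / R)
        if t_next >= boundary:
            t = boundary
            if boundary == t_end:
                break
            b_idx += 1
            continue
        t = t_next
        channel = int(rng.choice(96, p=rates / R))
        want_ctx = _CTX_OF_CHANNEL[channel]
        sites = np.nonzero(ctx == want_ctx)[0]
        k = int(sites[rng.integers(len(sites))])
        alt_pyr = int(_ALT_OF_CHANNEL[channel])
        ref = int(seq[k])
        alt = alt_pyr if ref in (1, 3) else int(_COMP[alt_pyr])
        seq[k] = alt
        records.append(MutationRecord(
            kind="SNV", position=k + 1, ref=BASES[ref], alt=BASES[alt],
            time=t, anc_position=k + 1,
        ))
        # refresh the contexts of the +-1 window
        lo = max(k - 1, 1)
        hi = min(k + 1, len(seq) - 2)
        for p in range(lo, hi + 1):
            old = ctx[p]
            counts[old] -= 1
            center = int(seq[p])
            if center in (1, 3):
                pyr = 0 if center == 1 else 1
                new = pyr * 16 + int(seq[p - 1]) * 4 + int(seq[p + 1])
            else:
                cc = int(_COMP[center])
                pyr = 0 if cc == 1 else 1
                new = pyr * 16 + int(_COMP[seq[p + 1]]) * 4 + int(_COMP[seq[p - 1]])
            ctx[p] = new
            counts[new] += 1
    return seq, records


def evolve_tree_signatures(
    tree: PhyloTree,
    ancestral: Genome,
    model: SignatureModel,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Evolve the ancestral genome along the tree under the signature model.

    Branch intervals are taken from the nodes' absolute event times when
    present; otherwise cumulative branch lengths from the root define the
    time frame (matching a depth-normalised tree with activities given over
    [0, 1]).

    Returns ``(sequences, sample_records)`` keyed by leaf name.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sequences: dict[str, Genome] = {}
    sample_records: dict[str, list] = {}

    use_times = tree.root.time is not None

    def visit(node: PhyloNode, seq: np.ndarray, t0: float,
              inherited: list) -> None:
        t1 = node.time if (use_times and node.time is not None) else t0 + node.length
        new_seq, recs = evolve_branch_signatures(seq, model, t0, t1, rng)
        mine = inherited + recs
        if node.is_leaf:
            sequences[node.name] = Genome(seq=new_seq)
            sample_records[node.name] = mine
        for child in node.children:
            visit(child, new_seq, t1, mine)

    t_root = tree.root.time if use_times else 0.0
    visit(tree.root, ancestral.seq, t_root, [])
    return sequences, sample_records


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_signature_table(path) -> dict:
    """Read a COSMIC-layout SBS table (column ``Type`` + one column per
    signature) into name -> 96-vector in canonical channel order."""
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    order = df[type_col].map(_CHANNEL_IDX)
    if order.isna().any():
        bad = df.loc[order.isna(), type_col].tolist()[:3]
        raise ValueError(f"unrecognised channel labels in signature table: {bad}")
    df = df.iloc[np.argsort(order.to_numpy())]
    return {col: df[col].to_numpy(dtype=float) for col in df.columns[1:]}


def write_sample_fasta(sequences: dict, directory, combined: bool = False):
    """Write per-sample ground-truth genomes as FASTA files.

    One file per sample (``sample_<name>.fasta``), or a single multi-FASTA
    when ``combined`` is set.  Returns the list of written paths.
    """
    from pathlib import Path

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    recs = [SeqRecord(Seq(str(g)), id=f"sample_{name}", description="")
            for name, g in sequences.items()]
    if combined:
        path = directory / "samples.fasta"
        SeqIO.write(recs, path, "fasta")
        return [path]
    paths = []
    for rec in recs:
        path = directory / f"{rec.id}.fasta"
        SeqIO.write([rec], path, "fasta")
        paths.append(path)
    return paths


def write_mutation_table(sample_records: dict, path) -> None:
    """Mutation list TSV: sample, type, position, anc_position, ref, alt, time."""
    rows = []
    for sample, records in sample_records.items():
        for r in records:
            rows.append((sample, r.kind, r.position,
                         r.anc_position if r.anc_position is not None else "",
                         r.ref, r.alt, r.time))
    pd.DataFrame(
        rows, columns=["sample", "type", "position", "anc_position",
                       "ref", "alt", "time"]
    ).to_csv(path, sep="\t", index=False)
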