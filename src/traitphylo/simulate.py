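"""Synthetic trees and trait matrices with the statistical structure the
inference assumes.

The generator exists so that every pipeline stage — likelihood, MCMC,
consensus, marginal likelihoods, congruence statistics — can be exercised
and calibrated without any external data. It forward-simulates a
birth-death tree conditioned on the number of extant sampled tips (with
optional fossil tips drawn from extinct lineages inside an age window),
then evolves binary characters along the tree by exact simulation of the
4-state covarion chain. Characters carry dependency levels 1-4 with
level-specific rate multipliers; a level-k character may depend on a
level-(k-1) parent character and is clamped absent wherever its parent is
absent. A punctuated variant concentrates a random fraction of each
branch's evolutionary time in a burst at the branch's origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError, SimulationFailureError, ValidationError
from .priors import BirthDeathParams
from .substitution import CovarionModel, covarion_generator
from .traits import TraitMatrix
from .trees import Node, TimeTree


@dataclass
class SimulationConfig:
    """Study-shaped defaults for the generator.

    The default character counts per level (159/27/30 split augmented into
    four dependency levels for levels 3-4 patterning) mirror a trait system
    in which most characters are independent "structure" characters and a
    minority are progressively dependent; the default covarion parameters
    give a moderately heterotachous process.
    """

    n_extant: int = 20
    bd: BirthDeathParams = field(
        default_factory=lambda: BirthDeathParams(lam=1.0, mu=0.3, rho=1.0, psi=0.0)
    )
    origin_age: float | None = None  # default: chosen from lam/mu/n_extant
    n_fossils: int = 0
    fossil_age_window: tuple[float, float] = (0.2, 0.8)  # fraction of origin age
    #: optional (low, high) rejection window on the root age, emulating the
    #: determinate time depth that fossil/historical calibrations give real
    #: datasets; None accepts any root age
    root_age_range: tuple[float, float] | None = None
    n_characters_per_level: dict[int, int] = field(
        default_factory=lambda: {1: 159, 2: 27, 3: 20, 4: 10}
    )
    covarion: CovarionModel = field(
        default_factory=lambda: CovarionModel(
            pi_present=0.4, alpha=0.5, switch_rate=0.5, overall_rate=1.0
        )
    )
    level_rate_multipliers: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 1.0, 3: 2.0, 4: 2.0}
    )
    dependencies: bool = True
    missing_fraction: float = 0.0
    burst_fraction: float = 0.0
    #: horizontal transfer: number of whole-character-block copies between
    #: contemporaneous (extant) lineages applied after vertical evolution;
    #: deliberately minimal and off by default
    n_transfer_events: int = 0
    transfer_block_fraction: float = 0.1
    seed: int = 0
    max_retries: int = 10000

    def __post_init__(self) -> None:
        if self.n_extant < 2:
            raise ParameterError("need at least 2 extant taxa")
        if self.n_fossils < 0:
            raise ParameterError("n_fossils must be >= 0")
        if not 0 <= self.burst_fraction < 1:
            raise ParameterError("burst_fraction must lie in [0, 1)")
        if not 0 <= self.missing_fraction < 1:
            raise ParameterError("missing_fraction must lie in [0, 1)")
        for lev, n in self.n_characters_per_level.items():
            if n < 0:
                raise ParameterError(f"negative character count for level {lev}")
        for lev, m in self.level_rate_multipliers.items():
            if not m > 0:
                raise ParameterError(f"rate multiplier for level {lev} must be > 0")

    @property
    def n_characters(self) -> int:
        return sum(self.n_characters_per_level.values())

    def default_origin_age(self) -> float:
        """Origin age giving roughly n_extant expected survivors under the
        supercritical process: E[N(t)] = e^{(lam-mu) t}."""
        r = self.bd.lam - self.bd.mu
        if r <= 0:
            return 2.0 / self.bd.lam
        return float(np.log(self.n_extant) / r)


# ---------------------------------------------------------------------- #
# Tree simulation
# ---------------------------------------------------------------------- #


class _Lineage:
    __slots__ = ("node", "birth_age")

    def __init__(self, node: Node, birth_age: float) -> None:
        self.node = node  # node at which this lineage terminates (to be set)
        self.birth_age = birth_age


def simulate_time_tree(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> TimeTree:
    """Forward birth-death simulation conditioned on ``n_extant`` sampled
    extant tips, with optional fossil tips from extinct lineages.

    The process starts with one lineage at ``origin_age`` and runs to the
    present; a replicate is kept only if exactly ``n_extant`` tips survive
    and pass rho-sampling. Fossil tips are placed on lineages whose subtree
    left no sampled extant descendant, at an age drawn uniformly inside the
    fossil window (expressed as fractions of the origin age).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    origin = cfg.origin_age if cfg.origin_age is not None else cfg.default_origin_age()
    lam, mu, rho = cfg.bd.lam, cfg.bd.mu, cfg.bd.rho
    lo = cfg.fossil_age_window[0] * origin
    hi = cfg.fossil_age_window[1] * origin

    for _ in range(cfg.max_retries):
        # forward Gillespie from age=origin down to age=0
        root_stub = Node(age=origin)
        alive: list[Node] = [root_stub]
        age = origin
        ok = True
        while alive and age > 0:
            total = len(alive) * (lam + mu)
            age -= rng.exponential(1.0 / total)
            if age <= 0:
                break
            node = alive[int(rng.integers(len(alive)))]
            node.age = age
            alive.remove(node)
            if rng.random() < lam / (lam + mu):
                left, right = Node(age=age), Node(age=age)
                node.add_child(left)
                node.add_child(right)
                alive.extend([left, right])
            # else: death — node stays a childless internal stub (extinct tip)
            if len(alive) > 40 * cfg.n_extant:
                ok = False  # runaway explosion; bail out early
                break
        if not ok:
            continue
        for node in alive:
            node.age = 0.0
        extant = [n for n in alive]
        sampled = [n for n in extant if rho == 1.0 or rng.random() < rho]
        if len(sampled) != cfg.n_extant:
            continue

        for i, n in enumerate(sampled):
            n.label = f"t{i + 1}"
        sampled_ids = {id(n) for n in sampled}
        fossils: list[Node] = []
        if cfg.n_fossils > 0:
            fossils = _attach_fossils(root_stub, sampled_ids, cfg, lo, hi, rng)
            if fossils is None:
                continue
        tree = _reduce_to_samples(root_stub, sampled, fossils)
        if tree is None:
            continue
        if cfg.root_age_range is not None:
            lo_r, hi_r = cfg.root_age_range
            if not lo_r <= tree.root.age <= hi_r:
                continue
        return tree

    raise SimulationFailureError(
        f"could not simulate a tree with exactly {cfg.n_extant} sampled tips "
        f"in {cfg.max_retries} attempts; adjust the birth-death parameters or origin age"
    )


def _attach_fossils(root_stub, sampled_ids, cfg, lo, hi, rng):
    """Pick fossil attachment points: edges whose subtree has no sampled
    extant tip and which cross the fossil age window."""
    # subtree-contains-sample flags
    has_sample: dict[int, bool] = {}
    order: list[Node] = []
    stack = [root_stub]
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(n.children)
    for n in reversed(order):
        flag = id(n) in sampled_ids
        for c in n.children:
            flag = flag or has_sample[id(c)]
        has_sample[id(n)] = flag
    candidates = []
    for n in order:
        if n is root_stub or has_sample[id(n)]:
            continue
        if not has_sample[id(n.parent)]:
            continue  # take only the topmost sample-free lineage of a clade
        top = min(n.parent.age, hi)
        bottom = max(n.age, lo)
        if top > bottom:
            candidates.append((n, bottom, top))
    if len(candidates) < cfg.n_fossils:
        return None
    picks = rng.choice(len(candidates), size=cfg.n_fossils, replace=False)
    fossils = []
    for k, idx in enumerate(np.atleast_1d(picks)):
        node, bottom, top = candidates[int(idx)]
        node.children = []  # truncate: fossil lineage's descendants are unsampled
        node.age = float(rng.uniform(bottom, top))
        node.label = f"fossil{k + 1}"
        fossils.append(node)
    return fossils


def _reduce_to_samples(root_stub: Node, sampled: list[Node], fossils: list[Node]):
    """Prune the complete simulated tree to sampled extant + fossil tips,
    suppressing unary nodes; returns None if fewer than 2 tips remain."""
    keep_ids = {id(n) for n in sampled} | {id(n) for n in fossils}

    def rec(node: Node) -> Node | None:
        if not node.children:
            if id(node) in keep_ids:
                out = Node(age=node.age, label=node.label)
                return out
            return None
        kept = [c for c in (rec(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = Node(age=node.age)
        for c in kept:
            new.add_child(c)
        return new

    new_root = rec(root_stub)
    if new_root is None or not new_root.children:
        return None
    return TimeTree(new_root)


# ---------------------------------------------------------------------- #
# Character simulation
# ---------------------------------------------------------------------- #


def _sim_branch(state: int, duration: float, Q: np.ndarray, rng) -> tuple[int, int]:
    """Exact CTMC simulation (exponential waiting times) along one branch.

    Returns (end state, number of events)."""
    t = 0.0
    events = 0
    while True:
        out_rate = -Q[state, state]
        if out_rate <= 0:
            return state, events
        t += rng.exponential(1.0 / out_rate)
        if t >= duration:
            return state, events
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(4, p=probs))
        events += 1


def _assign_levels(cfg: SimulationConfig, rng) -> tuple[np.ndarray, list[str], dict[int, int]]:
    levels = []
    char_ids = []
    for lev in sorted(cfg.n_characters_per_level):
        for k in range(cfg.n_characters_per_level[lev]):
            levels.append(lev)
            char_ids.append(f"L{lev}_{k + 1}")
    levels = np.array(levels)
    parents: dict[int, int] = {}
    if cfg.dependencies:
        by_level: dict[int, list[int]] = {}
        for j, lev in enumerate(levels):
            by_level.setdefault(int(lev), []).append(j)
        for j, lev in enumerate(levels):
            pool = by_level.get(int(lev) - 1, [])
            if pool:
                parents[j] = int(pool[int(rng.integers(len(pool)))])
    return levels, char_ids, parents


def simulate_covarion_matrix(
    tree: TimeTree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    branch_duration_overrides: dict[int, float] | None = None,
    event_counts: dict[int, int] | None = None,
) -> TraitMatrix:
    """Evolve binary characters along a tree under the covarion process.

    Root states are drawn from stationarity; the hidden fast/slow category
    is discarded at the tips. Level annotations and per-level rate
    multipliers are applied, and a dependent character is clamped absent at
    every node where its parent character is absent.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    levels, char_ids, parents = _assign_levels(cfg, rng)
    n_chars = len(levels)
    Q = covarion_generator(cfg.covarion)
    pi = cfg.covarion.stationary

    nodes = list(tree.preorder())
    node_index = {id(n): i for i, n in enumerate(nodes)}
    tips = tree.tips()

    # node-level visible presence per character, for the dependency clamp
    node_states = np.empty((len(nodes), n_chars), dtype=np.int8)

    overrides = branch_duration_overrides or {}
    for j in range(n_chars):
        mult = cfg.level_rate_multipliers.get(int(levels[j]), 1.0)
        parent_char = parents.get(j)
        for i, node in enumerate(nodes):
            if node.parent is None:
                state = int(rng.choice(4, p=pi))
            else:
                dur = overrides.get(id(node), node.branch_length) * mult
                start = node_states[node_index[id(node.parent)], j]
                state, n_events = _sim_branch(int(start), dur, Q, rng)
                if event_counts is not None:
                    event_counts[id(node)] = (
                        event_counts.get(id(node), 0) + n_events
                    )
            if parent_char is not None:
                parent_state = node_states[i, parent_char]
                if parent_state in (0, 2):  # parent visibly absent: clamp
                    state = (state // 2) * 2  # force visible absent, keep category
            node_states[i, j] = state

    visible = np.where(np.isin(node_states, (1, 3)), 1, 0).astype(np.int8)
    tip_rows = np.array([node_index[id(t)] for t in tips])
    states = visible[tip_rows, :]
    for _ in range(cfg.n_transfer_events):
        # abrupt change by borrowing: a recipient lineage overwrites a
        # contiguous character block with a contemporaneous donor's states
        donor, recipient = rng.choice(len(tips), size=2, replace=False)
        width = max(1, int(cfg.transfer_block_fraction * n_chars))
        start = int(rng.integers(0, max(1, n_chars - width + 1)))
        states[recipient, start : start + width] = states[donor, start : start + width]
    if cfg.n_transfer_events:
        # partial block copies must not break the dependency clamp
        for child, parent in parents.items():
            states[states[:, parent] == 0, child] = 0
    if cfg.missing_fraction > 0:
        mask = rng.random(states.shape) < cfg.missing_fraction
        states = np.where(mask, np.int8(-1), states)
    return TraitMatrix(
        taxa=[t.label for t in tips],  # type: ignore[misc]
        states=states,
        char_ids=char_ids,
        levels=levels,
    )


def simulate_punctuated_matrix(
    tree: TimeTree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    event_counts: dict[int, int] | None = None,
) -> TraitMatrix:
    """Covarion simulation with change partly concentrated at branch origins.

    For burst fraction f, each branch's evolutionary duration becomes
    (1 - f) * dt plus an Exponential(mean f * dt) burst drawn once per
    branch and shared by all characters. Expected total change per branch is
    conserved exactly while per-branch realised change becomes
    overdispersed; f = 0 delegates to the gradual simulator and is
    bit-identical under a shared seed.
    """
    f = cfg.burst_fraction
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if f == 0:
        return simulate_covarion_matrix(tree, cfg, rng=rng, event_counts=event_counts)
    overrides: dict[int, float] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        dt = node.branch_length
        overrides[id(node)] = (1.0 - f) * dt + rng.exponential(f * dt) if dt > 0 else 0.0
    return simulate_covarion_matrix(
        tree,
        cfg,
        rng=rng,
        branch_duration_overrides=overrides,
        event_counts=event_counts,
    )


def simulate_paired_datasets(
    cfg: SimulationConfig, same_tree: bool
) -> tuple[TraitMatrix, TraitMatrix, tuple[TimeTree, ...]]:
    """Two trait systems for the shared-vs-separate phylogeny experiments.

    ``same_tree=True``: both matrices evolve independently on one tree (the
    shared-history scenario). ``same_tree=False``: two independent trees are
    simulated over the same taxon labels (separate histories). Returns the
    generating tree(s) so recovery experiments can score against truth.
    """
    rng = np.random.default_rng(cfg.seed)
    tree_a = simulate_time_tree(cfg, rng=rng)
    if same_tree:
        tree_b = tree_a
        trees: tuple[TimeTree, ...] = (tree_a,)
    else:
        tree_b = simulate_time_tree(cfg, rng=rng)
        # align taxon labels across the two trees
        labels = tree_a.tip_labels
        for tip, lab in zip(tree_b.tips(), labels):
            tip.label = lab
        trees = (tree_a, tree_b)
    a = simulate_covarion_matrix(tree_a, cfg, rng=rng)
    b = simulate_covarion_matrix(tree_b, cfg, rng=rng)
    b.char_ids = [f"b_{c}" for c in b.char_ids]
    return a, b, trees
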