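"""Metropolis-Hastings sampler over time trees and model parameters.

The target is posterior(tree, params) proportional to

    likelihood^beta x FBD/BD tree prior x calibration bounds x parameter priors

with ``beta = 1`` for ordinary inference and ``beta`` in [0, 1] for the
power posteriors used by stepping-stone marginal-likelihood estimation.
The tree prior is origin-conditioned, with the origin age a sampled
parameter (exponential prior on the origin-root gap), so the prior over
root ages is proper and can be checked against forward simulation.

Operators: uniform node-age moves, root-age and whole-tree scaling,
narrow/wide exchange, subtree-slide, Wilson-Balding, scale moves for the
clock rate, covarion parameters, partition rate multipliers and
birth-death rates, per-branch relaxed-clock rate redraws, and fossil
tip-age moves within their calibration windows. Operator scales
auto-adapt during burn-in only, preserving detailed balance afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, SimulationFailureError, TraitPhyloError, ValidationError
from .likelihood import LikelihoodSpec, total_log_likelihood
from .priors import (
    EXTANT_TOL,
    BirthDeathParams,
    CalibrationConstraint,
    calibration_log_prior,
    fbd_log_density,
)
from .substitution import ClockModel, CovarionModel
from .traits import PartitionScheme
from .trees import Node, TimeTree

LOG2 = math.log(2.0)


# ---------------------------------------------------------------------- #
# Configuration and state
# ---------------------------------------------------------------------- #


@dataclass
class MCMCConfig:
    """Chain settings. Burn-in defaults to 10% of the chain; operator
    scales adapt during burn-in only."""

    chain_length: int = 10000
    thin: int = 10
    burnin: float = 0.1
    seed: int = 0
    sample_topology: bool = True
    sample_ages: bool = True
    sample_clock_rate: bool = True
    sample_covarion: bool = True
    sample_partition_rates: bool = True
    sample_bd: bool = True
    sample_origin: bool = True
    origin_age: float | None = None  # fixed origin age when sample_origin=False
    init_tree: TimeTree | None = None
    operator_weights: dict[str, float] | None = None
    # hyperprior means (exponential unless noted)
    rate_prior_mean: float = 1.0
    switch_prior_mean: float = 1.0
    bd_prior_mean: float = 1.0
    origin_gap_prior_mean: float = 0.5

    def __post_init__(self) -> None:
        if self.chain_length < self.thin:
            raise ParameterError("chain length must be >= thinning interval")
        if not 0 <= self.burnin < 1:
            raise ParameterError("burnin fraction must lie in [0, 1)")


@dataclass
class ChainState:
    """Current tree + parameters with cached log densities."""

    tree: TimeTree
    model: CovarionModel
    clock: ClockModel
    bd: BirthDeathParams
    origin_age: float
    branch_mult: dict[int, float] = field(default_factory=dict)
    part_g: dict[str, float] = field(default_factory=dict)
    log_prior: float = np.nan
    log_lik: float = np.nan

    def copy(self) -> "ChainState":
        mapping: dict[int, Node] = {}

        def rec(node: Node) -> Node:
            clone = Node(age=node.age, label=node.label)
            mapping[id(node)] = clone
            for ch in node.children:
                clone.add_child(rec(ch))
            return clone

        new_tree = TimeTree(rec(self.tree.root))
        new_mult = {
            id(mapping[k]): v for k, v in self.branch_mult.items() if k in mapping
        }
        return ChainState(
            tree=new_tree,
            model=replace(self.model),
            clock=replace(self.clock),
            bd=replace(self.bd),
            origin_age=self.origin_age,
            branch_mult=new_mult,
            part_g=dict(self.part_g),
            log_prior=self.log_prior,
            log_lik=self.log_lik,
        )

    def param_record(self) -> dict[str, float]:
        rec = {
            "root_age": self.tree.root.age,
            "origin_age": self.origin_age,
            "mean_rate": self.clock.mean_rate,
            "pi_present": self.model.pi_present,
            "alpha": self.model.alpha,
            "switch_rate": self.model.switch_rate,
            "lambda": self.bd.lam,
            "mu": self.bd.mu,
            "psi": self.bd.psi,
        }
        for lab, g in sorted(self.part_g.items()):
            rec[f"g_{lab}"] = g
        return rec


@dataclass
class PosteriorSample:
    """Thinned post-burn-in states of one chain."""

    trees: list[TimeTree]
    params: list[dict[str, float]]
    log_likelihoods: np.ndarray
    log_priors: np.ndarray
    sampling_interval: int
    seed: int
    acceptance: dict[str, tuple[int, int]]
    burnin_steps: int

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def log_posteriors(self) -> np.ndarray:
        return self.log_likelihoods + self.log_priors

    def trace(self, name: str) -> np.ndarray:
        return np.array([p[name] for p in self.params])

    def partition_multipliers(self, labels: list[str], weights: dict[str, float]) -> dict[str, np.ndarray]:
        """Posterior traces of renormalised partition multipliers.

        ``weights`` gives each partition's share of total character weight.
        """
        gs = {lab: self.trace(f"g_{lab}") for lab in labels}
        denom = sum(weights[lab] * gs[lab] for lab in labels)
        return {lab: gs[lab] / denom for lab in labels}

    def write_trace(self, path: str) -> None:
        """Tab-separated trace compatible with standard trace inspectors."""
        names = sorted(self.params[0]) if self.params else []
        with open(path, "w") as fh:
            fh.write("state\tlogPosterior\tlogLikelihood\tlogPrior\t" + "\t".join(names) + "\n")
            for i, p in enumerate(self.params):
                row = [
                    str(i * self.sampling_interval),
                    f"{self.log_posteriors[i]:.8g}",
                    f"{self.log_likelihoods[i]:.8g}",
                    f"{self.log_priors[i]:.8g}",
                ] + [f"{p[n]:.8g}" for n in names]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------- #
# Random starting trees
# ---------------------------------------------------------------------- #


def random_start_tree(
    taxa: list[str],
    rng: np.random.Generator,
    calibrations: list[CalibrationConstraint] = [],
    scale: float = 1.0,
    retries: int = 100,
) -> TimeTree:
    """Random coalescent-style tree compatible with hard calibrations.

    Fossil tips named in tip calibrations start at the middle of their age
    window; the tree is rescaled at random until every calibration bound
    holds, with an explicit failure after ``retries`` attempts.
    """
    tip_ages = {}
    for c in calibrations:
        if c.kind == "tip":
            tip_ages[c.taxa[0]] = 0.5 * (c.lower + c.upper)

    # candidate timescales: the caller's scale plus the scale implied by
    # each MRCA calibration (midpoint over the coalescent's ~ln n growth)
    scales = [scale]
    log_n = max(math.log(max(len(taxa), 2)), 1.0)
    for c in calibrations:
        if c.kind == "mrca":
            scales.append(0.5 * (c.lower + c.upper) / log_n)

    for attempt in range(retries):
        base = scales[attempt % len(scales)]
        factor = base * float(np.exp(rng.normal(0.0, 0.8)))
        lineages = [Node(age=tip_ages.get(lab, 0.0), label=lab) for lab in taxa]
        age = max((n.age for n in lineages), default=0.0)
        while len(lineages) > 1:
            mergeable = [n for n in lineages if n.age <= age]
            if len(mergeable) < 2:
                age = sorted(n.age for n in lineages)[1]
                continue
            age += rng.exponential(factor / len(mergeable))
            i, j = rng.choice(len(mergeable), size=2, replace=False)
            a, b = mergeable[int(i)], mergeable[int(j)]
            parent = Node(age=age)
            parent.add_child(a)
            parent.add_child(b)
            lineages = [n for n in lineages if n is not a and n is not b]
            lineages.append(parent)
        tree = TimeTree(lineages[0])
        if calibration_log_prior(tree, calibrations) == 0.0:
            return tree
    raise SimulationFailureError(
        f"no calibration-compatible starting tree found in {retries} attempts"
    )


# ---------------------------------------------------------------------- #
# The sampler
# ---------------------------------------------------------------------- #


class Sampler:
    """Metropolis-Hastings sampler; drive directly for power posteriors or
    use :func:`run_mcmc` for plain posterior sampling."""

    def __init__(
        self,
        spec: LikelihoodSpec | None,
        bd: BirthDeathParams,
        calibrations: list[CalibrationConstraint] | None,
        config: MCMCConfig,
        taxa: list[str] | None = None,
    ) -> None:
        self.config = config
        self.calibrations = list(calibrations or [])
        self.rng = np.random.default_rng(config.seed)
        self.has_data = spec is not None

        if spec is not None:
            tree = config.init_tree or spec.tree
            model, clock, partitions = spec.model, spec.clock, spec.partitions
            self.matrix = spec.matrix
        else:
            if config.init_tree is not None:
                tree = config.init_tree
            elif taxa is not None:
                tree = random_start_tree(taxa, self.rng, self.calibrations)
            else:
                raise ParameterError("prior-only sampling needs taxa or an init tree")
            model, clock, partitions = CovarionModel(), ClockModel(), None
            self.matrix = None
        self.partitions = partitions

        tree = tree.copy()
        if calibration_log_prior(tree, self.calibrations) == -np.inf:
            tree = self._retry_start(tree)

        origin = (
            config.origin_age
            if config.origin_age is not None
            else tree.root.age * 1.25 + config.origin_gap_prior_mean
        )
        part_g = {lab: 1.0 for lab in partitions.groups} if partitions else {}
        branch_mult = {}
        if clock.kind == "relaxed" and clock.stdev_log > 0:
            branch_mult = {
                id(n): 1.0 for n in tree.preorder() if n.parent is not None
            }
        self.state = ChainState(
            tree=tree,
            model=replace(model),
            clock=replace(clock),
            bd=replace(bd),
            origin_age=origin,
            branch_mult=branch_mult,
            part_g=part_g,
        )
        self._has_fossils = any(t.age > EXTANT_TOL for t in tree.tips())
        if self._has_fossils and bd.psi == 0:
            raise ParameterError(
                "tree has fossil tips: the fossil sampling rate psi must be > 0"
            )
        self._part_label_index = None
        self._part_labels: list[str] = []
        if partitions is not None and self.matrix is not None:
            w = self.matrix.weights
            labels = partitions.labels_for(self.matrix.char_ids)
            tot = w.sum()
            self._part_weight_frac = {
                lab: float(w[[l == lab for l in labels]].sum() / tot)
                for lab in partitions.groups
            }
            self._part_labels = sorted(partitions.groups)
            pos = {lab: i for i, lab in enumerate(self._part_labels)}
            self._part_label_index = np.array([pos[lab] for lab in labels])
        if self.has_data:
            self._spec_template = LikelihoodSpec(
                matrix=self.matrix,
                tree=tree,
                model=replace(model),
                clock=replace(clock),
            )
        self._fossil_calibs = [
            c
            for c in self.calibrations
            if c.kind == "tip" and tree.find_tip(c.taxa[0]).age > EXTANT_TOL
        ]

        depth0 = max(tree.depth, 1e-6)
        # proposal scales, adapted per operator during burn-in only
        self.tune = {
            "slide": 0.3 * depth0,
            "root": 0.3,
            "tree_scale": 0.2,
            "rate": 0.3,
            "switch": 0.5,
            "bd": 0.5,
            "origin": 0.5,
            "partition": 0.3,
        }
        self.operators = self._build_operators()
        self.accept_counts = {name: [0, 0] for name, _, _ in self.operators}

        lp, ll = self._evaluate(self.state)
        # a random start can still land at zero prior (e.g. root older than a
        # fixed origin): retry with fresh, progressively smaller start trees
        attempt = 0
        while lp == -np.inf and attempt < 100:
            attempt += 1
            labels = self.state.tree.tip_labels
            if config.origin_age is not None:
                scale = config.origin_age / (2.0 * max(np.log(len(labels)), 1.0))
            else:
                scale = max(self.state.tree.depth, 1e-6) * 0.7
            fresh = random_start_tree(labels, self.rng, self.calibrations, scale=scale)
            self.state.tree = fresh
            if self.state.branch_mult:
                self.state.branch_mult = {
                    id(n): 1.0 for n in fresh.preorder() if n.parent is not None
                }
            if config.origin_age is None:
                self.state.origin_age = (
                    fresh.root.age * 1.25 + config.origin_gap_prior_mean
                )
            lp, ll = self._evaluate(self.state)
        if lp == -np.inf:
            raise SimulationFailureError(
                "initial state has zero prior probability (calibrations or tree prior)"
            )
        self.state.log_prior, self.state.log_lik = lp, ll

    # -- initialisation helpers --------------------------------------- #

    def _retry_start(self, tree: TimeTree) -> TimeTree:
        taxa = tree.tip_labels
        return random_start_tree(
            taxa, self.rng, self.calibrations, scale=max(tree.depth, 1e-6)
        )

    def _build_operators(self):
        cfg = self.config
        ops: list[tuple[str, float, object]] = []
        weights = cfg.operator_weights or {}

        def add(name, default_weight, fn, enabled=True):
            w = weights.get(name, default_weight)
            if enabled and w > 0:
                ops.append((name, w, fn))

        n_internal = len(self.state.tree.internal_nodes())
        add("ages", 4.0, self._op_node_age, cfg.sample_ages and n_internal > 1)
        add("root", 1.0, self._op_root_scale, cfg.sample_ages)
        add("tree_scale", 1.0, self._op_tree_scale, cfg.sample_ages)
        add("narrow", 3.0, self._op_narrow, cfg.sample_topology and n_internal > 1)
        add("wide", 1.0, self._op_wide, cfg.sample_topology and n_internal > 1)
        add("slide", 2.0, self._op_slide, cfg.sample_topology)
        add("wb", 1.0, self._op_wilson_balding, cfg.sample_topology and n_internal > 1)
        add("origin", 1.0, self._op_origin, cfg.sample_origin)
        add("rate", 2.0, self._op_rate, cfg.sample_clock_rate and self.has_data)
        add("pi", 1.0, self._op_pi, cfg.sample_covarion and self.has_data)
        add("alpha", 1.0, self._op_alpha, cfg.sample_covarion and self.has_data)
        add("switch", 1.0, self._op_switch, cfg.sample_covarion and self.has_data)
        add(
            "partition",
            2.0,
            self._op_partition,
            cfg.sample_partition_rates and bool(self.state.part_g),
        )
        add("bd", 1.0, self._op_bd, cfg.sample_bd)
        add(
            "branch_rates",
            3.0,
            self._op_branch_rate,
            bool(self.state.branch_mult),
        )
        add("tip_ages", 1.0, self._op_tip_age, bool(self._fossil_calibs))
        if not ops:
            raise ParameterError("no operators enabled")
        return ops

    # -- densities ------------------------------------------------------ #

    def _log_prior(self, state: ChainState) -> float:
        cfg = self.config
        tree_lp = fbd_log_density(
            state.tree,
            state.bd,
            conditioning="origin",
            origin_age=state.origin_age,
        )
        if tree_lp == -np.inf:
            return -np.inf
        lp = tree_lp + calibration_log_prior(state.tree, self.calibrations)
        if lp == -np.inf:
            return -np.inf
        lp += _exp_logpdf(state.clock.mean_rate, cfg.rate_prior_mean)
        lp += _exp_logpdf(state.model.switch_rate, cfg.switch_prior_mean)
        lp += _exp_logpdf(state.bd.lam, cfg.bd_prior_mean)
        if state.bd.mu > 0:
            lp += _exp_logpdf(state.bd.mu, cfg.bd_prior_mean)
        if state.bd.psi > 0:
            lp += _exp_logpdf(state.bd.psi, cfg.bd_prior_mean)
        gap = state.origin_age - state.tree.root.age
        if gap < 0:
            return -np.inf
        if cfg.sample_origin:
            lp += _exp_logpdf(max(gap, 1e-300), cfg.origin_gap_prior_mean)
        if not (0 < state.model.pi_present < 1 and 0 < state.model.alpha <= 1):
            return -np.inf
        if state.branch_mult:
            lp += state.clock.multiplier_log_prior(
                np.fromiter(state.branch_mult.values(), dtype=float)
            )
        for g in state.part_g.values():  # Gamma(shape=2, mean=1) i.i.d.
            if g <= 0:
                return -np.inf
            lp += math.log(4.0) + math.log(g) - 2.0 * g
        return lp

    def _log_lik(self, state: ChainState) -> float:
        if not self.has_data:
            return 0.0
        spec = self._spec_template
        spec.tree = state.tree
        spec.model = state.model
        spec.clock = state.clock
        if state.branch_mult:
            r = state.clock.mean_rate
            spec.branch_rates = {k: r * m for k, m in state.branch_mult.items()}
        else:
            spec.branch_rates = None
        if self._part_label_index is not None:
            g = np.array([state.part_g[lab] for lab in self._part_labels])
            spec.char_rate_multipliers = g[self._part_label_index]
        return total_log_likelihood(spec)

    def _evaluate(self, state: ChainState) -> tuple[float, float]:
        lp = self._log_prior(state)
        if lp == -np.inf:
            return -np.inf, -np.inf
        return lp, self._log_lik(state)

    # -- main loop ------------------------------------------------------ #

    def run(
        self,
        n_steps: int,
        beta: float = 1.0,
        record_interval: int | None = None,
        adapt: bool = False,
        consistency_interval: int = 100,
    ):
        """Advance the chain; returns (trees, params, logL, logP) of the
        recorded states (empty lists when record_interval is None)."""
        names = [name for name, _, _ in self.operators]
        w = np.array([wt for _, wt, _ in self.operators])
        w = w / w.sum()
        fns = [fn for _, _, fn in self.operators]
        trees, params, lls, lps = [], [], [], []
        window = {n: [0, 0] for n in names}
        for step in range(n_steps):
            k = int(self.rng.choice(len(fns), p=w))
            name = names[k]
            self.accept_counts[name][1] += 1
            window[name][1] += 1
            proposal = fns[k](self.state)
            if proposal is not None:
                new_state, log_h = proposal
                lp, ll = self._evaluate(new_state)
                if lp > -np.inf:
                    new_target = lp + beta * ll
                    old_target = self.state.log_prior + beta * self.state.log_lik
                    if math.log(self.rng.random() + 1e-300) < (
                        new_target - old_target + log_h
                    ):
                        new_state.log_prior, new_state.log_lik = lp, ll
                        self.state = new_state
                        self.accept_counts[name][0] += 1
                        window[name][0] += 1
            if adapt and (step + 1) % 50 == 0:
                self._adapt(window)
                window = {n: [0, 0] for n in names}
            if consistency_interval and (step + 1) % consistency_interval == 0:
                lp, ll = self._evaluate(self.state)
                if not (
                    abs(lp - self.state.log_prior) < 1e-8
                    and abs(ll - self.state.log_lik) < 1e-8
                ):  # pragma: no cover - internal consistency guard
                    raise TraitPhyloError(
                        "cached posterior drifted from recomputation: "
                        f"prior {self.state.log_prior} vs {lp}, "
                        f"lik {self.state.log_lik} vs {ll}"
                    )
            if record_interval and (step + 1) % record_interval == 0:
                trees.append(self.state.tree.copy())
                params.append(self.state.param_record())
                lls.append(self.state.log_lik)
                lps.append(self.state.log_prior)
        return trees, params, lls, lps

    def _adapt(self, window) -> None:
        """Per-operator scale tuning toward ~25% acceptance (burn-in only)."""
        for name, (acc, tried) in window.items():
            if name in self.tune and tried >= 8:
                rate = acc / tried
                self.tune[name] *= math.exp(0.6 * (rate - 0.25))
                self.tune[name] = min(max(self.tune[name], 1e-6), 1e6)

    # -- operators ------------------------------------------------------ #
    # Each returns (proposed ChainState, log Hastings ratio) or None for an
    # immediately invalid proposal.

    def _scale_factor(self, name: str) -> float:
        return math.exp(self.tune[name] * (self.rng.random() - 0.5))

    def _op_node_age(self, state: ChainState):
        new = state.copy()
        internals = [
            n for n in new.tree.internal_nodes() if n.parent is not None
        ]
        if not internals:
            return None
        node = internals[int(self.rng.integers(len(internals)))]
        lo = max(c.age for c in node.children)
        hi = node.parent.age
        if hi <= lo:
            return None
        node.age = float(self.rng.uniform(lo, hi))
        return new, 0.0

    def _op_root_scale(self, state: ChainState):
        new = state.copy()
        root = new.tree.root
        lo = max(c.age for c in root.children)
        m = self._scale_factor("root")
        root.age = lo + (root.age - lo) * m
        return new, math.log(m)

    def _op_tree_scale(self, state: ChainState):
        new = state.copy()
        m = self._scale_factor("tree_scale")
        internals = new.tree.internal_nodes()
        for node in internals:
            node.age *= m
        for tip in new.tree.tips():
            if tip.parent.age < tip.age:
                return None
        if self.config.sample_origin:
            new.origin_age = state.origin_age * m
            return new, (len(internals) + 1) * math.log(m)
        return new, len(internals) * math.log(m)

    def _op_origin(self, state: ChainState):
        new = state.copy()
        gap = state.origin_age - state.tree.root.age
        if gap <= 0:
            return None
        m = self._scale_factor("origin")
        new.origin_age = new.tree.root.age + gap * m
        return new, math.log(m)

    def _op_narrow(self, state: ChainState):
        new = state.copy()
        cands = [
            n
            for n in new.tree.internal_nodes()
            if n.parent is not None and len(n.children) == 2
        ]
        if not cands:
            return None
        c = cands[int(self.rng.integers(len(cands)))]
        p = c.parent
        sibs = [x for x in p.children if x is not c]
        if len(sibs) != 1:
            return None
        s = sibs[0]
        if c.age <= s.age:
            return None
        a = c.children[int(self.rng.integers(2))]
        _swap_subtrees(p, s, c, a)
        return new, 0.0

    def _op_wide(self, state: ChainState):
        new = state.copy()
        nodes = [n for n in new.tree.preorder() if n.parent is not None]
        i, j = self.rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        if _is_ancestor(a, b) or _is_ancestor(b, a):
            return None
        if a.parent.age <= b.age or b.parent.age <= a.age:
            return None
        _swap_subtrees(a.parent, a, b.parent, b)
        return new, 0.0

    def _op_slide(self, state: ChainState):
        new = state.copy()
        nodes = [n for n in new.tree.preorder() if n.parent is not None]
        node = nodes[int(self.rng.integers(len(nodes)))]
        parent = node.parent
        delta = (self.rng.random() - 0.5) * self.tune["slide"]
        new_h = parent.age + delta
        if new_h <= node.age:
            return None
        sibs = [x for x in parent.children if x is not node]
        if len(sibs) != 1:
            return None
        s = sibs[0]
        if delta >= 0:
            if parent.parent is None or new_h <= parent.parent.age:
                parent.age = new_h
                return new, 0.0
            if new_h > new.tree.root.age:
                return None
            # climb: detach parent, find ancestor edge containing new_h
            gp = parent.parent
            _replace_child(gp, parent, s)
            below, climbs = gp, 0
            while below.parent is not None and below.parent.age < new_h:
                below = below.parent
                climbs += 1
            above = below.parent
            if above is None:
                return None
            _replace_child(above, below, parent)
            parent.children = [node]
            parent.add_child(below)
            parent.age = new_h
            # reverse descent makes one binary choice at gp and at each
            # ancestor climbed past
            return new, -(climbs + 1) * LOG2
        else:
            if new_h > s.age:
                parent.age = new_h
                return new, 0.0
            if parent.parent is None:
                return None  # would dissolve the root
            gp = parent.parent
            _replace_child(gp, parent, s)
            cur, choices = s, 0
            while new_h < cur.age:
                if cur.is_tip:
                    return None
                cur = cur.children[int(self.rng.integers(len(cur.children)))]
                choices += 1
            _replace_child(cur.parent, cur, parent)
            parent.children = [node]
            parent.add_child(cur)
            parent.age = new_h
            return new, choices * LOG2

    def _op_wilson_balding(self, state: ChainState):
        new = state.copy()
        cands = [
            n
            for n in new.tree.preorder()
            if n.parent is not None and n.parent.parent is not None
        ]
        if not cands:
            return None
        i = cands[int(self.rng.integers(len(cands)))]
        p = i.parent
        g = p.parent
        s = [x for x in p.children if x is not i][0]
        interval_old = g.age - max(i.age, s.age)
        if interval_old <= 0:
            return None
        # detach: the pruned tree has edge (s, g)
        _replace_child(g, p, s)
        in_subtree = {id(n) for n in _subtree(i)}
        targets = [
            j
            for j in new.tree.preorder()
            if j.parent is not None
            and id(j) not in in_subtree
            and j.parent.age > i.age
        ]
        if not targets:
            return None
        j = targets[int(self.rng.integers(len(targets)))]
        pj = j.parent
        lo = max(i.age, j.age)
        interval_new = pj.age - lo
        h = float(self.rng.uniform(lo, pj.age))
        _replace_child(pj, j, p)
        p.children = [i]
        p.add_child(j)
        p.age = h
        return new, math.log(interval_new) - math.log(interval_old)

    def _op_rate(self, state: ChainState):
        new = state.copy()
        m = self._scale_factor("rate")
        new.clock.mean_rate = state.clock.mean_rate * m
        return new, math.log(m)

    def _op_pi(self, state: ChainState):
        new = state.copy()
        x = _reflect(state.model.pi_present + 0.1 * (self.rng.random() - 0.5), 0.0, 1.0)
        if not 0 < x < 1:
            return None
        new.model = replace(state.model, pi_present=x)
        return new, 0.0

    def _op_alpha(self, state: ChainState):
        new = state.copy()
        x = _reflect(state.model.alpha + 0.1 * (self.rng.random() - 0.5), 0.0, 1.0)
        if not 0 < x <= 1:
            return None
        new.model = replace(state.model, alpha=x)
        return new, 0.0

    def _op_switch(self, state: ChainState):
        new = state.copy()
        m = self._scale_factor("switch")
        new.model = replace(state.model, switch_rate=max(state.model.switch_rate, 1e-8) * m)
        return new, math.log(m)

    def _op_partition(self, state: ChainState):
        new = state.copy()
        labels = sorted(new.part_g)
        lab = labels[int(self.rng.integers(len(labels)))]
        m = self._scale_factor("partition")
        new.part_g[lab] = state.part_g[lab] * m
        return new, math.log(m)

    def _op_bd(self, state: ChainState):
        new = state.copy()
        fields = ["lam"]
        if state.bd.mu > 0:
            fields.append("mu")
        if state.bd.psi > 0:
            fields.append("psi")
        name = fields[int(self.rng.integers(len(fields)))]
        m = self._scale_factor("bd")
        try:
            new.bd = replace(state.bd, **{name: getattr(state.bd, name) * m})
        except ParameterError:
            return None
        return new, math.log(m)

    def _op_branch_rate(self, state: ChainState):
        new = state.copy()
        keys = list(new.branch_mult)
        key = keys[int(self.rng.integers(len(keys)))]
        s = new.clock.stdev_log
        old = new.branch_mult[key]
        prop = float(self.rng.lognormal(mean=-0.5 * s * s, sigma=s))
        new.branch_mult[key] = prop
        # independence proposal from the prior: Hastings = p(old)/p(new)
        log_h = _lognormal_logpdf(old, s) - _lognormal_logpdf(prop, s)
        return new, log_h

    def _op_tip_age(self, state: ChainState):
        new = state.copy()
        c = self._fossil_calibs[int(self.rng.integers(len(self._fossil_calibs)))]
        tip = new.tree.find_tip(c.taxa[0])
        hi = min(c.upper, tip.parent.age)
        if hi <= c.lower:
            return None
        tip.age = float(self.rng.uniform(c.lower, hi))
        return new, 0.0


def _exp_logpdf(x: float, mean: float) -> float:
    if x < 0:
        return -np.inf
    return -math.log(mean) - x / mean


def _lognormal_logpdf(x: float, s: float) -> float:
    if x <= 0:
        return -np.inf
    mu = -0.5 * s * s
    lx = math.log(x)
    return -lx - math.log(s) - 0.5 * math.log(2 * math.pi) - (lx - mu) ** 2 / (2 * s * s)


def _swap_subtrees(pa: Node, a: Node, pb: Node, b: Node) -> None:
    """Exchange subtrees a (child of pa) and b (child of pb)."""
    ia = pa.children.index(a)
    ib = pb.children.index(b)
    pa.children[ia] = b
    pb.children[ib] = a
    a.parent = pb
    b.parent = pa


def _replace_child(parent: Node, old: Node, new_child: Node) -> None:
    idx = parent.children.index(old)
    parent.children[idx] = new_child
    new_child.parent = parent
    old.parent = None


def _is_ancestor(a: Node, b: Node) -> bool:
    node = b
    while node is not None:
        if node is a:
            return True
        node = node.parent
    return False


def _subtree(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    x = (x - lo) % (2 * width)
    if x > width:
        x = 2 * width - x
    return lo + x


# ---------------------------------------------------------------------- #
# Public entry points
# ---------------------------------------------------------------------- #


def run_mcmc(
    spec: LikelihoodSpec | None,
    bd: BirthDeathParams,
    calibrations: list[CalibrationConstraint] | None,
    config: MCMCConfig,
    taxa: list[str] | None = None,
) -> PosteriorSample:
    """Sample the posterior over trees and parameters.

    ``spec=None`` runs a constant-likelihood (prior-only) chain over the
    given ``taxa`` or ``config.init_tree``, which is how the tree prior is
    validated against forward simulation.
    """
    sampler = Sampler(spec, bd, calibrations, config, taxa=taxa)
    burn = int(config.chain_length * config.burnin)
    if burn:
        sampler.run(burn, adapt=True)
    trees, params, lls, lps = sampler.run(
        config.chain_length - burn, record_interval=config.thin
    )
    return PosteriorSample(
        trees=trees,
        params=params,
        log_likelihoods=np.array(lls),
        log_priors=np.array(lps),
        sampling_interval=config.thin,
        seed=config.seed,
        acceptance={k: tuple(v) for k, v in sampler.accept_counts.items()},
        burnin_steps=burn,
    )


def effective_sample_size(trace) -> float:
    """ESS by Geyer's initial-positive-sequence truncation of the
    autocorrelation function; never exceeds the trace length."""
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 10:
        raise ParameterError("trace too short for an ESS estimate (need >= 10)")
    var = x.var()
    if var == 0:
        warnings.warn("constant trace: ESS degenerate, reporting n", stacklevel=2)
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    tau = 1.0
    for m in range(1, n // 2):
        pair = rho[2 * m - 1] + rho[2 * m] if 2 * m < n else rho[2 * m - 1]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(min(n, n / tau))


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    k = max(1, int(math.ceil(prob * n)))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def summarise_ages(
    sample: PosteriorSample,
    clades: dict[str, set[str]],
    grid_points: int = 128,
) -> dict[str, dict]:
    """Median, 95% HPD and a density grid of MRCA ages per named clade.

    Monophyly is not required: the MRCA is taken per tree, so the summary
    reflects whatever ancestor covers the named taxa in each sampled state.
    """
    from scipy.stats import gaussian_kde

    out = {}
    for name, taxa in clades.items():
        ages = np.array([t.mrca(taxa).age for t in sample.trees])
        lo, hi = hpd_interval(ages)
        summary: dict[str, object] = {
            "median": float(np.median(ages)),
            "hpd_low": lo,
            "hpd_high": hi,
            "n": len(ages),
        }
        if np.ptp(ages) > 0:
            grid = np.linspace(ages.min(), ages.max(), grid_points)
            summary["grid"] = grid
            summary["density"] = gaussian_kde(ages)(grid)
        out[name] = summary
    return out
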