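"""Calibration and recovery experiments for the whole pipeline.

Each function here runs one self-contained simulation experiment under the
package's reference study conditions and returns the measured quantity.
The conditions emulate a calibrated cultural-trait dataset: pure-birth
trees conditioned on a determinate time depth (as fossil/historical
calibrations effectively impose), and a binary covarion process whose
overall rate sits near the information optimum for binary traits.

Why that rate: a binary character's correlation with its ancestor decays
as exp(-t / (2 pi0 pi1)) — twice the substitution rate at equal
frequencies — so saturation begins near 0.5 expected substitutions.
Maximising (branch-change x retention) over rate r for tree depth D gives
r*D ~ 0.25, which is where these experiments operate; empirically, real
cognate datasets are likewise analysed in the weakly-saturated regime.
"""

from __future__ import annotations

import numpy as np

from .congruence import blomberg_k, mantel_test
from .likelihood import LikelihoodSpec
from .mcmc import MCMCConfig, random_start_tree, run_mcmc
from .model_comparison import shared_tree_bayes_factor, stepping_stone_log_ml
from .priors import BirthDeathParams, CalibrationConstraint
from .simulate import (
    SimulationConfig,
    simulate_covarion_matrix,
    simulate_paired_datasets,
    simulate_time_tree,
)
from .substitution import ClockModel, CovarionModel
from .traits import PartitionScheme
from .trees import TimeTree, majority_consensus, patristic_matrix

#: reference covarion process for the recovery experiments
REFERENCE_RATE = 0.125


def reference_conditions(
    n_extant: int = 16,
    n_characters: int = 400,
    seed: int = 0,
    level_multipliers: dict[int, float] | None = None,
    n_per_level: dict[int, int] | None = None,
) -> SimulationConfig:
    """The frozen study conditions shared by all recovery experiments."""
    return SimulationConfig(
        n_extant=n_extant,
        bd=BirthDeathParams(lam=1.0, mu=0.0, rho=1.0),
        origin_age=3.0 if n_extant <= 16 else 3.2,
        root_age_range=(1.8, 2.2) if n_extant <= 16 else (1.8, 2.4),
        seed=seed,
        n_characters_per_level=n_per_level or {1: n_characters},
        dependencies=False,
        covarion=CovarionModel(
            pi_present=0.5, alpha=0.5, switch_rate=0.5, overall_rate=REFERENCE_RATE
        ),
        level_rate_multipliers=level_multipliers or {1: 1.0},
    )


# ------------------------------------------------------------------ #
# Tree-prior validation
# ------------------------------------------------------------------ #


def prior_root_age_samples(
    seed: int, n: int = 2000, n_taxa: int = 6, chain_length: int = 200_000
) -> tuple[np.ndarray, np.ndarray]:
    """Root ages from forward birth-death simulation versus a data-free
    MCMC chain targeting the same origin-conditioned prior."""
    bd = BirthDeathParams(lam=1.0, mu=0.4, rho=1.0)
    origin = 2.0
    sim_cfg = SimulationConfig(
        n_extant=n_taxa, bd=bd, origin_age=origin, seed=seed,
        n_characters_per_level={1: 1},
    )
    rng = np.random.default_rng(seed)
    forward = np.array(
        [simulate_time_tree(sim_cfg, rng=rng).root.age for _ in range(n)]
    )
    mcfg = MCMCConfig(
        chain_length=chain_length, thin=chain_length // (n // 2) or 1,
        seed=seed + 1, burnin=0.1,
        sample_origin=False, origin_age=origin, sample_bd=False,
    )
    post = run_mcmc(None, bd, [], mcfg, taxa=[f"t{i + 1}" for i in range(n_taxa)])
    return forward, post.trace("root_age")


# ------------------------------------------------------------------ #
# Parameter recovery
# ------------------------------------------------------------------ #


def rate_coverage_replicate(seed: int, chain_length: int = 16_000) -> bool:
    """One replicate of the clock-rate recovery experiment.

    16 taxa x 500 covarion characters at a known rate; the root age is
    bounded within +-10% of truth (the identifying information real
    calibrations provide). Returns whether the central 95% posterior
    interval covers the generating rate.
    """
    cfg = reference_conditions(n_characters=500, seed=seed)
    tree = simulate_time_tree(cfg)
    matrix = simulate_covarion_matrix(tree, cfg)
    cal = [
        CalibrationConstraint(
            kind="mrca", taxa=tuple(tree.tip_labels),
            lower=tree.root.age * 0.9, upper=tree.root.age * 1.1,
        )
    ]
    rng = np.random.default_rng(seed + 900)
    start = random_start_tree(tree.tip_labels, rng, cal, scale=tree.depth / np.log(16))
    spec = LikelihoodSpec(
        matrix=matrix, tree=start, model=CovarionModel(),
        clock=ClockModel(mean_rate=0.2),
    )
    post = run_mcmc(
        spec, cfg.bd, cal,
        MCMCConfig(chain_length=chain_length, thin=10, seed=seed, burnin=0.4),
    )
    lo, hi = np.quantile(post.trace("mean_rate"), [0.025, 0.975])
    return bool(lo <= REFERENCE_RATE <= hi)


def level_rank_replicate(seed: int, chain_length: int = 8_000) -> bool:
    """Per-level mutation-rate recovery: data generated with level
    multipliers 0.5 / 1.0 / 2.0 / 2.0 over four equal partitions; returns
    whether posterior medians recover the rank order (level 1 < level 2 <
    both of levels 3 and 4; the tie between 3 and 4 is not ordered)."""
    cfg = reference_conditions(
        seed=seed,
        n_per_level={1: 125, 2: 125, 3: 125, 4: 125},
        level_multipliers={1: 0.5, 2: 1.0, 3: 2.0, 4: 2.0},
    )
    tree = simulate_time_tree(cfg)
    matrix = simulate_covarion_matrix(tree, cfg)
    parts = PartitionScheme.from_levels(matrix)
    spec = LikelihoodSpec(
        matrix=matrix, tree=tree.copy(), model=CovarionModel(),
        clock=ClockModel(mean_rate=REFERENCE_RATE), partitions=parts,
    )
    post = run_mcmc(
        spec, cfg.bd, [],
        MCMCConfig(chain_length=chain_length, thin=10, seed=seed, burnin=0.3),
    )
    labels = ["level1", "level2", "level3", "level4"]
    mult = post.partition_multipliers(labels, {lab: 0.25 for lab in labels})
    med = {lab: float(np.median(m)) for lab, m in mult.items()}
    return med["level1"] < med["level2"] < min(med["level3"], med["level4"])


def topology_recovery_replicate(seed: int, chain_length: int = 25_000) -> float:
    """Fraction of true clades recovered at >= 50% consensus support from a
    random-start chain on a 16-taxon, 400-character dataset."""
    cfg = reference_conditions(seed=seed)
    tree = simulate_time_tree(cfg)
    matrix = simulate_covarion_matrix(tree, cfg)
    rng = np.random.default_rng(seed + 500)
    start = random_start_tree(tree.tip_labels, rng, scale=tree.depth / np.log(16))
    spec = LikelihoodSpec(
        matrix=matrix, tree=start, model=CovarionModel(),
        clock=ClockModel(mean_rate=REFERENCE_RATE),
    )
    post = run_mcmc(
        spec, cfg.bd, [],
        MCMCConfig(chain_length=chain_length, thin=25, seed=seed, burnin=0.3),
    )
    cons = majority_consensus(post.trees)
    true_clades = set(tree.clades())
    return len(true_clades & set(cons.clades())) / len(true_clades)


# ------------------------------------------------------------------ #
# Bayes-factor sign recovery
# ------------------------------------------------------------------ #


def bf_sign_replicate(seed: int, same_tree: bool) -> float:
    """Log Bayes factor (positive favours separate phylogenies) for paired
    20-taxon x 300-character datasets simulated on one shared tree or on
    two independent trees."""
    cfg = reference_conditions(n_extant=20, n_characters=300, seed=seed)
    a, b, _ = simulate_paired_datasets(cfg, same_tree=same_tree)
    res = shared_tree_bayes_factor(
        a, b, [(t, t) for t in a.taxa],
        bd=cfg.bd,
        model=CovarionModel(),
        clock=ClockModel(mean_rate=REFERENCE_RATE),
        config=MCMCConfig(chain_length=600, thin=5, seed=seed * 7 + 1, burnin=0.2),
        steps=8, chain_length_per_step=700,
    )
    return float(res.log_bf)


# ------------------------------------------------------------------ #
# Congruence-statistic calibration
# ------------------------------------------------------------------ #


def mantel_type_one_error(
    seed: int, n_pairs: int = 1000, n_taxa: int = 8, permutations: int = 199
) -> float:
    """Empirical rejection rate at alpha = 0.05 for independent random
    distance matrices (should sit near 0.05)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for k in range(n_pairs):
        p1 = rng.normal(size=(n_taxa, 3))
        p2 = rng.normal(size=(n_taxa, 3))
        d1 = np.linalg.norm(p1[:, None] - p1[None, :], axis=-1)
        d2 = np.linalg.norm(p2[:, None] - p2[None, :], axis=-1)
        res = mantel_test(d1, d2, permutations=permutations, seed=seed + k + 1)
        rejections += res.p <= 0.05
    return rejections / n_pairs


def bm_k_mean(seed: int, n_reps: int = 200, n_tips: int = 32) -> float:
    """Mean Blomberg's K over Brownian-motion simulations on one tree
    (should sit near 1)."""
    cfg = SimulationConfig(
        n_extant=n_tips, bd=BirthDeathParams(lam=1.0, mu=0.2), origin_age=4.0,
        seed=seed, n_characters_per_level={1: 1},
    )
    tree = simulate_time_tree(cfg)
    taxa = tree.tip_labels
    D = patristic_matrix(tree, taxa)
    depths = np.array([tree.root.age - tree.find_tip(t).age for t in taxa])
    V = (depths[:, None] + depths[None, :] - D) / 2.0
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n_tips))
    rng = np.random.default_rng(seed + 1)
    ks = []
    for _ in range(n_reps):
        x = dict(zip(taxa, L @ rng.normal(size=n_tips)))
        ks.append(blomberg_k(tree, x))
    return float(np.mean(ks))


# ------------------------------------------------------------------ #
# Marginal-likelihood oracle
# ------------------------------------------------------------------ #


def stepping_stone_vs_quadrature(seed: int) -> tuple[float, float, float]:
    """Stepping-stone estimate vs dense quadrature on a one-parameter toy
    (free clock rate under its exponential prior, fixed 4-taxon tree).

    Returns (estimate, oracle, estimator sd)."""
    from scipy.integrate import quad

    from .likelihood import total_log_likelihood

    cfg = reference_conditions(n_extant=4, n_characters=40, seed=seed)
    cfg.root_age_range = None
    cfg.origin_age = 2.0
    tree = simulate_time_tree(cfg)
    matrix = simulate_covarion_matrix(tree, cfg)
    model = CovarionModel()
    bd = cfg.bd

    def loglik(r: float) -> float:
        return total_log_likelihood(
            LikelihoodSpec(matrix=matrix, tree=tree, model=model,
                           clock=ClockModel(mean_rate=r))
        )

    peak = max(loglik(r) for r in np.linspace(0.02, 3, 40))
    integral, _ = quad(lambda r: np.exp(loglik(r) - peak) * np.exp(-r), 1e-6, 30, limit=200)
    oracle = float(np.log(integral) + peak)

    spec = LikelihoodSpec(matrix=matrix, tree=tree.copy(), model=model,
                          clock=ClockModel(mean_rate=1.0))
    ss_cfg = MCMCConfig(
        chain_length=800, thin=4, seed=seed + 3, burnin=0.2,
        sample_topology=False, sample_ages=False, sample_covarion=False,
        sample_bd=False, sample_origin=False, origin_age=tree.root.age * 1.3,
        rate_prior_mean=1.0,
    )
    est = stepping_stone_log_ml(spec, bd, [], ss_cfg, steps=12,
                                chain_length_per_step=800)
    return est.log_ml, oracle, est.standard_deviation
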