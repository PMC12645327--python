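"""Simulate a binary trait matrix on a birth-death tree, infer the
phylogeny by MCMC, and summarise it as a majority-rule consensus with
clade supports and MRCA age posteriors."""

import numpy as np

from traitphylo import (
    ClockModel,
    CovarionModel,
    LikelihoodSpec,
    MCMCConfig,
    majority_consensus,
    run_mcmc,
    summarise_ages,
)
from traitphylo.experiments import reference_conditions
from traitphylo.mcmc import random_start_tree
from traitphylo.simulate import simulate_covarion_matrix, simulate_time_tree

cfg = reference_conditions(n_extant=10, n_characters=200, seed=7)
tree = simulate_time_tree(cfg)
matrix = simulate_covarion_matrix(tree, cfg)
print(f"simulated {matrix.n_taxa} taxa x {matrix.n_characters} binary characters "
      f"on a tree of depth {tree.depth:.2f}")

start = random_start_tree(tree.tip_labels, np.random.default_rng(1))
spec = LikelihoodSpec(
    matrix=matrix, tree=start,
    model=CovarionModel(),                 # covarion parameters are sampled
    clock=ClockModel(mean_rate=0.125),     # starting value; sampled too
)
post = run_mcmc(spec, cfg.bd, [], MCMCConfig(chain_length=8000, thin=20, seed=3, burnin=0.3))
print(f"retained {len(post)} posterior samples")

cons = majority_consensus(post.trees)
print("\nmajority-rule consensus (support in % as node comments):")
print(cons.to_newick(include_support=True, precision=3))

ages = summarise_ages(post, {"root": set(matrix.taxa)})
s = ages["root"]
print(f"\nroot age posterior: median {s['median']:.2f}, "
      f"95% HPD [{s['hpd_low']:.2f}, {s['hpd_high']:.2f}] (truth {tree.root.age:.2f})")
print("\nClades recovered at >= 50% support match the generating tree where the "
      "data carry enough change; the HPD shows the dating uncertainty that "
      "remains without external calibrations.")
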