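"""Configuration-driven orchestration of the standard analyses.

A single declarative YAML/dict config describes data, model, priors, MCMC
settings and comparison options; the four entry points below run the
per-dataset inference, the cross-phylogeny congruence suite, the
shared-vs-separate-tree Bayes factor, and the synthetic fixture generator.
Every stochastic stage derives its seed from the single root seed plus a
fixed per-stage offset, so each stage is independently reproducible.

Calibration bounds are declared with an explicit unit: ``BP`` (years before
present) or ``CE`` (calendar years, converted as BP = 1950 - CE, which
swaps the bound order). Mixing the two silently is the classic
dating-pipeline error this config format is designed to prevent.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import numpy as np
import yaml

from . import congruence, model_comparison
from .errors import ParameterError, ValidationError
from .likelihood import LikelihoodSpec
from .mcmc import MCMCConfig, run_mcmc, summarise_ages
from .priors import BirthDeathParams, CalibrationConstraint, ce_to_bp
from .simulate import (
    SimulationConfig,
    simulate_covarion_matrix,
    simulate_time_tree,
)
from .substitution import ClockModel, CovarionModel
from .traits import (
    PartitionScheme,
    apply_level_weights,
    match_shared_taxa,
    read_trait_matrix,
    write_annotations,
    write_trait_matrix,
)
from .trees import majority_consensus, read_trees, write_trees

# per-stage seed offsets off the root seed
_STAGE_SEEDS = {"simulate": 11, "infer": 23, "compare": 37, "bf": 53}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    if "seed" not in cfg:
        raise ParameterError("config must set an explicit root seed")
    return cfg


def _stage_seed(cfg: dict, stage: str) -> int:
    return (int(cfg["seed"]) * 1000 + _STAGE_SEEDS[stage]) % (2**31 - 1)


def parse_calibrations(entries: list[dict]) -> list[CalibrationConstraint]:
    out = []
    for e in entries or []:
        unit = e.get("unit", "BP").upper()
        lower, upper = float(e["lower"]), float(e["upper"])
        if unit == "CE":
            lower, upper = ce_to_bp(upper), ce_to_bp(lower)
        elif unit != "BP":
            raise ParameterError(f"unknown calibration unit {unit!r} (use BP or CE)")
        out.append(
            CalibrationConstraint(
                kind=e.get("kind", "mrca"),
                taxa=tuple(e["taxa"]),
                lower=lower,
                upper=upper,
            )
        )
    return out


def _load_matrix(cfg: dict, key: str = "data"):
    d = cfg[key]
    m = read_trait_matrix(
        d["matrix"], format=d.get("format", "csv"), annotations=d.get("annotations")
    )
    weights = cfg.get("model", {}).get("weights")
    if weights:
        m = apply_level_weights(m, {int(k): float(v) for k, v in weights.items()})
    return m


def _model_block(cfg: dict):
    model_cfg = cfg.get("model", {})
    model = CovarionModel(**model_cfg.get("covarion", {}))
    clock = ClockModel(**model_cfg.get("clock", {}))
    return model, clock, model_cfg.get("partition_by")


def _bd_block(cfg: dict) -> BirthDeathParams:
    return BirthDeathParams(**cfg.get("prior", {}).get("birth_death", {"lam": 1.0}))


def cmd_infer(config, output_dir: str | None = None) -> dict:
    """Per-dataset Bayesian inference: trace, tree log, consensus, ages.

    Returns a small manifest of the written artefacts.
    """
    cfg = load_config(config)
    out = output_dir or cfg.get("output_dir", ".")
    os.makedirs(out, exist_ok=True)
    m = _load_matrix(cfg)
    model, clock, partition_by = _model_block(cfg)
    partitions = None
    if partition_by == "level":
        partitions = PartitionScheme.from_levels(m)
    elif partition_by == "category":
        partitions = PartitionScheme.from_categories(m)
    bd = _bd_block(cfg)
    calibrations = parse_calibrations(cfg.get("prior", {}).get("calibrations"))
    mcfg_dict = dict(cfg.get("mcmc", {}))
    mcfg = MCMCConfig(seed=_stage_seed(cfg, "infer"), **mcfg_dict)

    from .mcmc import random_start_tree

    rng = np.random.default_rng(mcfg.seed + 1)
    start = random_start_tree(list(m.taxa), rng, calibrations)
    spec = LikelihoodSpec(
        matrix=m, tree=start, model=model, clock=clock, partitions=partitions
    )
    post = run_mcmc(spec, bd, calibrations, mcfg)

    trace_path = os.path.join(out, "trace.tsv")
    trees_path = os.path.join(out, "trees.nex")
    cons_path = os.path.join(out, "consensus.nwk")
    ages_path = os.path.join(out, "ages.tsv")
    post.write_trace(trace_path)
    write_trees(post.trees, trees_path, schema="nexus")
    cons = majority_consensus(post.trees)
    with open(cons_path, "w") as fh:
        fh.write(cons.to_newick(include_support=True) + "\n")
    clades = {
        name: set(taxa) for name, taxa in (cfg.get("clades") or {}).items()
    }
    if not clades:
        clades = {"root": set(m.taxa)}
    ages = summarise_ages(post, clades)
    with open(ages_path, "w") as fh:
        fh.write("clade\tmedian\thpd_low\thpd_high\tn\n")
        for name, s in ages.items():
            fh.write(
                f"{name}\t{s['median']:.6g}\t{s['hpd_low']:.6g}"
                f"\t{s['hpd_high']:.6g}\t{s['n']}\n"
            )
    from .mcmc import effective_sample_size

    warnings_list = []
    for name in ("root_age", "mean_rate"):
        trace = post.trace(name)
        if len(trace) >= 10 and np.ptp(trace) > 0:
            ess = effective_sample_size(trace)
            if ess < 200:
                warnings_list.append(f"ESS({name}) = {ess:.0f} < 200")
    import hashlib as _hashlib

    cfg_hash = _hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "seed": mcfg.seed,
        "config_hash": cfg_hash,
        "convergence_warnings": warnings_list,
        "n_samples": len(post),
        "calibrations_bp": [
            {"taxa": list(c.taxa), "lower": c.lower, "upper": c.upper, "kind": c.kind}
            for c in calibrations
        ],
        "artefacts": [trace_path, trees_path, cons_path, ages_path],
    }
    with open(os.path.join(out, "infer_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _read_taxon_map(path: str) -> list[tuple[str, str]]:
    import pandas as pd

    df = pd.read_csv(path)
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def cmd_compare(config, output_dir: str | None = None) -> dict:
    """Congruence suite: Mantel tests (consensus and posterior-averaged) and
    the two Blomberg's K cross-mappings."""
    cfg = load_config(config)
    out = output_dir or cfg.get("output_dir", ".")
    os.makedirs(out, exist_ok=True)
    comp = cfg["compare"]
    seed = _stage_seed(cfg, "compare")
    a = _load_matrix(cfg, "data_a")
    b = _load_matrix(cfg, "data_b")
    taxon_map = _read_taxon_map(comp["taxon_map"])
    a_shared, b_shared = match_shared_taxa(a, b, taxon_map)
    if a_shared.n_taxa < 4:
        raise ValidationError(
            f"only {a_shared.n_taxa} shared taxa: congruence tests need >= 4"
        )
    trees_a = read_trees(comp["trees_a"])
    trees_b = read_trees(comp["trees_b"])
    perms = int(comp.get("permutations", 999))
    n_post = min(int(comp.get("n_posterior", 1000)), len(trees_a), len(trees_b))
    normalise = bool(comp.get("normalise", True))

    order_a = list(a_shared.taxa)
    order_b = list(b_shared.taxa)
    # consensus-tree Mantel
    from .trees import patristic_matrix, prune_tips

    cons_a = majority_consensus(trees_a)
    cons_b = majority_consensus(trees_b)
    d_a = patristic_matrix(prune_tips(cons_a, order_a), order_a)
    d_b = patristic_matrix(prune_tips(cons_b, order_b), order_b)
    mantel_cons = congruence.mantel_test(d_a, d_b, permutations=perms, seed=seed)
    # posterior-averaged Mantel with depth normalisation
    pd_a = congruence.posterior_mean_distances(
        trees_a, order_a, n=n_post, normalise=normalise, seed=seed + 1
    )
    pd_b = congruence.posterior_mean_distances(
        trees_b, order_b, n=n_post, normalise=normalise, seed=seed + 2
    )
    mantel_post = congruence.mantel_test(pd_a, pd_b, permutations=perms, seed=seed + 3)

    # PCA cross-mappings: component of one dataset on the other's trees
    pc_a = congruence.first_principal_component(a_shared)
    pc_b = congruence.first_principal_component(b_shared)
    to_a_label = dict(zip(order_b, order_a))
    k_b_on_a = congruence.k_over_posterior(
        trees_a,
        {order_a[i]: float(pc_b[i]) for i in range(len(order_a))},
        permutations=perms,
        seed=seed + 4,
    )
    k_a_on_b = congruence.k_over_posterior(
        trees_b,
        {order_b[i]: float(pc_a[i]) for i in range(len(order_b))},
        permutations=perms,
        seed=seed + 5,
    )
    report = {
        "seed": seed,
        "n_shared_taxa": len(order_a),
        "mantel_consensus": asdict(mantel_cons),
        "mantel_posterior": {**asdict(mantel_post), "n_trees": n_post, "normalised": normalise},
        "k_b_traits_on_a_trees": asdict(k_b_on_a),
        "k_a_traits_on_b_trees": asdict(k_a_on_b),
    }
    with open(os.path.join(out, "congruence_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def cmd_bf(config, output_dir: str | None = None) -> dict:
    """Shared-vs-separate phylogeny Bayes factor report."""
    cfg = load_config(config)
    out = output_dir or cfg.get("output_dir", ".")
    os.makedirs(out, exist_ok=True)
    comp = cfg["compare"]
    seed = _stage_seed(cfg, "bf")
    a = _load_matrix(cfg, "data_a")
    b = _load_matrix(cfg, "data_b")
    taxon_map = _read_taxon_map(comp["taxon_map"])
    model, clock, _ = _model_block(cfg)
    bd = _bd_block(cfg)
    calibrations = parse_calibrations(cfg.get("prior", {}).get("calibrations"))
    bf_cfg = cfg.get("bf", {})
    mcfg = MCMCConfig(
        chain_length=int(bf_cfg.get("chain_length", 1000)),
        thin=int(bf_cfg.get("thin", 5)),
        seed=seed,
    )
    result = model_comparison.shared_tree_bayes_factor(
        a,
        b,
        taxon_map,
        bd,
        calibrations=calibrations,
        model=model,
        clock=clock,
        config=mcfg,
        steps=int(bf_cfg.get("steps", 8)),
        chain_length_per_step=int(bf_cfg.get("chain_length_per_step", 600)),
    )
    report = result.to_dict()
    report["beta_ladder"] = model_comparison.beta_ladder(
        int(bf_cfg.get("steps", 8))
    ).tolist()
    with open(os.path.join(out, "bayes_factor_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def cmd_simulate(config, output_dir: str | None = None) -> dict:
    """Write a synthetic fixture bundle: matrix, annotations, truth tree,
    parameter record, and a checksum manifest."""
    cfg = load_config(config)
    out = output_dir or cfg.get("output_dir", ".")
    os.makedirs(out, exist_ok=True)
    sim_cfg_dict = dict(cfg.get("simulate", {}))
    if "bd" in sim_cfg_dict:
        sim_cfg_dict["bd"] = BirthDeathParams(**sim_cfg_dict["bd"])
    if "covarion" in sim_cfg_dict:
        sim_cfg_dict["covarion"] = CovarionModel(**sim_cfg_dict["covarion"])
    if "n_characters_per_level" in sim_cfg_dict:
        sim_cfg_dict["n_characters_per_level"] = {
            int(k): int(v) for k, v in sim_cfg_dict["n_characters_per_level"].items()
        }
    if "level_rate_multipliers" in sim_cfg_dict:
        sim_cfg_dict["level_rate_multipliers"] = {
            int(k): float(v) for k, v in sim_cfg_dict["level_rate_multipliers"].items()
        }
    sim = SimulationConfig(seed=_stage_seed(cfg, "simulate"), **sim_cfg_dict)
    rng = np.random.default_rng(sim.seed)
    tree = simulate_time_tree(sim, rng=rng)
    matrix = simulate_covarion_matrix(tree, sim, rng=rng)

    matrix_path = os.path.join(out, "matrix.csv")
    nexus_path = os.path.join(out, "matrix.nex")
    ann_path = os.path.join(out, "annotations.csv")
    tree_path = os.path.join(out, "truth_tree.nwk")
    params_path = os.path.join(out, "truth_params.json")
    write_trait_matrix(matrix, matrix_path, format="csv")
    write_trait_matrix(matrix, nexus_path, format="nexus")
    write_annotations(matrix, ann_path)
    with open(tree_path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
    with open(params_path, "w") as fh:
        json.dump(
            {
                "seed": sim.seed,
                "bd": sim.bd.to_dict(),
                "covarion": sim.covarion.to_dict(),
                "level_rate_multipliers": sim.level_rate_multipliers,
                "n_characters_per_level": sim.n_characters_per_level,
                "burst_fraction": sim.burst_fraction,
            },
            fh,
            indent=2,
        )
    files = [matrix_path, nexus_path, ann_path, tree_path, params_path]
    manifest = {
        "seed": sim.seed,
        "files": {
            os.path.basename(p): hashlib.sha256(open(p, "rb").read()).hexdigest()
            for p in files
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def cmd_consensus(tree_log: str, output: str, threshold: float = 0.5) -> str:
    """Majority-rule consensus of a tree log, written as newick with
    per-node support comments."""
    trees = read_trees(tree_log)
    cons = majority_consensus(trees, threshold=threshold)
    newick = cons.to_newick(include_support=True)
    with open(output, "w") as fh:
        fh.write(newick + "\n")
    return newick
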