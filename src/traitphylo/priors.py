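"""Birth-death and fossilised birth-death (FBD) tree priors, plus
hard age-calibration constraints.

The FBD process has speciation rate ``lam`` (births per lineage-year),
extinction rate ``mu``, extant sampling fraction ``rho`` and fossil
sampling rate ``psi``; ``psi = 0`` recovers the plain reconstructed
birth-death process. Fossils are terminal tips only (no sampled
ancestors): each fossil is a sampled lineage whose descendants left no
other sample.

Densities are available under two conditionings:

``root``
    Density of the tree given its root age (no density term for the root
    age itself). Each root-child subtree is treated as a process started
    at the root age, conditioned on leaving at least one sample.
``origin``
    Density given the age of the origin (the start of the stem lineage),
    conditioned on the process leaving at least one sample. This is the
    conditioning the MCMC uses, with the origin age as a sampled
    parameter, because it induces a proper density over the root age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import MissingReferenceError, ParameterError, ValidationError
from .trees import Node, TimeTree

#: Age tolerance (years) below which a tip counts as extant.
EXTANT_TOL = 1e-9

#: Radiocarbon convention: present = 1950 CE.
PRESENT_CE = 1950


def ce_to_bp(year_ce: float) -> float:
    """Convert a CE calendar year to years before present (present = 1950 CE)."""
    return PRESENT_CE - year_ce


@dataclass
class BirthDeathParams:
    """Rates of the (fossilised) birth-death process."""

    lam: float
    mu: float = 0.0
    rho: float = 1.0
    psi: float = 0.0

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ParameterError("lam (birth rate) must be > 0")
        if self.mu < 0:
            raise ParameterError("mu (death rate) must be >= 0")
        if not 0 < self.rho <= 1:
            raise ParameterError("rho (extant sampling fraction) must be in (0, 1]")
        if self.psi < 0:
            raise ParameterError("psi (fossil sampling rate) must be >= 0")
        if self.psi == 0 and abs(self.lam - self.mu) < 1e-14:
            raise ParameterError(
                "critical process (lam == mu with psi == 0) is not supported"
            )

    def to_dict(self) -> dict:
        return {"lam": self.lam, "mu": self.mu, "rho": self.rho, "psi": self.psi}


# ---------------------------------------------------------------------- #
# FBD primitives (c1/c2 parameterisation)
# ---------------------------------------------------------------------- #


def _c1_c2(p: BirthDeathParams) -> tuple[float, float]:
    c1 = math.sqrt((p.lam - p.mu - p.psi) ** 2 + 4.0 * p.lam * p.psi)
    c2 = -(p.lam - p.mu - 2.0 * p.lam * p.rho - p.psi) / c1
    return c1, c2


def _log_q(t: float, c1: float, c2: float) -> float:
    """log q(t): per-lineage density factor of producing one observed lineage."""
    # q(t) = 4 e^{-c1 t} / (e^{-c1 t}(1-c2) + (1+c2))^2
    e = math.exp(-c1 * t)
    return math.log(4.0) - c1 * t - 2.0 * math.log(e * (1.0 - c2) + (1.0 + c2))


def _p0(t: float, p: BirthDeathParams, c1: float, c2: float) -> float:
    """Probability a lineage at age t leaves no sampled descendants at all."""
    e = math.exp(-c1 * t)
    frac = (e * (1.0 - c2) - (1.0 + c2)) / (e * (1.0 - c2) + (1.0 + c2))
    return (p.lam + p.mu + p.psi + c1 * frac) / (2.0 * p.lam)


def _subtree_log_density(
    root: Node, start_age: float, p: BirthDeathParams, c1: float, c2: float
) -> float:
    """Log density of the sampled subtree below ``root``, for a process that
    starts with a single lineage at ``start_age``, conditioned on leaving at
    least one sample. ``root`` itself contributes its own lambda-q factor if
    internal, or its tip factor if terminal."""
    if start_age < root.age - 1e-12:
        return -np.inf
    p0_start = _p0(start_age, p, c1, c2)
    if p0_start >= 1.0:
        return -np.inf
    logf = _log_q(start_age, c1, c2) - math.log1p(-p0_start)
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_tip:
            if node.age <= EXTANT_TOL:
                logf += math.log(p.rho)
            else:
                if p.psi == 0:
                    raise ValidationError(
                        "fossil tip present but psi = 0: the fossil sampling "
                        "rate must be positive to explain non-contemporaneous tips"
                    )
                p0_tip = _p0(node.age, p, c1, c2)
                logf += (
                    math.log(p.psi)
                    + math.log(p0_tip)
                    - _log_q(node.age, c1, c2)
                )
        else:
            logf += math.log(p.lam) + _log_q(node.age, c1, c2)
            stack.extend(node.children)
    return logf


def fbd_log_density(
    t: TimeTree,
    p: BirthDeathParams,
    conditioning: str = "root",
    origin_age: float | None = None,
) -> float:
    """Log density of a sampled time tree under the FBD process.

    With ``psi = 0`` and an extant-only tree this equals
    :func:`bd_log_density` under the same conditioning. Fossil tips require
    ``psi > 0``.
    """
    fossil_tips = [tip for tip in t.tips() if tip.age > EXTANT_TOL]
    if fossil_tips and p.psi == 0:
        raise ValidationError(
            f"tree has {len(fossil_tips)} fossil tip(s) but psi = 0; "
            "set a positive fossil sampling rate"
        )
    c1, c2 = _c1_c2(p)
    if conditioning == "origin":
        if origin_age is None:
            raise ParameterError("origin conditioning requires origin_age")
        if origin_age < t.root.age:
            return -np.inf
        # stem lineage from origin down to the root split
        p0_or = _p0(origin_age, p, c1, c2)
        if p0_or >= 1.0:
            return -np.inf
        logf = _log_q(origin_age, c1, c2) - math.log1p(-p0_or)
        logf += math.log(p.lam) + _log_q(t.root.age, c1, c2)
        for child in t.root.children:
            logf += _subtree_log_density_unconditioned(child, p, c1, c2)
        return logf
    if conditioning == "root":
        if len(t.root.children) != 2:
            raise ValidationError("root conditioning requires a bifurcating root")
        return sum(
            _subtree_log_density(child, t.root.age, p, c1, c2)
            for child in t.root.children
        )
    raise ParameterError(f"unknown conditioning {conditioning!r}")


def _subtree_log_density_unconditioned(
    node: Node, p: BirthDeathParams, c1: float, c2: float
) -> float:
    """Product of per-node factors below (and including) ``node``,
    without the per-subtree survival conditioning (used by the
    origin-conditioned form, which conditions once globally)."""
    logf = 0.0
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd.is_tip:
            if nd.age <= EXTANT_TOL:
                logf += math.log(p.rho)
            else:
                logf += (
                    math.log(p.psi)
                    + math.log(_p0(nd.age, p, c1, c2))
                    - _log_q(nd.age, c1, c2)
                )
        else:
            logf += math.log(p.lam) + _log_q(nd.age, c1, c2)
            stack.extend(nd.children)
    return logf


def bd_log_density(
    t: TimeTree,
    p: BirthDeathParams,
    conditioning: str = "root",
    origin_age: float | None = None,
) -> float:
    """Log prior density of an extant-only time tree under the reconstructed
    birth-death process with extant sampling fraction rho.

    Raises a model-mismatch error for fossil (non-contemporaneous) tips —
    use :func:`fbd_log_density` for those.
    """
    if p.psi != 0:
        raise ParameterError("bd_log_density requires psi = 0; use fbd_log_density")
    fossil_tips = [tip.label for tip in t.tips() if tip.age > EXTANT_TOL]
    if fossil_tips:
        raise ValidationError(
            f"tree has fossil tip(s) {fossil_tips}: the plain birth-death prior "
            "assumes contemporaneous tips — use the fossilised birth-death prior"
        )
    return fbd_log_density(t, p, conditioning=conditioning, origin_age=origin_age)


# ---------------------------------------------------------------------- #
# Calibrations
# ---------------------------------------------------------------------- #


@dataclass
class CalibrationConstraint:
    """Hard uniform bound on a clade MRCA age or a fossil tip age.

    ``kind`` is ``"mrca"`` (bound the MRCA age of ``taxa``) or ``"tip"``
    (bound the age of a single, typically fossil, tip). Bounds are in years
    BP; use :func:`ce_to_bp` for calendar dates.
    """

    kind: str
    taxa: tuple[str, ...]
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.kind not in ("mrca", "tip"):
            raise ParameterError("calibration kind must be 'mrca' or 'tip'")
        self.taxa = tuple(self.taxa)
        if self.kind == "tip" and len(self.taxa) != 1:
            raise ParameterError("tip calibration takes exactly one taxon")
        if not self.taxa:
            raise ParameterError("calibration needs at least one taxon")
        if self.lower < 0 or self.upper < 0:
            raise ParameterError("calibration bounds must be >= 0 (years BP)")
        if not self.lower < self.upper:
            raise ParameterError("calibration lower bound must be < upper bound")

    def satisfied_age(self, t: TimeTree) -> float:
        if self.kind == "tip":
            return t.find_tip(self.taxa[0]).age
        return t.mrca(self.taxa).age


def calibration_log_prior(
    t: TimeTree, constraints: Sequence[CalibrationConstraint]
) -> float:
    """0 when every constrained age lies inside its [lower, upper] bound,
    -inf otherwise (uniform hard bounds)."""
    for c in constraints:
        for lab in c.taxa:
            t.find_tip(lab)  # raises MissingReferenceError for unknown taxa
        age = c.satisfied_age(t)
        if not (c.lower <= age <= c.upper):
            return -np.inf
    return 0.0
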