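"""Binary covarion substitution model and clock (branch-rate) models.

The covarion process has four hidden states: {absent, present} visible
states crossed with {fast, slow} rate categories. Within a category the
visible state flips at rates proportional to the stationary visible
frequencies — at relative rate 1 in the fast category and ``alpha`` (<= 1)
in the slow one — while the hidden category toggles at a symmetric switch
rate ``s`` without changing the visible state. The generator is scaled so
that one unit of (branch length x clock rate) equals one expected *visible*
substitution at stationarity, which keeps clock rates interpretable and node
ages identifiable.

State order everywhere: 0=(absent,fast), 1=(present,fast), 2=(absent,slow),
3=(present,slow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import ParameterError
from .trees import Node, TimeTree

STATE_ABSENT = (0, 2)
STATE_PRESENT = (1, 3)


@dataclass
class CovarionModel:
    """Parameters of the binary covarion process.

    Parameters
    ----------
    pi_present:
        Stationary frequency of the visible "present" state (0 < pi < 1).
    alpha:
        Slow/fast rate ratio in (0, 1]; alpha = 1 removes rate variation.
    switch_rate:
        Rate of toggling between hidden fast and slow categories (>= 0), in
        the same normalised time units as the substitution process.
    overall_rate:
        Expected visible substitutions per unit time at stationarity
        (clock units fold in separately via the branch rates).
    """

    pi_present: float = 0.5
    alpha: float = 0.5
    switch_rate: float = 0.5
    overall_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.pi_present < 1:
            raise ParameterError("pi_present must lie strictly between 0 and 1")
        if not 0 < self.alpha <= 1:
            raise ParameterError("alpha must lie in (0, 1]")
        if self.switch_rate < 0:
            raise ParameterError("switch_rate must be >= 0")
        if not self.overall_rate >= 0:
            raise ParameterError("overall_rate must be >= 0")

    @property
    def pi_absent(self) -> float:
        return 1.0 - self.pi_present

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution over the 4 hidden states
        (hidden categories equally frequent)."""
        pa, pp = self.pi_absent, self.pi_present
        return np.array([pa / 2, pp / 2, pa / 2, pp / 2])

    def to_dict(self) -> dict:
        return {
            "pi_present": self.pi_present,
            "alpha": self.alpha,
            "switch_rate": self.switch_rate,
            "overall_rate": self.overall_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovarionModel":
        return cls(**d)


def covarion_generator(model: CovarionModel) -> np.ndarray:
    """4x4 rate matrix of the covarion process.

    Rows sum to zero; the matrix is scaled so the expected visible
    substitution rate at stationarity equals ``model.overall_rate``. With
    ``switch_rate = 0`` the fast and slow blocks decouple; with
    ``alpha = 1`` the visible process is a plain two-state CTMC.
    """
    pa, pp = model.pi_absent, model.pi_present
    a, s = model.alpha, model.switch_rate
    Q = np.array(
        [
            [0.0, pp, s, 0.0],
            [pa, 0.0, 0.0, s],
            [s, 0.0, 0.0, a * pp],
            [0.0, s, a * pa, 0.0],
        ]
    )
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # expected visible substitutions per unit time at stationarity
    visible_rate = pa * pp * (1.0 + a)
    return Q * (model.overall_rate / visible_rate)


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t): the stochastic transition matrix over a duration t >= 0."""
    if t < 0:
        raise ParameterError("duration must be >= 0")
    P = scipy.linalg.expm(Q * t)
    return np.clip(P, 0.0, 1.0)


class GeneratorPropagator:
    """Eigendecomposition of a generator for fast P(t) over many durations.

    Diagonalises Q once so transition matrices over an array of branch
    durations come from a single einsum instead of repeated expm calls.
    """

    def __init__(self, Q: np.ndarray) -> None:
        w, V = np.linalg.eig(Q)
        self.w = w
        self.V = V
        self.Vinv = np.linalg.inv(V)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """P matrices for an array of durations; output shape t.shape + (4, 4)."""
        t = np.asarray(t, dtype=float)
        ewt = np.exp(np.multiply.outer(t, self.w))
        P = np.einsum("ij,...j,jk->...ik", self.V, ewt, self.Vinv)
        return np.clip(P.real, 0.0, None)


def two_state_transition(pi_present: float, rate: float, t: float) -> np.ndarray:
    """Closed-form 2x2 transition matrix of the plain binary CTMC.

    The generator is q(absent->present) = pi_present * c and
    q(present->absent) = pi_absent * c with c chosen so the expected
    substitution rate at stationarity is ``rate``; then
    P(t) = Pi + (I - Pi) * exp(-c t).
    """
    pa = 1.0 - pi_present
    c = rate / (2.0 * pa * pi_present)
    pi = np.array([[pa, pi_present], [pa, pi_present]])
    decay = np.exp(-c * t)
    return pi + (np.eye(2) - pi) * decay


# ---------------------------------------------------------------------- #
# Clock models
# ---------------------------------------------------------------------- #


@dataclass
class ClockModel:
    """Strict or relaxed-lognormal clock.

    Under the strict clock all branches share ``mean_rate`` (expected
    substitutions per year). The relaxed clock multiplies ``mean_rate`` by
    i.i.d. per-branch lognormal factors with mean 1 and log-sd
    ``stdev_log``; ``stdev_log = 0`` recovers the strict clock.
    """

    kind: str = "strict"
    mean_rate: float = 1.0
    stdev_log: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("strict", "relaxed"):
            raise ParameterError("clock kind must be 'strict' or 'relaxed'")
        if not self.mean_rate > 0:
            raise ParameterError("mean_rate must be > 0")
        if self.stdev_log < 0:
            raise ParameterError("stdev_log must be >= 0")

    def multiplier_log_prior(self, multipliers: np.ndarray) -> float:
        """Log density of per-branch mean-one lognormal multipliers."""
        if self.kind == "strict" or self.stdev_log == 0:
            return 0.0
        s = self.stdev_log
        x = np.asarray(multipliers)
        if np.any(x <= 0):
            return -np.inf
        mu = -0.5 * s * s
        logx = np.log(x)
        return float(
            np.sum(
                -logx
                - np.log(s)
                - 0.5 * np.log(2 * np.pi)
                - (logx - mu) ** 2 / (2 * s * s)
            )
        )

    def to_dict(self) -> dict:
        return {"kind": self.kind, "mean_rate": self.mean_rate, "stdev_log": self.stdev_log}

    @classmethod
    def from_dict(cls, d: dict) -> "ClockModel":
        return cls(**d)


def draw_branch_rates(
    clock: ClockModel, tree: TimeTree, seed: int
) -> dict[int, float]:
    """Per-branch rates keyed by ``id(node)`` for every non-root node.

    Strict clock: every branch gets ``mean_rate``. Relaxed: mean_rate times
    a mean-one lognormal multiplier, drawn in preorder so the result is
    reproducible under the seed.
    """
    rng = np.random.default_rng(seed)
    nodes = [n for n in tree.preorder() if n.parent is not None]
    if clock.kind == "strict" or clock.stdev_log == 0:
        return {id(n): clock.mean_rate for n in nodes}
    s = clock.stdev_log
    mult = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=len(nodes))
    return {id(n): clock.mean_rate * m for n, m in zip(nodes, mult)}
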