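"""Individual vaccination decision dynamics on a contact network.

Each individual ``i`` holds a binary decision ``d_i``: +1 accepts
vaccination, -1 rejects it.  Every iteration each individual forms

1. a **cost-minimized choice**: the perceived infection risk
   ``lambda_i = beta_perc * (unvaccinated neighbors) / (all neighbors)`` is
   compared against the cost ratio ``r = c_vac / c_inf``.  Vaccination is
   the cheaper option when ``lambda_i > r``; at an exact tie the previous
   decision is kept (so an individual surrounded entirely by vaccinated
   neighbors free-rides on herd immunity even at zero vaccine cost);

2. a **social opinion** via social impact theory: each camp's influence
   strength grows with the number of neighbors holding that opinion (at a
   diminishing square-root rate) and with the closeness (edge weight) of
   those neighbors.  The normalized discrepancy between the two strengths
   is pushed through a Fermi function with responsiveness ``kappa`` to give
   the probability that the social opinion is acceptance;

3. a **final decision**: with probability ``p`` (the conformity rate) the
   individual adopts the social opinion, otherwise the cost-minimized
   choice.  ``p = 0`` is a pure cost-based decider, ``p = 1`` an absolute
   social follower.

At ``p = 0`` the dynamics terminate early at a Nash fixed point (no node
changes over a full update); the synchronous scheme can additionally land
on a 2-cycle, reported with cycle-averaged coverage.  Otherwise the chain
runs a fixed horizon and coverage is averaged over a trailing window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numba
import numpy as np
import scipy.sparse as sp

from .network import ContactNetwork

__all__ = [
    "DecisionParams",
    "DecisionState",
    "SteadyStateResult",
    "initialize_decisions",
    "perceived_risk",
    "cost_minimized_choice",
    "influence_strengths",
    "normalized_discrepancy",
    "opinion_probability",
    "final_decision",
    "step",
    "run",
    "coverage",
]

ACCEPT = 1
REJECT = -1


@dataclass(frozen=True)
class DecisionParams:
    """Parameters of the decision model.

    Attributes
    ----------
    r : float
        Cost ratio ``c_vac / c_inf`` (>= 0).  The decision threshold
        against the perceived infection risk.
    p : float
        Conformity rate in [0, 1]: probability of adopting the social
        opinion instead of the cost-minimized choice.
    beta_perc : float
        Perceived disease transmission rate in [0, 1].  By default equal
        to the actual transmission rate ``R0 * gamma`` of the epidemic
        module (1.4 * 0.312 = 0.4368).
    kappa : float
        Fermi responsiveness (> 0); smaller values make the dominant
        opinion win more sharply.
    w0 : float
        Initial vaccination willingness: each individual independently
        starts as an acceptor with this probability.
    sit_exponent : float
        Exponent on the source count in the influence strength,
        ``I = (sum of weights) / n**(1 - exponent)`` with the classic
        social-impact value 0.5; 1.0 gives plain weighted sums.
    max_iters, window : int
        Horizon and trailing averaging window for ``p > 0`` runs.
    update_scheme : str
        ``"asynchronous"`` (default): each iteration updates every node
        once in a random order, in place, so neighbors see fresh
        decisions; ``"synchronous"``: all nodes update from the previous
        state at once.  Synchronous pure-cost dynamics can lock into
        global parity 2-cycles (everyone vaccinates, then nobody does),
        an update-artifact that distorts steady-state coverage, hence the
        asynchronous default.
    """

    r: float = 0.5
    p: float = 0.0
    beta_perc: float = 0.4368
    kappa: float = 0.1
    w0: float = 0.5
    sit_exponent: float = 0.5
    max_iters: int = 200
    window: int = 50
    update_scheme: Literal["synchronous", "asynchronous"] = "asynchronous"

    def __post_init__(self):
        if self.r < 0:
            raise ValueError("cost ratio r must be >= 0")
        if not 0 <= self.p <= 1:
            raise ValueError("conformity rate p must lie in [0, 1]")
        if not 0 <= self.beta_perc <= 1:
            raise ValueError("beta_perc must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0 <= self.w0 <= 1:
            raise ValueError("w0 must lie in [0, 1]")
        if self.window > self.max_iters:
            raise ValueError("window must not exceed max_iters")


@dataclass
class DecisionState:
    """Per-node decisions (+1 accept / -1 reject) at an iteration."""

    decisions: np.ndarray
    iteration: int = 0

    def __post_init__(self):
        self.decisions = np.asarray(self.decisions, dtype=np.int8)
        if not np.all(np.isin(self.decisions, (ACCEPT, REJECT))):
            raise ValueError("decisions must be +1 or -1")

    def copy(self) -> "DecisionState":
        return DecisionState(self.decisions.copy(), self.iteration)


@dataclass
class SteadyStateResult:
    """Outcome of iterating the decision dynamics.

    ``coverage`` is the fraction of acceptors at termination; for
    stochastic runs (p > 0) it is the mean over the trailing window, and
    for a 2-cycle the average over the two alternating states.
    """

    coverage: float
    trajectory: np.ndarray
    converged: bool
    termination_reason: Literal["fixed_point", "two_cycle", "max_iters"]
    final_state: DecisionState


def initialize_decisions(
    net: ContactNetwork, w0: float, rng: np.random.Generator
) -> DecisionState:
    """Independent Bernoulli(w0) acceptance per node."""
    if not 0 <= w0 <= 1:
        raise ValueError("w0 must lie in [0, 1]")
    accept = rng.random(net.n_nodes) < w0
    return DecisionState(np.where(accept, ACCEPT, REJECT))


def perceived_risk(
    node: int, state: DecisionState, net: ContactNetwork, beta_perc: float
) -> float:
    """``lambda_i``: perceived transmission rate scaled by the unweighted
    fraction of unvaccinated neighbors; 0 for an isolated node."""
    nbrs = [v for v, _ in net.neighbors(node)]
    if not nbrs:
        return 0.0
    unvac = sum(1 for v in nbrs if state.decisions[v] == REJECT)
    return beta_perc * unvac / len(nbrs)


def cost_minimized_choice(lambda_i: float, r: float, previous: int) -> int:
    """Threshold rule: accept iff risk exceeds cost ratio, keep the
    previous decision at an exact tie."""
    if lambda_i > r:
        return ACCEPT
    if lambda_i < r:
        return REJECT
    return previous


def influence_strengths(
    node: int,
    state: DecisionState,
    net: ContactNetwork,
    sit_exponent: float = 0.5,
) -> tuple[float, float]:
    """Social-impact strengths ``(I_plus, I_minus)`` of the two camps.

    For a camp with ``n`` neighbor sources of total closeness ``W``,
    ``I = W / n**(1 - sit_exponent)`` — with the default exponent 0.5 this
    is ``sqrt(n)`` times the camp's mean closeness, so impact grows with
    the number of sources at a diminishing rate.
    """
    strengths = {ACCEPT: 0.0, REJECT: 0.0}
    counts = {ACCEPT: 0, REJECT: 0}
    for v, w in net.neighbors(node):
        o = int(state.decisions[v])
        strengths[o] += w
        counts[o] += 1
    out = []
    for o in (ACCEPT, REJECT):
        n = counts[o]
        out.append(strengths[o] / n ** (1.0 - sit_exponent) if n else 0.0)
    return out[0], out[1]


def normalized_discrepancy(i_plus: float, i_minus: float) -> float:
    """Relative influence discrepancy in [-1, 1]; 0 when both camps are
    absent (scale-free in the weights, so ``kappa`` is comparable across
    networks)."""
    total = i_plus + i_minus
    if total <= 0:
        return 0.0
    return (i_plus - i_minus) / total


def opinion_probability(delta: float, kappa: float) -> float:
    """Fermi function: probability the social opinion is acceptance."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    with np.errstate(over="ignore"):  # exp overflow saturates to the limit
        return float(1.0 / (1.0 + np.exp(-delta / kappa)))


def final_decision(
    cost_choice: int, social_opinion: int, p: float, rng: np.random.Generator
) -> int:
    """Conformity mixing: social opinion with probability ``p``, else the
    cost-minimized choice."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p > 0 and rng.random() < p:
        return social_opinion
    return cost_choice


class _Workspace:
    """Precomputed sparse structure for vectorized updates; reusable
    across runs on the same network."""

    def __init__(self, net: ContactNetwork):
        self.binary, self.weighted = net.adjacency()
        self.degree = np.asarray(self.binary.sum(axis=1)).ravel()
        self.isolated = self.degree == 0

    def node_fields(self, decisions: np.ndarray, p: DecisionParams):
        """Per-node (lambda, I_plus, I_minus) from the current decisions,
        all vectorized."""
        vac = (decisions == ACCEPT).astype(float)
        n_vac = self.binary @ vac
        n_unvac = self.degree - n_vac
        with np.errstate(invalid="ignore", divide="ignore"):
            lam = np.where(
                self.degree > 0, p.beta_perc * n_unvac / self.degree, 0.0
            )
        w_plus = self.weighted @ vac
        w_minus = self.weighted @ (1.0 - vac)
        e = 1.0 - p.sit_exponent
        with np.errstate(invalid="ignore", divide="ignore"):
            i_plus = np.where(n_vac > 0, w_plus / n_vac**e, 0.0)
            i_minus = np.where(n_unvac > 0, w_minus / n_unvac**e, 0.0)
        return lam, i_plus, i_minus

    def cost_choice(
        self, lam: np.ndarray, previous: np.ndarray, p: DecisionParams
    ) -> np.ndarray:
        r = p.r
        return np.where(lam > r, ACCEPT, np.where(lam < r, REJECT, previous)).astype(
            np.int8
        )

    def social_opinion(
        self,
        i_plus: np.ndarray,
        i_minus: np.ndarray,
        p: DecisionParams,
        rng: np.random.Generator,
    ) -> np.ndarray:
        total = i_plus + i_minus
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = np.where(total > 0, (i_plus - i_minus) / total, 0.0)
        with np.errstate(over="ignore"):
            q_plus = 1.0 / (1.0 + np.exp(-delta / p.kappa))
        draw = rng.random(delta.shape[0])
        return np.where(draw < q_plus, ACCEPT, REJECT).astype(np.int8)


def _step_impl(
    state: DecisionState,
    ws: _Workspace,
    params: DecisionParams,
    rng: np.random.Generator,
) -> DecisionState:
    """One synchronous update: every node's fields are computed from the
    incoming state, then all decisions replaced at once.

    RNG consumption order is fixed and documented: (1) one uniform per node
    for the social-opinion draw, (2) one uniform per node for the
    conformity draw — both skipped entirely when p = 0, which makes pure
    cost dynamics deterministic given the initial state.
    """
    p = params
    d = state.decisions
    lam, i_plus, i_minus = ws.node_fields(d, p)
    cost = ws.cost_choice(lam, d, p)
    if p.p == 0:
        new = cost
    else:
        social = ws.social_opinion(i_plus, i_minus, p, rng)
        conform = rng.random(d.shape[0]) < p.p
        # isolated nodes have no opinion sources: keep the cost choice
        conform &= ~ws.isolated
        new = np.where(conform, social, cost).astype(np.int8)
    return DecisionState(new, state.iteration + 1)


@numba.njit(cache=False)
def _async_sweep_kernel(
    decisions, indptr, indices, weights, r, p, beta, kappa, e, order,
    u_opinion, u_conform,
):  # pragma: no cover - exercised through _step_async
    for idx in range(order.shape[0]):
        i = order[idx]
        start, end = indptr[i], indptr[i + 1]
        deg = end - start
        n_vac = 0
        w_vac = 0.0
        w_unvac = 0.0
        for k in range(start, end):
            if decisions[indices[k]] == 1:
                n_vac += 1
                w_vac += weights[k]
            else:
                w_unvac += weights[k]
        lam = beta * (deg - n_vac) / deg if deg > 0 else 0.0
        if lam > r:
            choice = 1
        elif lam < r:
            choice = -1
        else:
            choice = decisions[i]
        if p > 0.0 and deg > 0:
            n_unvac = deg - n_vac
            i_plus = w_vac / n_vac**e if n_vac > 0 else 0.0
            i_minus = w_unvac / n_unvac**e if n_unvac > 0 else 0.0
            total = i_plus + i_minus
            delta = (i_plus - i_minus) / total if total > 0 else 0.0
            q_plus = 1.0 / (1.0 + math.exp(-delta / kappa))
            if u_conform[idx] < p:
                choice = 1 if u_opinion[idx] < q_plus else -1
        decisions[i] = choice


def _step_async(
    state: DecisionState,
    ws: _Workspace,
    params: DecisionParams,
    rng: np.random.Generator,
) -> DecisionState:
    """Asynchronous sweep: every node updated once, in a random order,
    each seeing the freshest decisions of its neighbors.

    RNG consumption per sweep, in fixed order: the node permutation, then
    (only when p > 0) one uniform per node for the social-opinion draw and
    one for the conformity draw.
    """
    p = params
    d = state.decisions.copy()
    n = d.shape[0]
    order = rng.permutation(n)
    if p.p > 0:
        u_opinion = rng.random(n)
        u_conform = rng.random(n)
    else:
        u_opinion = u_conform = np.empty(0)
    _async_sweep_kernel(
        d, ws.binary.indptr, ws.binary.indices, ws.weighted.data,
        p.r, p.p, p.beta_perc, p.kappa, 1.0 - p.sit_exponent,
        order, u_opinion, u_conform,
    )
    return DecisionState(d, state.iteration + 1)


def step(
    state: DecisionState,
    net: ContactNetwork,
    params: DecisionParams,
    rng: np.random.Generator,
) -> DecisionState:
    """Advance the decision dynamics by one iteration."""
    ws = _Workspace(net)
    impl = _step_impl if params.update_scheme == "synchronous" else _step_async
    return impl(state, ws, params, rng)


def coverage(state: DecisionState) -> float:
    """Fraction of nodes currently accepting vaccination."""
    return float(np.mean(state.decisions == ACCEPT))


def run(
    net: ContactNetwork,
    params: DecisionParams,
    rng: np.random.Generator,
    initial: DecisionState | None = None,
    workspace: _Workspace | None = None,
) -> SteadyStateResult:
    """Iterate to a steady state.

    At ``p = 0`` iteration stops early at a Nash fixed point (a full
    update that changes no decision); the synchronous scheme additionally
    detects 2-cycles, whose coverage is averaged over the cycle.
    Otherwise the chain runs ``max_iters`` steps and coverage is the mean
    over the final ``window`` iterations.
    """
    ws = workspace if workspace is not None else _Workspace(net)
    impl = _step_impl if params.update_scheme == "synchronous" else _step_async
    state = (
        initial.copy()
        if initial is not None
        else initialize_decisions(net, params.w0, rng)
    )
    traj = [coverage(state)]
    deterministic = params.p == 0 and params.update_scheme == "synchronous"
    prev = prev2 = None
    reason: str = "max_iters"
    for _ in range(params.max_iters):
        prev2, prev = prev, state
        state = impl(state, ws, params, rng)
        traj.append(coverage(state))
        if params.p == 0:
            # an unchanged full update is a Nash fixed point in any scheme
            if np.array_equal(state.decisions, prev.decisions):
                reason = "fixed_point"
                break
            if (
                deterministic
                and prev2 is not None
                and np.array_equal(state.decisions, prev2.decisions)
            ):
                reason = "two_cycle"
                break
    trajectory = np.asarray(traj)
    if reason == "fixed_point":
        cov = trajectory[-1]
    elif reason == "two_cycle":
        cov = float(trajectory[-2:].mean())
    elif deterministic:
        cov = trajectory[-1]  # hit the horizon without settling
    else:
        cov = float(trajectory[-params.window :].mean())
    converged = reason != "max_iters" if params.p == 0 else True
    return SteadyStateResult(
        coverage=float(cov),
        trajectory=trajectory,
        converged=converged,
        termination_reason=reason,  # type: ignore[arg-type]
        final_state=state,
    )
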