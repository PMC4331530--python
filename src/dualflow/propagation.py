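"""Dual-flow network propagation: operator, priors, steady state, ranking.

Propagation iterates

    F(t+1) = (1 - alpha) * W @ F(t) + alpha * Y,    F(1) = Y

where Y is a signed prior flow vector (positive on known disease genes,
negative on non-disease essential genes) and W is a degree-normalized
adjacency operator.  The fixed point has the closed form

    F(inf) = alpha * (I - (1 - alpha) * W)^-1 @ Y

which is always solvable for alpha in (0, 1] because the operator norm of
(1 - alpha) * W is at most 1 - alpha < 1 under every supported
normalization (and alpha = 1 gives F = Y outright).

Three normalizations are supported:

``pump``
    Each node distributes its current flow equally to its neighbours: the
    flow sent from x to y is F(x) * A(x, y) / k(x).  As a matrix acting on
    column vectors this is A @ D^-1 (column-stochastic on non-isolated
    nodes), so total flow is conserved on graphs without isolated nodes.
``average``
    The new value at x is the mean of its neighbours' values, D^-1 @ A.
``symmetric``
    D^-1/2 @ A @ D^-1/2, the symmetric normalization common in the
    network-propagation literature.

Degree-zero nodes have all-zero operator rows and columns: they pump
nothing, and retain only the alpha * Y injection at steady state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network_model import AnnotatedNetwork, ConfigurationError

__all__ = [
    "PropagationConfig",
    "PriorVector",
    "PropagationResult",
    "ConvergenceError",
    "build_operator",
    "propagate",
    "build_prior",
    "similarity_matrix",
    "score_candidates",
    "rank_scores",
]

Normalization = Literal["pump", "average", "symmetric"]
PriorMode = Literal["normalized", "unit"]

#: node count above which the automatic solver switches from sparse direct
#: factorization to fixed-point iteration
_DIRECT_SOLVE_LIMIT = 20_000


class ConvergenceError(RuntimeError):
    """Iterative solver failed to reach tolerance within max_iterations."""


@dataclass(frozen=True)
class PropagationConfig:
    """Solver and model settings for one propagation run.

    alpha is the restart fraction in (0, 1]: the weight of the prior versus
    the network term at each step.  The originating study does not state the
    value it used; 0.5 is this package's default and should be treated as a
    free parameter.
    """

    alpha: float = 0.5
    solver: Literal["iterative", "direct", "auto"] = "auto"
    tolerance: float = 1e-8
    max_iterations: int = 10_000
    normalization: Normalization = "pump"
    prior_mode: PriorMode = "normalized"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.normalization not in ("pump", "average", "symmetric"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.solver not in ("iterative", "direct", "auto"):
            raise ConfigurationError(f"unknown solver {self.solver!r}")
        if self.prior_mode not in ("normalized", "unit"):
            raise ConfigurationError(f"unknown prior_mode {self.prior_mode!r}")
        if self.solver != "direct" and not self.tolerance > 0:
            raise ConfigurationError("tolerance must be > 0 for the iterative solver")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be positive")


@dataclass(frozen=True)
class PriorVector:
    """Signed prior flow Y over network nodes, with its generating gene sets."""

    values: np.ndarray
    positive_set: frozenset[str]
    negative_set: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class PropagationResult:
    """Steady-state flow plus solver diagnostics."""

    flow: np.ndarray
    iterations_used: int
    residual: float
    config: PropagationConfig

    def as_dict(self, net: AnnotatedNetwork) -> dict[str, float]:
        return {g: float(v) for g, v in zip(net.nodes, self.flow)}


def build_operator(net: AnnotatedNetwork, normalization: Normalization = "pump") -> sp.csr_array:
    """Degree-normalized propagation operator W acting on column flow vectors."""
    if net.n_nodes == 0:
        raise ValueError("cannot build an operator for an empty network")
    a = sp.csr_array(net.adjacency, dtype=float)
    k = net.degrees.astype(float)
    with np.errstate(divide="ignore"):
        inv = np.where(k > 0, 1.0 / k, 0.0)
        inv_sqrt = np.where(k > 0, 1.0 / np.sqrt(k), 0.0)
    if normalization == "pump":
        # column y of A scaled by 1/k(y): new F(x) = sum_y A(x,y) F(y) / k(y)
        w = a @ sp.diags_array(inv)
    elif normalization == "average":
        w = sp.diags_array(inv) @ a
    elif normalization == "symmetric":
        w = sp.diags_array(inv_sqrt) @ a @ sp.diags_array(inv_sqrt)
    else:  # pragma: no cover - guarded by PropagationConfig
        raise ConfigurationError(f"unknown normalization {normalization!r}")
    return sp.csr_array(w)


def _prior_to_array(net: AnnotatedNetwork, prior: PriorVector | np.ndarray) -> np.ndarray:
    if isinstance(prior, PriorVector):
        y = prior.values
    else:
        y = np.asarray(prior, dtype=float)
    if y.shape != (net.n_nodes,):
        raise ValueError(f"prior has shape {y.shape}, expected ({net.n_nodes},)")
    return y


def propagate(
    net: AnnotatedNetwork,
    prior: PriorVector | np.ndarray,
    config: PropagationConfig = PropagationConfig(),
) -> PropagationResult:
    """Steady-state flow for a prior vector.

    The ``direct`` solver factorizes (I - (1-alpha) W); the ``iterative``
    solver runs the fixed-point update from F(1) = Y until the L1 change
    between successive iterates drops below ``config.tolerance``.  ``auto``
    picks direct for networks up to 20k nodes.
    """
    y = _prior_to_array(net, prior)
    alpha = config.alpha
    if alpha == 1.0:
        return PropagationResult(flow=y.copy(), iterations_used=0, residual=0.0, config=config)
    w = build_operator(net, config.normalization)
    solver = config.solver
    if solver == "auto":
        solver = "direct" if net.n_nodes <= _DIRECT_SOLVE_LIMIT else "iterative"
    if solver == "direct":
        system = sp.eye_array(net.n_nodes, format="csc") - (1.0 - alpha) * w
        flow = spla.spsolve(sp.csc_array(system), alpha * y)
        flow = np.atleast_1d(np.asarray(flow, dtype=float))
        residual = float(np.abs(flow - ((1 - alpha) * (w @ flow) + alpha * y)).sum())
        return PropagationResult(flow=flow, iterations_used=0, residual=residual, config=config)
    f = y.copy()
    for it in range(1, config.max_iterations + 1):
        f_next = (1.0 - alpha) * (w @ f) + alpha * y
        change = float(np.abs(f_next - f).sum())
        f = f_next
        if change <= config.tolerance:
            return PropagationResult(flow=f, iterations_used=it, residual=change, config=config)
    raise ConvergenceError(
        f"no convergence after {config.max_iterations} iterations (residual {change:.3e})"
    )


def build_prior(
    net: AnnotatedNetwork,
    mode: str,
    T_h: Iterable[str] = (),
    E_minus: Iterable[str] = (),
    prior_mode: PriorMode = "normalized",
) -> PriorVector:
    """Signed prior Y for one of the three strategies.

    ``np_d``  — positive flow on the disease training genes T_h only.
    ``np_e``  — negative flow on the non-disease essential genes E- only.
    ``np_de`` — both, the dual-flow prior.

    In ``normalized`` mode each on-network positive gene receives
    +1/|T_h ∩ V| and each negative gene -1/|E- ∩ V|, so positive and
    negative flow each total one unit.  In ``unit`` mode every gene gets a
    literal +1 or -1.  Genes supplied on both sides keep the positive
    assignment (with a warning); off-network genes are ignored with a
    warning.
    """
    key = mode.lower().replace("&", "").replace("np_de", "np_de")
    if key in ("np_d&e", "np_de", "npde"):
        key = "np_de"
    if key not in ("np_d", "np_e", "np_de"):
        raise ConfigurationError(f"unknown prioritization mode {mode!r}")
    pos = frozenset(T_h) if key in ("np_d", "np_de") else frozenset()
    neg = frozenset(E_minus) if key in ("np_e", "np_de") else frozenset()
    overlap = pos & neg
    if overlap:
        warnings.warn(
            f"{len(overlap)} gene(s) in both the positive and negative sets; "
            "positive assignment wins",
            stacklevel=2,
        )
        neg = neg - overlap
    pos_on = [g for g in pos if g in net]
    neg_on = [g for g in neg if g in net]
    if (pos - set(pos_on)) or (neg - set(neg_on)):
        n_off = len(pos - set(pos_on)) + len(neg - set(neg_on))
        warnings.warn(f"{n_off} prior gene(s) absent from the network; ignored", stacklevel=2)
    if key in ("np_d", "np_de") and not pos_on:
        raise ConfigurationError(f"mode {mode!r} requires disease training genes on the network")
    if key in ("np_e", "np_de") and not neg_on:
        raise ConfigurationError(f"mode {mode!r} requires essential (E-) genes on the network")
    y = np.zeros(net.n_nodes)
    idx = net.node_index
    pos_w = 1.0 / len(pos_on) if (prior_mode == "normalized" and pos_on) else 1.0
    neg_w = 1.0 / len(neg_on) if (prior_mode == "normalized" and neg_on) else 1.0
    for g in pos_on:
        y[idx[g]] = pos_w
    for g in neg_on:
        y[idx[g]] = -neg_w
    return PriorVector(values=y, positive_set=pos, negative_set=neg)


def similarity_matrix(
    net: AnnotatedNetwork, config: PropagationConfig = PropagationConfig()
) -> np.ndarray:
    """Dense similarity matrix S = alpha (I - (1-alpha) W)^-1.

    Column y is the steady-state flow from one unit injected at y.  Intended
    for small networks; the memory cost is |V|^2.
    """
    n = net.n_nodes
    if n > 5000:
        raise ValueError("similarity_matrix is dense; refuse networks above 5000 nodes")
    if config.alpha == 1.0:
        return np.eye(n)
    w = build_operator(net, config.normalization).toarray()
    return config.alpha * np.linalg.inv(np.eye(n) - (1.0 - config.alpha) * w)


def rank_scores(
    candidates: Sequence[str], scores: dict[str, float]
) -> list[tuple[str, float, int]]:
    """1-based descending ranks over a candidate list, ties ranked last.

    Every member of a tie group receives the group's worst rank (a gene's
    rank is the number of candidates scoring at least as high as it).
    Candidates absent from ``scores`` sit below every scored candidate and
    share the overall worst rank; their reported score is NaN.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    key = {g: scores.get(g, -math.inf) for g in candidates}
    vals = np.array([key[g] for g in candidates])
    out = []
    for g in candidates:
        s = key[g]
        rank = int(np.sum(vals > s) + np.sum(vals == s))
        out.append((g, float(s) if math.isfinite(s) else math.nan, rank))
    out.sort(key=lambda t: (t[2], t[0]))
    return out


def score_candidates(
    net: AnnotatedNetwork,
    mode: str,
    T_h: Iterable[str],
    E_minus: Iterable[str],
    config: PropagationConfig = PropagationConfig(),
    candidates: Sequence[str] | None = None,
) -> list[tuple[str, float, int]]:
    """Rank candidate genes by steady-state net flow under a strategy.

    Returns (gene, score, rank) sorted by rank; ``candidates`` defaults to
    every network node outside the training set.
    """
    prior = build_prior(net, mode, T_h=T_h, E_minus=E_minus, prior_mode=config.prior_mode)
    result = propagate(net, prior, config)
    if candidates is None:
        candidates = [g for g in net.nodes if g not in prior.positive_set]
    scores = {g: float(result.flow[net.node_index[g]]) for g in candidates if g in net}
    return rank_scores(list(candidates), scores)
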