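"""Discrete belief-propagation primitives.

This module implements the message algebra used by every node of the
hierarchical network: exact Pearl-style operations on discrete
distributions (the oracle path, valid on singly-connected networks) and
the three approximations that make loopy propagation tractable at scale:

1. probability flooring, so that products of many bottom-up messages
   stay inside the floating-point range;
2. replacing outgoing top-down messages with the node belief;
3. variance-based sampling of incoming messages and of the states within
   each message.

Multi-parent interactions use an independence-of-causal-influences
style weighted sum of per-parent conditional tables, so the parameter
count grows linearly (not exponentially) with the number of parents.

Distributions are plain 1-D ``float64`` arrays over a node's K states;
conditional tables are ``(K_child, K_parent)`` arrays whose columns are
distributions over the child's states.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ApproximationConfig",
    "ConfigError",
    "StructuralError",
    "DegenerateEvidenceError",
    "normalize",
    "uniform",
    "validate_distribution",
    "validate_cpt",
    "floor_and_renormalize",
    "max_lambda_count",
    "select_top_variance",
    "combine_lambda",
    "lambda_to_parent",
    "combine_pi",
    "belief",
    "pi_to_child",
    "pi_to_child_exact",
    "TreeNetwork",
    "enumerate_marginals",
    "exact_bp_marginals",
    "kl_divergence",
]


class ConfigError(ValueError):
    """Raised for internally inconsistent approximation parameters."""


class StructuralError(ValueError):
    """Raised when message/table shapes do not match the network structure."""


class DegenerateEvidenceError(ValueError):
    """Raised when contradictory evidence yields an all-zero product."""


@dataclass
class ApproximationConfig:
    """Knobs of the three belief-propagation approximations.

    Parameters
    ----------
    eps_min : float
        Probability floor applied to every message before multiplicative
        combination; must satisfy ``0 < eps_min < 1/K`` for every layer.
    r_max : float
        Numeric-range ceiling of the host float system. Together with
        ``eps_min`` it bounds how many floored messages may be multiplied
        before normalisation could overflow. ``math.inf`` disables the
        bound.
    m_pi : int
        Number of incoming top-down messages retained (highest variance
        first) when combining parent messages.
    m_states : int
        Number of states retained per selected top-down message (highest
        probability first).
    parent_weights_rule : str
        Rule for the per-parent weights of the weighted-sum CPT
        combination; only ``"uniform"`` (w_k = 1/P) is implemented.
    """

    eps_min: float = 1e-12
    r_max: float = float(np.finfo(np.float64).max)
    m_pi: int = 16
    m_states: int = 10
    parent_weights_rule: str = "uniform"

    def __post_init__(self) -> None:
        if not (0.0 < self.eps_min < 1.0):
            raise ConfigError(f"eps_min must lie in (0, 1); got {self.eps_min}")
        if self.r_max <= 1.0:
            raise ConfigError(f"r_max must exceed 1; got {self.r_max}")
        if self.m_pi < 1 or self.m_states < 1:
            raise ConfigError("m_pi and m_states must be >= 1")
        if self.parent_weights_rule != "uniform":
            raise ConfigError(
                f"unknown parent_weights_rule {self.parent_weights_rule!r}"
            )


#: A configuration under which every operation reduces to exact
#: belief propagation (no flooring beyond the denormal range, no
#: message or state sampling).
EXACT = ApproximationConfig(
    eps_min=5e-324, r_max=math.inf, m_pi=2**31, m_states=2**31
)


def normalize(d: np.ndarray) -> np.ndarray:
    """Sum-normalise a nonnegative vector; raise if it has no mass."""
    d = np.asarray(d, dtype=np.float64)
    s = d.sum()
    if s <= 0.0 or not np.isfinite(s):
        raise DegenerateEvidenceError(
            f"cannot normalise distribution with sum {s}"
        )
    return d / s


def uniform(k: int) -> np.ndarray:
    return np.full(k, 1.0 / k)


def validate_distribution(d: np.ndarray, *, normalized: bool = True,
                          atol: float = 1e-9) -> None:
    d = np.asarray(d)
    if d.ndim != 1:
        raise StructuralError(f"distribution must be 1-D, got shape {d.shape}")
    if np.any(d < 0):
        raise StructuralError("distribution has negative entries")
    if normalized and abs(d.sum() - 1.0) > atol:
        raise StructuralError(f"distribution sums to {d.sum()}, not 1")


def validate_cpt(cpt: np.ndarray, *, atol: float = 1e-9) -> None:
    cpt = np.asarray(cpt)
    if cpt.ndim != 2:
        raise StructuralError(f"CPT must be 2-D, got shape {cpt.shape}")
    if np.any(cpt < 0):
        raise StructuralError("CPT has negative entries")
    colsums = cpt.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=atol):
        raise StructuralError("CPT columns must each sum to 1")


# ---------------------------------------------------------------------------
# Approximation 1: flooring and the message-count bound
# ---------------------------------------------------------------------------

def floor_and_renormalize(d: np.ndarray, eps_min: float) -> np.ndarray:
    """Raise every entry of a normalised distribution to at least ``eps_min``.

    Entries below the floor are set to it and the added mass is removed
    proportionally from the remaining entries, so the result still sums
    to one. The shape of the distribution is essentially preserved since
    the raised mass is tiny in practice.
    """
    d = np.asarray(d, dtype=np.float64)
    k = d.shape[-1]
    if not (0.0 < eps_min < 1.0 / k):
        raise ConfigError(
            f"eps_min must lie in (0, 1/K) with K={k}; got {eps_min}"
        )
    below = d < eps_min
    if not below.any():
        return d.copy()
    out = d.copy()
    if d.ndim == 1:
        n_below = below.sum()
        rest = ~below
        rest_target = 1.0 - eps_min * n_below
        rest_sum = out[rest].sum()
        out[below] = eps_min
        out[rest] *= rest_target / rest_sum
        return out
    # batched rows (engine fast path)
    n_below = below.sum(axis=-1, keepdims=True)
    rest_sum = np.where(below, 0.0, out).sum(axis=-1, keepdims=True)
    scale = (1.0 - eps_min * n_below) / np.where(rest_sum > 0, rest_sum, 1.0)
    out = np.where(below, eps_min, out * scale)
    return out


def max_lambda_count(k_states: int, r_max: float, eps_min: float) -> float:
    """Largest count of floored messages that can be safely multiplied.

    After flooring, every message entry is at least ``eps_min``, so the
    normalisation constant of a product of N messages is bounded by
    ``eps_min**(-N)``; keeping that below ``r_max`` gives
    ``N_max = floor(log(r_max) / (-log(eps_min)))``.

    Returns ``math.inf`` when ``r_max`` is infinite (no ceiling).
    """
    if math.isinf(r_max):
        return math.inf
    if r_max <= 1.0:
        raise ConfigError(f"r_max must exceed 1; got {r_max}")
    if not (0.0 < eps_min < 1.0):
        raise ConfigError(f"eps_min must lie in (0, 1); got {eps_min}")
    return int(math.log(r_max) / (-math.log(eps_min)))


def _variances(messages: np.ndarray) -> np.ndarray:
    """Population variance of each row's entries."""
    return np.var(messages, axis=-1)


def select_top_variance(messages, n: int):
    """Indices of the ``n`` messages with highest entry variance.

    Ties break deterministically towards the lower index. Returns all
    indices (in variance order) when ``n`` exceeds the list length.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1; got {n}")
    msgs = [np.asarray(m, dtype=np.float64) for m in messages]
    if not msgs:
        return []
    var = np.array([np.var(m) for m in msgs])
    # stable sort on descending variance keeps ascending index on ties
    order = np.argsort(-var, kind="stable")
    return list(order[: min(n, len(msgs))])


def combine_lambda(child_messages, cfg: ApproximationConfig) -> np.ndarray:
    """Multiplicative combination of bottom-up messages (likelihood).

    Floors each message, keeps only the ``N_max`` highest-variance
    messages (``N_max`` from :func:`max_lambda_count`), multiplies them
    element-wise and renormalises. Identical to the exact product when
    the fan-in does not exceed ``N_max``.
    """
    msgs = [np.asarray(m, dtype=np.float64) for m in child_messages]
    if not msgs:
        raise StructuralError("combine_lambda requires at least one message")
    k = msgs[0].shape[0]
    if any(m.shape != (k,) for m in msgs):
        raise StructuralError("lambda messages must share a common length")
    msgs = [floor_and_renormalize(normalize(m), cfg.eps_min) for m in msgs]
    n_max = max_lambda_count(k, cfg.r_max, cfg.eps_min)
    if len(msgs) > n_max:
        keep = select_top_variance(msgs, int(n_max))
        msgs = [msgs[i] for i in sorted(keep)]
    out = np.ones(k)
    for i, m in enumerate(msgs):
        out *= m
        if (i + 1) % 16 == 0:  # guard against gradual underflow
            out = normalize(out)
    return normalize(out)


# ---------------------------------------------------------------------------
# Messages through conditional tables
# ---------------------------------------------------------------------------

def lambda_to_parent(lambda_x: np.ndarray, cpt: np.ndarray) -> np.ndarray:
    """Bottom-up message to one parent through that parent's table.

    ``out[p] = sum_x lambda(x) * P(x | u=p)``. The result is left
    unnormalised; the receiving node floors and normalises.
    """
    lambda_x = np.asarray(lambda_x, dtype=np.float64)
    cpt = np.asarray(cpt, dtype=np.float64)
    if cpt.ndim != 2 or lambda_x.shape[0] != cpt.shape[0]:
        raise StructuralError(
            f"lambda length {lambda_x.shape} does not match CPT {cpt.shape}"
        )
    return lambda_x @ cpt


def combine_pi(parent_messages, cpts, cfg: ApproximationConfig) -> np.ndarray:
    """Top-down prior of a node from its parents' messages.

    Weighted sum over per-parent tables (w_k = 1/P), with message and
    state sampling: only the ``m_pi`` highest-variance parent messages
    are used and, within each, only its ``m_states`` most probable
    states. Reduces to the exact single-parent product
    ``pi(x) = sum_q P(x|q) pi(q)`` when P = 1 and sampling is off.
    """
    msgs = [np.asarray(m, dtype=np.float64) for m in parent_messages]
    tables = [np.asarray(c, dtype=np.float64) for c in cpts]
    if len(msgs) != len(tables) or not msgs:
        raise StructuralError("need one CPT per parent message")
    k_child = tables[0].shape[0]
    for m, c in zip(msgs, tables):
        if c.shape[0] != k_child or c.shape[1] != m.shape[0]:
            raise StructuralError(
                f"CPT {c.shape} incompatible with child K={k_child} "
                f"and parent message length {m.shape[0]}"
            )
    p = len(msgs)
    w = 1.0 / p  # uniform parent weights
    keep = select_top_variance(msgs, min(cfg.m_pi, p))
    out = np.zeros(k_child)
    for i in keep:
        m, c = msgs[i], tables[i]
        kq = m.shape[0]
        if cfg.m_states < kq:
            # top-m_states entries, deterministic lowest-index tie-break
            q_idx = np.argsort(-m, kind="stable")[: cfg.m_states]
            out += w * (c[:, q_idx] @ m[q_idx])
        else:
            out += w * (c @ m)
    return normalize(out)


def belief(lambda_x: np.ndarray, pi_x: np.ndarray) -> np.ndarray:
    """Posterior of a node: ``Bel(x) = alpha * lambda(x) * pi(x)``."""
    lambda_x = np.asarray(lambda_x, dtype=np.float64)
    pi_x = np.asarray(pi_x, dtype=np.float64)
    if lambda_x.shape != pi_x.shape:
        raise StructuralError("lambda and pi must have equal lengths")
    prod = lambda_x * pi_x
    if prod.sum() <= 0.0:
        raise DegenerateEvidenceError(
            "all-zero lambda*pi product: contradictory evidence"
        )
    return normalize(prod)


def pi_to_child(bel: np.ndarray) -> np.ndarray:
    """Approximate top-down message: the node's belief itself.

    The exact message would exclude the destination child's own bottom-up
    contribution; with fan-ins in the hundreds that single message is a
    negligible fraction of the belief, so the belief is sent to every
    child unchanged.
    """
    return np.asarray(bel, dtype=np.float64).copy()


def pi_to_child_exact(pi_x: np.ndarray, child_lambda_messages,
                      child_index: int) -> np.ndarray:
    """Exact top-down message to one child (excludes that child's lambda).

    ``pi_j(x) = alpha * pi(x) * prod_{k != j} lambda_k(x)``.
    """
    out = np.asarray(pi_x, dtype=np.float64).copy()
    for j, lam in enumerate(child_lambda_messages):
        if j == child_index:
            continue
        out = out * np.asarray(lam, dtype=np.float64)
    return normalize(out)


# ---------------------------------------------------------------------------
# Exact inference on small singly-connected networks (test oracle)
# ---------------------------------------------------------------------------

@dataclass
class TreeNetwork:
    """A small singly-connected Bayesian network for oracle computations.

    ``parent[i]`` is the parent index of node ``i`` (or -1 for a root),
    ``k[i]`` its state count, ``cpt[i]`` the ``(k[i], k[parent[i]])``
    table (for a root, its prior as a length-``k[i]`` vector).
    """

    parent: list
    k: list
    cpt: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.parent)
        for i, p in enumerate(self.parent):
            if p >= i:
                raise StructuralError(
                    "nodes must be topologically ordered (parent index < child)"
                )
        if len(self.k) != n or len(self.cpt) != n:
            raise StructuralError("parent, k and cpt lists must align")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def children(self, i: int) -> list:
        return [j for j, p in enumerate(self.parent) if p == i]


def enumerate_marginals(tree: TreeNetwork, evidence=None) -> list:
    """Posterior marginals by brute-force joint enumeration.

    Builds the full joint table by broadcasting each factor of the
    network's factorisation along its own axes, multiplies in the
    evidence likelihood vectors, and sums out all other variables.
    Independent of the message-passing code path; test oracle only.
    """
    n = tree.n_nodes
    evidence = evidence or {}
    joint = np.ones([1] * n)
    for i in range(n):
        shape = [1] * n
        p = tree.parent[i]
        if p < 0:
            shape[i] = tree.k[i]
            factor = np.asarray(tree.cpt[i]).reshape(shape)
        else:
            shape[i] = tree.k[i]
            shape[p] = tree.k[p]
            # axes must follow node order; parent < child, so transpose
            factor = np.asarray(tree.cpt[i]).T.reshape(shape)
        joint = joint * factor
    for i, lam in evidence.items():
        shape = [1] * n
        shape[i] = tree.k[i]
        joint = joint * np.asarray(lam).reshape(shape)
    marginals = []
    for i in range(n):
        axes = tuple(j for j in range(n) if j != i)
        marginals.append(normalize(joint.sum(axis=axes)))
    return marginals


def exact_bp_marginals(tree: TreeNetwork, evidence=None) -> list:
    """Posterior marginals by exact belief propagation on a tree.

    Runs a single upward (leaves-to-roots) lambda pass and a downward
    pi pass built from the same primitives the large-scale engine uses,
    but with sampling disabled and the exact outgoing-pi rule. Two
    passes suffice on a singly-connected network.
    """
    n = tree.n_nodes
    evidence = evidence or {}
    lam = [np.ones(tree.k[i]) for i in range(n)]
    lam_msg_to_parent = [None] * n

    # upward pass in reverse topological order
    for i in reversed(range(n)):
        parts = [np.asarray(evidence[i], dtype=np.float64)] if i in evidence \
            else []
        parts += [lam_msg_to_parent[j] for j in tree.children(i)]
        if parts:
            lam[i] = combine_lambda(parts, EXACT)
        p = tree.parent[i]
        if p >= 0:
            lam_msg_to_parent[i] = normalize(
                lambda_to_parent(lam[i], np.asarray(tree.cpt[i]))
            )

    # downward pass in topological order
    pi = [None] * n
    pi_msg_from_parent = [None] * n
    for i in range(n):
        p = tree.parent[i]
        if p < 0:
            pi[i] = normalize(np.asarray(tree.cpt[i], dtype=np.float64))
        else:
            pi[i] = combine_pi([pi_msg_from_parent[i]],
                               [np.asarray(tree.cpt[i])], EXACT)
        kids = tree.children(i)
        kid_msgs = [lam_msg_to_parent[j] for j in kids]
        for slot, j in enumerate(kids):
            extra = [np.asarray(evidence[i])] if i in evidence else []
            pi_msg_from_parent[j] = pi_to_child_exact(
                pi[i], kid_msgs + extra, slot
            )
    return [belief(lam[i], pi[i]) for i in range(n)]


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in nats, with 0*log(0/q) treated as 0."""
    p = normalize(np.asarray(p, dtype=np.float64))
    q = normalize(np.asarray(q, dtype=np.float64))
    mask = p > 0
    if np.any(q[mask] == 0):
        return math.inf
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
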