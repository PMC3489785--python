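"""Message-passing schedules on the layered network.

Three schedules are provided, matching the three experimental modes of
the model:

* :func:`feedforward` -- categorisation: one bottom-up pass, updating
  one layer at a time with flat top-down priors; each node's belief is
  its bottom-up likelihood.
* :func:`feedback_sweep` -- recognition followed by top-down feedback:
  layers update in the order S1-C1-S2-C2-S3-C2-S2-C1-S1. Downward steps
  send each node's belief as the top-down message (the destination
  child's own contribution is deliberately not excluded) and combine
  per-parent tables as a weighted sum; bottom-up likelihoods from the
  upward pass are retained. Reproduces illusory-contour completion and,
  with a clamped top node on a blank input, mental imagery.
* :func:`attend` -- object attention: the top node is clamped to the
  attended category and layers update top-down only (S3-C2-S2-C1-S1),
  so the abstract object representation descends and is combined with
  the image evidence at the input layer.

All per-layer updates are vectorised over the grid: messages for every
(relative RF position) are computed for all nodes at once through the
shared tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import bp_core
from .bp_core import ApproximationConfig, StructuralError, max_lambda_count
from .gabor import GaborBank, image_to_lambda
from .network_arch import NetworkModel

logger = logging.getLogger(__name__)

__all__ = ["Clamp", "NetworkState", "feedforward", "categorize",
           "feedback_sweep", "attend", "group_sum_map"]


@dataclass(frozen=True)
class Clamp:
    """Fix one node's distribution to a delta on ``state``.

    A clamped node's belief and every message it emits are the delta
    distribution, immune to updates until the clamp is removed.
    """

    layer: str
    node: tuple = (0, 0)
    state: int = 0


@dataclass
class NetworkState:
    """Per-layer lambda (likelihood), pi (prior) and belief arrays,
    each of shape ``(grid_rows, grid_cols, k_states)``."""

    lam: dict = field(default_factory=dict)
    pi: dict = field(default_factory=dict)
    bel: dict = field(default_factory=dict)

    def snapshot_beliefs(self) -> dict:
        return {name: b.copy() for name, b in self.bel.items()}


def _delta(k: int, state: int) -> np.ndarray:
    d = np.zeros(k)
    d[state] = 1.0
    return d


def _apply_clamps(model: NetworkModel, state: NetworkState, clamps) -> None:
    for cl in clamps:
        spec = model.layer_by_name[cl.layer]
        if not (0 <= cl.state < spec.k_states):
            raise StructuralError(
                f"clamp state {cl.state} out of range for {cl.layer}"
            )
        d = _delta(spec.k_states, cl.state)
        r, c = cl.node
        for arrs in (state.lam, state.pi, state.bel):
            if cl.layer in arrs:
                arrs[cl.layer][r, c] = d


def _init_state(model: NetworkModel, s1_lambda: np.ndarray,
                cfg: ApproximationConfig) -> NetworkState:
    """Flat distributions everywhere; input evidence on the first layer."""
    state = NetworkState()
    for spec in model.layers:
        flat = np.full((spec.grid_rows, spec.grid_cols, spec.k_states),
                       1.0 / spec.k_states)
        state.lam[spec.name] = flat.copy()
        state.pi[spec.name] = flat.copy()
        state.bel[spec.name] = flat.copy()
    first = model.layers[0]
    if s1_lambda.shape != (first.grid_rows, first.grid_cols, first.k_states):
        raise StructuralError(
            f"input evidence shape {s1_lambda.shape} does not match "
            f"{first.name} grid"
        )
    lam = s1_lambda / s1_lambda.sum(axis=-1, keepdims=True)
    state.lam[first.name] = bp_core.floor_and_renormalize(lam, cfg.eps_min)
    state.bel[first.name] = state.lam[first.name].copy()
    return state


def _upward_messages(model: NetworkModel, child_lam: np.ndarray,
                     child_name: str, parent_name: str,
                     cfg: ApproximationConfig) -> np.ndarray:
    """Bottom-up messages from every child to every parent, stacked per
    relative RF position: shape ``(n_rel, p_rows, p_cols, k_parent)``."""
    parent = model.layer_by_name[parent_name]
    (nr, nc), (sr, sc) = parent.rf_size, parent.rf_step
    pr, pc = parent.grid_rows, parent.grid_cols
    cpt = model.cpts[child_name]  # (nr, nc, k_child, k_parent)
    msgs = np.empty((nr * nc, pr, pc, parent.k_states))
    for i in range(nr):
        for j in range(nc):
            # children of all parents at relative position (i, j)
            block = child_lam[i:i + sr * (pr - 1) + 1:sr,
                              j:j + sc * (pc - 1) + 1:sc]
            m = block @ cpt[i, j]
            m /= m.sum(axis=-1, keepdims=True)
            msgs[i * nc + j] = m
    return bp_core.floor_and_renormalize(msgs, cfg.eps_min)


def _combine_lambda_grid(msgs: np.ndarray, cfg: ApproximationConfig
                         ) -> np.ndarray:
    """Per-node multiplicative combination of stacked floored messages,
    keeping only the N_max highest-variance messages per node."""
    n_msgs, pr, pc, k = msgs.shape
    n_max = max_lambda_count(k, cfg.r_max, cfg.eps_min)
    if n_msgs > n_max:
        var = np.var(msgs, axis=-1)                       # (n_msgs, pr, pc)
        order = np.argsort(-var, axis=0, kind="stable")[: int(n_max)]
        msgs = np.take_along_axis(msgs, order[..., None], axis=0)
    # product in log domain (entries are floored, hence positive)
    log_l = np.log(msgs).sum(axis=0)
    log_l -= log_l.max(axis=-1, keepdims=True)
    lam = np.exp(log_l)
    return lam / lam.sum(axis=-1, keepdims=True)


def _upward_step(model: NetworkModel, state: NetworkState, child_name: str,
                 parent_name: str, cfg: ApproximationConfig) -> None:
    msgs = _upward_messages(model, state.lam[child_name], child_name,
                            parent_name, cfg)
    state.lam[parent_name] = _combine_lambda_grid(msgs, cfg)


def _downward_step(model: NetworkModel, state: NetworkState, child_name: str,
                   parent_name: str, cfg: ApproximationConfig) -> None:
    """Compute the child layer's pi from the parent beliefs (sent as
    top-down messages) and refresh the child beliefs as lambda * pi."""
    child = model.layer_by_name[child_name]
    parent = model.layer_by_name[parent_name]
    (nr, nc), (sr, sc) = parent.rf_size, parent.rf_step
    pr, pc = parent.grid_rows, parent.grid_cols
    cpt = model.cpts[child_name]
    parent_msg = state.bel[parent_name]  # pi_to_child: belief as message
    acc = np.zeros((child.grid_rows, child.grid_cols, child.k_states))
    if cfg.m_states < parent.k_states:
        q_idx = np.argsort(-parent_msg, axis=-1, kind="stable")[
            ..., : cfg.m_states]                          # (pr, pc, m)
        vals = np.take_along_axis(parent_msg, q_idx, axis=-1)
    else:
        q_idx = None
    for i in range(nr):
        for j in range(nc):
            if q_idx is None:
                contrib = parent_msg @ cpt[i, j].T        # (pr, pc, k_child)
            else:
                cols = cpt[i, j][:, q_idx]                # (k_child, pr, pc, m)
                contrib = np.einsum("kprm,prm->prk", cols, vals)
            acc[i:i + sr * (pr - 1) + 1:sr,
                j:j + sc * (pc - 1) + 1:sc] += contrib
    total = acc.sum(axis=-1, keepdims=True)
    flat = total[..., 0] <= 0
    if flat.any():
        acc[flat] = 1.0 / child.k_states
        total = acc.sum(axis=-1, keepdims=True)
    state.pi[child_name] = acc / total
    prod = state.lam[child_name] * state.pi[child_name]
    s = prod.sum(axis=-1, keepdims=True)
    bad = s[..., 0] <= 0
    if bad.any():
        logger.warning("degenerate lambda*pi at %d %s nodes; using uniform",
                       int(bad.sum()), child_name)
        prod[bad] = 1.0 / child.k_states
        s = prod.sum(axis=-1, keepdims=True)
    state.bel[child_name] = prod / s


def _prepare_input(model: NetworkModel, image, bank: GaborBank | None,
                   invert: bool) -> np.ndarray:
    first = model.layers[0]
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        return image  # already per-node evidence
    return image_to_lambda(image, (first.grid_rows, first.grid_cols),
                           bank, invert=invert)


def feedforward(model: NetworkModel, image, cfg: ApproximationConfig = None,
                bank: GaborBank | None = None, clamps=(),
                invert: bool = False) -> NetworkState:
    """One bottom-up pass; beliefs equal the bottom-up likelihoods.

    ``image`` is either a 2-D grayscale array or a precomputed
    ``(rows, cols, K)`` evidence array for the first layer. Returns the
    full network state; the top layer's belief is the category
    distribution.
    """
    cfg = cfg or ApproximationConfig()
    if not model.trained.get(model.layers[0].name, True):
        warnings.warn("network has untrained (uniform) tables; "
                      "feedforward will be uninformative", stacklevel=2)
    state = _init_state(model, _prepare_input(model, image, bank, invert), cfg)
    _apply_clamps(model, state, clamps)
    for child, parent in model.pairs():
        _upward_step(model, state, child.name, parent.name, cfg)
        state.bel[parent.name] = state.lam[parent.name].copy()
        _apply_clamps(model, state, clamps)
    return state


def categorize(s3_belief: np.ndarray) -> int:
    """Most probable category; ties break to the lowest index."""
    b = np.asarray(s3_belief, dtype=np.float64).ravel()
    winners = np.flatnonzero(np.isclose(b, b.max(), rtol=0, atol=1e-12))
    if winners.size > 1:
        warnings.warn(f"categorize tie among states {winners.tolist()}; "
                      "returning the lowest index", stacklevel=2)
    return int(winners[0])


def feedback_sweep(model: NetworkModel, image, clamps=(), sweeps: int = 1,
                   cfg: ApproximationConfig = None,
                   bank: GaborBank | None = None, invert: bool = False,
                   convergence_tol: float = 1e-6):
    """Up-then-down schedule (S1-C1-S2-C2-S3-C2-S2-C1-S1).

    Upward steps recompute likelihoods from the (fixed) input evidence;
    downward steps send beliefs as top-down messages and recompute each
    layer's belief as lambda * pi. Returns ``(state, history)`` where
    ``history`` is a list of per-layer belief snapshots: one taken after
    the upward pass ("pre-feedback") and one after each full sweep.
    """
    cfg = cfg or ApproximationConfig()
    state = _init_state(model, _prepare_input(model, image, bank, invert), cfg)
    _apply_clamps(model, state, clamps)
    history = []
    names = [sp.name for sp in model.layers]
    for sweep in range(sweeps):
        for child, parent in model.pairs():
            _upward_step(model, state, child.name, parent.name, cfg)
            state.bel[parent.name] = _lambda_pi_belief(state, parent.name)
            _apply_clamps(model, state, clamps)
        if sweep == 0:
            history.append(state.snapshot_beliefs())  # pre-feedback
        prev = state.snapshot_beliefs()
        for child_name, parent_name in zip(names[-2::-1], names[:0:-1]):
            _downward_step(model, state, child_name, parent_name, cfg)
            _apply_clamps(model, state, clamps)
        history.append(state.snapshot_beliefs())
        delta = max(np.abs(state.bel[n] - prev[n]).sum(axis=-1).max()
                    for n in names)
        if delta < convergence_tol:
            break
    return state, history


def _lambda_pi_belief(state: NetworkState, name: str) -> np.ndarray:
    prod = state.lam[name] * state.pi[name]
    s = prod.sum(axis=-1, keepdims=True)
    bad = s[..., 0] <= 0
    if bad.any():
        prod[bad] = 1.0
        s = prod.sum(axis=-1, keepdims=True)
    return prod / s


def attend(model: NetworkModel, image, category: int,
           cfg: ApproximationConfig = None, bank: GaborBank | None = None,
           invert: bool = False) -> NetworkState:
    """Top-down-first object attention (S3-C2-S2-C1-S1).

    The top node is clamped to ``category`` and the layers update
    downward only; at the input layer the descending prior is combined
    with the image evidence, enhancing the attended object's features.
    """
    cfg = cfg or ApproximationConfig()
    top = model.layers[-1]
    if not (0 <= category < top.k_states):
        raise StructuralError(
            f"unknown category {category}: top layer has {top.k_states} states"
        )
    clamps = (Clamp(top.name, (0, 0), category),)
    state = _init_state(model, _prepare_input(model, image, bank, invert), cfg)
    _apply_clamps(model, state, clamps)
    names = [sp.name for sp in model.layers]
    for child_name, parent_name in zip(names[-2::-1], names[:0:-1]):
        _downward_step(model, state, child_name, parent_name, cfg)
        _apply_clamps(model, state, clamps)
    return state


def group_sum_map(bel: np.ndarray, k_group: int) -> np.ndarray:
    """Sum contiguous state blocks: ``(..., G*k_group) -> (..., G)``."""
    if bel.shape[-1] % k_group:
        raise StructuralError(
            f"state count {bel.shape[-1]} not divisible by k_group {k_group}"
        )
    g = bel.shape[-1] // k_group
    return bel.reshape(*bel.shape[:-1], g, k_group).sum(axis=-1)
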