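"""Layerwise greedy learning of the shared conditional tables.

Training proceeds bottom-up, one layer pair at a time, freezing the
layers below and propagating the training images through them. During
learning each node is treated as parentless when computing its belief
(so beliefs equal bottom-up likelihoods) and as single-parented when
emitting its output message, which sidesteps the untrained top-down
priors without an expectation-maximisation loop.

Three learners produce prototype weight matrices, all later converted
to column-normalised conditional tables:

* simple -> complex (invariance): per child state, k-means over the
  thresholded response patches feeding a parent node, with a refined
  (subsample-clustering) initialisation; the cluster centres become the
  parent states of that state's *group*.
* complex -> simple (selectivity): the greedy *minimum-distance*
  algorithm over group-summed response patches -- a patch is stored as
  a prototype when it is farther than ``d_min`` from everything stored
  so far, with ``d_min`` relaxed between scans until the requested
  number of prototypes is reached.
* top layer (supervised, one-shot): the prototype of each category is
  simply the group-summed top complex-layer response to that category's
  single training image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.cluster import KMeans

from .bp_core import ApproximationConfig, StructuralError
from .gabor import GaborBank, image_to_lambda
from .network_arch import NetworkModel

logger = logging.getLogger(__name__)

__all__ = [
    "LearningConfig",
    "DatasetTooSmallError",
    "extract_thresholded_patches",
    "refined_kmeans",
    "learn_invariance_cpts",
    "weights_to_cpt_invariance",
    "group_sum",
    "learn_selectivity_prototypes",
    "weights_to_cpt_selectivity",
    "learn_s3_supervised",
    "train_network",
]


class DatasetTooSmallError(ValueError):
    """Raised when the training data cannot yield the requested
    number of prototypes."""


@dataclass
class LearningConfig:
    """Parameters of the table learners.

    patch_threshold : minimum peak response for a patch to enter
        k-means clustering (responses are probabilities in [0, 1]).
    dmin_init : starting minimum distance for selectivity learning;
        ``None`` uses the maximum pairwise distance over a subsample.
    dmin_step_frac : fraction of ``dmin_init`` subtracted between scans.
    kmeans_subsamples / kmeans_subsample_frac : number and size of the
        subsample clusterings pooled for the refined k-means start.
    rng_seed : seed for every stochastic step (k-means, subsampling).
    """

    patch_threshold: float = 0.3
    dmin_init: float | None = None
    dmin_step_frac: float = 0.05
    kmeans_subsamples: int = 10
    kmeans_subsample_frac: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.patch_threshold <= 1.0) and \
                self.patch_threshold != -1:
            raise StructuralError("patch_threshold must lie in [0, 1]")
        if self.dmin_init is not None and self.dmin_init <= 0:
            raise StructuralError("dmin_init must be positive")


def extract_thresholded_patches(state_map: np.ndarray, n, t: float
                                ) -> np.ndarray:
    """All stride-1 ``n x n`` patches whose maximum entry exceeds ``t``.

    Returns an array of shape ``(n_patches, nr, nc)`` (possibly empty),
    in row-major scan order.
    """
    state_map = np.asarray(state_map, dtype=np.float64)
    nr, nc = (n, n) if isinstance(n, int) else tuple(n)
    if state_map.shape[0] < nr or state_map.shape[1] < nc:
        raise StructuralError(
            f"map {state_map.shape} smaller than patch size {(nr, nc)}"
        )
    windows = sliding_window_view(state_map, (nr, nc))
    flat = windows.reshape(-1, nr, nc)
    keep = flat.max(axis=(1, 2)) > t
    return flat[keep].copy()


def refined_kmeans(patches: np.ndarray, k: int, cfg: LearningConfig
                   ) -> np.ndarray:
    """K-means with a refined start: cluster several small subsamples,
    pool their centres, cluster the pool, and use the result to seed
    the final run. Deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.rng_seed)
    x = patches.reshape(len(patches), -1)
    sub_centres = []
    m = max(k, int(round(cfg.kmeans_subsample_frac * len(x))))
    for _ in range(cfg.kmeans_subsamples):
        idx = rng.choice(len(x), size=min(m, len(x)), replace=False)
        km = KMeans(n_clusters=k, n_init=1,
                    random_state=int(rng.integers(2**31))).fit(x[idx])
        sub_centres.append(km.cluster_centers_)
    pool = np.concatenate(sub_centres)
    seed_km = KMeans(n_clusters=k, n_init=1,
                     random_state=int(rng.integers(2**31))).fit(pool)
    final = KMeans(n_clusters=k, init=seed_km.cluster_centers_,
                   n_init=1, random_state=0).fit(x)
    return final.cluster_centers_.reshape(k, *patches.shape[1:])


def learn_invariance_cpts(state_maps: dict, rf_size, k_group: int,
                          k_child_states: int, cfg: LearningConfig
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Learn simple->complex tables by clustering response patches.

    ``state_maps[f]`` is the list of 2-D response maps (one per training
    image) of child state ``f``. For each state, k-means with
    ``k_group`` clusters runs over that state's thresholded patches;
    the centres become the parent states of group ``f``. Returns
    ``(centres, cpts)`` where ``centres`` has shape
    ``(k_child_states, k_group, nr, nc)`` and ``cpts``
    ``(nr, nc, k_child_states, k_child_states * k_group)``.
    """
    nr, nc = (rf_size, rf_size) if isinstance(rf_size, int) else tuple(rf_size)
    centres = np.zeros((k_child_states, k_group, nr, nc))
    for f in range(k_child_states):
        patches = [extract_thresholded_patches(m, (nr, nc),
                                               cfg.patch_threshold)
                   for m in state_maps[f]]
        patches = np.concatenate([p for p in patches if len(p)]) \
            if any(len(p) for p in patches) else np.empty((0, nr, nc))
        uniq = np.unique(patches.reshape(len(patches), -1), axis=0) \
            if len(patches) else patches.reshape(0, -1)
        if len(uniq) == 0:
            warnings.warn(f"no patches above threshold for state {f}; "
                          "its group stays uniform", stacklevel=2)
            continue
        if len(uniq) < k_group:
            warnings.warn(
                f"state {f}: only {len(uniq)} distinct patches for "
                f"{k_group} clusters; padding group with empty prototypes",
                stacklevel=2)
            centres[f, :len(uniq)] = uniq.reshape(-1, nr, nc)
            continue
        centres[f] = refined_kmeans(patches, k_group, cfg)
    return centres, weights_to_cpt_invariance(centres, k_child_states)


def weights_to_cpt_invariance(centres: np.ndarray, k_child_states: int
                              ) -> np.ndarray:
    """Convert invariance cluster centres to conditional tables.

    For the parent state of group ``f`` with centre weight ``w`` at
    child position (i, j), the column over the child's states is
    ``w * onehot(f) + (1 - w) * uniform(K)`` -- a unit weight pins the
    child to state ``f``, an empty weight leaves it uninformed (flat).
    """
    k_states, k_group, nr, nc = centres.shape
    if k_states != k_child_states:
        raise StructuralError("centres not grouped by child state")
    k_parent = k_states * k_group
    w = np.clip(centres, 0.0, 1.0)
    cpt = np.empty((nr, nc, k_child_states, k_parent))
    for f in range(k_states):
        for c in range(k_group):
            p = f * k_group + c
            col = (1.0 - w[f, c]) / k_child_states       # (nr, nc)
            cpt[:, :, :, p] = col[..., None]
            cpt[:, :, f, p] += w[f, c]
    return cpt


def group_sum(values: np.ndarray, k_group: int) -> np.ndarray:
    """Contiguous-block sums over the last axis (states -> groups)."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape[-1] % k_group:
        raise StructuralError(
            f"length {values.shape[-1]} not divisible by k_group {k_group}"
        )
    g = values.shape[-1] // k_group
    return values.reshape(*values.shape[:-1], g, k_group).sum(axis=-1)


def _patch_scan(group_maps, nr: int, nc: int) -> np.ndarray:
    """All ``nr x nc x G`` patches over all images, in a fixed
    deterministic order (image order, then row-major location)."""
    out = []
    for gm in group_maps:
        windows = sliding_window_view(gm, (nr, nc), axis=(0, 1))
        # windows: (rows', cols', G, nr, nc) -> (n, nr, nc, G)
        out.append(np.moveaxis(windows, 2, -1).reshape(-1, nr, nc,
                                                       gm.shape[-1]))
    return np.concatenate(out)


def learn_selectivity_prototypes(group_maps, rf_size, k: int,
                                 cfg: LearningConfig) -> np.ndarray:
    """Greedy minimum-distance prototype selection.

    ``group_maps`` is a list of ``(rows, cols, G)`` group-summed
    response arrays, one per training image. Scans all patches in a
    fixed order, storing a patch when its Euclidean distance to every
    stored prototype exceeds ``d_min``; after each full scan ``d_min``
    is lowered by a fixed step and the scan repeats, until ``k``
    prototypes are stored. Raises :class:`DatasetTooSmallError` when
    even ``d_min = 0`` (which still excludes exact duplicates) cannot
    produce ``k`` prototypes.
    """
    if k < 1:
        raise StructuralError("k must be >= 1")
    nr, nc = (rf_size, rf_size) if isinstance(rf_size, int) else tuple(rf_size)
    patches = _patch_scan(group_maps, nr, nc)
    if len(patches) == 0:
        raise DatasetTooSmallError("no patches available")
    flat = patches.reshape(len(patches), -1)
    if cfg.dmin_init is not None:
        d0 = float(cfg.dmin_init)
    else:
        rng = np.random.default_rng(cfg.rng_seed)
        idx = rng.choice(len(flat), size=min(len(flat), 256), replace=False)
        sub = flat[idx]
        d0 = float(np.sqrt(
            ((sub[:, None] - sub[None]) ** 2).sum(-1)).max())
        if d0 <= 0:
            d0 = 1.0
    step = cfg.dmin_step_frac * d0
    stored: list[np.ndarray] = []
    d_min = d0
    while True:
        bank = np.array([s for s in stored]).reshape(len(stored), -1) \
            if stored else np.empty((0, flat.shape[1]))
        for row in flat:
            if len(stored) >= k:
                break
            if bank.shape[0]:
                d = np.sqrt(((bank - row) ** 2).sum(-1)).min()
            else:
                d = np.inf
            if d > d_min:
                stored.append(row.copy())
                bank = np.vstack([bank, row])
        if len(stored) >= k:
            break
        if d_min <= 0:
            raise DatasetTooSmallError(
                f"only {len(stored)} of {k} prototypes reachable "
                f"even at d_min = 0"
            )
        d_min = max(0.0, d_min - step)
    return np.array(stored).reshape(k, nr, nc, patches.shape[-1])


def weights_to_cpt_selectivity(prototypes: np.ndarray, k_child_states: int,
                               k_group: int) -> np.ndarray:
    """Convert group-level selectivity prototypes to conditional tables.

    ``prototypes`` has shape ``(k_parent, nr, nc, G)`` with one weight
    per child *group*; the weight is replicated across the group's
    ``k_group`` states and each column is sum-normalised (all-zero
    columns become flat).
    """
    k_parent, nr, nc, g = prototypes.shape
    if g * k_group != k_child_states:
        raise StructuralError(
            f"{g} groups x {k_group} states != {k_child_states} child states"
        )
    w = np.repeat(np.clip(prototypes, 0.0, None), k_group, axis=-1)
    w = np.moveaxis(w, 0, -1)                    # (nr, nc, K_child, k_parent)
    colsum = w.sum(axis=2, keepdims=True)
    flat_cols = colsum[:, :, 0, :] <= 0
    cpt = np.where(colsum > 0, w / np.where(colsum > 0, colsum, 1.0),
                   1.0 / k_child_states)
    if flat_cols.any():
        idx = np.where(flat_cols)
        cpt[idx[0], idx[1], :, idx[2]] = 1.0 / k_child_states
    return cpt


def learn_s3_supervised(c2_group_maps, labels, k_child_states: int,
                        k_group: int) -> tuple[np.ndarray, np.ndarray]:
    """One-shot supervised top layer: the prototype of each category is
    the group-summed top-complex-layer response to its training image.

    Returns ``(prototypes, cpts)``; categories follow the order of
    ``labels``, which must be unique.
    """
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise StructuralError("duplicate category labels")
    protos = np.stack([np.asarray(m, dtype=np.float64)
                       for m in c2_group_maps])
    flat = protos.reshape(len(protos), -1)
    for a in range(len(flat)):
        for b in range(a + 1, len(flat)):
            if np.array_equal(flat[a], flat[b]):
                warnings.warn(
                    f"categories {labels[a]!r} and {labels[b]!r} have "
                    "identical prototypes", stacklevel=2)
    return protos, weights_to_cpt_selectivity(protos, k_child_states, k_group)


# ---------------------------------------------------------------------------
# Full training pipeline
# ---------------------------------------------------------------------------

def train_network(model: NetworkModel, images, labels,
                  learn_cfg: LearningConfig | None = None,
                  approx_cfg: ApproximationConfig | None = None,
                  bank: GaborBank | None = None,
                  invert: bool = False) -> NetworkModel:
    """Learn all tables of the five-layer network, one pair at a time.

    ``images`` is one training image per category (one-shot learning;
    weight sharing supplies the positional variation a larger set would
    otherwise provide). The model is modified in place and returned.
    """
    from .inference import feedforward  # deferred: cycle-free at import

    learn_cfg = learn_cfg or LearningConfig()
    approx_cfg = approx_cfg or ApproximationConfig()
    bank = bank or GaborBank()
    s1, c1, s2, c2, s3 = model.layers
    if s3.k_states != len(images):
        raise StructuralError(
            f"top layer has {s3.k_states} states but {len(images)} "
            "training images were given (one-shot: one per category)"
        )

    logger.info("stage 1/5: Gabor front end")
    lams = [image_to_lambda(np.asarray(img, dtype=np.float64),
                            (s1.grid_rows, s1.grid_cols), bank,
                            invert=invert)
            for img in images]

    logger.info("stage 2/5: S1->C1 invariance (k-means groups)")
    state_maps = {f: [lam[..., f] for lam in lams]
                  for f in range(s1.k_states)}
    centres, cpts = learn_invariance_cpts(
        state_maps, c1.rf_size, c1.k_group, s1.k_states, learn_cfg)
    model.cpts[s1.name] = cpts
    model.prototypes["C1_centres"] = centres
    model.trained[s1.name] = True

    logger.info("stage 3/5: C1->S2 selectivity (minimum distance)")
    c1_group_maps = [
        group_sum(feedforward(model, lam, approx_cfg).bel[c1.name],
                  c1.k_group)
        for lam in lams
    ]
    protos = learn_selectivity_prototypes(
        c1_group_maps, s2.rf_size, s2.k_states, learn_cfg)
    model.cpts[c1.name] = weights_to_cpt_selectivity(
        protos, c1.k_states, c1.k_group)
    model.prototypes["S2"] = protos
    model.trained[c1.name] = True

    logger.info("stage 4/5: S2->C2 invariance (k-means groups)")
    s2_bels = [feedforward(model, lam, approx_cfg).bel[s2.name]
               for lam in lams]
    s2_state_maps = {f: [b[..., f] for b in s2_bels]
                     for f in range(s2.k_states)}
    centres2, cpts2 = learn_invariance_cpts(
        s2_state_maps, c2.rf_size, c2.k_group, s2.k_states, learn_cfg)
    model.cpts[s2.name] = cpts2
    model.trained[s2.name] = True

    logger.info("stage 5/5: supervised S3 (one-shot)")
    c2_group_maps = [
        group_sum(feedforward(model, lam, approx_cfg).bel[c2.name],
                  c2.k_group)
        for lam in lams
    ]
    s3_protos, s3_cpts = learn_s3_supervised(
        c2_group_maps, labels, c2.k_states, c2.k_group)
    model.cpts[c2.name] = s3_cpts
    model.prototypes["S3"] = s3_protos
    model.trained[c2.name] = True
    model.categories = list(labels)
    return model
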