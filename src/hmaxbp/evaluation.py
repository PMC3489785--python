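"""Performance statistics, S1 reconstruction and approximation quality.

Categorisation performance is summarised the way the feedforward
experiments report it: for each distortion d, the percentage of
correctly categorised images is computed per variation v (over
categories), then averaged over variations to give C_d with spread
sigma_d, and finally averaged over distortions.

The reconstruction routine renders an input-layer belief map back into
image space by superposing the oriented Gabor kernels weighted by the
mean-removed orientation probabilities, so flat (uninformed) regions
come out neutral grey.

The KL harness measures, on random small fan-in problems, how far the
sampled message combinations are from their exact counterparts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from . import bp_core
from .bp_core import ApproximationConfig, StructuralError
from .gabor import GaborBank

__all__ = ["ResultTable", "score", "reconstruct_image",
           "kl_approximation_error", "sparseness"]


@dataclass
class ResultTable:
    """Per-distortion and overall correct-categorisation percentages."""

    per_variation: dict      # (distortion, variation) -> percentage
    per_distortion: dict     # distortion -> mean over variations
    std_per_distortion: dict  # distortion -> std over variations
    overall_mean: float
    mean_std: float


def score(records) -> ResultTable:
    """Summarise per-image results.

    ``records`` is an iterable of ``(category, variation, distortion,
    correct)`` tuples, one per test image; every (category, variation,
    distortion) cell must appear exactly once.
    """
    cells = {}
    for cat, var, dist, ok in records:
        key = (cat, var, dist)
        if key in cells:
            raise StructuralError(f"duplicate result cell {key}")
        cells[key] = bool(ok)
    cats = sorted({k[0] for k in cells})
    variations = sorted({k[1] for k in cells})
    dists = sorted({k[2] for k in cells})
    missing = [(c, v, d) for c in cats for v in variations for d in dists
               if (c, v, d) not in cells]
    if missing:
        raise StructuralError(f"missing result cells: {missing[:10]}"
                              f"{'...' if len(missing) > 10 else ''}")
    per_variation = {
        (d, v): 100.0 * np.mean([cells[(c, v, d)] for c in cats])
        for d in dists for v in variations
    }
    per_distortion = {
        d: float(np.mean([per_variation[(d, v)] for v in variations]))
        for d in dists
    }
    std_per_distortion = {
        d: float(np.std([per_variation[(d, v)] for v in variations]))
        for d in dists
    }
    return ResultTable(
        per_variation=per_variation,
        per_distortion=per_distortion,
        std_per_distortion=std_per_distortion,
        overall_mean=float(np.mean(list(per_distortion.values()))),
        mean_std=float(np.mean(list(std_per_distortion.values()))),
    )


def reconstruct_image(s1_beliefs: np.ndarray,
                      bank: GaborBank | None = None) -> np.ndarray:
    """Render input-layer beliefs as an image.

    Adds, at every grid location, each oriented kernel scaled by that
    orientation's belief minus the flat level 1/K, then rescales
    linearly to [0, 1]. Uniform beliefs therefore render as constant
    mid-grey (0.5).
    """
    bank = bank or GaborBank()
    bel = np.asarray(s1_beliefs, dtype=np.float64)
    rows, cols, k = bel.shape
    if k != bank.n_orientations:
        raise StructuralError("belief states do not match the filter bank")
    canvas = np.zeros((rows + bank.size - 1, cols + bank.size - 1))
    centred = bel - 1.0 / k
    for o in range(k):
        canvas += signal.fftconvolve(centred[..., o], bank.kernels[o],
                                     mode="full")
    lo, hi = canvas.min(), canvas.max()
    if hi - lo < 1e-12:
        return np.full_like(canvas, 0.5)
    return (canvas - lo) / (hi - lo)


def kl_approximation_error(fan_in: int, k: int, m_pi: int, m_states: int,
                           trials: int = 50, seed: int = 0,
                           k_parent: int | None = None) -> dict:
    """Mean KL divergence between exact and sampled message combination.

    Draws random column-Dirichlet(1) tables and random Dirichlet(1)
    messages for a node with ``fan_in`` parents of ``k_parent`` states
    (default ``k``), and compares the exact prior combination with the
    sampled one (``m_pi`` messages, ``m_states`` states each); likewise
    compares the exact bottom-up product with the one restricted to the
    ``m_pi`` highest-variance messages. Both KL directions are
    reported, averaged over trials.
    """
    rng = np.random.default_rng(seed)
    kp = k_parent or k
    out = {"combine_pi": 0.0, "combine_pi_rev": 0.0,
           "combine_lambda": 0.0, "combine_lambda_rev": 0.0}
    approx = ApproximationConfig(m_pi=m_pi, m_states=m_states)
    for _ in range(trials):
        cpts = [rng.dirichlet(np.ones(k), size=kp).T for _ in range(fan_in)]
        pis = [rng.dirichlet(np.ones(kp)) for _ in range(fan_in)]
        exact = bp_core.combine_pi(pis, cpts, bp_core.EXACT)
        sampled = bp_core.combine_pi(pis, cpts, approx)
        out["combine_pi"] += bp_core.kl_divergence(exact, sampled)
        out["combine_pi_rev"] += bp_core.kl_divergence(sampled, exact)
        lams = [rng.dirichlet(np.ones(k)) for _ in range(fan_in)]
        exact_l = bp_core.combine_lambda(lams, bp_core.EXACT)
        keep = bp_core.select_top_variance(lams, m_pi)
        approx_l = bp_core.combine_lambda([lams[i] for i in sorted(keep)],
                                          approx)
        out["combine_lambda"] += bp_core.kl_divergence(exact_l, approx_l)
        out["combine_lambda_rev"] += bp_core.kl_divergence(approx_l, exact_l)
    return {name: v / trials for name, v in out.items()}


def sparseness(beliefs: np.ndarray) -> float:
    """Diagnostic: percentage of entries above the flat level 1/K."""
    beliefs = np.asarray(beliefs, dtype=np.float64)
    k = beliefs.shape[-1]
    return 100.0 * float(np.mean(beliefs > 1.0 / k))
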