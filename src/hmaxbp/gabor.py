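"""Gabor front end: turns an image into input-layer evidence messages.

A bank of four oriented 9x9 Gabor kernels plays the role of hard-wired
V1 simple-cell filters. Their absolute (energy) responses, sum-normalised
over orientation at each location, are the bottom-up messages emitted by
a sheet of dummy input nodes -- dummy because they carry no belief, they
only provide the likelihood over the four orientation states of each
input-layer node. Locations with no oriented structure (blank regions)
emit the flat distribution (1/4, 1/4, 1/4, 1/4): "no information".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bp_core import StructuralError

__all__ = ["GaborBank", "gabor_response_maps", "responses_to_lambda",
           "image_to_lambda"]


@dataclass
class GaborBank:
    """Four-orientation, single-scale Gabor filter bank.

    ``theta`` is the orientation of the preferred bar/edge in degrees;
    the carrier runs perpendicular to it. Kernels are made exactly
    zero-mean (so constant regions give zero response) and unit L2 norm.
    Defaults follow the standard 9x9 parameterisation of HMAX-style
    front ends: wavelength 3.5 px, envelope width 2.8 px, aspect 0.3,
    cosine phase.
    """

    size: int = 9
    orientations: tuple = (0.0, 45.0, 90.0, 135.0)
    wavelength: float = 3.5
    sigma: float = 2.8
    gamma: float = 0.3
    kernels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        half = self.size // 2
        y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
        ks = []
        for theta_deg in self.orientations:
            t = np.deg2rad(theta_deg)
            # carrier axis perpendicular to the preferred orientation
            x0 = -x * np.sin(t) + y * np.cos(t)
            y0 = x * np.cos(t) + y * np.sin(t)
            k = np.exp(-(x0**2 + (self.gamma * y0)**2)
                       / (2.0 * self.sigma**2)) \
                * np.cos(2.0 * np.pi * x0 / self.wavelength)
            k -= k.mean()
            k /= np.linalg.norm(k)
            ks.append(k)
        self.kernels = np.stack(ks)

    @property
    def n_orientations(self) -> int:
        return len(self.orientations)


def gabor_response_maps(image: np.ndarray,
                        bank: GaborBank | None = None) -> np.ndarray:
    """Absolute valid-mode filter responses, one map per orientation.

    Returns an array of shape ``(n_orientations, H-size+1, W-size+1)``.
    """
    bank = bank or GaborBank()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < bank.size:
        raise StructuralError(
            f"image must be 2-D and at least {bank.size}x{bank.size}; "
            f"got shape {image.shape}"
        )
    maps = [np.abs(signal.fftconvolve(image, k[::-1, ::-1], mode="valid"))
            for k in bank.kernels]
    return np.stack(maps)


def responses_to_lambda(maps: np.ndarray,
                        s1_grid: tuple[int, int]) -> np.ndarray:
    """Per-node evidence distributions from the orientation energy maps.

    The maps are centre-cropped to the input-layer grid (the grid is
    derived top-down and is a few pixels smaller than the valid response
    map; the surplus border is discarded symmetrically), then
    sum-normalised over orientation at each location. Locations whose
    total energy is negligible map to the flat distribution.
    """
    maps = np.asarray(maps, dtype=np.float64)
    n_orient, h, w = maps.shape
    rows, cols = s1_grid
    if rows > h or cols > w:
        raise StructuralError(
            f"S1 grid {s1_grid} larger than response maps {(h, w)}"
        )
    r0 = (h - rows) // 2
    c0 = (w - cols) // 2
    crop = maps[:, r0:r0 + rows, c0:c0 + cols]
    total = crop.sum(axis=0)
    # blank threshold: relative to the strongest response, with an
    # absolute floor so a fully blank image is flat everywhere
    thresh = max(1e-9 * total.max(), 1e-12)
    flat = total <= thresh
    safe = np.where(flat, 1.0, total)
    lam = crop / safe
    lam[:, flat] = 1.0 / n_orient
    return np.moveaxis(lam, 0, -1)  # (rows, cols, n_orientations)


def image_to_lambda(image: np.ndarray, s1_grid: tuple[int, int],
                    bank: GaborBank | None = None,
                    invert: bool = False) -> np.ndarray:
    """Image -> per-node input evidence, shape ``(rows, cols, 4)``.

    ``invert=True`` treats dark-object-on-light-ground silhouettes as
    object = high intensity (the energy responses are unchanged by
    inversion up to sign, so this mainly matters for reconstruction
    conventions).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.max() > 1.0:
        image = image / 255.0
    if invert:
        image = 1.0 - image
    return responses_to_lambda(gabor_response_maps(image, bank), s1_grid)
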