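"""Synthetic imagery: silhouette categories, distortions and fixtures.

The model is trained one-shot on binary object silhouettes (dark object
on a white 140 x 140 ground) and tested on seven distortion families:
a ~20% rectangular occlusion, 5% and 10% uniform pixel noise, 10 px and
20 px translations, and 10% and 20% size reductions, each in five fixed
variations. This module generates such a dataset deterministically from
a seed -- the silhouette shapes are parametric emulations (polygons,
stars, crosses, blobs), not reproductions of any particular photograph
set -- plus the two feedback stimuli (a Kanizsa square with ground-truth
illusory-edge coordinates, and superimposed object pairs) and the exact
three-layer toy fixture used to validate the message algebra.

Convention: images are float arrays in [0, 1]; object pixels are 0.0
(dark), background 1.0 (white).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon, disk as draw_disk
from skimage.transform import resize

from .bp_core import StructuralError
from .network_arch import LayerSpec, NetworkModel

__all__ = [
    "ImageSet", "ToyFixture", "DISTORTIONS",
    "make_silhouettes", "occlude", "add_pixel_noise", "translate", "scale",
    "make_test_set", "make_kanizsa_square", "superimpose",
    "build_toy_fixture",
]

FRAME = 140
DISTORTIONS = ("occluded", "noise5", "noise10", "trans10", "trans20",
               "scale10", "scale20")


@dataclass
class ImageSet:
    """A labelled collection of 140x140 images with distortion tags."""

    images: list
    labels: list
    distortions: list
    variations: list
    rng_seed: int

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(zip(self.images, self.labels, self.distortions,
                        self.variations))


def _object_mask(img: np.ndarray) -> np.ndarray:
    return np.asarray(img) < 0.5


# ---------------------------------------------------------------------------
# Silhouette generation
# ---------------------------------------------------------------------------

def _poly_image(rows, cols, frame: int = FRAME) -> np.ndarray:
    img = np.ones((frame, frame))
    rr, cc = draw_polygon(np.asarray(rows), np.asarray(cols),
                          shape=(frame, frame))
    img[rr, cc] = 0.0
    return img


def _regular_polygon(n: int, radius: float, rot: float, centre=(70, 70)):
    ang = rot + 2 * np.pi * np.arange(n) / n
    return centre[0] + radius * np.sin(ang), centre[1] + radius * np.cos(ang)


def _star(n: int, r_out: float, r_in: float, rot: float, centre=(70, 70)):
    ang = rot + np.pi * np.arange(2 * n) / n
    rad = np.where(np.arange(2 * n) % 2 == 0, r_out, r_in)
    return centre[0] + rad * np.sin(ang), centre[1] + rad * np.cos(ang)


def _blob(rng, centre=(70, 70), base_r: float = 38.0):
    theta = np.linspace(0, 2 * np.pi, 90, endpoint=False)
    r = np.full_like(theta, base_r)
    for k in range(2, 6):
        amp = base_r * rng.uniform(0.05, 0.18)
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 12, 62)
    return centre[0] + r * np.sin(theta), centre[1] + r * np.cos(theta)


def _cross(arm: float, width: float, rot: float, centre=(70, 70)):
    w, a = width / 2, arm
    pts = np.array([
        (-w, -a), (w, -a), (w, -w), (a, -w), (a, w), (w, w),
        (w, a), (-w, a), (-w, w), (-a, w), (-a, -w), (-w, -w),
    ], dtype=float)
    rotm = np.array([[np.cos(rot), -np.sin(rot)],
                     [np.sin(rot), np.cos(rot)]])
    pts = pts @ rotm.T
    return centre[0] + pts[:, 1], centre[1] + pts[:, 0]


def _lshape(size: float, thick: float, centre=(70, 70)):
    s, t = size, thick
    pts = np.array([(0, 0), (t, 0), (t, s - t), (s, s - t), (s, s), (0, s)],
                   dtype=float) - np.array([s / 2, s / 2])
    return centre[0] + pts[:, 1], centre[1] + pts[:, 0]


def _one_silhouette(i: int, jit) -> np.ndarray:
    """One jittered silhouette of category ``i``'s shape family."""
    kind = i % 10
    # repeated families get a different overall scale so that two
    # instances of the same family stay clearly distinct
    f = (1.0, 0.78, 1.12)[(i // 10) % 3]
    if kind == 0 and i == 0:
        # side matches the default Kanizsa square (feedback stimuli)
        half = 32
        img = np.ones((FRAME, FRAME))
        img[70 - half:70 + half, 70 - half:70 + half] = 0.0
        return img
    # near-centre placement with a little play, so that same-size
    # convex shapes of different categories do not coincide
    ctr = (70 + int(jit.integers(-10, 11)), 70 + int(jit.integers(-10, 11)))
    if kind == 0:
        r, c = _regular_polygon(4, f * jit.uniform(40, 48),
                                np.pi / 4 + jit.uniform(-0.2, 0.2), ctr)
    elif kind == 1:
        img = np.ones((FRAME, FRAME))
        rr, cc = draw_disk(ctr, f * jit.uniform(26, 32),
                           shape=(FRAME, FRAME))
        img[rr, cc] = 0.0
        return img
    elif kind == 2:
        r, c = _regular_polygon(3, f * jit.uniform(44, 54),
                                jit.uniform(0, 2 * np.pi), ctr)
    elif kind == 3:
        r, c = _star(5, f * jit.uniform(48, 58), f * jit.uniform(20, 26),
                     jit.uniform(0, 2 * np.pi), ctr)
    elif kind == 4:
        r, c = _cross(f * jit.uniform(44, 54), f * jit.uniform(18, 26),
                      jit.uniform(-0.3, 0.3), ctr)
    elif kind == 5:
        h, w = f * jit.uniform(22, 28), f * jit.uniform(52, 62)
        img = np.ones((FRAME, FRAME))
        img[int(ctr[0] - h):int(ctr[0] + h),
            int(ctr[1] - w):int(ctr[1] + w)] = 0.0
        return img
    elif kind == 6:
        r, c = _star(6, f * jit.uniform(44, 52), f * jit.uniform(22, 27),
                     jit.uniform(0, 2 * np.pi), ctr)
    elif kind == 7:
        r, c = _regular_polygon(5, f * jit.uniform(36, 42),
                                jit.uniform(0, 2 * np.pi), ctr)
    elif kind == 8:
        r, c = _lshape(f * jit.uniform(72, 86), f * jit.uniform(22, 30), ctr)
    else:
        r, c = _blob(jit, ctr, base_r=f * 38.0)
    return _poly_image(r, c)


def make_silhouettes(n_categories: int, seed: int = 0) -> ImageSet:
    """Generate ``n_categories`` distinct binary silhouettes.

    Deterministic for a fixed seed. Category 0 is always a plain
    square (the shape the feedback experiments rely on); the remaining
    categories cycle through parametric families with seeded jitter,
    re-jittered until every pair of categories is clearly distinct
    (pixel IoU < 0.75). Objects are centred, occupy roughly 10-40% of
    the frame, and use exactly the two pixel values {0, 1}.
    """
    if n_categories < 1:
        raise StructuralError("need at least one category")
    rng = np.random.default_rng(seed)
    images: list = []
    masks: list = []
    for i in range(n_categories):
        for _attempt in range(80):
            img = _one_silhouette(i, rng)
            m = img < 0.5
            if not (0.09 <= m.mean() <= 0.42):
                continue
            if all((m & o).sum() / (m | o).sum() < 0.75 for o in masks):
                break
        else:
            raise StructuralError(
                f"could not draw a distinct silhouette for category {i}"
            )
        images.append(img)
        masks.append(m)
    return ImageSet(images=images, labels=list(range(n_categories)),
                    distortions=["none"] * n_categories,
                    variations=[0] * n_categories, rng_seed=seed)


# ---------------------------------------------------------------------------
# Distortions
# ---------------------------------------------------------------------------

_OCCLUDE_BAND = (0.18, 0.22)


def occlude(img: np.ndarray, variation: int) -> np.ndarray:
    """Remove ~20% of the object's pixels with a white rectangle.

    The five variations anchor the occluder at the object's
    bounding-box centre or at the centre of one of its four quadrants;
    the occluder size is found by search so the removed fraction of
    object pixels lands in [18%, 22%].
    """
    if not 1 <= variation <= 5:
        raise StructuralError(f"variation must be 1..5, got {variation}")
    img = np.asarray(img, dtype=np.float64)
    mask = _object_mask(img)
    area = int(mask.sum())
    if area == 0:
        raise StructuralError("cannot occlude a blank image")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    r0, r1, c0, c1 = rows[0], rows[-1], cols[0], cols[-1]
    rc, cc = (r0 + r1) / 2, (c0 + c1) / 2
    qr, qc = (r1 - r0) / 4, (c1 - c0) / 4
    anchors = [(rc, cc), (rc - qr, cc - qc), (rc - qr, cc + qc),
               (rc + qr, cc - qc), (rc + qr, cc + qc)]
    ar, ac = anchors[variation - 1]
    lo, hi = _OCCLUDE_BAND
    cum = np.pad(mask.cumsum(0).cumsum(1), ((1, 0), (1, 0)))

    def removed(hr: int, hc: int) -> int:
        a = max(0, int(ar - hr))
        b = min(FRAME, int(ar + hr + 1))
        c = max(0, int(ac - hc))
        d = min(FRAME, int(ac + hc + 1))
        return int(cum[b, d] - cum[a, d] - cum[b, c] + cum[a, c])

    # near-square rectangles first, relaxing the aspect if the discrete
    # size steps jump over the target band
    best = None
    for slack in range(0, 6):
        for h in range(1, FRAME // 2):
            for hr, hc in {(h, h), (h, h + slack), (h + slack, h)}:
                if lo <= removed(hr, hc) / area <= hi:
                    best = (hr, hc)
                    break
            if best:
                break
        if best:
            break
    if best is None:
        raise StructuralError(
            "no occluder size removes 18-22% of the object at this anchor"
        )
    hr, hc = best
    out = img.copy()
    out[max(0, int(ar - hr)):min(FRAME, int(ar + hr + 1)),
        max(0, int(ac - hc)):min(FRAME, int(ac + hc + 1))] = 1.0
    return out


def add_pixel_noise(img: np.ndarray, fraction: float, variation: int,
                    seed: int = 0) -> np.ndarray:
    """Replace exactly ``round(fraction * H * W)`` distinct pixels with
    uniform random values; the pixel choice is seeded by
    ``(seed, variation)``."""
    img = np.asarray(img, dtype=np.float64)
    if not 0.0 <= fraction < 1.0:
        raise StructuralError(f"fraction must lie in [0, 1), got {fraction}")
    n = round(fraction * img.size)
    if n == 0:
        return img.copy()
    rng = np.random.default_rng([seed, variation])
    idx = rng.choice(img.size, size=n, replace=False)
    out = img.copy()
    out.flat[idx] = rng.uniform(0.0, 1.0, size=n)
    return out


_TRANSLATE_DIRS = [(-1, 0), (1, 0), (0, 1), (0, -1), (1, 1)]  # u,d,r,l,diag


def translate(img: np.ndarray, pixels: int, variation: int) -> np.ndarray:
    """Integer shift of the whole frame with white fill; content pushed
    over the border is cropped (a small extra occlusion). Variations:
    up, down, right, left, diagonal (bottom-right)."""
    if not 1 <= variation <= 5:
        raise StructuralError(f"variation must be 1..5, got {variation}")
    img = np.asarray(img, dtype=np.float64)
    dr, dc = (d * pixels for d in _TRANSLATE_DIRS[variation - 1])
    out = np.ones_like(img)
    h, w = img.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    dst_r = slice(max(0, dr), min(h, h + dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def scale(img: np.ndarray, percent: int, variation: int) -> np.ndarray:
    """Shrink the object to (100 - percent)% linear size.

    The shrunken object is pasted so that its bounding box aligns with
    the original box's top-right, top-left, bottom-right or bottom-left
    corner, or its centre (the five variations)."""
    if not 1 <= variation <= 5:
        raise StructuralError(f"variation must be 1..5, got {variation}")
    img = np.asarray(img, dtype=np.float64)
    if percent == 0:
        return img.copy()
    mask = _object_mask(img)
    if not mask.any():
        raise StructuralError("cannot scale a blank image")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    r0, r1, c0, c1 = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
    box = mask[r0:r1, c0:c1]
    f = 1.0 - percent / 100.0
    nh = max(1, int(round(box.shape[0] * f)))
    nw = max(1, int(round(box.shape[1] * f)))
    small = resize(box.astype(float), (nh, nw), order=0,
                   anti_aliasing=False) > 0.5
    anchors = {
        1: (r0, c1 - nw),                    # top-right
        2: (r0, c0),                         # top-left
        3: (r1 - nh, c1 - nw),               # bottom-right
        4: (r1 - nh, c0),                    # bottom-left
        5: (r0 + (r1 - r0 - nh) // 2, c0 + (c1 - c0 - nw) // 2),  # centre
    }
    pr, pc = anchors[variation]
    out = np.ones_like(img)
    out[pr:pr + nh, pc:pc + nw][small] = 0.0
    return out


def make_test_set(originals: ImageSet, seed: int = 0) -> ImageSet:
    """The full distorted test set: every category x 5 variations x the
    7 distortion families (1050 images for 30 categories)."""
    images, labels, dists, vars_ = [], [], [], []
    for img, label in zip(originals.images, originals.labels):
        for dist in DISTORTIONS:
            for v in range(1, 6):
                if dist == "occluded":
                    out = occlude(img, v)
                elif dist == "noise5":
                    out = add_pixel_noise(img, 0.05, v, seed=seed + label)
                elif dist == "noise10":
                    out = add_pixel_noise(img, 0.10, v, seed=seed + label)
                elif dist == "trans10":
                    out = translate(img, 10, v)
                elif dist == "trans20":
                    out = translate(img, 20, v)
                elif dist == "scale10":
                    out = scale(img, 10, v)
                else:
                    out = scale(img, 20, v)
                images.append(out)
                labels.append(label)
                dists.append(dist)
                vars_.append(v)
    return ImageSet(images, labels, dists, vars_, seed)


# ---------------------------------------------------------------------------
# Feedback stimuli
# ---------------------------------------------------------------------------

def make_kanizsa_square(size: int = 64, pacman_radius: int = 28,
                        frame: int = FRAME):
    """Four 'pacman' discs inducing an illusory square.

    Black discs sit at the corners of an (invisible) centred square of
    side ``size``; the quarter of each disc inside the square is
    removed, so the square's sides are bounded by real corners (the
    collinear mouth edges) but have no luminance edge along their
    middle. The default geometry matches the scale of the square
    silhouette category. Returns ``(image, edges)`` where ``edges`` is
    a list of ``(row, col, orientation_deg)`` ground-truth
    illusory-edge pixels (orientation 0 for the horizontal sides, 90
    for the vertical sides): the mid-gap locations that carry no
    luminance gradient of their own.
    """
    if pacman_radius < 0 or size <= 0:
        raise StructuralError("size and pacman_radius must be positive")
    half = size // 2
    ctr = frame // 2
    corners = [(ctr - half, ctr - half), (ctr - half, ctr + half),
               (ctr + half, ctr - half), (ctr + half, ctr + half)]
    if pacman_radius > 0 and (corners[0][0] - pacman_radius < 0 or
                              corners[3][0] + pacman_radius >= frame):
        raise StructuralError("Kanizsa geometry exceeds the frame")
    if 2 * pacman_radius >= size:
        raise StructuralError("pacmen overlap: radius too large for size")
    img = np.ones((frame, frame))
    if pacman_radius == 0:
        return img, []
    for (r, c) in corners:
        rr, cc = draw_disk((r, c), pacman_radius, shape=(frame, frame))
        img[rr, cc] = 0.0
    # carve the quadrant of each disc that lies inside the square
    img[ctr - half:ctr + half + 1, ctr - half:ctr + half + 1] = 1.0
    edges = []
    # ground-truth pixels must carry no luminance gradient of their own:
    # stay one filter half-width away from the disc mouths
    margin = pacman_radius + 4
    for c in range(ctr - half + margin, ctr + half - margin + 1):
        edges.append((ctr - half, c, 0))     # top side, horizontal
        edges.append((ctr + half, c, 0))     # bottom side
    for r in range(ctr - half + margin, ctr + half - margin + 1):
        edges.append((r, ctr - half, 90))    # left side, vertical
        edges.append((r, ctr + half, 90))
    return img, edges


def superimpose(img_a: np.ndarray, img_b: np.ndarray) -> np.ndarray:
    """Pixel-wise union of two silhouettes (dark object convention)."""
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise StructuralError(f"size mismatch {a.shape} vs {b.shape}")
    return np.minimum(a, b)


# ---------------------------------------------------------------------------
# Toy fixture (three-layer network with printed message values)
# ---------------------------------------------------------------------------

@dataclass
class ToyFixture:
    """The 15-node validation network: 15 S1 nodes (3x5 grid, 2
    orientation states), 3 overlapping C1 nodes (6 states = 2 groups of
    3 line positions) and one S2 node (3 prototype states).

    ``panel_a`` and ``panel_b`` are the two input configurations: the
    same bar pattern at two positions that fall inside the same C1
    groups, demonstrating translation invariance at S2.
    """

    model: NetworkModel
    panel_a: np.ndarray
    panel_b: np.ndarray
    s2_prototypes: np.ndarray = field(default=None)


def build_toy_fixture() -> ToyFixture:
    """Construct the fixture's tables and inputs explicitly.

    C1 state (f, r): orientation f (0 horizontal, 1 vertical) as a line
    at position r; the child at that line's position gets the one-hot
    column for f, children outside the line get the flat column. The
    C1->S2 tables are group-uniform: each S2 prototype assigns a single
    weight to each child C1 *group*, replicated over the group's three
    states and column-normalised.
    """
    layers = [
        LayerSpec("S1", "simple", 3, 5, 2, (1, 1), (1, 1)),
        LayerSpec("C1", "complex", 1, 3, 6, (3, 3), (1, 1), k_group=3),
        LayerSpec("S2", "top", 1, 1, 3, (1, 3), (1, 1)),
    ]
    model = NetworkModel(layers)

    # S1 -> C1: 3x3 relative positions, 2 child x 6 parent states
    cpt1 = np.empty((3, 3, 2, 6))
    for i in range(3):
        for j in range(3):
            for s in range(6):
                f, r = divmod(s, 3)
                in_line = (i == r) if f == 0 else (j == r)
                if in_line:
                    col = np.array([1.0, 0.0]) if f == 0 else \
                        np.array([0.0, 1.0])
                else:
                    col = np.array([0.5, 0.5])
                cpt1[i, j, :, s] = col
    model.cpts["S1"] = cpt1

    # C1 -> S2: group weights per (S2 state, child C1 node)
    # s2_0 = (h, h, v); s2_1 = (v, v, h); s2_2 = (h, h, h)
    group_w = np.array([
        [[1, 0], [1, 0], [0, 1]],
        [[0, 1], [0, 1], [1, 0]],
        [[1, 0], [1, 0], [1, 0]],
    ], dtype=float)                       # (s2_state, child, group)
    cpt2 = np.zeros((1, 3, 6, 3))
    for s in range(3):
        for j in range(3):
            col = np.repeat(group_w[s, j], 3)
            cpt2[0, j, :, s] = col / col.sum()
    model.cpts["C1"] = cpt2
    for name in ("S1", "C1"):
        model.trained[name] = True

    strong_h = np.array([0.9, 0.1])
    strong_v = np.array([0.1, 0.9])
    flat = np.array([0.5, 0.5])

    def panel(h_row: int) -> np.ndarray:
        lam = np.tile(flat, (3, 5, 1))
        lam[h_row, 0:4] = strong_h          # horizontal bar
        lam[:, 4] = strong_v                # vertical bar, rightmost col
        return lam

    return ToyFixture(model=model, panel_a=panel(0), panel_b=panel(1),
                      s2_prototypes=group_w)
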