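"""Layered-grid network structure with receptive-field adjacency.

The model is a five-layer Bayesian network mirroring a simplified HMAX
architecture: alternating simple (selectivity) and complex (invariance)
layers of nodes arranged on 2-D grids, with a single top node over the
object categories. Each parent node pools an ``rf_size x rf_size``
block of children at stride ``rf_step``; overlapping receptive fields
(stride < size) give children multiple parents and introduce the loops
that make propagation "loopy". All nodes of a layer share one set of
conditional tables, indexed by the child's position inside the parent's
receptive field, which is what makes one-shot learning possible.

Grid sizes are derived top-down from the single top node through
``child_grid = rf_step * (parent_grid - 1) + rf_size`` per axis, which
guarantees exact cover: with the default parameters the input layer is
a 125 x 125 grid, centred on the 132 x 132 valid Gabor-response map of
a 140 x 140 image.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .bp_core import StructuralError, uniform

SCHEMA_VERSION = 1

__all__ = [
    "ArchitectureParams",
    "LayerSpec",
    "NetworkModel",
    "build_network",
    "build_layers",
    "save_model",
    "load_model",
]


@dataclass
class ArchitectureParams:
    """Structural parameters of the default five-layer network.

    Defaults are the reference configuration of the model: a 9x9
    four-orientation Gabor front end, C1 pooling 10x10 S1 nodes at
    stride 5 into 40 states (4 groups of 10), S2 pooling 4x4 C1 nodes
    at stride 1 into 250 learned features, C2 pooling 6x6 S2 nodes at
    stride 3 into 2500 states (250 groups of 10), and a single S3 node
    pooling the 6x6 C2 grid into one state per object category.
    """

    N_S1: int = 9          # Gabor kernel size (dummy-node RF)
    K_S1: int = 4          # Gabor orientations
    N_C1: int = 10
    step_C1: int = 5
    K_C1: int = 40
    K_C1group: int = 10
    N_S2: int = 4
    step_S2: int = 1
    K_S2: int = 250
    N_C2: int = 6
    step_C2: int = 3
    K_C2: int = 2500
    K_C2group: int = 10
    K_S3: int = 30
    N_S3: int = 6

    def __post_init__(self) -> None:
        if self.K_C1 != self.K_S1 * self.K_C1group:
            raise StructuralError(
                f"K_C1 ({self.K_C1}) must equal K_S1*K_C1group "
                f"({self.K_S1}*{self.K_C1group}): one C1 group per S1 state"
            )
        if self.K_C2 != self.K_S2 * self.K_C2group:
            raise StructuralError(
                f"K_C2 ({self.K_C2}) must equal K_S2*K_C2group "
                f"({self.K_S2}*{self.K_C2group}): one C2 group per S2 state"
            )
        for name in ("C1", "S2", "C2"):
            size = getattr(self, f"N_{name}")
            step = getattr(self, f"step_{name}")
            if step > size:
                raise StructuralError(
                    f"step_{name} ({step}) must not exceed N_{name} ({size})"
                )


@dataclass
class LayerSpec:
    """One layer of the grid: its size, state count and pooling geometry.

    ``rf_size``/``rf_step`` describe how a node of this layer pools the
    layer below (for the input layer they describe the Gabor front end);
    each may be an int (square RF) or a (rows, cols) pair. ``k_group``
    is set on complex layers only: states come in contiguous blocks of
    ``k_group``, one block (group) per state of the child simple layer.
    """

    name: str
    kind: str                  # "simple" | "complex" | "top"
    grid_rows: int
    grid_cols: int
    k_states: int
    rf_size: tuple | int
    rf_step: tuple | int
    k_group: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.rf_size, int):
            self.rf_size = (self.rf_size, self.rf_size)
        else:
            self.rf_size = tuple(self.rf_size)
        if isinstance(self.rf_step, int):
            self.rf_step = (self.rf_step, self.rf_step)
        else:
            self.rf_step = tuple(self.rf_step)

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def n_groups(self) -> int:
        if self.k_group is None:
            raise StructuralError(f"layer {self.name} has no group structure")
        return self.k_states // self.k_group

    def group_of_state(self, state: int) -> int:
        """Group index of a state (contiguous blocks of ``k_group``)."""
        if self.k_group is None:
            raise StructuralError(
                f"group_of_state is only defined on complex layers, "
                f"not {self.name}"
            )
        if not (0 <= state < self.k_states):
            raise IndexError(f"state {state} out of range for {self.name}")
        return state // self.k_group


def build_layers(specs: list[LayerSpec]) -> None:
    """Validate that consecutive layer grids satisfy the RF chain."""
    for child, parent in zip(specs, specs[1:]):
        for axis, (cdim, pdim) in enumerate(
            [(child.grid_rows, parent.grid_rows),
             (child.grid_cols, parent.grid_cols)]
        ):
            expect = parent.rf_step[axis] * (pdim - 1) + parent.rf_size[axis]
            if cdim != expect:
                raise StructuralError(
                    f"grid equation fails between {child.name} and "
                    f"{parent.name} on axis {axis}: child dim {cdim} != "
                    f"step*(parent-1)+size = {expect}"
                )
        if parent.kind == "complex":
            if parent.k_group is None:
                raise StructuralError(f"complex layer {parent.name} needs k_group")
            if parent.n_groups != child.k_states:
                raise StructuralError(
                    f"{parent.name} must have one group per {child.name} state: "
                    f"{parent.n_groups} groups vs {child.k_states} states"
                )


class NetworkModel:
    """The layered network: specs, shared tables and adjacency.

    ``cpts[child_name]`` holds the shared conditional tables of the
    (child layer, parent layer) pair as an array of shape
    ``(rf_size, rf_size, k_child, k_parent)`` -- one ``K_child x K_parent``
    table per relative child position inside a parent's receptive
    field. Tables are uniform (uninformative) until learned; every node
    of a layer references the same array.
    """

    def __init__(self, layers: list[LayerSpec],
                 params: ArchitectureParams | None = None):
        build_layers(layers)
        self.layers = layers
        self.params = params
        self.layer_by_name = {sp.name: sp for sp in layers}
        self.cpts: dict[str, np.ndarray] = {}
        self.trained: dict[str, bool] = {}
        self.prototypes: dict[str, np.ndarray] = {}
        self.categories: list | None = None
        for child, parent in self.pairs():
            nr, nc = parent.rf_size
            self.cpts[child.name] = np.full(
                (nr, nc, child.k_states, parent.k_states),
                1.0 / child.k_states,
            )
            self.trained[child.name] = False

    # -- structure ---------------------------------------------------------

    def pairs(self):
        """(child, parent) LayerSpec pairs, bottom-up."""
        return list(zip(self.layers, self.layers[1:]))

    def layer_index(self, name: str) -> int:
        for i, sp in enumerate(self.layers):
            if sp.name == name:
                return i
        raise KeyError(name)

    def rf_children(self, parent_name: str, node: tuple[int, int]):
        """Row-major child coordinates under a parent node's RF."""
        pi = self.layer_index(parent_name)
        if pi == 0:
            raise StructuralError(f"{parent_name} has no child layer")
        parent = self.layers[pi]
        r, c = node
        if not (0 <= r < parent.grid_rows and 0 <= c < parent.grid_cols):
            raise IndexError(f"node {node} outside {parent_name} grid")
        (nr, nc), (sr, sc) = parent.rf_size, parent.rf_step
        return [(r * sr + i, c * sc + j)
                for i in range(nr) for j in range(nc)]

    def parents_of(self, child_name: str, node: tuple[int, int]):
        """Parent coordinates covering a child node, with the child's
        relative position inside each parent's RF."""
        ci = self.layer_index(child_name)
        if ci == len(self.layers) - 1:
            return []
        parent = self.layers[ci + 1]
        i, j = node
        (nr, nc), (sr, sc) = parent.rf_size, parent.rf_step
        out = []
        for r in range(max(0, -(-(i - nr + 1) // sr)), i // sr + 1):
            if r >= parent.grid_rows:
                continue
            for c in range(max(0, -(-(j - nc + 1) // sc)), j // sc + 1):
                if c >= parent.grid_cols:
                    continue
                out.append(((r, c), (i - r * sr, j - c * sc)))
        return out

    def group_of_state(self, layer_name: str, state: int) -> int:
        return self.layer_by_name[layer_name].group_of_state(state)


def build_network(params: ArchitectureParams | None = None) -> NetworkModel:
    """Construct the default five-layer network from its parameters.

    Grids are sized top-down from the single S3 node; with the default
    parameters this yields C2 6x6, S2 21x21, C1 24x24 and S1 125x125.
    """
    p = params or ArchitectureParams()
    # top-down grid chain
    c2 = p.N_S3  # S3 pools the whole C2 grid
    s2 = p.step_C2 * (c2 - 1) + p.N_C2
    c1 = p.step_S2 * (s2 - 1) + p.N_S2
    s1 = p.step_C1 * (c1 - 1) + p.N_C1
    layers = [
        LayerSpec("S1", "simple", s1, s1, p.K_S1, p.N_S1, 1),
        LayerSpec("C1", "complex", c1, c1, p.K_C1, p.N_C1, p.step_C1,
                  k_group=p.K_C1group),
        LayerSpec("S2", "simple", s2, s2, p.K_S2, p.N_S2, p.step_S2),
        LayerSpec("C2", "complex", c2, c2, p.K_C2, p.N_C2, p.step_C2,
                  k_group=p.K_C2group),
        LayerSpec("S3", "top", 1, 1, p.K_S3, p.N_S3, 1),
    ]
    return NetworkModel(layers, params=p)


# ---------------------------------------------------------------------------
# Model archive: JSON metadata + float64 .npy arrays
# ---------------------------------------------------------------------------

def save_model(model: NetworkModel, path) -> None:
    """Write a model archive directory (JSON metadata + .npy arrays)."""
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "layers": [asdict(sp) for sp in model.layers],
        "params": asdict(model.params) if model.params else None,
        "trained": model.trained,
        "categories": model.categories,
        "prototypes": sorted(model.prototypes),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    for name, arr in model.cpts.items():
        np.save(path / f"cpt_{name}.npy", arr)
    for name, arr in model.prototypes.items():
        np.save(path / f"proto_{name}.npy", arr)


def load_model(path) -> NetworkModel:
    path = pathlib.Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta["schema_version"] != SCHEMA_VERSION:
        raise StructuralError(
            f"unsupported archive schema {meta['schema_version']}"
        )
    layers = [LayerSpec(**d) for d in meta["layers"]]
    params = ArchitectureParams(**meta["params"]) if meta["params"] else None
    model = NetworkModel(layers, params=params)
    for child, _parent in model.pairs():
        model.cpts[child.name] = np.load(path / f"cpt_{child.name}.npy")
    model.trained = meta["trained"]
    model.categories = meta["categories"]
    for name in meta["prototypes"]:
        model.prototypes[name] = np.load(path / f"proto_{name}.npy")
    return model
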