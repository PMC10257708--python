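"""Core containers: node geometry, connectivity matrices, binary rasters.

These are deliberately thin wrappers over numpy arrays — validation plus a
few derived quantities — shared by the generators, the coarse-graining
machinery and the spin model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["NodeGeometry", "ConnectivityMatrix", "BinaryRaster"]

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class NodeGeometry:
    """3D node positions (mm) with optional hemisphere labels.

    ``positions`` is an (N, 3) float array.  Distances are Euclidean;
    coincident nodes are rejected because zero distances break both the EDR
    model and distance-binned correlation functions.
    """

    positions: np.ndarray
    hemisphere_label: np.ndarray | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if pos.shape[0] < 2:
            raise ValueError("need at least 2 nodes")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        if self.hemisphere_label is not None:
            lab = np.asarray(self.hemisphere_label)
            if lab.shape != (pos.shape[0],):
                raise ValueError("hemisphere_label must have one entry per node")
            object.__setattr__(self, "hemisphere_label", lab)
        d = pdist(pos)
        if np.any(d <= 0):
            raise ValueError("coincident nodes (zero pairwise distance)")

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    def distance_matrix(self) -> np.ndarray:
        """Full symmetric matrix of pairwise Euclidean distances (mm)."""
        return squareform(pdist(self.positions))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric non-negative coupling matrix with zero diagonal.

    ``normalized`` marks matrices whose maximum off-diagonal entry is 1
    (weights divided by max(C), the convention used throughout).
    """

    weights: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] < 2:
            raise ValueError("need at least 2 nodes")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not np.allclose(w, w.T, atol=_SYM_TOL, rtol=0):
            raise ValueError("weights must be symmetric (use normalize_connectivity"
                             " to symmetrize noisy input)")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if self.normalized:
            off = w[~np.eye(w.shape[0], dtype=bool)]
            if not np.isclose(off.max(), 1.0):
                raise ValueError("normalized matrix must have max off-diagonal 1")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BinaryRaster:
    """N×T activity raster at coarse-graining level ``level``.

    Level-0 entries are in {0, 1}; a level-k entry is the sum of the 2^k
    original variables in its cluster, hence lies in [0, 2^k].  The number of
    time frames T never changes across levels.
    """

    values: np.ndarray
    level: int = 0

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be an (N, T) array")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.all(v == np.round(v)):
                raise ValueError("raster entries must be integers")
            v = v.astype(np.int64)
        if self.level < 0:
            raise ValueError("level must be >= 0")
        k = 2**self.level
        if v.size and (v.min() < 0 or v.max() > k):
            raise ValueError(f"level-{self.level} entries must lie in [0, {k}]")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def cluster_size(self) -> int:
        return 2**self.level
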