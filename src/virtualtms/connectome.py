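"""Structural connectome containers, I/O and transforms.

A connectome is a weighted, undirected graph over brain regions,
represented by a square symmetric non-negative matrix with zero
diagonal.  Weights are arbitrary tract-count-like units before
normalization and dimensionless afterwards.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "ConnectomeError",
    "NonSquareError",
    "NegativeWeightError",
    "AsymmetryError",
    "SelfLoopError",
    "DuplicateEdgeError",
    "DegenerateMatrixError",
    "read_connectome",
    "write_connectome",
    "node_strength",
    "normalize_connectome",
    "sparsify",
    "distance_correct",
]

#: relative tolerance for the symmetry check, as a fraction of max weight
SYMMETRY_RTOL = 1e-9


class ConnectomeError(ValueError):
    """Base class for connectome validation failures."""


class NonSquareError(ConnectomeError):
    pass


class NegativeWeightError(ConnectomeError):
    pass


class AsymmetryError(ConnectomeError):
    pass


class SelfLoopError(ConnectomeError):
    pass


class DuplicateEdgeError(ConnectomeError):
    pass


class DegenerateMatrixError(ConnectomeError):
    pass


@dataclasses.dataclass(frozen=True)
class Connectome:
    """Square symmetric non-negative weight matrix with region labels.

    Parameters
    ----------
    weights
        ``(N, N)`` non-negative symmetric matrix with zero diagonal.
    region_ids
        ``N`` unique labels, aligned with the matrix rows/columns.
    coordinates
        Optional ``(N, 3)`` region centroid positions in mm.
    """

    weights: np.ndarray
    region_ids: tuple
    coordinates: Optional[np.ndarray] = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NonSquareError(f"weight matrix has shape {w.shape}, expected square")
        n = w.shape[0]
        if len(self.region_ids) != n:
            raise ConnectomeError(
                f"{len(self.region_ids)} region ids for a {n}x{n} matrix"
            )
        if len(set(self.region_ids)) != n:
            dupes = pd.Index(self.region_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ConnectomeError(f"duplicate region ids: {dupes}")
        neg = np.argwhere(w < 0)
        if neg.size:
            i, j = neg[0]
            raise NegativeWeightError(
                f"negative weight {w[i, j]} at "
                f"({self.region_ids[i]}, {self.region_ids[j]})"
            )
        diag = np.diagonal(w)
        if np.any(diag != 0):
            i = int(np.argmax(diag != 0))
            raise SelfLoopError(
                f"nonzero diagonal (self-loop) at region {self.region_ids[i]}"
            )
        wmax = w.max() if w.size else 0.0
        asym = np.abs(w - w.T)
        tol = SYMMETRY_RTOL * max(wmax, 1e-300)
        if asym.size and asym.max() > tol:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise AsymmetryError(
                f"|W[{self.region_ids[i]},{self.region_ids[j]}] - transpose| ="
                f" {asym[i, j]:.3g} exceeds tolerance {tol:.3g}"
            )
        # exact symmetry downstream: average out any sub-tolerance noise
        object.__setattr__(self, "weights", (w + w.T) / 2.0)
        if self.coordinates is not None:
            xyz = np.asarray(self.coordinates, dtype=float)
            if xyz.shape != (n, 3):
                raise ConnectomeError(
                    f"coordinates have shape {xyz.shape}, expected ({n}, 3)"
                )
            object.__setattr__(self, "coordinates", xyz)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def index_of(self, region_id) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise KeyError(f"unknown region id: {region_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.region_ids)
        return pd.DataFrame(self.weights, index=ids, columns=ids)


def read_connectome(path, format: str = "dense") -> Connectome:
    """Read a connectome from a dense matrix or an undirected edge list.

    Dense format: tab-delimited text whose first row and first column hold
    region ids; cell ``(i, j)`` is the weight.  Edge-list format: three
    tab-separated columns ``region_a``, ``region_b``, ``weight`` with one
    row per unordered pair; missing pairs are weight zero.
    """
    path = Path(path)
    if format == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.shape[0] != df.shape[1]:
            raise NonSquareError(
                f"{path}: dense matrix has shape {df.shape}, expected square"
            )
        if list(df.index) != list(df.columns):
            raise ConnectomeError(f"{path}: row ids do not match column ids")
        return Connectome(df.to_numpy(dtype=float), tuple(df.index))
    if format == "edge-list":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if df.shape[1] != 3:
            raise ConnectomeError(
                f"{path}: edge list must have 3 columns, found {df.shape[1]}"
            )
        df.columns = ["region_a", "region_b", "weight"]
        ids = sorted(set(df["region_a"]) | set(df["region_b"]))
        idx = {r: k for k, r in enumerate(ids)}
        n = len(ids)
        w = np.zeros((n, n))
        seen: dict = {}
        for a, b, wt in df.itertuples(index=False):
            wt = float(wt)
            if a == b:
                raise SelfLoopError(f"{path}: self-loop on region {a}")
            if wt < 0:
                raise NegativeWeightError(
                    f"{path}: negative weight {wt} on edge ({a}, {b})"
                )
            key = (min(a, b), max(a, b))
            if key in seen and seen[key] != wt:
                raise DuplicateEdgeError(
                    f"{path}: edge {key} listed with conflicting weights "
                    f"{seen[key]} and {wt}"
                )
            seen[key] = wt
            w[idx[a], idx[b]] = wt
            w[idx[b], idx[a]] = wt
        return Connectome(w, tuple(ids))
    raise ValueError(f"unknown format {format!r}; use 'dense' or 'edge-list'")


def write_connectome(conn: Connectome, path) -> None:
    """Write the dense tab-delimited matrix format."""
    conn.to_frame().to_csv(path, sep="\t")


def node_strength(conn: Connectome) -> pd.Series:
    """Per-region strength s_i = sum_j W_ji, indexed by region id."""
    return pd.Series(
        conn.weights.sum(axis=0), index=list(conn.region_ids), name="strength"
    )


def normalize_connectome(conn: Connectome, mode: str = "global-max") -> Connectome:
    """Rescale weights to dimensionless units.

    ``global-max`` (default) divides by the largest weight, so the output
    maximum is 1 and the operation is idempotent.  ``mean-strength``
    divides by the mean node strength.  Both preserve weight ratios and
    hence the strength heterogeneity the frequency gradient depends on.
    """
    wmax = conn.weights.max()
    if wmax <= 0:
        raise DegenerateMatrixError("cannot normalize an all-zero matrix")
    if mode == "global-max":
        scale = wmax
    elif mode == "mean-strength":
        scale = float(node_strength(conn).mean())
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Connectome(conn.weights / scale, conn.region_ids, conn.coordinates)


def sparsify(conn: Connectome, density: float) -> Connectome:
    """Keep the ``ceil(density * N*(N-1)/2)`` largest undirected edges.

    Ties at the cutoff are broken deterministically by lexicographic
    ``(i, j)`` index order (earlier pairs survive).
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    n = conn.n_regions
    iu, ju = np.triu_indices(n, k=1)
    w = conn.weights[iu, ju]
    n_keep = int(np.ceil(density * n * (n - 1) / 2))
    # stable sort on -w keeps lexicographic (i, j) order among ties
    order = np.argsort(-w, kind="stable")
    keep = order[:n_keep]
    out = np.zeros_like(conn.weights)
    out[iu[keep], ju[keep]] = w[keep]
    out[ju[keep], iu[keep]] = w[keep]
    return Connectome(out, conn.region_ids, conn.coordinates)


def distance_correct(conn: Connectome) -> Connectome:
    """Divide each weight by the Euclidean distance between region centroids.

    Centroid distance stands in for fiber distance, which requires
    tractography geometry.  Unconnected pairs stay zero.
    """
    if conn.coordinates is None:
        raise ConnectomeError("distance correction requires region coordinates")
    xyz = conn.coordinates
    d = np.sqrt(((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=-1))
    connected = conn.weights > 0
    zero_d = connected & (d <= 0)
    if zero_d.any():
        i, j = np.argwhere(zero_d)[0]
        raise ConnectomeError(
            f"zero distance between connected regions "
            f"{conn.region_ids[i]} and {conn.region_ids[j]}"
        )
    out = np.zeros_like(conn.weights)
    np.divide(conn.weights, d, out=out, where=connected)
    return Connectome(out, conn.region_ids, conn.coordinates)
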