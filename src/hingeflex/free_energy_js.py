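"""Free-energy surfaces over collective-variable pairs and Jensen-Shannon
comparison of sampled distributions.

The FES is the Boltzmann inversion F = -kB*T*ln(rho) + F0 of a normalized
2-D histogram of collective variables (here typically radius of gyration
vs. interdomain angle), with F0 chosen so the global minimum sits at zero
and empty bins masked (formally infinite free energy).  Sampled
distributions of different systems are compared with the base-2
Jensen-Shannon divergence — 0 for identical histograms, 1 for disjoint
supports — and summarised by average-linkage dendrograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .model_io import KB_KCAL_MOL_K, ParameterError, StructureError

__all__ = [
    "FESGrid",
    "DivergenceMatrix",
    "histogram2d",
    "free_energy_surface",
    "js_divergence",
    "js_matrix",
    "js_dendrogram",
    "fes_overlay_report",
    "point_in_unmasked_bin",
]


@dataclass(frozen=True)
class FESGrid:
    """2-D free-energy surface over (x, y) collective variables.

    ``density`` sums to 1 over bins; ``free_energy`` is a masked array in
    kcal/mol with minimum 0 and empty bins masked.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray
    free_energy: np.ma.MaskedArray
    temperature: float

    def minimum_bin(self) -> tuple[int, int]:
        """(ix, iy) of the global free-energy minimum (= density maximum)."""
        flat = int(np.argmax(self.density))
        return np.unravel_index(flat, self.density.shape)

    def to_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        rows = []
        for i, x in enumerate(xc):
            for j, y in enumerate(yc):
                f = self.free_energy[i, j]
                rows.append({"x": x, "y": y,
                             "density": self.density[i, j],
                             "free_energy": (np.nan if np.ma.is_masked(f)
                                             else float(f))})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DivergenceMatrix:
    """Symmetric matrix of pairwise JS divergences with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.labels), len(self.labels)):
            raise StructureError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise StructureError("divergence matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise StructureError("divergence matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


def histogram2d(x, y, bins=(40, 40), range=None) -> tuple[np.ndarray,
                                                          np.ndarray,
                                                          np.ndarray]:
    """Normalized 2-D histogram: returns (density, x_edges, y_edges).

    Bins are half-open [lo, hi) with the last bin closed (numpy's
    convention).  Counts are normalized to sum to 1; points outside an
    explicit range raise (out-of-range data must be handled upstream).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ParameterError("empty series")
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if range is not None:
        (xlo, xhi), (ylo, yhi) = range
        n_out = int(np.sum((x < xlo) | (x > xhi) | (y < ylo) | (y > yhi)))
        if n_out:
            raise ParameterError(
                f"{n_out} points fall outside the requested range")
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=range)
    return counts / counts.sum(), x_edges, y_edges


def free_energy_surface(density: np.ndarray, temperature: float = 310.0,
                        x_edges: np.ndarray | None = None,
                        y_edges: np.ndarray | None = None) -> FESGrid:
    """Boltzmann inversion of a normalized density.

    F = -kB*T*ln(rho) + F0, F0 = +kB*T*ln(max rho), so the most populated
    bin has F = 0; empty bins are masked.
    """
    rho = np.asarray(density, dtype=float)
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    if rho.sum() <= 0:
        raise ParameterError("all-zero density")
    if not np.isclose(rho.sum(), 1.0, atol=1e-8):
        rho = rho / rho.sum()
    kT = KB_KCAL_MOL_K * temperature
    mask = rho <= 0
    with np.errstate(divide="ignore"):
        F = -kT * np.log(np.where(mask, 1.0, rho)) + kT * np.log(rho.max())
    F = np.ma.MaskedArray(F, mask=mask)
    nx, ny = rho.shape if rho.ndim == 2 else (rho.shape[0], 1)
    if rho.ndim == 1:
        rho = rho[:, None]
        F = F.reshape(nx, 1)
    if x_edges is None:
        x_edges = np.arange(nx + 1, dtype=float)
    if y_edges is None:
        y_edges = np.arange(ny + 1, dtype=float)
    return FESGrid(x_edges=np.asarray(x_edges, dtype=float),
                   y_edges=np.asarray(y_edges, dtype=float),
                   density=rho, free_energy=F, temperature=temperature)


def js_divergence(P: np.ndarray, Q: np.ndarray, base: float = 2.0,
                  pseudocount: float = 0.0) -> float:
    """Jensen-Shannon divergence between two normalized histograms.

    JS = 1/2 KL(P||M) + 1/2 KL(Q||M) with M = (P+Q)/2, logarithms base 2
    by default so the value lies in [0, 1]; the 0*log0 := 0 convention
    keeps JS(P, P) = 0 exact.  A pseudocount > 0 is added to every bin
    (then renormalized) for sparse-data smoothing when requested.
    """
    P = np.asarray(P, dtype=float).ravel()
    Q = np.asarray(Q, dtype=float).ravel()
    if P.shape != Q.shape:
        raise StructureError("histograms must share one bin geometry")
    if np.any(P < 0) or np.any(Q < 0):
        raise ParameterError("histograms must be non-negative")
    if pseudocount > 0:
        P = P + pseudocount
        Q = Q + pseudocount
    if P.sum() <= 0 or Q.sum() <= 0:
        raise ParameterError("histograms must have positive mass")
    P = P / P.sum()
    Q = Q / Q.sum()
    M = 0.5 * (P + Q)

    def kl(a, m):
        nz = a > 0
        return float(np.sum(a[nz] * (np.log(a[nz]) - np.log(m[nz]))))

    js_nats = 0.5 * kl(P, M) + 0.5 * kl(Q, M)
    js = js_nats / np.log(base)
    return float(np.clip(js, 0.0, 1.0))


def js_matrix(histograms: dict[str, np.ndarray], **kwargs) -> DivergenceMatrix:
    """Pairwise JS divergences of a labelled set of histograms."""
    labels = tuple(histograms)
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = js_divergence(histograms[labels[i]], histograms[labels[j]],
                              **kwargs)
            vals[i, j] = vals[j, i] = d
    return DivergenceMatrix(labels=labels, values=vals)


def js_dendrogram(matrix: DivergenceMatrix) -> tuple[np.ndarray, TreeNode]:
    """Average-linkage clustering of a JS divergence matrix.

    Returns the scipy linkage matrix and the tree (exportable as Newick
    via ``str(tree)`` / ``tree.write``); leaf labels are the matrix labels,
    with ties broken deterministically by scipy's ordering.
    """
    v = matrix.values
    if np.any(~np.isfinite(v)):
        raise ParameterError("divergence matrix contains NaN/inf entries")
    if len(matrix.labels) < 2:
        raise ParameterError("need at least two systems to cluster")
    condensed = squareform(v, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    tree = TreeNode.from_linkage_matrix(Z, list(matrix.labels))
    return Z, tree


def fes_overlay_report(variant: FESGrid, wt: FESGrid) -> dict:
    """Basin locations and marginal CV statistics of a variant vs. WT.

    Reports each system's global-minimum bin center, the density-weighted
    marginal means/SDs of both collective variables, and the variant - WT
    differences.
    """
    if variant.density.shape != wt.density.shape or \
       not np.allclose(variant.x_edges, wt.x_edges) or \
       not np.allclose(variant.y_edges, wt.y_edges):
        raise StructureError("FES grids must share one bin geometry")

    def stats(grid: FESGrid) -> dict:
        xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
        px = grid.density.sum(axis=1)
        py = grid.density.sum(axis=0)
        x_mean = float(np.sum(px * xc))
        y_mean = float(np.sum(py * yc))
        x_sd = float(np.sqrt(max(np.sum(px * xc ** 2) - x_mean ** 2, 0.0)))
        y_sd = float(np.sqrt(max(np.sum(py * yc ** 2) - y_mean ** 2, 0.0)))
        ix, iy = grid.minimum_bin()
        return {"min_bin": (int(ix), int(iy)),
                "min_bin_center": (float(xc[ix]), float(yc[iy])),
                "x_mean": x_mean, "x_sd": x_sd,
                "y_mean": y_mean, "y_sd": y_sd}

    sv, sw = stats(variant), stats(wt)
    return {
        "variant": sv,
        "wt": sw,
        "x_mean_shift": sv["x_mean"] - sw["x_mean"],
        "y_mean_shift": sv["y_mean"] - sw["y_mean"],
        "min_bin_shift": (sv["min_bin"][0] - sw["min_bin"][0],
                          sv["min_bin"][1] - sw["min_bin"][1]),
    }


def point_in_unmasked_bin(grid: FESGrid, x: float, y: float) -> bool:
    """Whether a CV-space point (e.g. the starting structure's (Rg, theta))
    falls inside a sampled (unmasked) bin of the surface."""
    ix = int(np.searchsorted(grid.x_edges, x, side="right")) - 1
    iy = int(np.searchsorted(grid.y_edges, y, side="right")) - 1
    if not (0 <= ix < grid.density.shape[0] and 0 <= iy < grid.density.shape[1]):
        return False
    return not bool(np.ma.is_masked(grid.free_energy[ix, iy]))
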