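"""Model-to-data similarity of temporal-signature distributions.

The (TAU, LAT) cloud of a neuronal population is summarised by a bivariate
normal-kernel density on a fixed shared grid; agreement between a model
population N and a reference (data) population U is the normalised Frobenius
inner product S(U, N) = <U, N>_F / (||U||_F ||N||_F), in [0, 1]. The overall
network similarity weights excitatory/RS and inhibitory/FS comparisons by
the cortical excitatory fraction: S = 0.8 S_RS,Exc + 0.2 S_FS,Inh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SignatureDensity",
    "bivariate_density",
    "cellular_similarity",
    "network_similarity",
    "overall_similarity",
    "best_fit_from_map",
    "P_EXC",
    "RATE_CEILING_HZ",
]

P_EXC = 0.8
RATE_CEILING_HZ = 20.0   # models firing above this are unrealistically fast
TAU_GRID = (0.0, 1000.0)
LAT_GRID = (0.0, 300.0)
GRID_N = 200


@dataclass(frozen=True)
class SignatureDensity:
    """Normalised bivariate density of (TAU, LAT) on a fixed grid."""

    tau_grid: np.ndarray     # (GRID_N,) ms
    lat_grid: np.ndarray     # (GRID_N,) ms
    density: np.ndarray      # (GRID_N, GRID_N), rows = TAU, cols = LAT
    bandwidth: float         # KDE scaling factor actually used
    tag: str = ""

    @property
    def cell_area(self) -> float:
        return float(
            (self.tau_grid[1] - self.tau_grid[0])
            * (self.lat_grid[1] - self.lat_grid[0])
        )

    def value_at(self, tau: float, lat: float) -> float:
        """Nearest-grid-cell density; 0 (with the caller warned) off-grid."""
        if not (self.tau_grid[0] <= tau <= self.tau_grid[-1]
                and self.lat_grid[0] <= lat <= self.lat_grid[-1]):
            return 0.0
        i = int(np.argmin(np.abs(self.tau_grid - tau)))
        j = int(np.argmin(np.abs(self.lat_grid - lat)))
        return float(self.density[i, j])


def bivariate_density(
    points: np.ndarray,
    tag: str = "",
    grid_n: int = GRID_N,
    bw_method: str | float = "scott",
) -> SignatureDensity:
    """Gaussian-kernel density of (TAU, LAT) points on the shared grid.

    ``points`` is (n, 2) with TAU in [0, 1000] ms and LAT in [0, 300] ms;
    at least 10 points and non-degenerate spread in both coordinates are
    required. Bandwidth follows Scott's rule unless overridden. The result
    is renormalised to unit Riemann sum over the grid.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) = (TAU, LAT)")
    if len(pts) < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(pts[:, 0]) == 0 or np.ptp(pts[:, 1]) == 0:
        raise ValueError("degenerate (zero-variance) point cloud")
    kde = stats.gaussian_kde(pts.T, bw_method=bw_method)
    tau = np.linspace(*TAU_GRID, grid_n)
    lat = np.linspace(*LAT_GRID, grid_n)
    TT, LL = np.meshgrid(tau, lat, indexing="ij")
    dens = kde(np.vstack([TT.ravel(), LL.ravel()])).reshape(grid_n, grid_n)
    cell = (tau[1] - tau[0]) * (lat[1] - lat[0])
    total = dens.sum() * cell
    if total <= 0:
        raise ValueError("density vanished on the grid")
    return SignatureDensity(tau, lat, dens / total, float(kde.factor), tag)


def cellular_similarity(
    reference: SignatureDensity,
    model_point: tuple[float, float],
    mean_rate: float,
) -> tuple[float, bool]:
    """Similarity of a single-cell model to a reference cortex.

    Returns ``(value, discarded)``: the reference probability density at the
    model's (TAU, LAT), and whether the model is discarded for firing above
    the 20 Hz realism ceiling.
    """
    discarded = mean_rate > RATE_CEILING_HZ
    tau, lat = model_point
    val = reference.value_at(tau, lat)
    if val == 0.0:
        import warnings

        if not (reference.tau_grid[0] <= tau <= reference.tau_grid[-1]
                and reference.lat_grid[0] <= lat <= reference.lat_grid[-1]):
            warnings.warn("model point off the density grid; similarity 0")
    return val, discarded


def network_similarity(U: SignatureDensity, N: SignatureDensity) -> float:
    """Normalised Frobenius inner product of two signature densities."""
    if U.density.shape != N.density.shape or not np.allclose(
        U.tau_grid, N.tau_grid
    ) or not np.allclose(U.lat_grid, N.lat_grid):
        raise ValueError("densities must share the same grid")
    num = float(np.sum(U.density * N.density))
    den = float(np.linalg.norm(U.density) * np.linalg.norm(N.density))
    if den == 0:
        return 0.0
    return num / den


def overall_similarity(
    s_rs_exc: float, s_fs_inh: float, p_exc: float = P_EXC
) -> float:
    """Population-weighted similarity: p_Exc S_RS,Exc + (1 - p_Exc) S_FS,Inh."""
    return p_exc * s_rs_exc + (1.0 - p_exc) * s_fs_inh


def best_fit_from_map(
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    similarity_map: np.ndarray,
    level: float = 0.8,
) -> tuple[float, float]:
    """Parameter values of the best fit on a similarity map.

    The region within ``level`` (default 80%) of the map maximum is
    delimited and the coordinates of its similarity-weighted average
    returned; used to place the area presets in conductance space.
    """
    m = np.asarray(similarity_map, dtype=float)
    mask = m >= level * m.max()
    XX, YY = np.meshgrid(grid_x, grid_y, indexing="ij")
    w = np.where(mask, m, 0.0)
    tot = w.sum()
    return float((XX * w).sum() / tot), float((YY * w).sum() / tot)
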