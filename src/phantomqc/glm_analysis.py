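"""Block-design GLM t-maps with voxelwise threshold and cluster-extent rule.

The phantom switches its stimulus current instantaneously and has no
hemodynamics, so the activation regressor is a pure boxcar (no HRF
convolution).  Each voxel is fit by ordinary least squares against
[boxcar, intercept, linear drift]; the map of t = beta / SE(beta) for the
boxcar column is thresholded two-sided at a Student-t quantile and
surviving voxels are grouped into positive and negative clusters with 2D
4-connectivity within each slice, discarding clusters below the extent
threshold (the conventional p = 0.05, cluster >= 5 rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .epi_simulator import AcquisitionParams, BlockDesign, TimeSeries4D, current_waveform
from .exceptions import ConfigurationError, InputError

#: t value reported for voxels with (numerically) zero residual variance.
T_SATURATED = 1e6

#: In-plane 4-connectivity; slices are clustered independently.
_STRUCTURE_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class DesignMatrix:
    """OLS design: columns [boxcar, intercept, (drift)]."""

    X: np.ndarray
    names: tuple[str, ...]

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))


@dataclass
class TMap:
    """Voxelwise t-statistics for the boxcar regressor."""

    t: np.ndarray  # (nx, ny, nz)
    beta: np.ndarray  # (nx, ny, nz), boxcar effect size
    dof: int
    n_saturated: int = 0


@dataclass(frozen=True)
class Cluster:
    sign: int  # +1 positive activation, -1 negative
    size: int
    peak_t: float
    peak_ijk: tuple[int, int, int]


@dataclass
class ClusterTable:
    clusters: list[Cluster]
    p_threshold: float
    t_critical: float
    min_cluster: int

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sign": "positive" if c.sign > 0 else "negative",
                    "size_voxels": c.size,
                    "peak_t": c.peak_t,
                    "peak_x": c.peak_ijk[0],
                    "peak_y": c.peak_ijk[1],
                    "peak_slice": c.peak_ijk[2],
                }
                for c in self.clusters
            ],
            columns=["sign", "size_voxels", "peak_t", "peak_x", "peak_y", "peak_slice"],
        )


def build_design(
    design: BlockDesign,
    acq: AcquisitionParams,
    include_drift: bool = True,
) -> DesignMatrix:
    """Boxcar + intercept (+ linear drift) design matrix.

    The boxcar is 1 on active volumes regardless of the current level and
    0 at baseline.  Designs without both states are rank deficient (the
    boxcar collapses into the intercept) and rejected.
    """
    wave = current_waveform(design, acq)
    boxcar = (wave > 0).astype(float)
    cols = [boxcar, np.ones(acq.n_volumes)]
    names = ["boxcar", "intercept"]
    if include_drift:
        cols.append(np.linspace(-1.0, 1.0, acq.n_volumes))
        names.append("drift")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigurationError(
            "design matrix is rank deficient (no baseline/active contrast)"
        )
    return DesignMatrix(X=X, names=tuple(names))


def fit_glm(series: TimeSeries4D, dm: DesignMatrix) -> TMap:
    """Voxelwise OLS fit; t = beta_boxcar / SE(beta_boxcar).

    Voxels with zero residual variance (noise-free constants or exact
    regressor copies) are flagged as saturated: their t is capped at
    ±``T_SATURATED`` instead of raising.
    """
    X = dm.X
    n, p = X.shape
    if series.n_volumes != n:
        raise InputError(
            f"series has {series.n_volumes} volumes but the design expects {n}"
        )
    rank = dm.rank
    dof = n - rank
    if dof < 1:
        raise ConfigurationError("no residual degrees of freedom")
    shape3 = series.shape[:3]
    Y = series.data.reshape(-1, n).T  # (n, nvox)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # (p, nvox)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
    saturated = sigma2 <= 1e-24 * scale
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[0, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[0] / se
    t[saturated] = np.sign(beta[0][saturated]) * T_SATURATED
    t[np.isnan(t)] = 0.0
    return TMap(
        t=t.reshape(shape3),
        beta=beta[0].reshape(shape3),
        dof=dof,
        n_saturated=int(saturated.sum()),
    )


def t_critical(dof: int, p_threshold: float) -> float:
    """Two-sided Student-t critical value at the map's degrees of freedom."""
    return float(stats.t.ppf(1.0 - p_threshold / 2.0, dof))


def _label_slicewise(mask3d: np.ndarray) -> tuple[np.ndarray, int]:
    labels = np.zeros(mask3d.shape, dtype=int)
    total = 0
    for z in range(mask3d.shape[2]):
        lab, n = ndimage.label(mask3d[:, :, z], structure=_STRUCTURE_2D)
        lab[lab > 0] += total
        labels[:, :, z] = lab
        total += n
    return labels, total


def threshold_and_cluster(
    tmap: TMap,
    p_threshold: float = 0.05,
    min_cluster: int = 5,
) -> ClusterTable:
    """Two-sided threshold then cluster-extent filtering.

    Positive and negative suprathreshold voxels are clustered separately
    under in-plane 4-connectivity; clusters smaller than ``min_cluster``
    voxels are discarded.
    """
    if tmap.dof < 1:
        raise InputError("invalid degrees of freedom")
    tcrit = t_critical(tmap.dof, p_threshold)
    clusters: list[Cluster] = []
    for sign, mask in ((+1, tmap.t > tcrit), (-1, tmap.t < -tcrit)):
        labels, n = _label_slicewise(mask)
        for lab in range(1, n + 1):
            idx = np.argwhere(labels == lab)
            if len(idx) < min_cluster:
                continue
            vals = tmap.t[labels == lab]
            peak_pos = idx[np.argmax(sign * vals)]
            clusters.append(
                Cluster(
                    sign=sign,
                    size=len(idx),
                    peak_t=float(vals[np.argmax(sign * vals)]),
                    peak_ijk=tuple(int(v) for v in peak_pos),
                )
            )
    clusters.sort(key=lambda c: (-c.sign, -abs(c.peak_t)))
    return ClusterTable(
        clusters=clusters,
        p_threshold=p_threshold,
        t_critical=tcrit,
        min_cluster=min_cluster,
    )
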