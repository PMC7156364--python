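"""Magnetic field of current-carrying straight wires on an axial voxel grid.

The phantom embeds enamelled copper wires, parallel to the scanner bore
(and hence to B0), in agarose gel.  Driving a current I through a wire of
radius ``a`` induces an azimuthal magnetic field that is everywhere
perpendicular to B0:

    B(r) = mu0 * I * r / (2 pi a^2)        r <  a   (inside the wire)
    B(r) = mu_rel * mu0 * I / (2 pi r)     r >= a   (outside, in gel)

with ``r`` the in-plane distance from the wire axis and ``mu_rel`` the
relative permeability of the gel (≈ 1 for agarose).  Wires are modelled as
infinite straight conductors, so the field is invariant along the bore and
a single axial map serves every slice.

Superposition: the per-wire fields are parallel-transported azimuthal
vectors; they are summed as signed in-plane vector components (sign from
the current direction relative to B0) before the magnitude is taken, which
reduces exactly to the scalar formula for a single wire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InputError

#: Vacuum permeability, T·m/A.
MU0 = 4.0e-7 * np.pi


@dataclass(frozen=True)
class WireSpec:
    """A straight wire crossing the axial plane.

    Parameters
    ----------
    position_mm:
        (x, y) of the wire axis in the axial plane, millimetres, origin at
        the cylinder axis.
    radius_a_mm:
        Wire radius ``a`` in millimetres (default 0.5 mm: 1 mm diameter
        enamelled copper).
    direction_sign:
        +1 for current parallel to B0, -1 for antiparallel.
    connected:
        Whether the wire is part of the stimulus circuit.  Unconnected
        wires carry no current and contribute no field.
    """

    position_mm: tuple[float, float]
    radius_a_mm: float = 0.5
    direction_sign: int = 1
    connected: bool = False

    def __post_init__(self):
        if self.radius_a_mm <= 0:
            raise ConfigurationError(f"wire radius must be > 0, got {self.radius_a_mm}")
        if self.direction_sign not in (+1, -1):
            raise ConfigurationError(
                f"direction_sign must be +1 or -1, got {self.direction_sign}"
            )


@dataclass(frozen=True)
class GelProperties:
    """Relaxation times and permeability of the agarose gel compartment.

    Defaults are the peripheral-region relaxometry of the doped agarose
    recipe (T1 1409.8 ms, T2 292.5 ms, T2* 121.3 ms); mu_rel defaults to 1
    because agarose diamagnetism is negligible at this precision.
    """

    T1_ms: float = 1409.8
    T2_ms: float = 292.5
    T2star_ms: float = 121.3
    mu_rel: float = 1.0

    def __post_init__(self):
        for name in ("T1_ms", "T2_ms", "T2star_ms"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if abs(self.mu_rel - 1.0) > 1e-4:
            raise ConfigurationError(
                f"mu_rel must lie within 1 ± 1e-4 for agarose, got {self.mu_rel}"
            )


def default_wires(
    pitch_mm: float = 25.0,
    radius_a_mm: float = 0.5,
    connected_index: int = 2,
) -> tuple[WireSpec, ...]:
    """Four wires on a line through the cylinder axis at the given pitch.

    Positions are x = (-1.5, -0.5, +0.5, +1.5) × pitch, y = 0.  By default
    only the wire at +0.5 × pitch is connected to the stimulus circuit; the
    mirror wire at -0.5 × pitch acts as the unconnected control.
    """
    xs = (np.arange(4) - 1.5) * pitch_mm
    return tuple(
        WireSpec(
            position_mm=(float(x), 0.0),
            radius_a_mm=radius_a_mm,
            connected=(i == connected_index),
        )
        for i, x in enumerate(xs)
    )


@dataclass(frozen=True)
class PhantomGeometry:
    """Gel cylinder plus embedded wires.

    The default mirrors a 14 cm inner-diameter cylinder with four 1 mm
    wires at 2.5 cm pitch, one of them in the stimulus circuit.
    """

    cylinder_radius_mm: float = 70.0
    wires: tuple[WireSpec, ...] = field(default_factory=default_wires)
    gel: GelProperties = field(default_factory=GelProperties)

    def __post_init__(self):
        if self.cylinder_radius_mm <= 0:
            raise ConfigurationError("cylinder_radius_mm must be > 0")
        if not self.wires:
            raise ConfigurationError("geometry must contain at least one wire")
        for w in self.wires:
            r = float(np.hypot(*w.position_mm))
            if r >= self.cylinder_radius_mm:
                raise ConfigurationError(
                    f"wire at {w.position_mm} lies outside the cylinder "
                    f"(radius {self.cylinder_radius_mm} mm)"
                )

    @property
    def connected_wires(self) -> tuple[WireSpec, ...]:
        return tuple(w for w in self.wires if w.connected)


@dataclass(frozen=True)
class FieldMap:
    """Induced-field magnitudes (Tesla) sampled at voxel centers.

    ``values[i, j]`` corresponds to the in-plane position
    ``((i - (nx-1)/2) * sx, (j - (ny-1)/2) * sy)`` mm, origin on the
    cylinder axis.
    """

    values: np.ndarray  # (nx, ny), Tesla, magnitudes >= 0
    spacing_mm: tuple[float, float]

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-center coordinate vectors (x_mm, y_mm)."""
        nx, ny = self.values.shape
        sx, sy = self.spacing_mm
        x = (np.arange(nx) - (nx - 1) / 2.0) * sx
        y = (np.arange(ny) - (ny - 1) / 2.0) * sy
        return x, y


def induced_field_point(
    current_A: float,
    wire: WireSpec,
    r_m,
    mu0: float = MU0,
    mu_rel: float = 1.0,
):
    """Field magnitude (T) at distance ``r_m`` (metres) from one wire axis.

    Piecewise linear-in-r inside the conductor, 1/r outside; continuous at
    the surface when mu_rel = 1.  Vectorized over ``r_m``.
    """
    if not np.isfinite(current_A):
        raise InputError("current_A must be finite")
    r = np.asarray(r_m, dtype=float)
    if np.any(r < 0):
        raise InputError("distance r_m must be >= 0")
    a_m = wire.radius_a_mm * 1e-3
    if a_m <= 0:
        raise ConfigurationError("wire radius must be > 0")
    if current_A == 0.0:
        return np.zeros_like(r) if r.ndim else 0.0
    inside = mu0 * abs(current_A) * r / (2.0 * np.pi * a_m**2)
    with np.errstate(divide="ignore"):
        outside = mu_rel * mu0 * abs(current_A) / (2.0 * np.pi * np.maximum(r, a_m))
    out = np.where(r < a_m, inside, outside)
    return float(out) if out.ndim == 0 else out


def _field_vectors(
    geometry: PhantomGeometry,
    current_A: float,
    x_mm: np.ndarray,
    y_mm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed in-plane field components (Bx, By) summed over connected wires.

    For a wire along +z the field at offset (dx, dy) points along the
    azimuthal unit vector (-dy, dx)/r (right-hand rule); direction_sign
    flips it for antiparallel current.
    """
    bx = np.zeros(np.broadcast(x_mm, y_mm).shape, dtype=float)
    by = np.zeros_like(bx)
    if current_A == 0.0:
        return bx, by
    for w in geometry.connected_wires:
        dx = (x_mm - w.position_mm[0]) * 1e-3
        dy = (y_mm - w.position_mm[1]) * 1e-3
        r = np.hypot(dx, dy)
        mag = induced_field_point(current_A, w, r, mu_rel=geometry.gel.mu_rel)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(r > 0, -dy / np.maximum(r, 1e-300), 0.0)
            uy = np.where(r > 0, dx / np.maximum(r, 1e-300), 0.0)
        s = float(w.direction_sign) * np.sign(current_A)
        bx += s * mag * ux
        by += s * mag * uy
    return bx, by


def field_magnitude(
    geometry: PhantomGeometry, current_A: float, x_mm, y_mm
) -> np.ndarray:
    """Superposed field magnitude (T) at arbitrary in-plane points (mm)."""
    bx, by = _field_vectors(
        geometry, current_A, np.asarray(x_mm, float), np.asarray(y_mm, float)
    )
    return np.hypot(bx, by)


def field_map_grid(
    geometry: PhantomGeometry,
    current_A: float,
    n: tuple[int, int] = (64, 64),
    spacing_mm: tuple[float, float] = (3.75, 3.75),
) -> FieldMap:
    """Superposed field magnitude over a voxel-center grid.

    The grid is centred on the cylinder axis; ``n`` and ``spacing_mm``
    normally come from the EPI matrix and FOV (240 mm / 64 = 3.75 mm).
    """
    if not geometry.wires:
        raise ConfigurationError("geometry must contain at least one wire")
    nx, ny = n
    sx, sy = spacing_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    values = field_magnitude(geometry, current_A, xx, yy)
    return FieldMap(values=values, spacing_mm=(float(sx), float(sy)))


def field_span_map(
    geometry: PhantomGeometry,
    current_A: float,
    n: tuple[int, int] = (64, 64),
    spacing_mm: tuple[float, float] = (3.75, 3.75),
    subgrid: int = 5,
) -> np.ndarray:
    """Intra-voxel field range (max - min, Tesla) on a q×q subgrid per voxel.

    This is the inhomogeneity span that drives intra-voxel dephasing in the
    EPI simulator.  ``subgrid`` = 5 converges well for 1/r fields at
    3.75 mm voxels.
    """
    if subgrid < 1:
        raise ConfigurationError("subgrid must be >= 1")
    nx, ny = n
    sx, sy = spacing_mm
    q = subgrid
    offs_x = (np.arange(q) - (q - 1) / 2.0) / q * sx
    offs_y = (np.arange(q) - (q - 1) / 2.0) / q * sy
    cx = (np.arange(nx) - (nx - 1) / 2.0) * sx
    cy = (np.arange(ny) - (ny - 1) / 2.0) * sy
    fx = (cx[:, None] + offs_x[None, :]).ravel()
    fy = (cy[:, None] + offs_y[None, :]).ravel()
    xx, yy = np.meshgrid(fx, fy, indexing="ij")
    mag = field_magnitude(geometry, current_A, xx, yy)
    mag = mag.reshape(nx, q, ny, q)
    return mag.max(axis=(1, 3)) - mag.min(axis=(1, 3))


def wire_occupancy_mask(
    geometry: PhantomGeometry,
    n: tuple[int, int] = (64, 64),
    spacing_mm: tuple[float, float] = (3.75, 3.75),
) -> np.ndarray:
    """Boolean (nx, ny) mask of voxels whose footprint overlaps any wire.

    Copper yields no MR signal, so these voxels are blanked by the
    simulator regardless of whether the wire is connected.  Overlap uses
    the separating-axis test between the voxel rectangle and the wire's
    bounding square (adequate at wire radii ≪ voxel size).
    """
    nx, ny = n
    sx, sy = spacing_mm
    cx = (np.arange(nx) - (nx - 1) / 2.0) * sx
    cy = (np.arange(ny) - (ny - 1) / 2.0) * sy
    mask = np.zeros((nx, ny), dtype=bool)
    for w in geometry.wires:
        hit_x = np.abs(cx - w.position_mm[0]) < (sx / 2.0 + w.radius_a_mm)
        hit_y = np.abs(cy - w.position_mm[1]) < (sy / 2.0 + w.radius_a_mm)
        mask |= hit_x[:, None] & hit_y[None, :]
    return mask


def cylinder_mask(
    geometry: PhantomGeometry,
    n: tuple[int, int] = (64, 64),
    spacing_mm: tuple[float, float] = (3.75, 3.75),
) -> np.ndarray:
    """Boolean (nx, ny) mask of voxel centers inside the gel cylinder."""
    nx, ny = n
    sx, sy = spacing_mm
    cx = (np.arange(nx) - (nx - 1) / 2.0) * sx
    cy = (np.arange(ny) - (ny - 1) / 2.0) * sy
    rr = np.hypot(cx[:, None], cy[None, :])
    return rr <= geometry.cylinder_radius_mm


def field_map_to_csv(fmap: FieldMap, path) -> None:
    """Dump a field map as a plain CSV grid (rows = x index)."""
    np.savetxt(path, fmap.values, delimiter=",")


def field_map_to_nifti(fmap: FieldMap, path) -> None:
    """Write a field map as a single-volume float NIfTI-1 image."""
    import nibabel as nib

    sx, sy = fmap.spacing_mm
    affine = np.diag([sx, sy, 1.0, 1.0])
    img = nib.Nifti1Image(fmap.values[..., None].astype(np.float32), affine)
    img.header.set_zooms((sx, sy, 1.0))
    nib.save(img, str(path))
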