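"""Multi-slice forward model: transmission and reflection matrices.

The medium is a stack of thin phase screens separated by free space.  A
downward pass from the surface at ``z_N`` to the object plane at ``z_0`` is
the ordered product ``T = T_1 T_2 ... T_N`` with ``T_k = P_{z_{k-1}, z_k}
Phi_k``; the time-gated roundtrip response is ``R = T^T O T`` with ``O`` the
diagonal object reflectance.  Time gating enters only as the modeling
assumption that intra-medium back-reflections are absent — the gated regime
is what makes the single-object-plane roundtrip model valid — so it is
carried as matrix metadata, not simulated temporally.

Matrices are dense (the reference representation); the heavy lifting of
multiplying by propagation operators is done implicitly with batched FFTs,
which agrees with the dense operators to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import (FieldGrid, PropagationOperator, ReflectionMatrix,
                     TransmissionMatrix, ValidationError, propagation_matrix)
from .synthesis import MediumModel, ObjectMap, PhasePlate


# --------------------------------------------------------------------------
# batched helpers: operate on an (n^2, n^2) matrix without dense products
# --------------------------------------------------------------------------

def _prop_cols(values: np.ndarray, grid: FieldGrid, distance: float,
               conjugate: bool = False) -> np.ndarray:
    """Left-multiply by the propagator: propagate every column field."""
    n = grid.n
    fields = values.T.reshape(n * n, n, n)   # batch over columns
    op = PropagationOperator(grid, 0.0, distance)
    out = op.apply(fields, conjugate=conjugate)
    return out.reshape(n * n, n * n).T


def _prop_rows(values: np.ndarray, grid: FieldGrid, distance: float,
               conjugate: bool = False) -> np.ndarray:
    """Right-multiply by the (symmetric) propagator: act on row index fields."""
    n = grid.n
    fields = values.reshape(n * n, n, n)     # batch over rows
    op = PropagationOperator(grid, 0.0, distance)
    out = op.apply(fields, conjugate=conjugate)
    return out.reshape(n * n, n * n)


def _diag_right(values: np.ndarray, phase_factor: np.ndarray) -> np.ndarray:
    """Right-multiply by diag(phase_factor) (phase_factor is (n, n))."""
    return values * phase_factor.ravel()[None, :]


def _diag_left(values: np.ndarray, phase_factor: np.ndarray) -> np.ndarray:
    return values * phase_factor.ravel()[:, None]


def apply_medium(values: np.ndarray, medium: MediumModel,
                 inverse: bool = False) -> np.ndarray:
    """Apply T (surface -> object) — or its structural inverse — to columns.

    ``values`` is (n^2, m): m vectorized input fields at the surface plane
    (or at the object plane for the inverse).  The inverse is the reversed
    product of conjugated unitary factors, never a numeric matrix inversion.
    """
    grid = medium.grid
    n = grid.n
    fields = values.T.reshape(-1, n, n)
    plates = medium.plates
    depths = [0.0] + [p.depth for p in plates]
    if not inverse:
        # input at z_N: plate N first, then propagate gap by gap down to z0
        for k in range(len(plates) - 1, -1, -1):
            fields = fields * plates[k].transmittance().astype(fields.dtype)
            d = depths[k + 1] - depths[k]
            fields = PropagationOperator(grid, 0.0, d).apply(fields)
    else:
        for k in range(len(plates)):
            d = depths[k + 1] - depths[k]
            fields = PropagationOperator(grid, 0.0, d).apply(fields,
                                                             conjugate=True)
            fields = fields * np.conj(
                plates[k].transmittance().astype(fields.dtype))
    return fields.reshape(-1, n * n).T


# --------------------------------------------------------------------------
# matrix builders
# --------------------------------------------------------------------------

def layer_transmission(plate: PhasePlate,
                       propagation: PropagationOperator) -> TransmissionMatrix:
    """Single-layer factor ``T_k = P * Phi_k`` as a dense matrix."""
    grid = propagation.grid
    if plate.phase_map.shape != (grid.n, grid.n):
        raise ValidationError("plate and propagation operator grids differ")
    vals = _diag_right(propagation.as_matrix(), plate.transmittance())
    return TransmissionMatrix(values=vals, grid=grid,
                              input_plane=plate.depth,
                              output_plane=plate.depth - abs(propagation.distance),
                              provenance="ground_truth")


def medium_transmission(medium: MediumModel) -> TransmissionMatrix:
    """Dense ground-truth ``T`` from the surface plane to the object plane."""
    n2 = medium.grid.n ** 2
    vals = apply_medium(np.eye(n2, dtype=complex), medium)
    return TransmissionMatrix(values=vals, grid=medium.grid,
                              input_plane=medium.surface_depth,
                              output_plane=0.0, provenance="ground_truth")


def reflection_from_medium(medium: MediumModel, obj: ObjectMap,
                           reference_plane: str = "z0") -> ReflectionMatrix:
    """Time-gated roundtrip matrix ``R = T^T O T`` of medium plus object.

    With ``reference_plane="zN"`` both indices sit at the medium surface;
    with ``"z0"`` the matrix is conjugate-back-propagated on both sides to
    the object plane, the form delivered by a focus-scanned measurement.
    """
    if obj.grid is not medium.grid and obj.grid != medium.grid:
        raise ValidationError("object and medium grids differ")
    if reference_plane not in ("z0", "zN"):
        raise ValidationError(f"unknown reference plane {reference_plane!r}")
    grid = medium.grid
    n2 = grid.n ** 2
    t = apply_medium(np.eye(n2, dtype=complex), medium)
    r = t.T @ _diag_left(t, obj.amplitude_reflectance)
    z_n = medium.surface_depth
    plane = z_n
    if reference_plane == "z0" and z_n > 0:
        r = _prop_cols(r, grid, z_n, conjugate=True)
        r = _prop_rows(r, grid, z_n, conjugate=True)
        plane = 0.0
    elif reference_plane == "z0":
        plane = 0.0
    return ReflectionMatrix(values=r, grid=grid, input_plane=plane,
                            output_plane=plane, time_gated=True)


def add_background_scattering(r: ReflectionMatrix, relative_power: float,
                              correlation_length: float,
                              seed: int) -> ReflectionMatrix:
    """Superimpose object-uncorrelated clutter of the given relative power.

    Emulates the roundtrip multiple scattering that never visits the object
    plane: a symmetric random complex matrix, correlated over
    ``correlation_length`` in both the detection and illumination images,
    scaled to ``relative_power`` times the power of ``r``.
    """
    if relative_power < 0:
        raise ValidationError("relative_power must be non-negative")
    out = r.copy()
    if relative_power == 0:
        return out
    rng = np.random.default_rng(seed)
    n = r.grid.n
    w = (rng.standard_normal((n, n, n, n))
         + 1j * rng.standard_normal((n, n, n, n)))
    kx, ky = r.grid.kgrid()
    filt = np.exp(-(kx * kx + ky * ky) * correlation_length ** 2 / 8.0)
    w = np.fft.ifft2(np.fft.fft2(w, axes=(0, 1)) * filt[:, :, None, None],
                     axes=(0, 1))
    w = np.fft.ifft2(np.fft.fft2(w, axes=(2, 3)) * filt[None, None, :, :],
                     axes=(2, 3))
    m = w.reshape(n * n, n * n)
    m = 0.5 * (m + m.T)                       # keep roundtrip reciprocity
    power = np.sum(np.abs(m) ** 2)
    target = relative_power * np.sum(np.abs(r.values) ** 2)
    m *= np.sqrt(target / power)
    out.values = out.values + m
    return out


# --------------------------------------------------------------------------
# scan-frame assembly
# --------------------------------------------------------------------------

@dataclass
class ScanStack:
    """Per-scan-position complex field images in the descanned frame.

    ``images[m]`` is the (n, n) field recorded while illuminating scan
    position ``positions[m]`` (integer lattice indices).  A full stack has
    ``n^2`` positions covering the ROI exactly once.
    """

    grid: FieldGrid
    images: np.ndarray             # (n^2, n, n) complex
    positions: np.ndarray          # (n^2, 2) int lattice indices

    def __post_init__(self) -> None:
        n = self.grid.n
        self.images = np.asarray(self.images, dtype=complex)
        self.positions = np.asarray(self.positions)
        if self.images.shape != (n * n, n, n):
            raise ValidationError(
                f"expected ({n * n}, {n}, {n}) images, got {self.images.shape}")
        if self.positions.shape != (n * n, 2):
            raise ValidationError("positions must be (n^2, 2)")
        if not np.issubdtype(self.positions.dtype, np.integer):
            if not np.allclose(self.positions, np.round(self.positions)):
                raise ValidationError("scan positions are off-lattice")
            self.positions = np.round(self.positions).astype(int)
        seen = {tuple(p) for p in self.positions.tolist()}
        if len(seen) != n * n or any(
                not (0 <= i < n and 0 <= j < n) for i, j in seen):
            raise ValidationError("positions must cover the ROI exactly once")


def assemble_from_scan(stack: ScanStack) -> ReflectionMatrix:
    """Columns of R from laterally registered scan images.

    Each descanned image is shifted into the laboratory frame by its scan
    position relative to the ROI center, vectorized, and placed in the
    column addressed by that position.
    """
    grid = stack.grid
    n = grid.n
    ci, cj = grid.center_index
    vals = np.empty((n * n, n * n), dtype=complex)
    for img, (i, j) in zip(stack.images, stack.positions):
        lab = np.roll(img, shift=(i - ci, j - cj), axis=(0, 1))
        vals[:, i * n + j] = lab.ravel()
    return ReflectionMatrix(values=vals, grid=grid, input_plane=0.0,
                            output_plane=0.0, time_gated=True)


def synthesize_scan(r: ReflectionMatrix) -> ScanStack:
    """Inverse of :func:`assemble_from_scan` (exact round trip)."""
    grid = r.grid
    n = grid.n
    ci, cj = grid.center_index
    positions = np.stack(np.unravel_index(np.arange(n * n), (n, n)), axis=1)
    images = np.empty((n * n, n, n), dtype=complex)
    for m, (i, j) in enumerate(positions):
        lab = r.values[:, i * n + j].reshape(n, n)
        images[m] = np.roll(lab, shift=(ci - i, cj - j), axis=(0, 1))
    return ScanStack(grid=grid, images=images, positions=positions)


def confocal_image(r: ReflectionMatrix, amplitude: bool = False) -> np.ndarray:
    """Confocal image from the diagonal of an object-plane matrix."""
    if r.basis != "space":
        raise ValidationError("confocal image requires the space basis")
    if r.input_plane != r.output_plane:
        raise ValidationError("confocal image requires equal reference planes")
    diag = r.diagonal_image()
    return np.abs(diag) if amplitude else np.abs(diag) ** 2
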