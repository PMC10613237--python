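"""Grids, angular-spectrum propagation and basis changes.

Everything downstream — the multi-slice forward model, the scattering-tracing
loop and the ballistic metrics — is expressed on a single square lateral
lattice shared by every axial plane.  Fields are sampled at a pitch of at
most half a wavelength so that the full numerical aperture is represented,
and free-space propagation between planes is the angular-spectrum transfer
function ``exp(i k_z d)`` with ``k_z = sqrt(k0^2 - k_par^2)`` over the
propagating band and ``k_z`` clipped to zero beyond it, so the operator is
unit-modulus on every sampled spatial frequency.

Propagation is carried out on the periodic computational domain.  There the
propagator is exactly unitary, exactly symmetric in the space basis
(reciprocity), and composes exactly over split distances, which is what
makes the structural inversion of a phase-plate stack an identity rather
than an approximation.  The circular pupil ``|k_par| <= NA * k0`` is kept
as grid metadata for passband projections and diagnostics rather than as a
truncation inside the propagators.  An optional zero-padded variant of the
field propagator is provided for open-boundary point-response studies where
wrap-around of a diverging wave would be misleading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ValidationError(ValueError):
    """Raised when a grid, field or matrix argument violates its contract."""


# --------------------------------------------------------------------------
# grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldGrid:
    """Square lateral sampling lattice plus the optical constants.

    Parameters
    ----------
    n : int
        Number of samples per side (``N0``); the matrices built on this grid
        are ``n**2 x n**2``.
    pitch : float
        Sample spacing ``dx0`` in micrometres.  Must not exceed half the
        wavelength, the interval at which the focus is scanned.
    wavelength : float
        Vacuum wavelength in micrometres.
    na : float
        Numerical aperture in (0, 1]; spatial frequencies beyond
        ``na * k0`` are treated as outside the pupil.
    """

    n: int
    pitch: float
    wavelength: float
    na: float

    def __post_init__(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 2:
            raise ValidationError(f"n must be an integer >= 2, got {self.n!r}")
        if not self.pitch > 0:
            raise ValidationError(f"pitch must be positive, got {self.pitch!r}")
        if not self.wavelength > 0:
            raise ValidationError(
                f"wavelength must be positive, got {self.wavelength!r}")
        if not 0 < self.na <= 1:
            raise ValidationError(f"na must be in (0, 1], got {self.na!r}")
        if self.pitch > self.wavelength / 2 + 1e-12 * self.wavelength:
            raise ValidationError(
                f"pitch {self.pitch} exceeds half the wavelength "
                f"{self.wavelength / 2}")

    @property
    def k0(self) -> float:
        """Vacuum wavenumber ``2*pi/wavelength`` (rad/um)."""
        return 2.0 * np.pi / self.wavelength

    @property
    def extent(self) -> float:
        """Side length ``L0 = n * pitch`` of the field of view (um)."""
        return self.n * self.pitch

    @property
    def coords(self) -> np.ndarray:
        """Centered lateral coordinates (um); 0 sits at index ``n // 2``."""
        return (np.arange(self.n) - self.n // 2) * self.pitch

    @property
    def center_index(self) -> tuple[int, int]:
        return (self.n // 2, self.n // 2)

    def kgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Angular spatial frequencies (rad/um) in FFT ordering."""
        k = 2.0 * np.pi * np.fft.fftfreq(self.n, d=self.pitch)
        return np.meshgrid(k, k, indexing="ij")

    def pupil_mask(self) -> np.ndarray:
        """Boolean pupil: True where ``|k_par| <= na * k0`` (FFT ordering)."""
        kx, ky = self.kgrid()
        return kx * kx + ky * ky <= (self.na * self.k0) ** 2 * (1 + 1e-12)

    def transfer(self, distance: float) -> np.ndarray:
        """Unitary angular-spectrum transfer function for ``distance``.

        Inside the pupil passband the transfer is the physical
        ``exp(i k_z d)`` with ``k_z = sqrt(k0^2 - k_par^2)``; beyond it the
        axial wavenumber is clipped to zero, so out-of-band components are
        carried inertly (no phase, no decay) instead of being truncated.
        Keeping every component unit-modulus makes the propagator exactly
        unitary and hence exactly invertible by its conjugate, which is what
        lets the structural inversion of a recorded stack be an identity.
        """
        kx, ky = self.kgrid()
        kpar2 = kx * kx + ky * ky
        kz = np.sqrt(np.maximum(self.k0 ** 2 - kpar2, 0.0))
        return np.exp(1j * kz * distance)


def make_grid(n: int, pitch: float, wavelength: float, na: float) -> FieldGrid:
    """Construct a validated :class:`FieldGrid`."""
    return FieldGrid(n=int(n), pitch=float(pitch), wavelength=float(wavelength),
                     na=float(na))


# --------------------------------------------------------------------------
# fields
# --------------------------------------------------------------------------

@dataclass
class ComplexField:
    """A complex scalar field sampled on a :class:`FieldGrid`."""

    grid: FieldGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != (self.grid.n, self.grid.n):
            raise ValidationError(
                f"field shape {self.values.shape} does not match grid "
                f"({self.grid.n}, {self.grid.n})")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("field contains non-finite values")

    def energy(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))


# --------------------------------------------------------------------------
# propagation
# --------------------------------------------------------------------------

def _propagate_values(values: np.ndarray, grid: FieldGrid,
                      distance: float) -> np.ndarray:
    """Band-limited angular-spectrum step on the periodic grid.

    ``values`` may carry leading batch axes; the two trailing axes are the
    lateral field axes.
    """
    spec = np.fft.fft2(values, axes=(-2, -1))
    spec *= grid.transfer(distance)
    return np.fft.ifft2(spec, axes=(-2, -1))


def _pad_samples(grid: FieldGrid, distance: float) -> int:
    """Per-side padding so a pupil-edge ray cannot wrap around."""
    na = min(grid.na, 0.999999)
    spread = abs(distance) * na / (grid.pitch * np.sqrt(1.0 - na * na))
    return min(int(np.ceil(spread)), 2 * grid.n)


def angular_spectrum_propagate(fld: ComplexField, distance: float, *,
                               pad: bool = False) -> ComplexField:
    """Propagate a field by ``distance`` (um) along the optical axis.

    The sign of ``distance`` gives the direction; negative distances undo
    positive ones exactly for passband fields.  With ``pad=True`` the field
    is embedded in a zero-padded lattice before propagation and cropped
    afterwards, which suppresses periodic wrap-around of diverging waves at
    the cost of exact energy bookkeeping.
    """
    if not np.isfinite(distance):
        raise ValidationError("distance must be finite")
    if not pad or distance == 0:
        return ComplexField(fld.grid, _propagate_values(
            fld.values, fld.grid, distance))
    extra = _pad_samples(fld.grid, distance)
    m = fld.grid.n + 2 * extra
    big = make_grid(m, fld.grid.pitch, fld.grid.wavelength, fld.grid.na)
    buf = np.zeros((m, m), dtype=complex)
    buf[extra:extra + fld.grid.n, extra:extra + fld.grid.n] = fld.values
    out = _propagate_values(buf, big, distance)
    return ComplexField(fld.grid,
                        out[extra:extra + fld.grid.n, extra:extra + fld.grid.n])


@dataclass
class PropagationOperator:
    """Free-space propagator between two planes on a shared grid.

    The operator is stored implicitly as its FFT-diagonal transfer function;
    :meth:`as_matrix` materialises the dense ``n**2 x n**2`` space-basis
    matrix, which is exactly symmetric (reciprocity of free-space
    propagation) and unitary on the pupil passband.
    """

    grid: FieldGrid
    z_from: float
    z_to: float
    _matrix: np.ndarray | None = field(default=None, repr=False)

    @property
    def distance(self) -> float:
        return self.z_to - self.z_from

    def apply(self, values: np.ndarray, *, conjugate: bool = False) -> np.ndarray:
        """Apply (optionally the complex conjugate of) the operator.

        ``values`` is one field ``(n, n)`` or a batch ``(..., n, n)``.
        The conjugate of the propagator is its inverse on the passband.
        """
        # conj(exp(i kz d)) = exp(-i kz d) on the (real-kz) passband, so the
        # conjugate operator is propagation by the reversed distance.
        d = -self.distance if conjugate else self.distance
        return _propagate_values(values, self.grid, d)

    def kernel(self) -> np.ndarray:
        """Point response ``h`` with the source at index (0, 0) (FFT order)."""
        return np.fft.ifft2(self.grid.transfer(self.distance))

    def as_matrix(self) -> np.ndarray:
        if self._matrix is None:
            n = self.grid.n
            h = self.kernel()
            idx = np.arange(n)
            di = (idx[:, None] - idx[None, :]) % n      # (n, n) row offsets
            # entry [(r1,c1),(r2,c2)] = h[(r1-r2)%n, (c1-c2)%n]
            m = h[np.ix_(di.ravel(), di.ravel())]
            self._matrix = m.reshape(n, n, n, n).transpose(0, 2, 1, 3).reshape(
                n * n, n * n)
        return self._matrix


def propagation_matrix(grid: FieldGrid, z_from: float,
                       z_to: float) -> PropagationOperator:
    """Propagator whose dense action equals :func:`angular_spectrum_propagate`."""
    return PropagationOperator(grid=grid, z_from=float(z_from), z_to=float(z_to))


def greens_reference(grid: FieldGrid, source_point: tuple[int, int] | None,
                     dz: float) -> ComplexField:
    """Band-limited free-space point response over an axial gap ``dz``.

    ``source_point`` is the lateral index of the source (``None`` puts it at
    the grid center).  The reference shares the pupil cutoff of the
    propagators so that dividing a propagated point-source column by it
    leaves an exactly flat phase.
    """
    if dz == 0:
        raise ValidationError("Green's reference undefined at zero separation")
    if source_point is None:
        source_point = grid.center_index
    h = np.fft.ifft2(grid.transfer(dz))
    vals = np.roll(h, shift=source_point, axis=(0, 1))
    return ComplexField(grid, vals)


# --------------------------------------------------------------------------
# operator containers and basis changes
# --------------------------------------------------------------------------

@dataclass
class OperatorMatrix:
    """Dense complex operator on vectorized fields with plane/basis metadata.

    ``values[i, j]`` couples input lattice point ``j`` (illumination) to
    output point ``i`` (detection); fields are vectorized in C order.
    """

    values: np.ndarray
    grid: FieldGrid
    basis: str = "space"            # "space" | "frequency"
    input_plane: float = 0.0
    output_plane: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        m = self.grid.n ** 2
        if self.values.shape != (m, m):
            raise ValidationError(
                f"matrix shape {self.values.shape}, expected ({m}, {m})")
        if self.basis not in ("space", "frequency"):
            raise ValidationError(f"unknown basis {self.basis!r}")

    @property
    def n(self) -> int:
        return self.grid.n

    def diagonal_image(self) -> np.ndarray:
        """Diagonal reshaped to the lateral lattice."""
        return np.diagonal(self.values).reshape(self.n, self.n).copy()

    def copy(self):
        return replace(self, values=self.values.copy())


@dataclass
class TransmissionMatrix(OperatorMatrix):
    """One-way operator from the medium surface to the object plane."""

    provenance: str = "ground_truth"   # "ground_truth" | "identified"


@dataclass
class ReflectionMatrix(OperatorMatrix):
    """Roundtrip operator at a fixed pair of reference planes."""

    time_gated: bool = True


def _basis_transform(values: np.ndarray, n: int, inverse: bool) -> np.ndarray:
    """Similarity transform F M F^H with the unitary 2-D DFT (FFT ordering)."""
    four = values.reshape(n, n, n, n)
    if not inverse:
        four = np.fft.fft2(four, axes=(0, 1), norm="ortho")
        four = np.fft.ifft2(four, axes=(2, 3), norm="ortho")
    else:
        four = np.fft.ifft2(four, axes=(0, 1), norm="ortho")
        four = np.fft.fft2(four, axes=(2, 3), norm="ortho")
    return np.ascontiguousarray(four.reshape(n * n, n * n))


def to_frequency_basis(matrix: OperatorMatrix) -> OperatorMatrix:
    """Re-express both indices in the spatial-frequency basis.

    The transform is the unitary DFT similarity ``F M F^H``; a matrix that is
    diagonal on plane waves (pure propagation) stays diagonal, and Parseval
    makes every power ratio basis-independent.
    """
    if matrix.basis == "frequency":
        raise ValidationError("matrix is already in the frequency basis")
    out = matrix.copy()
    out.values = _basis_transform(matrix.values, matrix.n, inverse=False)
    out.basis = "frequency"
    return out


def to_space_basis(matrix: OperatorMatrix) -> OperatorMatrix:
    """Inverse of :func:`to_frequency_basis` (exact round trip)."""
    if matrix.basis == "space":
        raise ValidationError("matrix is already in the space basis")
    out = matrix.copy()
    out.values = _basis_transform(matrix.values, matrix.n, inverse=True)
    out.basis = "space"
    return out
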