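"""The multiple-scattering tracing engine.

Given a time-gated reflection matrix of an object buried under a stack of
unknown phase screens, the engine recovers the per-layer phase functions and
the object reflectance.  The principle: after conjugate back-propagation of
the matrix so that its output index sits at the object plane and its input
index at layer ``k``, each column is (up to clutter from the other layers)
the object function times a free-space spherical wave times the single
phase factor ``exp(i phi_k)`` of the illumination point.  Dividing out the
spherical reference leaves a noisy rank-1 matrix — object map (rows) outer
unit-modulus phase vector (columns) — whose dominant singular vector, found
by power iteration, is the phase-function estimate.  Corrections are
applied in place, the same sweep is run on the matrix transpose to handle
the outgoing path, and the cycle repeats until the increments are
negligible, accumulating ``phi_k^c = sum_n phi_k^(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import (PropagationOperator, ReflectionMatrix,
                     TransmissionMatrix, ValidationError)
from .synthesis import (MediumModel, PhasePlate, fov_mask,
                        plate_fov_diameter)


# --------------------------------------------------------------------------
# configuration and result containers
# --------------------------------------------------------------------------

@dataclass
class MSTConfig:
    """Loop controls for the tracing engine.

    ``layer_depths`` are the assumed plate heights above the object plane
    (um, strictly increasing).  The cycle stops once the largest per-layer
    RMS phase increment of a cycle falls below ``phase_increment_tolerance``
    or after ``max_cycles``.  ``layer_order`` selects whether a sweep visits
    layers from the object outward (``"object_to_surface"``, the default:
    near layers have the best mapping resolution and stabilize first) or
    surface inward.

    Two estimator controls matter for robustness deep in the clutter-
    dominated regime.  ``power_iteration_max_steps`` is deliberately small:
    started from the all-ones vector the first iterations deliver the
    unbiased column-correlation average, whereas running to convergence
    when the rank-1 object signal is subdominant locks onto the strongest
    clutter direction; with a dominant signal a few steps already converge.
    ``band_limit_estimates`` projects each estimated phase vector onto the
    spatial-frequency band actually resolvable for that layer — the ROI of
    side L0 acts as the mapping aperture, giving an effective NA of
    ``L0 / (2 z_k)`` — which removes the estimation noise that the data
    cannot constrain.  ``spectral_shrinkage`` additionally applies a Wiener
    weight to the in-band modes, with the noise floor measured from the
    out-of-band modes of the same vector (which are estimation noise by
    construction); for clean rank-1 data the floor vanishes and the weight
    is unity.
    """

    layer_depths: list[float] = field(default_factory=list)
    max_cycles: int = 20
    phase_increment_tolerance: float = 0.01      # radians RMS
    power_iteration_max_steps: int = 3
    power_iteration_tolerance: float = 1e-6
    reference_point: tuple[int, int] | None = None   # lattice index of rho=0
    fov_masking: bool = True
    band_limit_estimates: bool = True
    spectral_shrinkage: bool = True
    layer_order: str = "object_to_surface"       # or "surface_to_object"
    compute_traces: bool = True
    greens_floor: float = 1e-6                   # |G| regularization fraction
    working_dtype: str = "complex128"            # or "complex64" for speed

    def __post_init__(self) -> None:
        self.layer_depths = [float(z) for z in self.layer_depths]
        if any(z2 <= z1 for z1, z2 in zip(self.layer_depths,
                                          self.layer_depths[1:])):
            raise ValidationError("layer depths must be strictly increasing")
        if any(z <= 0 for z in self.layer_depths):
            raise ValidationError("layer depths must be positive")
        if self.max_cycles < 1:
            raise ValidationError("max_cycles must be >= 1")
        if self.phase_increment_tolerance <= 0:
            raise ValidationError("phase tolerance must be positive")
        if self.power_iteration_tolerance <= 0:
            raise ValidationError("power-iteration tolerance must be positive")
        if self.layer_order not in ("object_to_surface", "surface_to_object"):
            raise ValidationError(f"unknown layer order {self.layer_order!r}")
        if self.working_dtype not in ("complex128", "complex64"):
            raise ValidationError(
                f"unknown working dtype {self.working_dtype!r}")


@dataclass
class LayerEstimate:
    """Accumulated phase function of one layer."""

    layer_index: int
    depth: float
    accumulated_phase: np.ndarray        # phi_k^c, radians (n, n)
    fov_mask: np.ndarray                 # bool (n, n)
    last_increment_rms: float = np.inf

    def wrapped(self) -> np.ndarray:
        w = np.angle(np.exp(1j * self.accumulated_phase))
        w[w <= -np.pi] = np.pi
        return w


@dataclass
class NormalizedMatrix:
    """Green's-normalized layer matrix ``S`` with its regularization mask."""

    values: np.ndarray
    layer_index: int
    validity_mask: np.ndarray            # bool, False where |G| was too small
    grid: object = None


@dataclass
class MSTResult:
    """Output of the tracing loop."""

    estimates: list[LayerEstimate]
    converged: bool
    cycles_run: int
    xi1_trace: list[float]
    xi2_trace: list[float]
    increment_rms_trace: list[float]
    mst_image: np.ndarray                # |diag R^c|^2 on the lattice
    object_estimate: np.ndarray          # complex diag R^c on the lattice
    corrected_matrix: ReflectionMatrix | None = None
    config: MSTConfig | None = None

    @property
    def accumulated_phases(self) -> list[np.ndarray]:
        return [e.accumulated_phase for e in self.estimates]


# --------------------------------------------------------------------------
# plane transforms
# --------------------------------------------------------------------------

def transform_to_layer(r: ReflectionMatrix, input_plane: float,
                       output_plane: float) -> ReflectionMatrix:
    """Conjugate back-propagation reindexing of a reflection matrix.

    Both indices are moved through free space only: moving an index from
    plane ``a`` to plane ``b`` multiplies the corresponding side by the
    conjugated propagator over the gap, which on the band-limited passband
    equals propagation by ``b - a``.  A transform followed by its inverse
    restores the matrix exactly.
    """
    if r.basis != "space":
        raise ValidationError("plane transforms require the space basis")
    grid = r.grid
    n = grid.n
    vals = r.values
    d_out = output_plane - r.output_plane
    d_in = input_plane - r.input_plane
    if d_out != 0:
        cols = vals.T.reshape(n * n, n, n)
        cols = PropagationOperator(grid, 0.0, d_out).apply(cols)
        vals = cols.reshape(n * n, n * n).T
    if d_in != 0:
        rows = vals.reshape(n * n, n, n)
        rows = PropagationOperator(grid, 0.0, d_in).apply(rows)
        vals = rows.reshape(n * n, n * n)
    out = r.copy()
    out.values = np.ascontiguousarray(vals)
    out.input_plane = float(input_plane)
    out.output_plane = float(output_plane)
    return out


# --------------------------------------------------------------------------
# Green's normalization and phase estimation
# --------------------------------------------------------------------------

def normalize_by_greens(r_layer: ReflectionMatrix, *,
                        floor: float = 1e-6) -> NormalizedMatrix:
    """Divide out the free-space spherical reference entry by entry.

    ``r_layer`` must be referenced to the object plane on the output side
    and to a layer plane on the input side.  The reference for entry
    ``(i, j)`` is the band-limited point response over the axial gap,
    evaluated at the lateral offset ``rho_i - rho_j``; entries where its
    magnitude is below ``floor`` times the peak are masked out rather than
    divided.
    """
    dz = r_layer.input_plane - r_layer.output_plane
    if dz == 0:
        raise ValidationError("normalization undefined at zero separation")
    op = PropagationOperator(r_layer.grid, 0.0, dz)
    g = op.as_matrix()
    mag = np.abs(g)
    mask = mag >= floor * mag.max()
    s = np.zeros_like(r_layer.values)
    np.divide(r_layer.values, g, out=s, where=mask)
    return NormalizedMatrix(values=s, layer_index=-1, validity_mask=mask,
                            grid=r_layer.grid)


def _power_iteration(s: np.ndarray, max_steps: int, tol: float) -> np.ndarray:
    """Dominant right singular vector of ``s`` (masked entries already 0)."""
    m = s.shape[1]
    v = np.ones(m, dtype=complex) / np.sqrt(m)
    prev = v
    for _ in range(max_steps):
        u = s @ v
        nu = np.linalg.norm(u)
        if nu == 0:
            raise ValidationError("power iteration on a zero matrix")
        u /= nu
        v = s.conj().T @ u
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValidationError("power iteration collapsed")
        v /= nv
        # gauge-align before measuring the change
        phase = np.vdot(prev, v)
        if abs(phase) > 0:
            aligned = v * np.conj(phase / abs(phase))
        else:
            aligned = v
        if np.linalg.norm(aligned - prev) < tol:
            prev = aligned
            break
        prev = aligned
    return prev


def mapping_band_mask(grid, depth: float) -> np.ndarray:
    """Spatial-frequency band resolvable when mapping a layer at ``depth``.

    The ROI of side L0 at the object plane is the aperture of the mapping,
    so the layer is resolved with an effective NA of ``L0 / (2 z_k)``; the
    boolean mask keeps ``|k_par| <= NA_eff * k0`` (all-true once the
    effective NA exceeds the lattice bandwidth, e.g. for shallow layers).
    """
    if depth <= 0:
        raise ValidationError("depth must be positive")
    kx, ky = grid.kgrid()
    na_eff = grid.extent / (2.0 * depth)
    return kx * kx + ky * ky <= (na_eff * grid.k0) ** 2


def estimate_phase(s: NormalizedMatrix, config: MSTConfig,
                   layer_fov: np.ndarray | None = None,
                   band_mask: np.ndarray | None = None,
                   max_steps: int | None = None) -> np.ndarray:
    """Phase increment of one layer from its normalized matrix.

    Solves the rank-1 fit ``S ~ o tau exp(i phi)^T`` by (truncated) power
    iteration; the recovered direction is projected onto the layer's
    resolvable spatial-frequency band when ``band_mask`` is given, and the
    increment is minus the angle of the result, pinned to zero at the
    reference point (or, if that column is masked or carries negligible
    signal, at the strongest column), and zeroed outside the layer's
    circular field of view.
    """
    vals = s.values
    if not np.any(s.validity_mask):
        raise ValidationError("all entries of S are masked")
    n = int(np.sqrt(vals.shape[0]))
    work = vals
    if layer_fov is not None:
        work = vals * layer_fov.ravel()[None, :]
    steps = (config.power_iteration_max_steps if max_steps is None
             else max_steps)
    v = _power_iteration(work, steps, config.power_iteration_tolerance)
    # S ~ o w^T with w = exp(i phi): the right singular vector is conj(w)
    if band_mask is not None:
        spec = np.fft.fft2(np.conj(v).reshape(n, n))
        if config.spectral_shrinkage and np.any(~band_mask):
            # out-of-band modes of the estimate carry no recoverable layer
            # content; their mean power is the per-mode noise floor
            floor = np.mean(np.abs(spec[~band_mask]) ** 2)
            power = np.abs(spec) ** 2
            spec = spec * np.where(
                power > floor, 1.0 - floor / np.maximum(power, 1e-300), 0.0)
        w = np.fft.ifft2(spec * band_mask)
        phi = np.angle(w).ravel()
        weight = np.abs(w).ravel()
    else:
        phi = -np.angle(v)
        weight = np.abs(v)
    ref = config.reference_point
    ref_flat = (n // 2) * n + (n // 2) if ref is None else ref[0] * n + ref[1]
    if weight[ref_flat] < 1e-3 * weight.max() or (
            layer_fov is not None and not layer_fov.ravel()[ref_flat]):
        ref_flat = int(np.argmax(weight))
    phi = phi - phi[ref_flat]
    phi = np.angle(np.exp(1j * phi))     # wrap after pinning the piston
    inc = phi.reshape(n, n).copy()
    if layer_fov is not None:
        inc[~layer_fov] = 0.0
    return inc


def pairwise_phase_estimate(s: NormalizedMatrix,
                            reference_index: int | None = None) -> np.ndarray:
    """Two-column correlation estimate of the layer phase.

    The inner product of column ``j`` with the reference column isolates
    ``exp(i [phi(rho_j) - phi(rho_ref)])`` times the object power; its angle
    is the direct pairwise estimator that the rank-1 fit generalizes.
    Provided as an independent cross-check of :func:`estimate_phase`.
    """
    vals = s.values
    n2 = vals.shape[1]
    n = int(np.sqrt(n2))
    if reference_index is None:
        reference_index = (n // 2) * n + (n // 2)
    ref_col = vals[:, reference_index]
    if not np.any(ref_col):
        raise ValidationError("reference column carries no signal")
    corr = vals.conj().T @ ref_col        # sum_i S*(i,j) S(i,ref)
    return (-np.angle(corr)).reshape(n, n)


# --------------------------------------------------------------------------
# corrections
# --------------------------------------------------------------------------

def apply_phase_correction(r: ReflectionMatrix, increment: np.ndarray,
                           side: str) -> ReflectionMatrix:
    """Multiply ``exp(-i increment)`` as a diagonal on one side of ``r``.

    The caller is responsible for having ``r`` referenced to the layer plane
    on that side; applying an increment and then its negation restores the
    matrix exactly.
    """
    if side not in ("input", "output"):
        raise ValidationError(f"side must be 'input' or 'output', got {side!r}")
    factor = np.exp(-1j * np.asarray(increment)).ravel()
    if factor.shape[0] != r.values.shape[0]:
        raise ValidationError("increment does not match the matrix size")
    out = r.copy()
    if side == "input":
        out.values = out.values * factor[None, :]
    else:
        out.values = out.values * factor[:, None]
    return out


def correction_medium(grid, phases: list[np.ndarray],
                      depths: list[float]) -> MediumModel:
    """Assemble the identified plate stack ``T^c`` from accumulated phases."""
    plates = [PhasePlate(phase_map=np.asarray(p, dtype=float), depth=z,
                         pitch=grid.pitch)
              for p, z in zip(phases, depths)]
    return MediumModel(grid=grid, plates=plates)


def identified_transmission(medium_c: MediumModel) -> TransmissionMatrix:
    """Dense ``T^c`` of an identified stack."""
    from .forward import apply_medium
    n2 = medium_c.grid.n ** 2
    vals = apply_medium(np.eye(n2, dtype=complex), medium_c)
    return TransmissionMatrix(values=vals, grid=medium_c.grid,
                              input_plane=medium_c.surface_depth,
                              output_plane=0.0, provenance="identified")


def _apply_invT_transpose(fields: np.ndarray,
                          medium_c: MediumModel) -> np.ndarray:
    """Apply ``((T^c)^-1)^T`` to a batch of fields at the surface plane.

    Because every factor of ``T^c`` is symmetric, this is the reversed
    structural inverse: undo plate N, conjugate-propagate the gap, ... undo
    plate 1, conjugate-propagate to the object plane.  Used on the columns
    of ``R`` it corrects the outgoing path; used on the rows it corrects the
    incoming path.
    """
    grid = medium_c.grid
    plates = medium_c.plates
    depths = [0.0] + [p.depth for p in plates]
    for k in range(len(plates) - 1, -1, -1):
        fields = fields * np.conj(plates[k].transmittance()).astype(
            fields.dtype)
        gap = depths[k + 1] - depths[k]
        fields = PropagationOperator(grid, 0.0, gap).apply(fields,
                                                           conjugate=True)
    return fields


def corrected_reflection(r: ReflectionMatrix,
                         medium_c: MediumModel) -> ReflectionMatrix:
    """Structural inverse of the identified stack applied to both sides.

    Computes ``R^c = [(T^c)^T]^-1 R_{zN,zN} (T^c)^-1`` with the inverse
    realized as the reversed product of conjugated unitary factors (never a
    numeric matrix inversion); the result is referenced to the object plane
    on both sides.  With the ground-truth stack this reduces the forward
    model to the bare object diagonal exactly.
    """
    if r.basis != "space":
        raise ValidationError("correction requires the space basis")
    if r.input_plane != r.output_plane:
        raise ValidationError("correction requires equal reference planes")
    z_n = medium_c.surface_depth
    if r.input_plane not in (0.0, z_n):
        raise ValidationError(
            f"matrix plane {r.input_plane} matches neither the object plane "
            f"nor the stack surface {z_n}")
    grid = r.grid
    n = grid.n
    vals = r.values
    if r.input_plane == 0.0 and z_n > 0:
        # undo the focal-plane referencing: R_zN = P R_z0 P
        rn = transform_to_layer(r, z_n, z_n)
        vals = rn.values
    cols = vals.T.reshape(n * n, n, n)
    cols = _apply_invT_transpose(cols, medium_c)
    vals = cols.reshape(n * n, n * n).T
    rows = vals.reshape(n * n, n, n)
    rows = _apply_invT_transpose(rows, medium_c)
    vals = rows.reshape(n * n, n * n)
    out = r.copy()
    out.values = np.ascontiguousarray(vals)
    out.input_plane = 0.0
    out.output_plane = 0.0
    return out


def reconstruct_object(r_c: ReflectionMatrix):
    """Complex reflectance estimate from the diagonal of ``R^c_{z0,z0}``."""
    from .optics import ComplexField
    if r_c.basis != "space":
        raise ValidationError("object reconstruction requires the space basis")
    if r_c.input_plane != 0.0 or r_c.output_plane != 0.0:
        raise ValidationError("object reconstruction requires the object plane")
    return ComplexField(r_c.grid, r_c.diagonal_image())


# --------------------------------------------------------------------------
# the iteration loop
# --------------------------------------------------------------------------

def _layer_gaps(depths: list[float]) -> list[float]:
    padded = [0.0] + list(depths)
    return [b - a for a, b in zip(padded, padded[1:])]


def _corrected_values(vals: np.ndarray, grid, medium_c: MediumModel
                      ) -> np.ndarray:
    """Structural correction of a surface-referenced matrix (raw arrays)."""
    n = grid.n
    cols = vals.T.reshape(n * n, n, n)
    cols = _apply_invT_transpose(cols, medium_c)
    out = cols.reshape(n * n, n * n).T
    rows = out.reshape(n * n, n, n)
    rows = _apply_invT_transpose(rows, medium_c)
    return rows.reshape(n * n, n * n)


def _ballistic_fraction_raw(vals: np.ndarray, n: int) -> float:
    """Frequency-basis diagonal power fraction without container overhead."""
    four = vals.reshape(n, n, n, n)
    four = np.fft.fft2(four, axes=(0, 1), norm="ortho")
    four = np.fft.ifft2(four, axes=(2, 3), norm="ortho")
    tf = four.reshape(n * n, n * n)
    total = float(np.sum(np.abs(vals) ** 2))     # Parseval
    return float(np.sum(np.abs(np.diagonal(tf)) ** 2)) / total


def _sweep(rn_vals: np.ndarray, grid, phases: list[np.ndarray],
           depths: list[float], fov_masks: list[np.ndarray | None],
           greens: list[np.ndarray], greens_masks: list[np.ndarray],
           band_masks: list[np.ndarray | None],
           config: MSTConfig, max_steps: int | None = None) -> list[float]:
    """One correction sweep over every layer on the incoming path.

    ``rn_vals`` is the surface-referenced matrix (or its transpose for the
    outgoing path).  Phases are updated in place; the per-layer RMS of the
    increments is returned.
    """
    n = grid.n
    nlay = len(depths)
    medium_c = correction_medium(grid, phases, depths)
    cols = rn_vals.T.reshape(n * n, n, n)
    cols = _apply_invT_transpose(cols, medium_c)
    a_vals = cols.reshape(n * n, n * n).T          # output corrected, in @ zN

    order = (range(nlay) if config.layer_order == "object_to_surface"
             else range(nlay - 1, -1, -1))
    gaps = _layer_gaps(depths)
    rms_list = [0.0] * nlay
    dt = a_vals.dtype
    for k in order:
        rows = a_vals.reshape(n * n, n, n)
        # walk the input index from the surface down to layer k, undoing the
        # layers above it with the current accumulated estimates
        for j in range(nlay - 1, k, -1):
            rows = rows * np.exp(-1j * phases[j]).astype(dt)
            rows = PropagationOperator(grid, 0.0, gaps[j]).apply(
                rows, conjugate=True)
        rows = rows * np.exp(-1j * phases[k]).astype(dt)
        w_vals = rows.reshape(n * n, n * n)
        s = np.zeros_like(w_vals)
        np.divide(w_vals, greens[k], out=s, where=greens_masks[k])
        sm = NormalizedMatrix(values=s, layer_index=k,
                              validity_mask=greens_masks[k], grid=grid)
        inc = estimate_phase(sm, config, layer_fov=fov_masks[k],
                             band_mask=band_masks[k], max_steps=max_steps)
        phases[k] = phases[k] + inc
        sel = fov_masks[k] if fov_masks[k] is not None else np.ones(
            (n, n), bool)
        rms_list[k] = float(np.sqrt(np.mean(inc[sel] ** 2)))
    return rms_list


def mst_iterate(r: ReflectionMatrix, config: MSTConfig) -> MSTResult:
    """Run the full tracing loop on a measured reflection matrix.

    Each cycle sweeps the incoming path (estimating and applying a phase
    increment per layer), then repeats the sweep on the matrix transpose to
    handle the outgoing path, and finally records the ballistic-enhancement
    traces.  The loop stops when every layer's RMS increment drops below the
    configured tolerance or after ``max_cycles``.
    """
    if r.basis != "space":
        raise ValidationError("the tracing loop requires the space basis")
    if not np.all(np.isfinite(r.values)):
        raise ValidationError("reflection matrix contains non-finite values")
    grid = r.grid
    n = grid.n
    depths = list(config.layer_depths)
    if not depths:
        # empty medium: nothing to identify, the matrix is its own correction
        r0 = (r if r.input_plane == 0.0 else transform_to_layer(r, 0.0, 0.0))
        obj = r0.diagonal_image()
        return MSTResult(estimates=[], converged=True, cycles_run=1,
                         xi1_trace=[1.0], xi2_trace=[1.0],
                         increment_rms_trace=[0.0],
                         mst_image=np.abs(obj) ** 2, object_estimate=obj,
                         corrected_matrix=r0, config=config)
    z_n = depths[-1]
    if r.input_plane != r.output_plane:
        raise ValidationError("expected equal reference planes")
    if r.input_plane == 0.0:
        rn = transform_to_layer(r, z_n, z_n)
    elif r.input_plane == z_n:
        rn = r
    else:
        raise ValidationError(
            f"matrix plane {r.input_plane} matches neither the object plane "
            f"nor the deepest configured layer {z_n}")
    rn_vals = np.ascontiguousarray(rn.values.astype(config.working_dtype))

    fov_masks: list[np.ndarray | None] = []
    for z in depths:
        if config.fov_masking:
            mask = fov_mask(grid, plate_fov_diameter(z, grid.extent))
            fov_masks.append(mask)
        else:
            fov_masks.append(None)
    greens = []
    greens_masks = []
    for z in depths:
        g = PropagationOperator(grid, 0.0, z).as_matrix().astype(
            config.working_dtype)
        mag = np.abs(g)
        greens.append(g)
        greens_masks.append(mag >= config.greens_floor * mag.max())
    band_masks = [mapping_band_mask(grid, z) if config.band_limit_estimates
                  else None for z in depths]

    phases = [np.zeros((n, n)) for _ in depths]
    d0 = None
    if config.compute_traces:
        r0 = transform_to_layer(rn, 0.0, 0.0)
        d0 = np.diagonal(r0.values).copy()
        del r0
    xi1_trace: list[float] = []
    xi2_trace: list[float] = []
    rms_trace: list[float] = []
    converged = False
    cycles = 0
    for cycle in range(config.max_cycles):
        cycles = cycle + 1
        rms_in = _sweep(rn_vals, grid, phases, depths, fov_masks,
                        greens, greens_masks, band_masks, config)
        rms_out = _sweep(np.ascontiguousarray(rn_vals.T), grid, phases,
                         depths, fov_masks, greens, greens_masks,
                         band_masks, config)
        cycle_rms = max(rms_in + rms_out)
        rms_trace.append(cycle_rms)
        if config.compute_traces:
            from .forward import apply_medium
            medium_c = correction_medium(grid, phases, depths)
            tc_vals = apply_medium(np.eye(n * n, dtype=rn_vals.dtype),
                                   medium_c)
            xi1_trace.append(_ballistic_fraction_raw(tc_vals, n) ** -2)
            dc = np.diagonal(_corrected_values(rn_vals, grid, medium_c))
            pc = float(np.sum(np.abs(dc) ** 2))
            p0 = float(np.sum(np.abs(d0) ** 2))
            eta_c = pc / p0
            alpha = float(np.abs(np.vdot(dc, d0)) ** 2) / (pc * p0)
            xi2_trace.append(eta_c / alpha)
        if not np.all([np.all(np.isfinite(p)) for p in phases]):
            raise ValidationError("non-finite phase estimate; diverged")
        if cycle_rms < config.phase_increment_tolerance:
            converged = True
            break

    medium_c = correction_medium(grid, phases, depths)
    r_c = corrected_reflection(rn, medium_c)
    obj = r_c.diagonal_image()
    estimates = [
        LayerEstimate(layer_index=k, depth=z, accumulated_phase=phases[k],
                      fov_mask=(fov_masks[k] if fov_masks[k] is not None
                                else np.ones((n, n), bool)),
                      last_increment_rms=rms_trace[-1] if rms_trace else np.inf)
        for k, z in enumerate(depths)
    ]
    return MSTResult(estimates=estimates, converged=converged,
                     cycles_run=cycles, xi1_trace=xi1_trace,
                     xi2_trace=xi2_trace, increment_rms_trace=rms_trace,
                     mst_image=np.abs(obj) ** 2, object_estimate=obj,
                     corrected_matrix=r_c, config=config)
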