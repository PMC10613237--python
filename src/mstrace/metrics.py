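"""Ballistic-enhancement diagnostics and correlation scoring.

The quantitative language of the method: the ballistic power fraction
``eta_T`` of a transmission matrix (diagonal-to-total power ratio in the
spatial-frequency basis), the roundtrip enhancement ``xi1 = eta_T**-2``,
the confocal power ratio ``eta_c`` between corrected and uncorrected
reflection matrices, the ballistic contribution ``alpha`` of the
uncorrected confocal signal, the image-domain enhancement
``xi2 = eta_c / alpha``, the one-way optical thickness ``-ln(eta_T)`` in
scattering mean free paths, angular spread functions, and Pearson scores
for maps and phase functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import (OperatorMatrix, PropagationOperator, ReflectionMatrix,
                     TransmissionMatrix, ValidationError, to_frequency_basis)
from .synthesis import MediumModel


# --------------------------------------------------------------------------
# transmission-side metrics
# --------------------------------------------------------------------------

def ballistic_fraction(t: TransmissionMatrix | OperatorMatrix) -> float:
    """Diagonal-to-total power ratio in the spatial-frequency basis.

    The frequency-basis diagonal collects the field that exits with the same
    transverse momentum it entered with, i.e. the ballistic component; the
    ratio lies in (0, 1] and equals 1 for aberration-free transmission.
    """
    tf = to_frequency_basis(t) if t.basis == "space" else t
    total = float(np.sum(np.abs(tf.values) ** 2))
    if total == 0:
        raise ValidationError("ballistic fraction of a zero matrix is undefined")
    diag = float(np.sum(np.abs(np.diagonal(tf.values)) ** 2))
    return diag / total


def xi1(t_c: TransmissionMatrix | OperatorMatrix) -> float:
    """Roundtrip ballistic enhancement ``eta_T**-2``."""
    return ballistic_fraction(t_c) ** -2


def optical_thickness(t: TransmissionMatrix | OperatorMatrix) -> float:
    """One-way optical thickness ``-ln(eta_T)`` in scattering mean free paths."""
    return -float(np.log(ballistic_fraction(t)))


def traced_scattering_events(n_plates: int) -> int:
    """Scattering events accounted for in one roundtrip: ``2 N + 1``.

    ``N`` plates on the way in, one reflection at the object, and the same
    ``N`` plates on the way out.
    """
    if n_plates < 0:
        raise ValidationError("n_plates must be non-negative")
    return 2 * n_plates + 1


# --------------------------------------------------------------------------
# reflection-side metrics
# --------------------------------------------------------------------------

def confocal_enhancement(r: ReflectionMatrix, r_c: ReflectionMatrix) -> float:
    """Corrected-over-uncorrected confocal power ratio ``eta_c``."""
    for m in (r, r_c):
        if m.basis != "space" or m.input_plane != m.output_plane:
            raise ValidationError(
                "eta_c requires space-basis matrices at equal planes")
    denom = float(np.sum(np.abs(np.diagonal(r.values)) ** 2))
    if denom == 0:
        raise ValidationError("uncorrected confocal power is zero")
    num = float(np.sum(np.abs(np.diagonal(r_c.values)) ** 2))
    return num / denom


def ballistic_contribution_alpha(r: ReflectionMatrix,
                                 object_estimate: np.ndarray) -> float:
    """Fraction ``alpha`` of the uncorrected confocal power that is ballistic.

    The ballistic part of the uncorrected confocal field is the component
    proportional to the object reflectance (the roundtrip-attenuated object
    signal); everything else on the diagonal is multiply scattered clutter.
    ``alpha`` is estimated as the squared magnitude of the normalized
    projection of ``diag(R)`` onto the object direction:

        alpha = |<d, o>|^2 / (||o||^2 ||d||^2),

    with ``d = diag(R)`` and ``o`` the (ground-truth or reconstructed)
    complex object map.  For an aberration-free medium ``d`` is proportional
    to ``o`` and alpha = 1; a diagonal dominated by clutter projects to a
    small alpha.
    """
    d = np.diagonal(r.values).ravel()
    o = np.asarray(object_estimate, dtype=complex).ravel()
    if d.shape != o.shape:
        raise ValidationError("object estimate does not match the matrix size")
    no = float(np.sum(np.abs(o) ** 2))
    nd = float(np.sum(np.abs(d) ** 2))
    if no == 0 or nd == 0:
        raise ValidationError("alpha undefined for zero diagonal or object")
    proj = np.vdot(o, d)
    return float(np.abs(proj) ** 2 / (no * nd))


def xi2(r: ReflectionMatrix, r_c: ReflectionMatrix,
        object_estimate: np.ndarray | None = None) -> float:
    """Image-domain ballistic enhancement ``eta_c / alpha``.

    If no object estimate is supplied, the corrected diagonal itself serves
    as the object direction for the alpha projection.
    """
    if object_estimate is None:
        object_estimate = np.diagonal(r_c.values).copy()
    return (confocal_enhancement(r, r_c)
            / ballistic_contribution_alpha(r, object_estimate))


# --------------------------------------------------------------------------
# angular spread function
# --------------------------------------------------------------------------

def angular_spread_function(medium: MediumModel, depth: float,
                            corrected_by: list[np.ndarray] | None = None
                            ) -> np.ndarray:
    """Spatial-frequency intensity of a normally incident plane wave.

    The wave enters at the surface and is propagated down to ``depth``
    (just below any plate at that depth); with ``corrected_by`` the
    conjugate of each supplied phase map is applied at its plate, emulating
    the rectified medium.  The returned map is fftshift-centered; its
    central pixel is the ballistic component.
    """
    if depth < 0 or depth > medium.surface_depth:
        raise ValidationError("depth outside the modeled axial range")
    if corrected_by is not None and len(corrected_by) != medium.n_plates:
        raise ValidationError("one correction map per plate is required")
    grid = medium.grid
    n = grid.n
    fieldv = np.ones((n, n), dtype=complex)
    z = medium.surface_depth
    for k in range(medium.n_plates - 1, -1, -1):
        plate = medium.plates[k]
        if plate.depth < depth:
            break
        fieldv = PropagationOperator(grid, 0.0, z - plate.depth).apply(fieldv)
        phi = plate.phase_map
        if corrected_by is not None:
            phi = phi - corrected_by[k]
        fieldv = fieldv * np.exp(1j * phi)
        z = plate.depth
    if z > depth:
        fieldv = PropagationOperator(grid, 0.0, z - depth).apply(fieldv)
    spec = np.fft.fftshift(np.fft.fft2(fieldv, norm="ortho"))
    return np.abs(spec) ** 2


def ballistic_gain(medium: MediumModel,
                   corrected_by: list[np.ndarray]) -> float:
    """One-way central-ASF intensity ratio, corrected over uncorrected."""
    n = medium.grid.n
    c = (n // 2, n // 2)
    asf0 = angular_spread_function(medium, 0.0)
    asf1 = angular_spread_function(medium, 0.0, corrected_by=corrected_by)
    return float(asf1[c] / asf0[c])


# --------------------------------------------------------------------------
# correlation scoring
# --------------------------------------------------------------------------

def pearson_score(estimate: np.ndarray, truth: np.ndarray,
                  mode: str = "intensity",
                  mask: np.ndarray | None = None) -> float:
    """Pearson agreement between two maps.

    ``intensity`` correlates real-valued maps (ordinary Pearson r).
    ``complex_phase`` compares phase maps through ``exp(i*phi)``: the
    magnitude of the normalized complex covariance, which removes the
    best-fit global piston and lies in [0, 1].
    """
    a = np.asarray(estimate)
    b = np.asarray(truth)
    if a.shape != b.shape:
        raise ValidationError("maps must share a shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValidationError("mask must share the map shape")
        a = a[mask]
        b = b[mask]
    a = a.ravel()
    b = b.ravel()
    if a.size < 2:
        raise ValidationError("need at least two samples")
    if mode == "intensity":
        a = a.real.astype(float)
        b = b.real.astype(float)
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            raise ValidationError("correlation undefined for constant input")
        return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    if mode == "complex_phase":
        za = np.exp(1j * a.real.astype(float))
        zb = np.exp(1j * b.real.astype(float))
        za = za - za.mean()
        zb = zb - zb.mean()
        na, nb = np.linalg.norm(za), np.linalg.norm(zb)
        if na == 0 or nb == 0:
            raise ValidationError("correlation undefined for constant phase")
        return float(np.abs(np.vdot(za, zb)) / (na * nb))
    raise ValidationError(f"unknown mode {mode!r}")


# --------------------------------------------------------------------------
# report container
# --------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Bundle of the standard diagnostics for one phantom/run."""

    eta_T: float
    xi1: float
    eta_c: float
    alpha: float
    xi2: float
    optical_thickness_one_way: float
    asf_maps: dict[float, np.ndarray] = field(default_factory=dict)
    correlations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.xi1, self.eta_T ** -2, rtol=1e-12):
            raise ValidationError("xi1 must equal eta_T**-2")
        if not np.isclose(self.xi2, self.eta_c / self.alpha, rtol=1e-12):
            raise ValidationError("xi2 must equal eta_c / alpha")
        if not np.isclose(self.optical_thickness_one_way,
                          -np.log(self.eta_T), rtol=1e-12):
            raise ValidationError(
                "optical thickness must equal -ln(eta_T)")

    def as_dict(self) -> dict[str, float]:
        d = {"eta_T": self.eta_T, "xi1": self.xi1, "eta_c": self.eta_c,
             "alpha": self.alpha, "xi2": self.xi2,
             "optical_thickness_one_way": self.optical_thickness_one_way}
        d.update(self.correlations)
        return d
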