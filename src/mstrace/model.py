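"""Model/Results interface over the tracing engine.

`MSTModel` holds the data (a time-gated reflection matrix) together with
the structural assumption (the assumed layer depths); ``fit()`` runs the
correction loop and returns an `MSTResults` object carrying the recovered
phase functions, the rectified image, the per-cycle enhancement traces and
a text summary, in the spirit of statistical modelling packages where a
model built from data yields a results object.
"""

from __future__ import annotations

import numpy as np

from .forward import confocal_image, reflection_from_medium
from .metrics import (ballistic_contribution_alpha, ballistic_fraction,
                      confocal_enhancement, optical_thickness, pearson_score,
                      traced_scattering_events)
from .mst import (MSTConfig, MSTResult, correction_medium,
                  identified_transmission, mst_iterate, transform_to_layer)
from .optics import ReflectionMatrix, ValidationError
from .synthesis import MediumModel, ObjectMap


class MSTModel:
    """Multi-slice phase-screen model of a measured reflection matrix.

    Parameters
    ----------
    reflection : ReflectionMatrix
        Time-gated reflection matrix, space basis, referenced either at the
        object plane or at the assumed medium surface.
    layer_depths : sequence of float
        Assumed heights of the phase screens above the object plane (um).
    config : MSTConfig, optional
        Loop controls; ``layer_depths`` of the config is overridden.
    """

    def __init__(self, reflection: ReflectionMatrix, layer_depths,
                 config: MSTConfig | None = None):
        if not isinstance(reflection, ReflectionMatrix):
            raise ValidationError("reflection must be a ReflectionMatrix")
        self.reflection = reflection
        cfg = config if config is not None else MSTConfig()
        cfg.layer_depths = [float(z) for z in layer_depths]
        MSTConfig.__post_init__(cfg)
        self.config = cfg

    @classmethod
    def from_medium(cls, medium: MediumModel, obj: ObjectMap,
                    layer_depths=None, config: MSTConfig | None = None,
                    reference_plane: str = "z0") -> "MSTModel":
        """Simulate the reflection matrix of a synthetic phantom and wrap it."""
        r = reflection_from_medium(medium, obj, reference_plane=reference_plane)
        depths = medium.depths if layer_depths is None else layer_depths
        return cls(r, depths, config=config)

    def fit(self) -> "MSTResults":
        raw = mst_iterate(self.reflection, self.config)
        return MSTResults(self, raw)


class MSTResults:
    """Fitted phase functions, rectified matrix and diagnostics."""

    def __init__(self, model: MSTModel, raw: MSTResult):
        self.model = model
        self._raw = raw

    # -- parameter estimates -------------------------------------------------
    @property
    def layer_phases(self) -> list[np.ndarray]:
        """Accumulated phase function per layer (radians, full lattice)."""
        return self._raw.accumulated_phases

    @property
    def fov_masks(self) -> list[np.ndarray]:
        return [e.fov_mask for e in self._raw.estimates]

    @property
    def identified_medium(self) -> MediumModel:
        return correction_medium(self.model.reflection.grid,
                                 self.layer_phases,
                                 self.model.config.layer_depths)

    @property
    def identified_transmission(self):
        return identified_transmission(self.identified_medium)

    # -- images ---------------------------------------------------------------
    @property
    def corrected_matrix(self) -> ReflectionMatrix:
        return self._raw.corrected_matrix

    @property
    def mst_image(self) -> np.ndarray:
        """Rectified confocal intensity image |diag R^c|^2."""
        return self._raw.mst_image

    @property
    def object_estimate(self) -> np.ndarray:
        """Complex reflectance estimate (diagonal of R^c)."""
        return self._raw.object_estimate

    def confocal_reference(self) -> np.ndarray:
        """Uncorrected confocal image for side-by-side comparison."""
        r0 = self.model.reflection
        if r0.input_plane != 0.0:
            r0 = transform_to_layer(r0, 0.0, 0.0)
        return confocal_image(r0)

    # -- diagnostics ----------------------------------------------------------
    @property
    def converged(self) -> bool:
        return self._raw.converged

    @property
    def cycles_run(self) -> int:
        return self._raw.cycles_run

    @property
    def xi1_trace(self) -> list[float]:
        return self._raw.xi1_trace

    @property
    def xi2_trace(self) -> list[float]:
        return self._raw.xi2_trace

    @property
    def increment_rms_trace(self) -> list[float]:
        return self._raw.increment_rms_trace

    @property
    def xi1(self) -> float:
        """Roundtrip ballistic enhancement of the identified stack."""
        if self.xi1_trace:
            return self.xi1_trace[-1]
        return ballistic_fraction(self.identified_transmission) ** -2

    @property
    def xi2(self) -> float:
        """Image-domain ballistic enhancement at convergence."""
        if self.xi2_trace:
            return self.xi2_trace[-1]
        r0 = self.model.reflection
        if r0.input_plane != 0.0:
            r0 = transform_to_layer(r0, 0.0, 0.0)
        eta_c = confocal_enhancement(r0, self.corrected_matrix)
        alpha = ballistic_contribution_alpha(
            r0, np.diagonal(self.corrected_matrix.values))
        return eta_c / alpha

    @property
    def identified_optical_thickness(self) -> float:
        """One-way thickness (in mean free paths) of the identified stack."""
        return optical_thickness(self.identified_transmission)

    def phase_correlations(self, truth_medium: MediumModel) -> list[float]:
        """Piston-free phase agreement per layer against a known stack."""
        scores = []
        for est, mask, plate in zip(self.layer_phases, self.fov_masks,
                                    truth_medium.plates):
            scores.append(pearson_score(est, plate.phase_map,
                                        mode="complex_phase", mask=mask))
        return scores

    def image_correlation(self, truth: ObjectMap) -> float:
        """Pearson agreement of the rectified image with |O|^2."""
        return pearson_score(self.mst_image, truth.intensity(),
                             mode="intensity")

    # -- presentation ---------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.config
        n = self.model.reflection.grid.n
        lines = [
            "Multiple Scattering Tracing Results",
            "=" * 51,
            f"grid: {n} x {n} px, pitch {self.model.reflection.grid.pitch:g} um,"
            f" wavelength {self.model.reflection.grid.wavelength:g} um,"
            f" NA {self.model.reflection.grid.na:g}",
            f"layers: {len(cfg.layer_depths)} at "
            + ", ".join(f"{z:g}" for z in cfg.layer_depths) + " um",
            f"traced scattering events (roundtrip): "
            f"{traced_scattering_events(len(cfg.layer_depths))}",
            f"cycles run: {self.cycles_run} "
            f"({'converged' if self.converged else 'not converged'})",
        ]
        if self.xi1_trace:
            lines.append(f"xi1 (roundtrip ballistic enhancement): "
                         f"{self.xi1:.4g}")
            lines.append(f"xi2 (image-domain ballistic enhancement): "
                         f"{self.xi2:.4g}")
            lines.append(f"identified one-way optical thickness: "
                         f"{self.identified_optical_thickness:.3f} l_s")
        if self.increment_rms_trace:
            lines.append(f"final max RMS phase increment: "
                         f"{self.increment_rms_trace[-1]:.2e} rad")
        lines.append("=" * 51)
        return "\n".join(lines)

    # -- plots ----------------------------------------------------------------
    def plot_phase_maps(self, truth_medium: MediumModel | None = None):
        """Panel of recovered (and optionally true) wrapped phase maps."""
        import matplotlib.pyplot as plt
        nlay = len(self.layer_phases)
        nrows = 2 if truth_medium is not None else 1
        fig, axes = plt.subplots(nrows, max(nlay, 1), squeeze=False,
                                 figsize=(3 * max(nlay, 1), 3 * nrows))
        for k in range(nlay):
            est = np.where(self.fov_masks[k],
                           np.angle(np.exp(1j * self.layer_phases[k])), np.nan)
            axes[0][k].imshow(est, cmap="twilight", vmin=-np.pi, vmax=np.pi)
            axes[0][k].set_title(f"layer {k + 1}")
            axes[0][k].axis("off")
            if truth_medium is not None:
                axes[1][k].imshow(truth_medium.plates[k].wrapped(),
                                  cmap="twilight", vmin=-np.pi, vmax=np.pi)
                axes[1][k].axis("off")
        return fig

    def plot_traces(self):
        """Per-cycle enhancement traces."""
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots()
        cyc = np.arange(1, len(self.xi1_trace) + 1)
        ax.plot(cyc, self.xi1_trace, "o-", label=r"$\xi_1$")
        if self.xi2_trace:
            ax.plot(cyc, self.xi2_trace, "s-", label=r"$\xi_2$")
        ax.set_xlabel("cycle")
        ax.set_ylabel("ballistic enhancement")
        ax.legend()
        return fig
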