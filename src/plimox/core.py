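"""Physical forward model for frequency-domain phosphorescence lifetime imaging.

Oxygen tension (pO2, mmHg) quenches the phosphorescence lifetime tau of an
injected probe according to the Stern-Volmer relation

    tau0 / tau = 1 + K_phi * tau0 * pO2,

where tau0 is the zero-oxygen lifetime and K_phi the quenching constant.
In the frequency domain the lifetime appears as a phase lag theta between the
modulated excitation and the emitted phosphorescence, tan(theta) = omega*tau,
and the gated intensity recorded at detector gain phase theta_n follows a
three-parameter sinusoid

    I(theta_n) = a0 + a1*cos(theta_n) + b1*sin(theta_n),

with theta = atan2(b1, a1).  This module holds the domain containers
(acquisition metadata, map geometry, parameter maps, oxygen maps, phase image
stacks) and the forward/backward primitives between pO2 and (a0, a1, b1).

Pixel vectorization is column-major throughout: pixel (r, c) (1-based) maps to
linear index (c-1)*R + r.  Within-column neighbours then differ by 1 in linear
index and across-column neighbours by R, which is what makes the banded
neighbourhood weighting matrix in :mod:`plimox.rls` correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionModel",
    "MapGeometry",
    "ParameterMaps",
    "OxygenMap",
    "PhaseImageStack",
    "build_design_matrix",
    "lifetime_from_po2",
    "po2_from_lifetime",
    "po2_from_phase_params",
    "params_to_po2_map",
    "phase_params_from_po2",
    "synthesize_intensities",
    "THETA_MIN",
]

#: Validity margin (radians) for recovered phases: theta must lie strictly
#: inside (THETA_MIN, pi/2 - THETA_MIN) for the lifetime chain to be applied.
THETA_MIN = 1e-6

# Defaults for acquisition metadata.  The probe constants are literature
# values for Pd-porphyrin at physiological temperature; the modulation period
# is taken as n_phases * phase-delay increment (74 us increments, 10 phases).
# All are configuration parameters, not measured constants of this package.
DEFAULT_N_PHASES = 10
DEFAULT_DT_S = 74e-6
DEFAULT_TAU0_S = 637e-6
DEFAULT_K_PHI = 381.0  # per (mmHg * s)


@dataclass(frozen=True)
class AcquisitionModel:
    """Acquisition metadata: gain-modulation phases and probe constants.

    Parameters
    ----------
    phases
        Gain-modulation phase angles theta_n in radians, all in [0, 2*pi).
        At least three pairwise distinct angles are required for the
        three-parameter sinusoid fit to be identifiable.
    omega
        Angular modulation frequency, rad/s.
    tau0
        Phosphorescence lifetime at zero oxygen, seconds.
    k_phi
        Stern-Volmer quenching constant, per (mmHg * s).
    """

    phases: np.ndarray
    omega: float
    tau0: float
    k_phi: float

    def __post_init__(self) -> None:
        phases = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "phases", phases)
        if phases.ndim != 1 or phases.size < 3:
            raise ValueError(
                f"need at least 3 modulation phases, got {phases.size}"
            )
        if np.any(phases < 0) or np.any(phases >= 2 * np.pi):
            raise ValueError("phases must lie in [0, 2*pi)")
        if np.unique(np.round(phases, 12)).size < 3:
            raise ValueError(
                "need at least 3 pairwise distinct phases for a full-rank "
                "design (rank-deficient sinusoid fit otherwise)"
            )
        if self.omega <= 0 or self.tau0 <= 0 or self.k_phi <= 0:
            raise ValueError("omega, tau0 and k_phi must be positive")

    @property
    def n_obs(self) -> int:
        """Number of phase-delayed observations S per pixel."""
        return int(self.phases.size)

    @property
    def theta_max(self) -> float:
        """Largest physical phase, arctan(omega * tau0), attained at pO2=0."""
        return float(np.arctan(self.omega * self.tau0))

    @classmethod
    def default(
        cls,
        n_phases: int = DEFAULT_N_PHASES,
        dt_s: float = DEFAULT_DT_S,
        tau0: float = DEFAULT_TAU0_S,
        k_phi: float = DEFAULT_K_PHI,
        omega: Optional[float] = None,
    ) -> "AcquisitionModel":
        """Equally spaced phases over one full modulation cycle.

        The modulation period defaults to ``n_phases * dt_s`` so the phase
        delays tile [0, 2*pi) exactly; ``omega`` may be given explicitly to
        override this inference.
        """
        if omega is None:
            omega = 2 * np.pi / (n_phases * dt_s)
        phases = np.arange(n_phases) * (2 * np.pi / n_phases)
        return cls(phases=phases, omega=omega, tau0=tau0, k_phi=k_phi)


@dataclass(frozen=True)
class MapGeometry:
    """Grid shape with the column-major vectorization convention."""

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("map dimensions must be positive")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def ravel(self, grid: np.ndarray) -> np.ndarray:
        """Vectorize an R x C grid column-major (pixel (r,c) -> (c-1)*R + r)."""
        grid = np.asarray(grid)
        if grid.shape != self.shape:
            raise ValueError(f"expected shape {self.shape}, got {grid.shape}")
        return grid.ravel(order="F")

    def unravel(self, vec: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`ravel`."""
        vec = np.asarray(vec)
        if vec.size != self.n_pixels:
            raise ValueError(f"expected {self.n_pixels} entries, got {vec.size}")
        return vec.reshape(self.shape, order="F")


@dataclass
class ParameterMaps:
    """Per-pixel sinusoid coefficients a0, a1, b1 over an R x C grid."""

    a0: np.ndarray
    a1: np.ndarray
    b1: np.ndarray

    def __post_init__(self) -> None:
        self.a0 = np.asarray(self.a0, dtype=float)
        self.a1 = np.asarray(self.a1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        if not (self.a0.shape == self.a1.shape == self.b1.shape):
            raise ValueError("a0, a1, b1 must share one grid shape")
        if self.a0.ndim != 2:
            raise ValueError("parameter maps must be 2-D grids")

    @property
    def geometry(self) -> MapGeometry:
        return MapGeometry(*self.a0.shape)

    def copy(self) -> "ParameterMaps":
        return ParameterMaps(self.a0.copy(), self.a1.copy(), self.b1.copy())


@dataclass
class OxygenMap:
    """Per-pixel oxygen tension (mmHg) with validity and vessel masks.

    ``valid_mask`` is False exactly where phase recovery failed (recovered
    phase outside the physical range); there ``po2`` holds NaN.
    ``vessel_mask``, when present, labels pixels 0=background, 1=artery,
    2=vein.
    """

    po2: np.ndarray
    valid_mask: np.ndarray
    vessel_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.po2 = np.asarray(self.po2, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.po2.shape != self.valid_mask.shape:
            raise ValueError("po2 and valid_mask shapes differ")
        if self.vessel_mask is not None:
            self.vessel_mask = np.asarray(self.vessel_mask)
            if self.vessel_mask.shape != self.po2.shape:
                raise ValueError("vessel_mask shape differs from po2")
        if np.any(~np.isfinite(self.po2[self.valid_mask])):
            raise ValueError("po2 must be finite where valid_mask is true")

    @property
    def geometry(self) -> MapGeometry:
        return MapGeometry(*self.po2.shape)


@dataclass
class PhaseImageStack:
    """S phase-delayed intensity images: frame s is the image at theta_s."""

    intensities: np.ndarray
    acquisition: AcquisitionModel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be an S x R x C array")
        if self.intensities.shape[0] != self.acquisition.n_obs:
            raise ValueError(
                f"frame count {self.intensities.shape[0]} does not match "
                f"acquisition n_obs {self.acquisition.n_obs}"
            )

    @property
    def geometry(self) -> MapGeometry:
        return MapGeometry(*self.intensities.shape[1:])

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]


def build_design_matrix(acquisition: AcquisitionModel) -> np.ndarray:
    """S x 3 design matrix with rows (1, cos theta_s, sin theta_s).

    For phases equally spaced over a full cycle A.T @ A is diagonal with
    entries (S, S/2, S/2), the structural fact the closed-form regularized
    estimates rely on.
    """
    th = acquisition.phases
    A = np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError(
            "design matrix is column-rank deficient: the phase set does not "
            "contain 3 effectively distinct angles"
        )
    return A


def lifetime_from_po2(po2, acquisition: AcquisitionModel):
    """Stern-Volmer: tau = tau0 / (1 + K_phi * tau0 * pO2).  Seconds."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("pO2 must be non-negative")
    out = acquisition.tau0 / (1.0 + acquisition.k_phi * acquisition.tau0 * po2)
    return out if out.ndim else float(out)


def po2_from_lifetime(tau, acquisition: AcquisitionModel):
    """Inverse Stern-Volmer: pO2 = (1/tau - 1/tau0) / K_phi.  mmHg."""
    tau = np.asarray(tau, dtype=float)
    out = (1.0 / tau - 1.0 / acquisition.tau0) / acquisition.k_phi
    return out if out.ndim else float(out)


def po2_from_phase_params(a1, b1, acquisition: AcquisitionModel):
    """Recover pO2 from sinusoid coefficients; flag unphysical phases.

    The phase is the quadrant-aware arctangent theta = atan2(b1, a1).  Only
    theta strictly inside (THETA_MIN, pi/2 - THETA_MIN) yields a finite
    positive lifetime tau = tan(theta)/omega; other pixels are flagged
    invalid (valid=False, pO2=NaN) rather than raised, so whole-image
    estimation never aborts.  Estimates are NOT clipped to physiological
    range: negative pO2 (tau > tau0) is a real failure mode of noisy
    least-squares fits and is deliberately left visible.

    Returns
    -------
    (po2, valid) — arrays (or scalars) of matching shape.
    """
    a1 = np.asarray(a1, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    theta = np.arctan2(b1, a1)
    valid = (theta > THETA_MIN) & (theta < np.pi / 2 - THETA_MIN)
    tau = np.where(valid, np.tan(np.where(valid, theta, 0.1)), np.nan)
    tau /= acquisition.omega
    with np.errstate(invalid="ignore", divide="ignore"):
        po2 = (1.0 / tau - 1.0 / acquisition.tau0) / acquisition.k_phi
    if po2.ndim == 0:
        return float(po2), bool(valid)
    return po2, valid


def params_to_po2_map(
    params: ParameterMaps, acquisition: AcquisitionModel
) -> OxygenMap:
    """Convert parameter maps to an oxygen map, flagging failed pixels."""
    po2, valid = po2_from_phase_params(params.a1, params.b1, acquisition)
    return OxygenMap(po2=po2, valid_mask=valid)


def phase_params_from_po2(
    po2, amplitude, baseline, acquisition: AcquisitionModel
):
    """Forward synthesis: pO2 -> (a0, a1, b1) for given modulation depth.

    theta = arctan(omega * tau(pO2)); a0 = baseline, a1 = amplitude*cos(theta),
    b1 = amplitude*sin(theta), so a1^2 + b1^2 = amplitude^2 exactly.
    Requires amplitude <= baseline so synthesized intensities stay
    non-negative.
    """
    po2 = np.asarray(po2, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(amplitude > baseline):
        raise ValueError(
            "amplitude must not exceed baseline (negative intensities)"
        )
    if np.any(amplitude <= 0):
        raise ValueError("amplitude must be positive")
    tau = lifetime_from_po2(po2, acquisition)
    theta = np.arctan(acquisition.omega * np.asarray(tau))
    a0 = np.broadcast_to(baseline, po2.shape).astype(float).copy()
    a1 = amplitude * np.cos(theta)
    b1 = amplitude * np.sin(theta)
    return a0, a1, b1


def synthesize_intensities(
    params: ParameterMaps, acquisition: AcquisitionModel
) -> PhaseImageStack:
    """Noise-free forward model: frame s = a0 + a1*cos(theta_s) + b1*sin(theta_s).

    Equals Y = A @ X in matrix form, with A the design matrix and X the
    3 x M stacked parameter matrix under column-major vectorization.
    """
    A = build_design_matrix(acquisition)
    X = np.stack([params.a0, params.a1, params.b1])  # 3 x R x C
    Y = np.einsum("sk,kij->sij", A, X)
    return PhaseImageStack(intensities=Y, acquisition=acquisition)
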