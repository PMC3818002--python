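"""Synthetic retinal oxygen tension phantoms and noisy phase stacks.

Emulates the vascular oxygenation pattern of the rat retina under normoxia:
arteries and veins radiate from the optic disc (diameter ~300 um, ~60 px at
5 um/px); arterial oxygen tension is ~60 mmHg at the disc rim and declines
approximately linearly with distance, while venous tension stays ~35 mmHg
everywhere.  Non-vessel pixels carry a constant plausible tissue value.
The phantom map is forward-modeled into S phase-delayed intensity images
through the Stern-Volmer / phase-sinusoid chain, and i.i.d. white Gaussian
noise at a prescribed SNR is added to the stack.

SNR is defined on mean squared signal (power): the noise variance is
sigma^2 = mean(I^2) / 10^(SNR_dB/10), averaged over all pixels and frames
of the noise-free stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    AcquisitionModel,
    OxygenMap,
    ParameterMaps,
    PhaseImageStack,
    phase_params_from_po2,
    synthesize_intensities,
)

__all__ = [
    "RetinaPhantomSpec",
    "NoiseSpec",
    "generate_po2_map",
    "generate_phase_stack",
    "add_awgn",
]

ARTERY_LABEL = 1
VEIN_LABEL = 2


@dataclass(frozen=True)
class RetinaPhantomSpec:
    """Geometric and physiological parameters of the synthetic retina.

    Defaults reproduce the simulated study conditions: a 485 x 600 px map
    (5 um/px), arterial tension 60 mmHg at the optic disc rim declining
    linearly to lose 15 mmHg at the farthest map corner, venous tension
    constant at 35 mmHg, and alternating radial arteries and veins.

    ``disc_diameter_px``, ``vessel_width_px`` and ``arterial_slope`` default
    to None, meaning "scale with the map": disc diameter min(R,C)/8 px
    (~300 um on the default map), vessel width max(2, min(R,C)/48) px
    (~50 um), and slope 15 mmHg spread over the rim-to-farthest-corner
    distance.
    """

    n_rows: int = 485
    n_cols: int = 600
    disc_center: Optional[tuple[float, float]] = None  # (row, col)
    disc_diameter_px: Optional[float] = None
    n_arteries: int = 6
    n_veins: int = 6
    arterial_po2_at_disc: float = 60.0
    venous_po2: float = 35.0
    arterial_slope: Optional[float] = None  # mmHg per pixel
    arterial_drop: float = 15.0  # mmHg lost from rim to farthest corner
    vessel_width_px: Optional[float] = None
    background_po2: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("phantom map too small")
        if min(self.arterial_po2_at_disc, self.venous_po2,
               self.background_po2) < 0:
            raise ValueError("pO2 values must be non-negative")
        if self.arterial_po2_at_disc <= self.venous_po2:
            raise ValueError(
                "normoxia ordering violated: arterial pO2 at the disc must "
                "exceed venous pO2"
            )
        if self.n_arteries < 1 or self.n_veins < 1:
            raise ValueError("need at least one artery and one vein")

    # resolved geometric defaults -------------------------------------
    @property
    def center(self) -> tuple[float, float]:
        if self.disc_center is not None:
            return self.disc_center
        return ((self.n_rows - 1) / 2.0, (self.n_cols - 1) / 2.0)

    @property
    def disc_radius(self) -> float:
        d = self.disc_diameter_px
        if d is None:
            d = min(self.n_rows, self.n_cols) / 8.0
        return d / 2.0

    @property
    def width(self) -> float:
        w = self.vessel_width_px
        if w is None:
            w = max(2.0, min(self.n_rows, self.n_cols) / 48.0)
        return float(w)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise level in dB SNR (inf = noise-free)."""

    snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if math.isnan(self.snr_db):
            raise ValueError("snr_db must be finite or +inf")


def generate_po2_map(spec: RetinaPhantomSpec) -> OxygenMap:
    """Radial artery/vein phantom with linear arterial decline.

    Vessels are straight radial spokes leaving the optic disc rim at
    seed-jittered angles, alternating artery/vein.  Along an artery the
    tension is arterial_po2_at_disc - slope * (distance beyond the rim),
    floored at venous_po2; veins are venous_po2 everywhere; background
    pixels carry background_po2.  Deterministic given the seed.
    """
    R, C = spec.n_rows, spec.n_cols
    cy, cx = spec.center
    rim = spec.disc_radius
    width = spec.width
    n_vessels = spec.n_arteries + spec.n_veins

    # vessels must fit side by side at the map's inscribed radius (spokes may
    # touch near the rim, but must not overlap over most of their length)
    circumference = 2 * np.pi * (min(R, C) / 2.0)
    if n_vessels * width > circumference:
        raise ValueError(
            f"{n_vessels} vessels of width {width} px do not fit in a "
            f"{R}x{C} map (circumference {circumference:.0f} px at the "
            f"inscribed radius)"
        )

    far = max(
        np.hypot(r - cy, c - cx)
        for r in (0, R - 1)
        for c in (0, C - 1)
    )
    slope = spec.arterial_slope
    if slope is None:
        slope = spec.arterial_drop / max(far - rim, 1.0)

    rng = np.random.default_rng(spec.seed)
    base = np.linspace(0.0, 2 * np.pi, n_vessels, endpoint=False)
    jitter = rng.uniform(-0.5, 0.5, n_vessels) * (2 * np.pi / n_vessels) * 0.3
    angles = base + jitter
    # alternate artery/vein as far as the counts allow, then fill the rest
    labels = np.empty(n_vessels, dtype=np.uint8)
    na = nv = 0
    for k in range(n_vessels):
        if (k % 2 == 0 and na < spec.n_arteries) or nv >= spec.n_veins:
            labels[k] = ARTERY_LABEL
            na += 1
        else:
            labels[k] = VEIN_LABEL
            nv += 1

    yy, xx = np.mgrid[0:R, 0:C]
    vy = yy - cy
    vx = xx - cx
    po2 = np.full((R, C), spec.background_po2, dtype=float)
    vmask = np.zeros((R, C), dtype=np.uint8)
    for ang, lab in zip(angles, labels):
        uy, ux = np.sin(ang), np.cos(ang)
        t = vy * uy + vx * ux            # distance along the spoke
        perp = np.abs(vy * ux - vx * uy)  # distance off the spoke axis
        sel = (t >= rim) & (perp <= width / 2.0)
        if lab == ARTERY_LABEL:
            val = np.maximum(
                spec.arterial_po2_at_disc - slope * (t[sel] - rim),
                spec.venous_po2,
            )
            po2[sel] = val
        else:
            po2[sel] = spec.venous_po2
        vmask[sel] = lab
    return OxygenMap(
        po2=po2, valid_mask=np.ones((R, C), dtype=bool), vessel_mask=vmask
    )


def generate_phase_stack(
    po2_map: OxygenMap,
    acquisition: AcquisitionModel,
    amplitude: float = 0.5,
    baseline: float = 1.0,
) -> PhaseImageStack:
    """Noise-free forward model of a pO2 map into S phase images."""
    a0, a1, b1 = phase_params_from_po2(
        po2_map.po2, amplitude, baseline, acquisition
    )
    params = ParameterMaps(a0=a0, a1=a1, b1=b1)
    return synthesize_intensities(params, acquisition)


def add_awgn(stack: PhaseImageStack, noise: NoiseSpec) -> PhaseImageStack:
    """Add i.i.d. zero-mean Gaussian noise at the prescribed SNR.

    sigma^2 = P_signal / 10^(snr_db/10) with P_signal the mean squared
    intensity over all pixels and frames of the input stack.  Deterministic
    given the seed; snr_db = inf returns an identical copy.
    """
    Y = stack.intensities
    if math.isinf(noise.snr_db):
        return PhaseImageStack(
            intensities=Y.copy(),
            acquisition=stack.acquisition,
            meta=dict(stack.meta),
        )
    p_signal = float(np.mean(Y**2))
    sigma = math.sqrt(p_signal / 10 ** (noise.snr_db / 10.0))
    rng = np.random.default_rng(noise.seed)
    noisy = Y + rng.normal(0.0, sigma, Y.shape)
    meta = dict(stack.meta)
    meta.update(snr_db=noise.snr_db, noise_seed=noise.seed, noise_sigma=sigma)
    return PhaseImageStack(
        intensities=noisy, acquisition=stack.acquisition, meta=meta
    )
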