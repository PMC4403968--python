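"""Synthetic ice-water diffusion phantom.

Emulates the temperature-pinned quality-assurance phantom used in
multi-centre DWI studies: five tubes of distilled water at 0 degrees C
(known diffusivity 1.099e-3 mm^2 s^-1, free isotropic diffusion, no
perfusion) plus one sucrose tube of lower diffusivity, surrounded by
ice-water that is treated as signal-free background here. Tubes are
cylinders along the slice axis: five water tubes evenly spaced on a ring
with the sucrose tube in the centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dwirepro.schemes import AcquisitionScheme
from dwirepro.signals import IVIMParams, ivim_signal, add_rician_noise

__all__ = ["PhantomSpec", "generate_phantom_image", "WATER_D_0C"]

#: Self-diffusion coefficient of water at 0 degrees C, mm^2 s^-1.
WATER_D_0C = 1.099e-3

#: Default sucrose-tube diffusivity, mm^2 s^-1 (lower than water, so the
#: tube appears darker on the ADC map; the exact value is configurable).
SUCROSE_D_DEFAULT = 0.5e-3


class ConfigurationError(ValueError):
    """Phantom geometry cannot be realised."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and ground-truth diffusivities of the synthetic phantom."""

    n_water_tubes: int = 5
    water_d: float = WATER_D_0C
    sucrose_d: float = SUCROSE_D_DEFAULT
    tube_radius_vox: float = 4.0
    image_shape: tuple[int, int, int] = (48, 48, 4)
    voxel_size_mm: tuple[float, float, float] = (1.8, 1.8, 5.0)
    s0: float = 1000.0

    SUCROSE_LABEL: int = field(default=0, init=False, repr=False)

    def __post_init__(self):
        if self.water_d <= 0:
            raise ConfigurationError(f"water_d must be > 0, got {self.water_d}")
        if self.n_water_tubes < 1:
            raise ConfigurationError("need at least one water tube")
        # sucrose label follows the water tubes (1..n)
        object.__setattr__(self, "SUCROSE_LABEL", self.n_water_tubes + 1)

    @property
    def water_labels(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_water_tubes + 1))

    def tube_centres(self) -> list[tuple[float, float]]:
        """In-plane centres: water tubes on a ring, sucrose in the middle."""
        nx, ny, _ = self.image_shape
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        ring = min(nx, ny) / 2.0 - self.tube_radius_vox - 2.0
        if ring <= self.tube_radius_vox:
            raise ConfigurationError(
                f"tubes of radius {self.tube_radius_vox} do not fit in "
                f"image of shape {self.image_shape}"
            )
        centres = []
        for k in range(self.n_water_tubes):
            theta = 2 * np.pi * k / self.n_water_tubes
            centres.append((cx + ring * np.cos(theta), cy + ring * np.sin(theta)))
        centres.append((cx, cy))  # sucrose
        # non-overlap check between every pair
        for i in range(len(centres)):
            for j in range(i + 1, len(centres)):
                d = np.hypot(centres[i][0] - centres[j][0],
                             centres[i][1] - centres[j][1])
                if d < 2 * self.tube_radius_vox:
                    raise ConfigurationError(
                        "tube geometry overlaps; reduce tube_radius_vox or "
                        "enlarge image_shape"
                    )
        return centres


def make_label_mask(spec: PhantomSpec) -> np.ndarray:
    """Integer label volume: 0 background, 1..n water tubes, n+1 sucrose."""
    nx, ny, nz = spec.image_shape
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    centres = spec.tube_centres()
    for idx, (cx, cy) in enumerate(centres):
        lab = idx + 1  # water tubes 1..n, sucrose n+1
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.tube_radius_vox**2
        labels[inside, :] = lab
    return labels


def generate_phantom_image(
    spec: PhantomSpec,
    scheme: AcquisitionScheme,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a 4-D phantom acquisition.

    Returns ``(volume, labels)`` where ``volume`` has shape
    ``image_shape + (n_measurements,)``. Water voxels decay
    mono-exponentially with ``spec.water_d`` (f = 0 -- the phantom is not
    perfused), sucrose voxels with ``spec.sucrose_d``, background is
    signal-free. Rician noise of scale ``sigma`` is applied to the whole
    volume; identical seeds give bit-identical output.
    """
    labels = make_label_mask(spec)
    nmeas = scheme.n_measurements
    vol = np.zeros(spec.image_shape + (nmeas,), dtype=float)

    water = ivim_signal(
        IVIMParams(s0=spec.s0, d=spec.water_d, d_star=spec.water_d, f=0.0),
        scheme,
    )
    sucrose = ivim_signal(
        IVIMParams(s0=spec.s0, d=spec.sucrose_d, d_star=spec.sucrose_d, f=0.0),
        scheme,
    )
    for lab in spec.water_labels:
        vol[labels == lab] = water
    vol[labels == spec.SUCROSE_LABEL] = sucrose

    vol = add_rician_noise(vol, sigma, seed)
    return vol, labels
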