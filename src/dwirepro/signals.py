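"""Forward signal models and Rician magnitude noise.

The bi-exponential IVIM model writes the diffusion-weighted signal as

    S(b) = S0 * ( f * exp(-b * D*) + (1 - f) * exp(-b * D) )

where D is the tissue diffusion coefficient, D* the fast perfusion-driven
pseudo-diffusion coefficient and f the perfusion fraction. With f = 0 this
reduces to the mono-exponential ADC model. The tensor model is
S(b, g) = S0 * exp(-b * g^T D g) for a symmetric PSD tensor D.

Magnitude MRI noise is Rician: the noiseless signal sits in one quadrature
channel and independent Gaussian noise is added to both channels before
taking the magnitude. This produces the rectified noise floor that biases
FA and f upward at low SNR, which a plain additive Gaussian model cannot
reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dwirepro.schemes import AcquisitionScheme

__all__ = [
    "IVIMParams",
    "TensorParams",
    "ivim_signal",
    "tensor_signal",
    "add_rician_noise",
]


class ParameterError(ValueError):
    """Model parameters violate an invariant."""


@dataclass(frozen=True)
class IVIMParams:
    """Ground-truth IVIM voxel parameters.

    s0 : unattenuated signal (> 0, arbitrary units)
    d : tissue diffusion coefficient D, mm^2 s^-1
    d_star : pseudo-diffusion coefficient D*, mm^2 s^-1 (>= d)
    f : perfusion fraction in [0, 1]
    """

    s0: float
    d: float
    d_star: float
    f: float

    def __post_init__(self):
        if not self.s0 > 0:
            raise ParameterError(f"s0 must be > 0, got {self.s0}")
        if not 0 <= self.f <= 1:
            raise ParameterError(f"f must be in [0, 1], got {self.f}")
        if self.d < 0:
            raise ParameterError(f"d must be >= 0, got {self.d}")
        if self.d_star < self.d:
            raise ParameterError(
                f"d_star ({self.d_star}) must be >= d ({self.d})"
            )


@dataclass(frozen=True)
class TensorParams:
    """Ground-truth diffusion-tensor voxel parameters (tensor in mm^2 s^-1)."""

    s0: float
    tensor: np.ndarray

    def __post_init__(self):
        if not self.s0 > 0:
            raise ParameterError(f"s0 must be > 0, got {self.s0}")
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3):
            raise ParameterError(f"tensor must be 3x3, got shape {t.shape}")
        if not np.allclose(t, t.T, atol=1e-12):
            raise ParameterError("tensor must be symmetric (tol 1e-12)")
        ev = np.linalg.eigvalsh(t)
        if np.any(ev < -1e-15):
            raise ParameterError(f"tensor must be PSD, eigenvalues {ev}")
        object.__setattr__(self, "tensor", t)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending."""
        return np.sort(np.linalg.eigvalsh(self.tensor))[::-1]


def ivim_signal(params: IVIMParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Noiseless IVIM signal at every measurement of ``scheme``.

    S(b) = s0 * (f * exp(-b d*) + (1-f) * exp(-b d)); S(0) = s0 exactly.
    """
    b = scheme.b_values
    return params.s0 * (
        params.f * np.exp(-b * params.d_star)
        + (1.0 - params.f) * np.exp(-b * params.d)
    )


def tensor_signal(params: TensorParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Noiseless tensor signal s0 * exp(-b g^T D g) per measurement.

    b=0 measurements return s0 regardless of direction.
    """
    b = scheme.b_values
    g = scheme.gradient_directions
    if g is None:
        raise ParameterError("tensor_signal requires gradient directions")
    # quadratic form per measurement; zero-weighted rows contribute exp(0)
    q = np.einsum("ij,jk,ik->i", g, params.tensor, g)
    return params.s0 * np.exp(-b * np.where(b > 0, q, 0.0))


def add_rician_noise(signal: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Rician-corrupt a magnitude signal.

    Each output value is sqrt((s + n1)^2 + n2^2) with n1, n2 independent
    N(0, sigma^2) draws. ``sigma=0`` returns the input unchanged (exactly).
    The RNG is local to the call: identical seeds give identical output.
    """
    if sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {sigma}")
    s = np.asarray(signal, dtype=float)
    if sigma == 0:
        return s.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, s.shape)
    n2 = rng.normal(0.0, sigma, s.shape)
    return np.sqrt((s + n1) ** 2 + n2**2)
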