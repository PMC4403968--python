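"""Diffusion acquisition schemes and FSL-style gradient-table I/O.

An :class:`AcquisitionScheme` lists the b-values (s mm^-2) of a DWI
protocol and, where relevant, the unit gradient direction of each
diffusion-weighted measurement. Trace-weighted (direction-averaged) DWI
needs only the b-values; tensor estimation needs at least six
non-collinear directions at b > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AcquisitionScheme", "read_bval_bvec", "write_bval_bvec"]

#: b-values (s mm^-2) acquired for the IVIM protocol at every centre.
IVIM_BVALUES = (0.0, 50.0, 100.0, 300.0, 500.0, 600.0, 1000.0)

#: Typical clinical ADC b-value set.
ADC_BVALUES = (0.0, 500.0, 1000.0)


class SchemeError(ValueError):
    """Invalid acquisition scheme."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values plus (optional) unit gradient directions, one per measurement.

    Parameters
    ----------
    b_values:
        One diffusion weighting per measurement, s mm^-2, all >= 0;
        at least one must be 0.
    gradient_directions:
        ``(n, 3)`` unit vectors, one per measurement, or ``None`` for
        trace-weighted DWI. Directions of b=0 rows are ignored.
    """

    b_values: np.ndarray
    gradient_directions: np.ndarray | None = None

    def __init__(self, b_values, gradient_directions=None):
        b = np.asarray(b_values, dtype=float)
        object.__setattr__(self, "b_values", b)
        if gradient_directions is not None:
            g = np.asarray(gradient_directions, dtype=float)
            if g.shape != (b.size, 3):
                raise SchemeError(
                    f"gradient_directions shape {g.shape} != ({b.size}, 3)"
                )
            object.__setattr__(self, "gradient_directions", g)
        else:
            object.__setattr__(self, "gradient_directions", None)
        self._validate()

    def _validate(self) -> None:
        b = self.b_values
        if b.ndim != 1 or b.size == 0:
            raise SchemeError("b_values must be a non-empty 1-D sequence")
        if np.any(b < 0):
            raise SchemeError("b_values must be non-negative")
        if not np.any(b == 0):
            raise SchemeError("at least one b=0 measurement is required")
        g = self.gradient_directions
        if g is not None:
            weighted = b > 0
            norms = np.linalg.norm(g[weighted], axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise SchemeError("gradient directions at b>0 must have unit norm")

    @property
    def n_measurements(self) -> int:
        return self.b_values.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b_values == 0))

    @property
    def unique_b(self) -> np.ndarray:
        return np.unique(self.b_values)

    def supports_tensor_fit(self) -> bool:
        """True when >= 6 non-collinear directions exist at b > 0."""
        if self.gradient_directions is None:
            return False
        g = self.gradient_directions[self.b_values > 0]
        if g.shape[0] < 6:
            return False
        # Non-collinearity is what the rank of the quadratic-form design
        # actually requires; check it directly.
        d = _tensor_design_rows(g)
        return np.linalg.matrix_rank(d) >= 6


def _tensor_design_rows(g: np.ndarray) -> np.ndarray:
    """Rows ``(gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)`` for each direction."""
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )


def spherical_directions(n: int, seed: int = 0) -> np.ndarray:
    """``n`` approximately uniform unit vectors (deterministic for a seed)."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def dti_scheme(n_directions: int = 32, b: float = 1000.0, n_b0: int = 1,
               seed: int = 0) -> AcquisitionScheme:
    """Single-shell tensor scheme: ``n_b0`` b=0 plus ``n_directions`` at ``b``."""
    g = spherical_directions(n_directions, seed=seed)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    dirs = np.vstack([np.zeros((n_b0, 3)), g])
    return AcquisitionScheme(bvals, dirs)


def read_bval_bvec(bval_path: str | Path,
                   bvec_path: str | Path | None = None) -> AcquisitionScheme:
    """Read an FSL-dialect ``.bval`` (one row) / ``.bvec`` (three rows) pair."""
    b = np.loadtxt(bval_path, ndmin=1).ravel()
    g = None
    if bvec_path is not None:
        raw = np.loadtxt(bvec_path, ndmin=2)
        if raw.shape[0] != 3:
            raise SchemeError(f"bvec file must have 3 rows, got {raw.shape[0]}")
        g = raw.T
        # FSL files carry limited precision; renormalise near-unit rows.
        # Zero vectors (b=0 rows) are left as written.
        norms = np.linalg.norm(g, axis=1)
        close = np.abs(norms - 1.0) < 1e-3
        g[close] /= norms[close, None]
    return AcquisitionScheme(b, g)


def write_bval_bvec(scheme: AcquisitionScheme, bval_path: str | Path,
                    bvec_path: str | Path | None = None) -> None:
    """Write FSL-dialect gradient tables (space-separated rows)."""
    Path(bval_path).write_text(
        " ".join(f"{b:g}" for b in scheme.b_values) + "\n"
    )
    if bvec_path is not None:
        g = scheme.gradient_directions
        if g is None:
            g = np.zeros((scheme.n_measurements, 3))
        rows = [" ".join(f"{x:.8f}" for x in g[:, i]) for i in range(3)]
        Path(bvec_path).write_text("\n".join(rows) + "\n")
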