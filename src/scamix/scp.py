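"""Single-component-point (SCP) detection on two-row mixtures.

A two-row linear mixture model ``X = A S`` (row 0 = reference sample, row 1
= test sample) is lifted to its complex analytic representation
``x~ = x + i H(x)``, the Hilbert transform taken per row along the feature
(m/z) axis in file order. At a feature where essentially one component is
active, the real 2-vector across the rows and its quadrature 2-vector point
in the same or in exactly opposite directions; such features pin down a
column of the mixing matrix. The selection criterion for feature ``k`` is

    |R(x~_k)^T I(x~_k)| / (||R(x~_k)|| * ||I(x~_k)||)  >=  cos(delta_theta)

with ``delta_theta`` the tolerated angular displacement from 0 or pi
radians. The absolute value implements the "same or opposite direction"
rule. Features whose real or quadrature 2-vector has zero norm are excluded
from candidacy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .errors import DimensionError, FormatError, ScpEmptyError

__all__ = ["AnalyticMixture", "ScpSet", "analytic_continuation",
           "analytic_mixture", "select_scps"]

log = logging.getLogger(__name__)


@dataclass
class AnalyticMixture:
    """Real and quadrature parts of a 2 x K mixture, per row."""

    real_part: np.ndarray  # 2 x K
    imag_part: np.ndarray  # 2 x K

    def __post_init__(self):
        if self.real_part.shape != self.imag_part.shape:
            raise DimensionError("real/imag parts must have identical shapes")


@dataclass
class ScpSet:
    """Sorted, unique feature indices passing the SCP criterion."""

    indices: np.ndarray
    delta_theta: float

    def __len__(self) -> int:
        return len(self.indices)


def analytic_continuation(x: np.ndarray) -> np.ndarray:
    """Complex analytic signal ``x + i H(x)`` of a real feature series.

    Frequency-domain construction: positive frequencies doubled, negative
    zeroed, DC (and Nyquist for even K) kept, so the imaginary output is the
    quadrature series. A constant series has zero quadrature.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise DimensionError("need at least 2 features")
    if not np.isfinite(x).all():
        raise FormatError("analytic continuation requires finite input")
    return hilbert(x, axis=-1)


def analytic_mixture(rows: np.ndarray) -> AnalyticMixture:
    """Analytic continuation of both rows of a 2 x K mixture."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] != 2:
        raise DimensionError(f"expected a 2 x K mixture, got shape {rows.shape}")
    z = analytic_continuation(rows)
    return AnalyticMixture(real_part=z.real.copy(), imag_part=z.imag.copy())


def select_scps(mixture: AnalyticMixture, delta_theta: float) -> ScpSet:
    """Retain features whose real/quadrature 2-vectors are aligned.

    ``delta_theta`` is in degrees, strictly inside (0, 90). Raises
    :class:`ScpEmptyError` when no feature passes (the remedy is a larger
    tolerance).
    """
    if not 0.0 < delta_theta < 90.0:
        raise ValueError(f"delta_theta must be in (0, 90) degrees, got {delta_theta}")
    r, im = mixture.real_part, mixture.imag_part
    num = np.abs(np.einsum("ij,ij->j", r, im))
    r_norm = np.linalg.norm(r, axis=0)
    i_norm = np.linalg.norm(im, axis=0)
    valid = (r_norm > 0) & (i_norm > 0)
    n_flat = int((~valid).sum())
    if n_flat:
        log.debug("excluding %d flat features with zero-norm 2-vectors", n_flat)
    ratio = np.zeros(r.shape[1])
    ratio[valid] = num[valid] / (r_norm[valid] * i_norm[valid])
    mask = valid & (ratio >= np.cos(np.radians(delta_theta)))
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise ScpEmptyError(
            f"no single-component points at delta_theta={delta_theta} deg; "
            f"increase delta_theta", n_selected=0)
    return ScpSet(indices=indices, delta_theta=float(delta_theta))
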