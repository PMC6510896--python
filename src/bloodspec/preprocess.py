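"""Spectral preprocessing: rubber-band baseline, vector normalisation,
Savitzky-Golay smoothing / derivatives, and the two standard recipes.

Recipe A — rubber-band baseline correction followed by vector normalisation —
gives spectra suitable for direct intensity reading.  Recipe B — Savitzky-
Golay second derivative (window 9, polynomial order 2) followed by vector
normalisation — sharpens overlapping bands and removes baseline in one step;
it is the usual input to classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import DegenerateInputError, ParameterError
from .io import SampleMeta, SpectralDataset, Spectrum

VARIANT_A = "A_rubberband_vecnorm"
VARIANT_B = "B_sg2d_vecnorm"
_VARIANT_ALIASES = {"A": VARIANT_A, "B": VARIANT_B, VARIANT_A: VARIANT_A, VARIANT_B: VARIANT_B}


@dataclass(frozen=True)
class PreprocessRecipe:
    """One of the two preprocessing recipes.

    Parameters
    ----------
    variant
        ``"A_rubberband_vecnorm"`` or ``"B_sg2d_vecnorm"`` (``"A"``/``"B"``
        accepted).
    sg_window, sg_polyorder
        Savitzky-Golay filter length (odd) and polynomial order; defaults 9
        and 2.
    sg_deriv_order
        0 for smoothing, 2 for the second derivative (forced to 2 by
        variant B).
    center_before_norm
        If True, subtract the spectrum mean before unit-norm scaling
        (the OPUS-style dialect); default False (plain Euclidean scaling).
    """

    variant: str = VARIANT_B
    sg_window: int = 9
    sg_polyorder: int = 2
    sg_deriv_order: int = 2
    center_before_norm: bool = False

    def __post_init__(self) -> None:
        v = _VARIANT_ALIASES.get(self.variant)
        if v is None:
            raise ParameterError(f"unknown recipe variant {self.variant!r}")
        object.__setattr__(self, "variant", v)
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ParameterError("sg_window must be odd and > sg_polyorder")
        if v == VARIANT_B and self.sg_deriv_order != 2:
            raise ParameterError("variant B implies sg_deriv_order = 2")
        if self.sg_deriv_order > self.sg_polyorder:
            raise ParameterError("sg_deriv_order must be <= sg_polyorder")


# ----------------------------------------------------------------------
# primitives (array level + Spectrum level)
# ----------------------------------------------------------------------

def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Andrew's monotone-chain lower convex hull of (x, y); x ascending."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j -> i
            if (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def rubberband_arrays(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rubber-band baseline of one spectrum given as plain arrays.

    Returns ``(corrected, baseline)`` where the baseline is the lower convex
    hull of the point set, linearly interpolated between hull vertices and
    anchored at both endpoints, and ``corrected = y - baseline >= 0``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise DegenerateInputError("rubber-band correction needs >= 3 points")
    idx = _lower_hull_indices(x, y)
    baseline = np.interp(x, x[idx], y[idx])
    corrected = y - baseline
    corrected[idx] = 0.0  # exact zeros at hull vertices
    # snap interpolation round-off to zero (relative to the spectrum range)
    span = float(np.ptp(y))
    corrected[np.abs(corrected) <= 1e-12 * max(span, 1.0)] = 0.0
    np.maximum(corrected, 0.0, out=corrected)
    return corrected, baseline


def rubberband_baseline(s: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Rubber-band baseline correction of a :class:`Spectrum`."""
    corrected, baseline = rubberband_arrays(s.wavenumbers, s.absorbance)
    return (
        Spectrum(s.wavenumbers.copy(), corrected, s.meta),
        Spectrum(s.wavenumbers.copy(), baseline, s.meta),
    )


def vector_normalize_arrays(y: np.ndarray, center: bool = False) -> np.ndarray:
    y = np.asarray(y, float)
    if center:
        y = y - y.mean()
    norm = np.linalg.norm(y)
    if norm == 0.0:
        raise DegenerateInputError("cannot vector-normalise an all-zero spectrum")
    return y / norm


def vector_normalize(s: Spectrum, center: bool = False) -> Spectrum:
    """Scale a spectrum to unit Euclidean norm (optionally mean-centred first)."""
    return Spectrum(s.wavenumbers.copy(), vector_normalize_arrays(s.absorbance, center), s.meta)


def savitzky_golay_arrays(
    y: np.ndarray, spacing: float, window: int, polyorder: int, deriv: int = 0
) -> np.ndarray:
    """Savitzky-Golay filter with derivatives taken per cm^-1.

    Edge points are evaluated from the polynomial fit to the nearest full
    window (scipy's ``mode="interp"``), so the output has the input length.
    """
    y = np.asarray(y, float)
    if window % 2 == 0 or window <= polyorder:
        raise ParameterError("window must be odd and > polyorder")
    if deriv > polyorder:
        raise ParameterError("deriv must be <= polyorder")
    if y.size < window:
        raise ParameterError(f"spectrum length {y.size} < window {window}")
    return savgol_filter(y, window, polyorder, deriv=deriv, delta=spacing, mode="interp")


def savitzky_golay(s: Spectrum, window: int = 9, polyorder: int = 2, deriv: int = 0) -> Spectrum:
    """Savitzky-Golay smoothing or derivative of a :class:`Spectrum`."""
    spacing = float(np.diff(s.wavenumbers).mean()) if s.wavenumbers.size >= 2 else 1.0
    out = savitzky_golay_arrays(s.absorbance, spacing, window, polyorder, deriv)
    return Spectrum(s.wavenumbers.copy(), out, s.meta)


# ----------------------------------------------------------------------
# dataset-level recipe application
# ----------------------------------------------------------------------

def apply_recipe(ds: SpectralDataset, recipe: PreprocessRecipe) -> SpectralDataset:
    """Apply a preprocessing recipe to every spectrum of a dataset.

    Variant A: rubber-band baseline then vector normalisation.
    Variant B: Savitzky-Golay derivative then vector normalisation.
    The axis and metadata records are untouched.
    """
    n, _ = ds.matrix.shape
    out = np.empty_like(ds.matrix)
    if recipe.variant == VARIANT_A:
        for i in range(n):
            corrected, _ = rubberband_arrays(ds.axis, ds.matrix[i])
            out[i] = vector_normalize_arrays(corrected, recipe.center_before_norm)
    else:
        spacing = float(np.diff(ds.axis).mean()) if ds.axis.size >= 2 else 1.0
        deriv = savgol_filter(
            ds.matrix,
            recipe.sg_window,
            recipe.sg_polyorder,
            deriv=recipe.sg_deriv_order,
            delta=spacing,
            mode="interp",
            axis=1,
        )
        for i in range(n):
            out[i] = vector_normalize_arrays(deriv[i], recipe.center_before_norm)
    return ds.with_matrix(out)
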