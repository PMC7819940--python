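"""Scatter removal and unit-variance scaling for EEM data.

Raw EEMs are contaminated by three scatter ridges that carry no fluorophore
information and break trilinearity:

* first-order Rayleigh scatter along ``em = ex``,
* second-order Rayleigh scatter along ``em = 2*ex``,
* water Raman scatter, red-shifted from the excitation line by a fixed
  wavenumber (~3400 cm^-1 for the OH stretch).

:func:`remove_scatter` excises (sets missing) or interpolates over bands
around these ridges.  Excision suits PARAFAC, whose masked ALS handles
missing cells; interpolation suits PLS, which needs a dense matrix.

:func:`uv_scale` performs unit-variance scaling (autoscaling) of the
unfolded calibration matrix, column by column, and records the calibration
means/SDs so validation rows can be scaled with the same parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from serumeem.eem_core import EEM


@dataclass(frozen=True)
class ScatterBands:
    """Half-widths (nm) of the excised bands around each scatter ridge.

    ``raman_shift`` is the Stokes shift of the water Raman line in cm^-1.
    ``mode`` is "excise" (cells -> NaN) or "interpolate" (cells replaced by
    linear interpolation along the emission axis).
    """

    rayleigh1_halfwidth: float = 15.0
    rayleigh2_halfwidth: float = 15.0
    raman_shift: float = 3400.0
    raman_halfwidth: float = 10.0
    mode: str = "excise"

    def __post_init__(self) -> None:
        for name in ("rayleigh1_halfwidth", "rayleigh2_halfwidth",
                     "raman_halfwidth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.raman_shift <= 0:
            raise ValueError("raman_shift must be > 0")
        if self.mode not in ("excise", "interpolate"):
            raise ValueError(f"mode must be excise|interpolate, got {self.mode!r}")


def raman_center(ex: float, shift: float) -> float:
    """Emission wavelength (nm) of the Raman ridge for excitation ``ex`` (nm).

    Converting the Stokes shift from wavenumber: ``em = 1/(1/ex - shift*1e-7)``
    with ``shift`` in cm^-1 and wavelengths in nm.
    """
    inv = 1.0 / ex - shift * 1e-7
    if inv <= 0:
        raise ValueError(
            f"nonphysical Raman line: ex={ex} nm, shift={shift} cm^-1"
        )
    return 1.0 / inv


def scatter_mask(ex_values: np.ndarray, em_values: np.ndarray,
                 bands: ScatterBands) -> np.ndarray:
    """Boolean [em x ex] mask of cells lying on any scatter ridge."""
    ex = np.asarray(ex_values, dtype=float)[None, :]
    em = np.asarray(em_values, dtype=float)[:, None]
    mask = np.abs(em - ex) <= bands.rayleigh1_halfwidth
    mask |= np.abs(em - 2.0 * ex) <= bands.rayleigh2_halfwidth
    raman_em = np.array([raman_center(x, bands.raman_shift)
                         for x in np.ravel(ex)])[None, :]
    mask |= np.abs(em - raman_em) <= bands.raman_halfwidth
    return mask


def remove_scatter(eem: EEM, bands: ScatterBands | None = None) -> EEM:
    """Remove scatter-ridge cells from one EEM.

    In "excise" mode masked cells become NaN.  In "interpolate" mode each
    masked cell is replaced by linear interpolation along the emission axis
    between the nearest flanking unmasked cells of the same excitation
    column (constant extension at the column ends).  Cells off every ridge
    are never altered; excision is idempotent.
    """
    bands = bands or ScatterBands()
    mask = scatter_mask(eem.ex_grid.values, eem.em_grid.values, bands)
    out = eem.copy()
    if bands.mode == "excise":
        out.intensity[mask] = np.nan
        return out
    em = eem.em_grid.values
    for col in range(mask.shape[1]):
        m = mask[:, col]
        if not m.any():
            continue
        good = ~m & np.isfinite(out.intensity[:, col])
        if not good.any():
            out.intensity[m, col] = np.nan
            continue
        out.intensity[m, col] = np.interp(em[m], em[good],
                                          out.intensity[good, col])
    return out


@dataclass
class ScalingParams:
    """Per-variable calibration mean/SD plus the retained-column mask.

    ``kept`` indexes into the original column order; zero-variance columns
    are dropped and listed in ``dropped``.
    """

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray
    dropped: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_variables(self) -> int:
        return len(self.kept)


def uv_scale(X: np.ndarray) -> tuple[np.ndarray, ScalingParams]:
    """Unit-variance scale a calibration matrix column by column.

    Each retained column is centred and divided by its sample standard
    deviation (n-1 denominator).  Zero-variance columns are dropped and
    flagged in the returned :class:`ScalingParams`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("uv_scale needs a 2-D matrix with >= 2 rows")
    if np.isnan(X).any():
        raise ValueError("uv_scale input must not contain missing values")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    kept = np.nonzero(keep)[0]
    dropped = np.nonzero(~keep)[0]
    params = ScalingParams(mean=mean[keep], sd=sd[keep], kept=kept,
                           dropped=dropped)
    scaled = (X[:, keep] - params.mean) / params.sd
    return scaled, params


def apply_scaling(params: ScalingParams, X: np.ndarray) -> np.ndarray:
    """Scale new rows with stored calibration means/SDs.

    ``X`` must have the original (pre-drop) column count; the dropped
    columns are removed before scaling.
    """
    X = np.asarray(X, dtype=float)
    n_orig = len(params.kept) + len(params.dropped)
    if X.ndim != 2 or X.shape[1] != n_orig:
        raise ValueError(
            f"expected {n_orig} columns, got {X.shape[1] if X.ndim == 2 else X.shape}"
        )
    return (X[:, params.kept] - params.mean) / params.sd
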