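"""Data model for excitation-emission matrices (EEMs) and stacks of them.

An EEM is a fluorescence intensity surface sampled on a rectangular grid of
excitation x emission wavelengths; a stack of EEMs sharing grids forms the
three-way array (excitation x emission x scan) consumed by PARAFAC, and can
be unfolded into the two-way (scan x wavelength-pair) matrix consumed by PLS.

Conventions (enforced throughout the package):

* ``EEM.intensity`` is stored ``[emission x excitation]`` -- emission varies
  along rows, matching the usual contour-plot orientation.
* Missing cells (e.g. excised scatter) are ``NaN``.
* Unfolding is excitation-major: all emission wavelengths for the first
  excitation wavelength, then the next excitation, and so on.  The order is
  recorded in a :class:`VariableMap` so coefficient/VIP vectors can be folded
  back into contour maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class GridError(ValueError):
    """Raised for inconsistent wavelength-grid definitions."""


class FormatError(ValueError):
    """Raised for malformed EEM CSV files."""


@dataclass(frozen=True)
class WavelengthGrid:
    """An inclusive arithmetic sequence of wavelengths in nm."""

    start: float
    end: float
    step: float
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.start == other.start
            and self.end == other.end
            and self.step == other.step
        )

    def __hash__(self) -> int:
        return hash((self.start, self.end, self.step))

    def index_of(self, wavelength: float) -> int:
        """Index of the grid point closest to ``wavelength``."""
        return int(np.argmin(np.abs(self.values - wavelength)))


def make_grid(start: float, end: float, step: float) -> WavelengthGrid:
    """Build a wavelength grid from ``start`` to ``end`` inclusive.

    ``(end - start)`` must be an exact multiple of ``step``; both endpoints
    are included, so the grid has ``(end - start)/step + 1`` points.
    """
    if step <= 0:
        raise GridError(f"step must be positive, got {step}")
    if end < start:
        raise GridError(f"end ({end}) must be >= start ({start})")
    n_steps = (end - start) / step
    if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, abs(n_steps)):
        raise GridError(
            f"range {start}-{end} nm is not divisible by step {step} nm"
        )
    n = int(round(n_steps)) + 1
    values = start + step * np.arange(n)
    values[-1] = end  # guard against float drift at the endpoint
    return WavelengthGrid(start=start, end=end, step=step, values=values)


def _grid_from_values(values: np.ndarray, axis_name: str) -> WavelengthGrid:
    """Infer a grid from header values; they must be evenly spaced ascending."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise FormatError(f"{axis_name} header is empty")
    if len(values) == 1:
        return WavelengthGrid(values[0], values[0], 1.0, values.copy())
    diffs = np.diff(values)
    if np.any(diffs <= 0):
        bad = int(np.argmax(diffs <= 0))
        raise FormatError(
            f"{axis_name} header not strictly increasing at position {bad + 1}"
        )
    step = diffs[0]
    if not np.allclose(diffs, step, rtol=0, atol=1e-6):
        bad = int(np.argmax(~np.isclose(diffs, step, rtol=0, atol=1e-6)))
        raise FormatError(
            f"{axis_name} header spacing changes at position {bad + 1}: "
            f"{diffs[bad]} after step {step}"
        )
    return WavelengthGrid(values[0], values[-1], step, values.copy())


@dataclass
class EEM:
    """One excitation-emission matrix scan.

    ``intensity`` has shape ``(len(em_grid), len(ex_grid))``; NaN marks a
    missing cell.  ``sample_id`` and ``replicate_id`` identify the scan within
    a stack (analytical replicates share a ``sample_id``).
    """

    ex_grid: WavelengthGrid
    em_grid: WavelengthGrid
    intensity: np.ndarray
    sample_id: str = ""
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        expected = (len(self.em_grid), len(self.ex_grid))
        if self.intensity.shape != expected:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != (em, ex) {expected}"
            )
        finite = np.isfinite(self.intensity)
        missing = np.isnan(self.intensity)
        if not np.all(finite | missing):
            raise ValueError("intensity contains non-finite, non-NaN entries")
        if not finite.any():
            raise ValueError("EEM has no observed (non-missing) entries")

    def copy(self) -> "EEM":
        return EEM(self.ex_grid, self.em_grid, self.intensity.copy(),
                   self.sample_id, self.replicate_id)


@dataclass
class EEMStack:
    """An ordered collection of EEMs on identical grids.

    ``reference`` optionally maps ``sample_id`` to the reference retinol
    concentration (IU/dl) used as the calibration target.
    """

    eems: list[EEM]
    reference: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.eems:
            raise ValueError("stack must contain at least one EEM")

    def __len__(self) -> int:
        return len(self.eems)

    @property
    def ex_grid(self) -> WavelengthGrid:
        return self.eems[0].ex_grid

    @property
    def em_grid(self) -> WavelengthGrid:
        return self.eems[0].em_grid

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.eems]

    def to_tensor(self) -> np.ndarray:
        """Three-way array, shape (n_ex, n_em, n_scans)."""
        return np.stack([e.intensity.T for e in self.eems], axis=2)

    def reference_vector(self) -> np.ndarray:
        """Per-scan reference values, replicates inheriting their sample's."""
        if self.reference is None:
            raise ValueError("stack carries no reference table")
        try:
            return np.array([self.reference[e.sample_id] for e in self.eems])
        except KeyError as exc:
            raise KeyError(f"no reference value for sample {exc.args[0]!r}")


def build_stack(
    eems: Sequence[EEM],
    reference: Mapping[str, float] | pd.DataFrame | None = None,
) -> EEMStack:
    """Assemble EEMs (identical grids, unique scan ids) into a stack.

    ``reference`` may be a mapping or a DataFrame with columns
    ``sample_id`` and ``retinol_iu_dl``.
    """
    eems = list(eems)
    if not eems:
        raise ValueError("cannot build a stack from zero EEMs")
    ex0, em0 = eems[0].ex_grid, eems[0].em_grid
    bad = [e.sample_id for e in eems if e.ex_grid != ex0 or e.em_grid != em0]
    if bad:
        raise GridError(f"grid mismatch for samples: {sorted(set(bad))}")
    seen: set[tuple[str, int]] = set()
    for e in eems:
        key = (e.sample_id, e.replicate_id)
        if key in seen:
            raise ValueError(f"duplicate (sample_id, replicate_id): {key}")
        seen.add(key)
    ref_map: dict[str, float] | None = None
    if reference is not None:
        if isinstance(reference, pd.DataFrame):
            ref_map = dict(
                zip(reference["sample_id"].astype(str),
                    reference["retinol_iu_dl"].astype(float))
            )
        else:
            ref_map = {str(k): float(v) for k, v in reference.items()}
    return EEMStack(eems=eems, reference=ref_map)


def read_eem_csv(path: str | Path) -> EEM:
    """Read one EEM from a matrix-dialect CSV.

    First row: excitation wavelengths (nm); first column: emission
    wavelengths (nm); body: intensities, blank cell = missing.  UTF-8,
    comma separator, '.' decimal.  The sample id defaults to the file stem;
    a trailing ``_r<k>`` suffix is parsed as the replicate id.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, header=0, encoding="utf-8",
                         float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    try:
        ex_values = df.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric excitation header") from exc
    try:
        em_values = df.index.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric emission column") from exc
    ex_grid = _grid_from_values(ex_values, "excitation")
    em_grid = _grid_from_values(em_values, "emission")
    body = df.to_numpy(dtype=float)  # blank cells become NaN
    stem = path.stem
    sample_id, replicate_id = stem, 0
    if "_r" in stem:
        head, _, tail = stem.rpartition("_r")
        if tail.isdigit():
            sample_id, replicate_id = head, int(tail)
    return EEM(ex_grid, em_grid, body, sample_id=sample_id,
               replicate_id=replicate_id)


def write_eem_csv(eem: EEM, path: str | Path) -> Path:
    """Write an EEM as a matrix-dialect CSV (inverse of :func:`read_eem_csv`)."""
    path = Path(path)
    df = pd.DataFrame(
        eem.intensity,
        index=eem.em_grid.values,
        columns=eem.ex_grid.values,
    )
    df.to_csv(path, encoding="utf-8", na_rep="")
    return path


def average_replicates(stack: EEMStack) -> EEMStack:
    """Collapse replicates to one EEM per sample by entrywise mean.

    A cell is missing in the output only if it is missing in every replicate;
    otherwise it is the mean of the observed replicate values.  Sample order
    follows first appearance in the stack.  Idempotent.
    """
    order: list[str] = []
    groups: dict[str, list[EEM]] = {}
    for e in stack.eems:
        if e.sample_id not in groups:
            order.append(e.sample_id)
            groups[e.sample_id] = []
        groups[e.sample_id].append(e)
    averaged = []
    for sid in order:
        members = groups[sid]
        cube = np.stack([m.intensity for m in members], axis=0)
        observed = np.isfinite(cube).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(observed > 0,
                            np.nansum(cube, axis=0) / np.maximum(observed, 1),
                            np.nan)
        averaged.append(EEM(stack.ex_grid, stack.em_grid, mean,
                            sample_id=sid, replicate_id=0))
    return EEMStack(eems=averaged, reference=stack.reference)


@dataclass(frozen=True)
class VariableMap:
    """Column order of the unfolded (scan x wavelength-pair) matrix.

    ``ex_nm[j]``/``em_nm[j]`` give the wavelength pair of column ``j``;
    ``ex_idx``/``em_idx`` the corresponding grid indices.  Bijective with the
    retained cells, so fold(unfold(.)) is the identity there.
    """

    ex_grid: WavelengthGrid
    em_grid: WavelengthGrid
    ex_idx: np.ndarray
    em_idx: np.ndarray

    def __len__(self) -> int:
        return len(self.ex_idx)

    @property
    def ex_nm(self) -> np.ndarray:
        return self.ex_grid.values[self.ex_idx]

    @property
    def em_nm(self) -> np.ndarray:
        return self.em_grid.values[self.em_idx]


def unfold(
    stack: EEMStack,
    missing_policy: str = "drop",
) -> tuple[np.ndarray, VariableMap]:
    """Unfold a stack into the (scan x variable) matrix used by PLS.

    Columns are ordered excitation-major (all emission wavelengths for the
    lowest excitation first).  ``missing_policy``:

    * ``"drop"`` (default): drop any column missing in at least one scan --
      appropriate when scatter excision removes the same cells everywhere.
    * ``"mean"``: impute a missing cell with the column mean over scans;
      columns missing everywhere are still dropped.
    """
    if missing_policy not in ("drop", "mean"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    tensor = stack.to_tensor()  # (ex, em, scan)
    n_ex, n_em, n_scan = tensor.shape
    X = tensor.transpose(2, 0, 1).reshape(n_scan, n_ex * n_em)
    ex_idx_full = np.repeat(np.arange(n_ex), n_em)
    em_idx_full = np.tile(np.arange(n_em), n_ex)
    col_missing = np.isnan(X)
    if missing_policy == "drop":
        keep = ~col_missing.any(axis=0)
        X = X[:, keep]
    else:
        keep = ~col_missing.all(axis=0)
        X = X[:, keep]
        miss = np.isnan(X)
        if miss.any():
            col_mean = np.nanmean(X, axis=0)
            X = np.where(miss, col_mean[None, :], X)
    vmap = VariableMap(
        ex_grid=stack.ex_grid,
        em_grid=stack.em_grid,
        ex_idx=ex_idx_full[keep],
        em_idx=em_idx_full[keep],
    )
    return X, vmap


def fold(vector: np.ndarray, vmap: VariableMap) -> np.ndarray:
    """Fold a per-variable vector back into an ``[em x ex]`` map.

    Cells dropped during unfolding come back as NaN.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(vmap),):
        raise ValueError(
            f"vector length {vector.shape} != variable count {len(vmap)}"
        )
    out = np.full((len(vmap.em_grid), len(vmap.ex_grid)), np.nan)
    out[vmap.em_idx, vmap.ex_idx] = vector
    return out


def read_reference_csv(path: str | Path) -> dict[str, float]:
    """Read a reference table CSV (sample_id, retinol_iu_dl[, metadata...])."""
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("sample_id", "retinol_iu_dl"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return dict(zip(df["sample_id"].astype(str),
                    df["retinol_iu_dl"].astype(float)))


def read_manifest(manifest_path: str | Path,
                  reference_path: str | Path | None = None) -> EEMStack:
    """Load a stack from a manifest CSV (sample_id, replicate_id, path).

    Relative EEM paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, encoding="utf-8")
    for col in ("sample_id", "replicate_id", "path"):
        if col not in df.columns:
            raise FormatError(f"{manifest_path}: missing column {col!r}")
    eems = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        e = read_eem_csv(p)
        e.sample_id = str(row.sample_id)
        e.replicate_id = int(row.replicate_id)
        eems.append(e)
    reference = read_reference_csv(reference_path) if reference_path else None
    return build_stack(eems, reference)
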