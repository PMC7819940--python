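"""Serum-like synthetic EEM generator with known trilinear ground truth.

Real serum EEMs are dominated by protein (tryptophan/tyrosine) fluorescence
with a weaker retinol band; bound retinol (retinol-binding protein complex)
emits red-shifted and more brightly than free retinol.  The generator
emulates this structure as a trilinear mixture of Gaussian-band
fluorophores:

    intensity(ex, em; sample) = sum_f amount_f * brightness_f
                                * exp(-(ex - ex_c)^2 / 2 s_ex^2)
                                * exp(-(em - em_c)^2 / 2 s_em^2)

plus per-replicate multiplicative jitter, additive Gaussian noise, and
(optionally) Rayleigh scatter ridges along em = ex and em = 2 ex.

Defaults reproduce the study conditions this package targets: 208 serum
samples with three analytical replicates on 250-450/5 nm excitation and
250-600/1 nm emission grids, retinol concentrations drawn from a truncated
normal with mean 46.7, SD 25.8, range 11-124 IU/dl.  Protein-component
amounts are lognormal and uncorrelated with retinol, so a calibration model
must isolate the retinol signal rather than shortcut through protein bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from serumeem.eem_core import (
    EEM,
    EEMStack,
    WavelengthGrid,
    build_stack,
    make_grid,
    write_eem_csv,
)

DEFAULT_EX_GRID = (250.0, 450.0, 5.0)
DEFAULT_EM_GRID = (250.0, 600.0, 1.0)

# Rayleigh ridge shape used when scatter simulation is on (amplitudes are
# fractions of the stack's maximum noiseless intensity).
_SCATTER_R1_AMPLITUDE = 0.5
_SCATTER_R2_AMPLITUDE = 0.25
_SCATTER_RIDGE_WIDTH_NM = 6.0


@dataclass(frozen=True)
class Fluorophore:
    """One Gaussian-band emitter.

    ``concentration_model`` sets how the per-sample amount is generated:
    ``retinol_linked`` (amount = concentration), ``retinol_linked_secondary``
    (amount = 0.6 * concentration + seeded scatter; the RBP-bound pool), or
    ``independent_lognormal`` (protein background uncorrelated with retinol).
    """

    name: str
    ex_center: float
    em_center: float
    ex_width: float = 18.0
    em_width: float = 28.0
    brightness: float = 1.0
    concentration_model: str = "independent_lognormal"

    def __post_init__(self) -> None:
        if self.ex_width <= 0 or self.em_width <= 0:
            raise ValueError("band widths must be positive")
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")
        if self.concentration_model not in (
            "retinol_linked", "retinol_linked_secondary",
            "independent_lognormal",
        ):
            raise ValueError(
                f"unknown concentration_model {self.concentration_model!r}"
            )


@dataclass(frozen=True)
class SerumSimConfig:
    """Study-condition parameters of the generator.

    Concentration defaults are the calibration-set descriptive statistics
    (mean 46.7, SD 25.8, range 11.0-124.0 IU/dl); noise_sd is the additive
    noise SD as a fraction of the median noiseless intensity.
    """

    n_samples: int = 208
    replicates: int = 3
    conc_mean: float = 46.7
    conc_sd: float = 25.8
    conc_range: tuple[float, float] = (11.0, 124.0)
    noise_sd: float = 0.02
    replicate_jitter: float = 0.01
    scatter: bool = True
    seed: int = 0
    ex_grid: tuple[float, float, float] = DEFAULT_EX_GRID
    em_grid: tuple[float, float, float] = DEFAULT_EM_GRID

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        lo, hi = self.conc_range
        if not (0 < lo < hi):
            raise ValueError("conc_range must satisfy 0 < low < high")
        if self.noise_sd < 0 or self.replicate_jitter < 0:
            raise ValueError("noise levels must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset (per-sample, not per-scan)."""

    names: list[str]
    ex_profiles: np.ndarray   # [n_ex x n_fluor], unit-max Gaussian bands
    em_profiles: np.ndarray   # [n_em x n_fluor]
    amounts: np.ndarray       # [n_samples x n_fluor], concentration units
    brightness: np.ndarray    # [n_fluor]

    def noiseless_eem(self, sample: int) -> np.ndarray:
        """Noiseless [em x ex] surface for one sample."""
        weights = self.amounts[sample] * self.brightness
        return (self.em_profiles * weights) @ self.ex_profiles.T


@dataclass
class SimulatedDataset:
    """An EEM stack with its reference table and generating truth."""

    stack: EEMStack
    reference: dict[str, float]
    truth: SimulationTruth
    config: SerumSimConfig
    fluorophores: list[Fluorophore]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.reference.keys())


def gaussian_band(grid: WavelengthGrid, center: float, width: float
                  ) -> np.ndarray:
    """Gaussian spectral band sampled on a grid, unit maximum at the center."""
    if width <= 0:
        raise ValueError("width must be positive")
    lam = grid.values
    return np.exp(-((lam - center) ** 2) / (2.0 * width ** 2))


def default_fluorophores(include_secondary: bool = True) -> list[Fluorophore]:
    """The five-band serum model.

    Three protein-like emitters (two tryptophan environments and a
    tyrosine-like band) dominate the signal and vary independently of
    retinol; the free-retinol band at 325/447 nm scales linearly with the
    reference concentration, and the RBP-bound pool at 330/520 nm carries a
    secondary, brighter retinol-linked signal.  ``include_secondary=False``
    drops the bound pool, leaving four spectrally distinct components.
    """
    fl = [
        Fluorophore("trp_1", 285.0, 342.0, brightness=120.0,
                    concentration_model="independent_lognormal"),
        Fluorophore("trp_2", 300.0, 350.0, brightness=60.0,
                    concentration_model="independent_lognormal"),
        Fluorophore("tyr_like", 270.0, 320.0, brightness=40.0,
                    concentration_model="independent_lognormal"),
        Fluorophore("retinol_free", 325.0, 447.0, brightness=1.0,
                    concentration_model="retinol_linked"),
    ]
    if include_secondary:
        fl.append(Fluorophore("rbp_bound", 330.0, 520.0, brightness=2.0,
                              concentration_model="retinol_linked_secondary"))
    return fl


def draw_concentrations(config: SerumSimConfig,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Seeded truncated-normal retinol concentrations (IU/dl).

    Normal(conc_mean, conc_sd) draws are rejected outside ``conc_range``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.conc_range
    if config.conc_sd == 0:
        if not (lo <= config.conc_mean <= hi):
            raise ValueError("conc_mean outside conc_range with zero SD")
        return np.full(config.n_samples, config.conc_mean)
    out = np.empty(config.n_samples)
    filled = 0
    while filled < config.n_samples:
        draws = rng.normal(config.conc_mean, config.conc_sd,
                           size=2 * (config.n_samples - filled))
        ok = draws[(draws >= lo) & (draws <= hi)]
        take = min(len(ok), config.n_samples - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


# amount = _RBP_LINK * concentration + Normal(0, _RBP_SCATTER_SD), floored at 0
_RBP_LINK = 0.6
_RBP_SCATTER_SD = 2.0
_PROTEIN_LOG_SD = 0.25


def _draw_amounts(fluorophores: list[Fluorophore], conc: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    n = len(conc)
    amounts = np.empty((n, len(fluorophores)))
    for j, f in enumerate(fluorophores):
        if f.concentration_model == "retinol_linked":
            amounts[:, j] = conc
        elif f.concentration_model == "retinol_linked_secondary":
            amounts[:, j] = np.maximum(
                _RBP_LINK * conc + rng.normal(0.0, _RBP_SCATTER_SD, n), 0.0
            )
        else:
            amounts[:, j] = rng.lognormal(0.0, _PROTEIN_LOG_SD, n)
    return amounts


def _scatter_surface(ex_grid: WavelengthGrid, em_grid: WavelengthGrid,
                     amplitude: float) -> np.ndarray:
    """Deterministic Rayleigh ridges ([em x ex]) added to every scan."""
    ex = ex_grid.values[None, :]
    em = em_grid.values[:, None]
    w = _SCATTER_RIDGE_WIDTH_NM
    r1 = _SCATTER_R1_AMPLITUDE * np.exp(-((em - ex) ** 2) / (2 * w ** 2))
    r2 = _SCATTER_R2_AMPLITUDE * np.exp(-((em - 2 * ex) ** 2) / (2 * w ** 2))
    return amplitude * (r1 + r2)


def simulate_dataset(
    config: SerumSimConfig | None = None,
    fluorophores: list[Fluorophore] | None = None,
) -> SimulatedDataset:
    """Generate a serum-like EEM stack with known ground truth.

    Per scan: the sample's noiseless trilinear surface is multiplied by a
    replicate-specific factor ``1 + jitter * N(0,1)``, optional scatter
    ridges are added, then i.i.d. Gaussian noise with SD
    ``noise_sd * median(noiseless stack)``.  Fully reproducible from
    ``config.seed``.
    """
    config = config or SerumSimConfig()
    fluorophores = (fluorophores if fluorophores is not None
                    else default_fluorophores())
    rng = np.random.default_rng(config.seed)
    ex_grid = make_grid(*config.ex_grid)
    em_grid = make_grid(*config.em_grid)
    for f in fluorophores:
        if not (ex_grid.start <= f.ex_center <= ex_grid.end
                and em_grid.start <= f.em_center <= em_grid.end):
            raise ValueError(f"fluorophore {f.name} peak off-grid")

    conc = draw_concentrations(config, rng)
    amounts = _draw_amounts(fluorophores, conc, rng)
    ex_profiles = np.column_stack(
        [gaussian_band(ex_grid, f.ex_center, f.ex_width) for f in fluorophores]
    )
    em_profiles = np.column_stack(
        [gaussian_band(em_grid, f.em_center, f.em_width) for f in fluorophores]
    )
    brightness = np.array([f.brightness for f in fluorophores])
    truth = SimulationTruth(
        names=[f.name for f in fluorophores],
        ex_profiles=ex_profiles,
        em_profiles=em_profiles,
        amounts=amounts,
        brightness=brightness,
    )

    noiseless = [truth.noiseless_eem(s) for s in range(config.n_samples)]
    median_signal = float(np.median(np.stack(noiseless)))
    noise_level = config.noise_sd * median_signal
    max_signal = float(np.max(np.stack(noiseless)))
    scatter = (_scatter_surface(ex_grid, em_grid, max_signal)
               if config.scatter else None)

    width = len(str(config.n_samples))
    sample_ids = [f"s{i + 1:0{width}d}" for i in range(config.n_samples)]
    eems = []
    for s, sid in enumerate(sample_ids):
        for r in range(1, config.replicates + 1):
            surface = noiseless[s]
            if config.replicate_jitter > 0:
                surface = surface * (1.0 + config.replicate_jitter
                                     * rng.standard_normal())
            else:
                surface = surface.copy()
            if scatter is not None:
                surface = surface + scatter
            if noise_level > 0:
                surface = surface + rng.normal(0.0, noise_level,
                                               surface.shape)
            eems.append(EEM(ex_grid, em_grid, surface,
                            sample_id=sid, replicate_id=r))
    reference = dict(zip(sample_ids, conc.astype(float)))
    stack = build_stack(eems, reference)
    return SimulatedDataset(stack=stack, reference=reference, truth=truth,
                            config=config, fluorophores=list(fluorophores))


def split_calibration_validation(
    ds: SimulatedDataset | EEMStack,
    n_cal: int,
    n_val: int,
    seed: int = 0,
) -> tuple[EEMStack, EEMStack]:
    """Seeded sample-level calibration/validation split.

    Replicate scans of one sample never straddle the two sets.
    """
    stack = ds.stack if isinstance(ds, SimulatedDataset) else ds
    ids = list(dict.fromkeys(stack.sample_ids))
    if n_cal + n_val > len(ids):
        raise ValueError(
            f"n_cal + n_val = {n_cal + n_val} exceeds {len(ids)} samples"
        )
    if n_cal < 1 or n_val < 1:
        raise ValueError("both sets must be non-empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    cal_ids = {ids[i] for i in perm[:n_cal]}
    val_ids = {ids[i] for i in perm[n_cal:n_cal + n_val]}

    def _subset(keep: set[str]) -> EEMStack:
        eems = [e for e in stack.eems if e.sample_id in keep]
        ref = None
        if stack.reference is not None:
            ref = {k: v for k, v in stack.reference.items() if k in keep}
        return EEMStack(eems=eems, reference=ref)

    return _subset(cal_ids), _subset(val_ids)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> Path:
    """Write a dataset as manifest + per-scan EEM CSVs + reference + truth.

    Produces the same on-disk layout the pipeline's load mode consumes, so
    disk-backed synthetic data run exactly like instrument exports.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eem_dir = outdir / "eems"
    eem_dir.mkdir(exist_ok=True)
    rows = []
    for e in ds.stack.eems:
        fname = f"{e.sample_id}_r{e.replicate_id}.csv"
        write_eem_csv(e, eem_dir / fname)
        rows.append({"sample_id": e.sample_id,
                     "replicate_id": e.replicate_id,
                     "path": f"eems/{fname}"})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(
        {"sample_id": list(ds.reference.keys()),
         "retinol_iu_dl": list(ds.reference.values())}
    ).to_csv(outdir / "reference.csv", index=False)
    truth = {
        "names": ds.truth.names,
        "brightness": ds.truth.brightness.tolist(),
        "amounts": ds.truth.amounts.tolist(),
        "ex_profiles": ds.truth.ex_profiles.tolist(),
        "em_profiles": ds.truth.em_profiles.tolist(),
        "config": asdict(ds.config),
    }
    (outdir / "truth.json").write_text(json.dumps(truth))
    return outdir
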