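"""Trilinear PARAFAC decomposition of EEM stacks.

A stack of EEMs is modelled as a three-way array X (excitation x emission x
scan) decomposed into F trilinear components,

    x_ijk ~= sum_f  a_if * b_jf * c_kf,

where a_f is the excitation profile, b_f the emission profile and c_f the
per-scan score of component f.  Spectra and concentrations are physically
nonnegative, so nonnegativity is imposed on all three modes by default.

Fitting is alternating least squares with columnwise (HALS) updates, which
are monotone in the observed-cell sum of squared errors.  Missing cells
(excised scatter) are handled EM-style: each iteration they are imputed from
the current model before the least-squares updates.

Component-number selection uses the core consistency diagnostic (CORCONDIA):
the least-squares Tucker core of the data given the PARAFAC loadings is
compared with the superdiagonal identity; values near 100 indicate an
appropriate trilinear model, and a collapse flags overfactoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from serumeem.eem_core import EEMStack

_EPS = 1e-12


@dataclass(frozen=True)
class ParafacConfig:
    """ALS settings.

    ``nonneg`` flags nonnegativity per mode (excitation, emission, scores).
    ``n_starts`` seeded random restarts; the best final SSE wins, ties going
    to the fit that converged in fewer iterations.
    """

    nonneg: tuple[bool, bool, bool] = (True, True, True)
    n_starts: int = 10
    max_iter: int = 2500
    rel_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")


@dataclass
class ParafacModel:
    """A fitted PARAFAC model.

    Spectral loadings (``ex_loadings`` [n_ex x F], ``em_loadings``
    [n_em x F]) are unit Euclidean norm per column; ``sample_scores``
    [n_scans x F] carry all magnitude.  Components are ordered by explained
    variance, descending.
    """

    n_components: int
    sample_scores: np.ndarray
    em_loadings: np.ndarray
    ex_loadings: np.ndarray
    sse: float
    explained_pct: float
    corcondia: float | None
    converged: bool
    n_iter: int
    sse_history: np.ndarray = field(repr=False, default=None)

    def reconstruct(self) -> np.ndarray:
        """Model tensor, shape (n_ex, n_em, n_scans)."""
        return _reconstruct(self.ex_loadings, self.em_loadings,
                            self.sample_scores)


def _as_tensor(data: EEMStack | np.ndarray) -> np.ndarray:
    if isinstance(data, EEMStack):
        return data.to_tensor()
    return np.asarray(data, dtype=float)


def _khatri_rao(B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Columnwise Khatri-Rao, row order (j, k) with k fastest."""
    J, F = B.shape
    K = C.shape[0]
    return (B[:, None, :] * C[None, :, :]).reshape(J * K, F)


def _reconstruct(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    I, F = A.shape
    J, K = B.shape[0], C.shape[0]
    return (A @ _khatri_rao(B, C).T).reshape(I, J, K)


def _mttkrp(T: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray,
            mode: int) -> np.ndarray:
    """Matricized-tensor times Khatri-Rao product for one mode.

    All three modes reduce to one GEMM on a flat view of the tensor, which
    dominates the ALS cost; no tensor copy is made.
    """
    I, J, K = T.shape
    flat = T.reshape(I * J, K)
    if mode == 0:
        return T.reshape(I, J * K) @ _khatri_rao(B, C)
    if mode == 1:
        tmp = (flat @ C).reshape(I, J, -1)          # (I, J, F)
        return np.einsum("ijf,if->jf", tmp, A)
    return flat.T @ _khatri_rao(A, B)               # (K, F)


def _hals_update(factor: np.ndarray, M: np.ndarray, G: np.ndarray,
                 nonneg: bool) -> np.ndarray:
    """One sweep of columnwise least-squares updates for one mode.

    Coordinate descent on each column is monotone in the SSE; clipping at
    zero keeps monotonicity under the nonnegativity constraint.
    """
    F = factor.shape[1]
    for f in range(F):
        denom = G[f, f]
        if denom < _EPS:
            continue
        col = factor[:, f] + (M[:, f] - factor @ G[:, f]) / denom
        if nonneg:
            np.maximum(col, 0.0, out=col)
            if not col.any():
                col[np.argmax(M[:, f])] = _EPS
        factor[:, f] = col
    return factor


def _als_single(T: np.ndarray, mask: np.ndarray | None, F: int,
                config: ParafacConfig, rng: np.random.Generator):
    """One ALS run from a random start.  Returns factors + diagnostics.

    Missing cells are imputed from the current model each iteration (EM
    style).  When the missing pattern is identical in every frontal slice
    (scatter excision removes the same (ex, em) cells in every scan), the
    imputation and the observed-cell SSE touch only the missing fibers and
    the SSE comes from the Gram matrices -- the full reconstruction is never
    formed.

    ALS can crawl through "swamps" when components are nearly collinear
    (here: free vs protein-bound retinol share almost-proportional scores),
    so every iteration a line-search extrapolation along the last update
    direction (step ~ iteration^(1/3)) is tried and accepted only if it
    lowers the SSE -- monotonicity is preserved.
    """
    I, J, K = T.shape
    A = rng.uniform(0.1, 1.0, (I, F))
    B = rng.uniform(0.1, 1.0, (J, F))
    C = rng.uniform(0.1, 1.0, (K, F))
    if not config.nonneg[0]:
        A -= 0.5
    if not config.nonneg[1]:
        B -= 0.5
    if not config.nonneg[2]:
        C -= 0.5

    miss_ij = None  # (miss_i, miss_j) when the pattern is slice-constant
    if mask is not None:
        miss2d_any = ~mask.all(axis=2)
        if (~mask == miss2d_any[:, :, None]).all():
            miss_ij = np.nonzero(miss2d_any)
        Tw = T.copy()
        Tw[~mask] = np.nanmean(T[mask])
        obs_ss = float(np.sum(T[mask] ** 2))
    else:
        Tw = T.copy()
        obs_ss = float(np.sum(T ** 2))
    # scale the random start to the data's magnitude
    scale = (obs_ss / max(np.sum(_reconstruct(A, B, C) ** 2), _EPS)) ** (1 / 6)
    A *= scale
    B *= scale
    C *= scale

    def _sse_obs(A_, B_, C_):
        """Observed-cell SSE wrt the current Tw; also returns the missing-cell
        model values needed for the next imputation."""
        gram = (A_.T @ A_) * (B_.T @ B_)
        if mask is None or miss_ij is not None:
            M2 = _mttkrp(Tw, A_, B_, C_, 2)
            full = (float(np.sum(Tw ** 2)) if miss_ij is not None else obs_ss)
            full = (full - 2.0 * float(np.sum(C_ * M2))
                    + float(np.sum(gram * (C_.T @ C_))))
            if miss_ij is None:
                return max(full, 0.0), None
            mi, mj = miss_ij
            recon_miss = (A_[mi, :] * B_[mj, :]) @ C_.T     # (n_miss, K)
            resid_miss = float(np.sum((Tw[mi, mj, :] - recon_miss) ** 2))
            return max(full - resid_miss, 0.0), recon_miss
        recon = _reconstruct(A_, B_, C_)
        return float(np.sum((T[mask] - recon[mask]) ** 2)), recon

    def _impute(recon_like):
        if mask is None:
            return
        if miss_ij is not None:
            Tw[miss_ij[0], miss_ij[1], :] = recon_like
        else:
            Tw[~mask] = recon_like[~mask]

    sse_prev = np.inf
    history = []
    converged = False
    n_iter = 0
    A_old = B_old = C_old = None
    for it in range(1, config.max_iter + 1):
        n_iter = it
        gC = C.T @ C
        gB = B.T @ B
        A = _hals_update(A, _mttkrp(Tw, A, B, C, 0), gB * gC,
                         config.nonneg[0])
        gA = A.T @ A
        B = _hals_update(B, _mttkrp(Tw, A, B, C, 1), gA * gC, config.nonneg[1])
        gB = B.T @ B
        C = _hals_update(C, _mttkrp(Tw, A, B, C, 2), gA * gB,
                         config.nonneg[2])
        sse, recon_like = _sse_obs(A, B, C)
        if A_old is not None and it >= 3:
            step = it ** (1.0 / 3.0)
            A_t = A + step * (A - A_old)
            B_t = B + step * (B - B_old)
            C_t = C + step * (C - C_old)
            if config.nonneg[0]:
                np.maximum(A_t, 0.0, out=A_t)
            if config.nonneg[1]:
                np.maximum(B_t, 0.0, out=B_t)
            if config.nonneg[2]:
                np.maximum(C_t, 0.0, out=C_t)
            sse_t, recon_t = _sse_obs(A_t, B_t, C_t)
            if sse_t < sse:
                A_old, B_old, C_old = A, B, C
                A, B, C, sse, recon_like = A_t, B_t, C_t, sse_t, recon_t
            else:
                A_old, B_old, C_old = A.copy(), B.copy(), C.copy()
        else:
            A_old, B_old, C_old = A.copy(), B.copy(), C.copy()
        _impute(recon_like)
        history.append(sse)
        if sse_prev < np.inf:
            denom = max(sse_prev, _EPS * obs_ss, _EPS)
            if abs(sse_prev - sse) / denom < config.rel_tol:
                converged = True
                break
        sse_prev = sse
    return A, B, C, history[-1], converged, n_iter, np.array(history)


def _normalize_factors(A, B, C, nonneg):
    """Unit-norm spectral loadings, magnitude into scores, order by variance."""
    F = A.shape[1]
    A, B, C = A.copy(), B.copy(), C.copy()
    for f in range(F):
        if not nonneg[0] and A[np.argmax(np.abs(A[:, f])), f] < 0:
            A[:, f] *= -1
            C[:, f] *= -1
        if not nonneg[1] and B[np.argmax(np.abs(B[:, f])), f] < 0:
            B[:, f] *= -1
            C[:, f] *= -1
        na = np.linalg.norm(A[:, f])
        nb = np.linalg.norm(B[:, f])
        if na > _EPS:
            A[:, f] /= na
        if nb > _EPS:
            B[:, f] /= nb
        C[:, f] *= na * nb
    order = np.argsort(-np.linalg.norm(C, axis=0))
    return A[:, order], B[:, order], C[:, order]


def fit_parafac(
    data: EEMStack | np.ndarray,
    n_components: int,
    config: ParafacConfig | None = None,
) -> ParafacModel:
    """Fit an F-component PARAFAC model to an EEM stack (or raw tensor).

    The tensor axis order is (excitation, emission, scan); NaN cells are
    treated as missing and imputed from the model each iteration.  The best
    of ``config.n_starts`` seeded random starts is returned.  Non-convergence
    within ``max_iter`` is reported via ``converged=False``, not an error.
    """
    config = config or ParafacConfig()
    T = _as_tensor(data)
    if T.ndim != 3:
        raise ValueError("expected a 3-way tensor (ex, em, scan)")
    F = int(n_components)
    if F < 1:
        raise ValueError("n_components must be >= 1")
    if F > min(T.shape):
        raise ValueError(
            f"n_components {F} exceeds smallest tensor mode {min(T.shape)}"
        )
    finite = np.isfinite(T)
    if not finite.any():
        raise ValueError("tensor is entirely missing")
    mask = None if finite.all() else finite
    obs = T[finite]
    obs_ss = float(np.sum(obs ** 2))
    if obs_ss == 0.0:
        raise ValueError("tensor is identically zero")
    for axis in range(3):
        per_mode = finite.sum(axis=tuple(a for a in range(3) if a != axis))
        if np.any(per_mode <= F):
            raise ValueError(
                f"mode {axis} has fibers with <= {F} observed cells; "
                "the model is not identifiable"
            )

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_starts)
    best = None
    for ss in seeds:
        run = _als_single(T, mask, F, config, np.random.default_rng(ss))
        if best is None or (run[3], run[5]) < (best[3], best[5]):
            best = run
    A, B, C, sse, converged, n_iter, history = best
    A, B, C = _normalize_factors(A, B, C, config.nonneg)
    model = ParafacModel(
        n_components=F,
        sample_scores=C,
        em_loadings=B,
        ex_loadings=A,
        sse=sse,
        explained_pct=100.0 * (1.0 - sse / obs_ss),
        corcondia=None,
        converged=converged,
        n_iter=n_iter,
        sse_history=history,
    )
    model.corcondia = corcondia(model, T)
    return model


def corcondia(model: ParafacModel, data: EEMStack | np.ndarray) -> float:
    """Core consistency diagnostic, in percent.

    The least-squares Tucker core ``g`` of the data given the fitted
    loadings is compared with the superdiagonal identity ``t``:
    ``100 * (1 - sum((g - t)^2) / sum(t^2))``.  Missing cells are imputed
    from the model first.  100 indicates a perfectly trilinear fit; values
    well below 100 (or negative) indicate overfactoring.
    """
    T = _as_tensor(data)
    finite = np.isfinite(T)
    if not finite.all():
        T = T.copy()
        recon = model.reconstruct()
        T[~finite] = recon[~finite]
    A, B, C = model.ex_loadings, model.em_loadings, model.sample_scores
    F = model.n_components
    Ap = np.linalg.pinv(A)
    Bp = np.linalg.pinv(B)
    Cp = np.linalg.pinv(C)
    core = np.tensordot(Ap, T, axes=([1], [0]))          # (F, J, K)
    core = np.tensordot(core, Bp, axes=([1], [1]))       # (F, K, F)
    core = np.tensordot(core, Cp, axes=([1], [1]))       # (F, F, F) = (f,g,h)
    target = np.zeros((F, F, F))
    target[np.arange(F), np.arange(F), np.arange(F)] = 1.0
    return float(100.0 * (1.0 - np.sum((core - target) ** 2) / F))


def congruence_matrix(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Tucker congruence (cosine similarity) between columns of U and V."""
    Un = U / np.maximum(np.linalg.norm(U, axis=0, keepdims=True), _EPS)
    Vn = V / np.maximum(np.linalg.norm(V, axis=0, keepdims=True), _EPS)
    return Un.T @ Vn


def greedy_match(congruence: np.ndarray) -> list[tuple[int, int]]:
    """Greedily pair rows to columns by descending congruence."""
    cg = np.abs(congruence.copy())
    pairs = []
    for _ in range(min(cg.shape)):
        i, j = np.unravel_index(np.argmax(cg), cg.shape)
        pairs.append((int(i), int(j)))
        cg[i, :] = -np.inf
        cg[:, j] = -np.inf
    return pairs


@dataclass
class SelectionResult:
    """Diagnostics from component-number selection."""

    n_components: int
    warned: bool
    corcondia_by_f: dict[int, float]
    degenerate_by_f: dict[int, bool]
    models: dict[int, ParafacModel]


def _is_degenerate(model: ParafacModel, cutoff: float = 0.95) -> bool:
    """Two components congruent (> cutoff) in BOTH spectral modes."""
    F = model.n_components
    if F < 2:
        return False
    cg_ex = np.abs(congruence_matrix(model.ex_loadings, model.ex_loadings))
    cg_em = np.abs(congruence_matrix(model.em_loadings, model.em_loadings))
    both = (cg_ex > cutoff) & (cg_em > cutoff)
    both[np.diag_indices(F)] = False
    return bool(both.any())


def select_n_components(
    data: EEMStack | np.ndarray,
    f_range: range | list[int],
    threshold: float = 60.0,
    config: ParafacConfig | None = None,
    degeneracy_cutoff: float = 0.95,
    return_diagnostics: bool = False,
) -> int | SelectionResult:
    """Choose the PARAFAC component number by core consistency.

    Fits each F in ``f_range`` (ascending) and returns the largest F whose
    CORCONDIA is at least ``threshold`` and whose model is non-degenerate
    (no two components with spectral congruence above ``degeneracy_cutoff``
    in both the excitation and emission modes).  If no F qualifies, the
    smallest F is returned with a warning.
    """
    f_list = sorted(set(int(f) for f in f_range))
    if not f_list:
        raise ValueError("f_range is empty")
    config = config or ParafacConfig()
    cc: dict[int, float] = {}
    degen: dict[int, bool] = {}
    models: dict[int, ParafacModel] = {}
    for F in f_list:
        model = fit_parafac(data, F, config)
        models[F] = model
        cc[F] = model.corcondia
        degen[F] = _is_degenerate(model, degeneracy_cutoff)
    qualifying = [F for F in f_list if cc[F] >= threshold and not degen[F]]
    warned = not qualifying
    if warned:
        chosen = f_list[0]
        warnings.warn(
            f"no component number in {f_list} reached CORCONDIA >= "
            f"{threshold} without degeneracy; falling back to {chosen}",
            stacklevel=2,
        )
    else:
        chosen = max(qualifying)
    if return_diagnostics:
        return SelectionResult(chosen, warned, cc, degen, models)
    return chosen


def component_peaks(model: ParafacModel,
                    ex_grid, em_grid) -> list[tuple[float, float]]:
    """Per-component (excitation, emission) wavelengths of the loading maxima.

    Ties break to the lowest wavelength (first grid point).
    """
    ex_values = np.asarray(getattr(ex_grid, "values", ex_grid), dtype=float)
    em_values = np.asarray(getattr(em_grid, "values", em_grid), dtype=float)
    peaks = []
    for f in range(model.n_components):
        i = int(np.argmax(model.ex_loadings[:, f]))
        j = int(np.argmax(model.em_loadings[:, f]))
        peaks.append((float(ex_values[i]), float(em_values[j])))
    return peaks


def score_reference_correlation(
    model: ParafacModel,
    component: int,
    reference: np.ndarray,
) -> tuple[float, float, int]:
    """Pearson correlation between one component's scores and reference values.

    ``reference`` must align with the score rows (replicate scans inherit
    their sample's reference value).  Returns (r, two-sided p from the t
    distribution with n-2 df, n).
    """
    scores = model.sample_scores[:, component]
    reference = np.asarray(reference, dtype=float)
    if reference.shape != scores.shape:
        raise ValueError(
            f"reference length {reference.shape} != scores {scores.shape}"
        )
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 scans for a correlation")
    if np.std(scores) == 0 or np.std(reference) == 0:
        raise ValueError("zero-variance scores or reference")
    r, p = stats.pearsonr(scores, reference)
    return float(r), float(p), n
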