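"""NIPALS PLS1 calibration with chemometric evaluation metrics.

The calibration regresses a single response y (retinol concentration,
IU/dl) on the unit-variance-scaled unfolded EEM matrix X.  For a single
response the NIPALS weight extraction is non-iterative: each latent
variable takes

    w_a = X_a' y_a / ||X_a' y_a||,   t_a = X_a w_a,
    p_a = X_a' t_a / t_a't_a,        q_a = y_a' t_a / t_a't_a,

followed by deflation X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - q_a t_a.
The regression vector on scaled variables is b = W (P'W)^{-1} q.

Model quality follows the SIMCA conventions used in spectroscopic
calibration: RMSEE with an (n - 1 - A) denominator on the calibration set,
RMSEP as the plain root mean square on the validation set, R^2 as the
squared Pearson correlation of observed vs predicted, Q^2 = 1 - PRESS/SS
from k-fold cross-validation, and RPD = SD(y_val)/RMSEP.  Variable
importance in projection (VIP) scores summarise each wavelength pair's
contribution; mean(VIP^2) = 1 by construction and VIP > 1 marks influential
variables.  A y-permutation test guards against chance correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from serumeem.eem_core import VariableMap, fold
from serumeem.preprocess import ScalingParams, apply_scaling

_EPS = 1e-12


@dataclass
class PlsModel:
    """Fitted NIPALS PLS1 model.

    ``coefficients`` act on scaled X and scaled y; :func:`predict` applies
    the stored X scaling and y de-scaling.  ``n_lv`` may be smaller than
    requested if the X rank was exhausted (``truncated`` is then set).
    """

    n_lv: int
    x_weights: np.ndarray    # W  [p x A]
    x_loadings: np.ndarray   # P  [p x A]
    y_loadings: np.ndarray   # q  [A]
    x_scores: np.ndarray     # T  [n x A]
    coefficients: np.ndarray  # b [p], scaled-variable scale
    y_mean: float
    y_sd: float
    fitted: np.ndarray       # training predictions, original y units
    scaling: ScalingParams | None = None
    variable_map: VariableMap | None = None
    truncated: bool = False


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    scaling: ScalingParams | None = None,
    variable_map: VariableMap | None = None,
) -> PlsModel:
    """Fit PLS1 with ``n_lv`` latent variables on a scaled matrix X.

    y is centred and scaled internally (its mean/SD are stored for
    prediction).  If a score norm becomes negligible the rank is exhausted
    and the model is truncated to the attained number of latent variables.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    A = int(n_lv)
    if A < 1:
        raise ValueError("n_lv must be >= 1")
    if n < A + 2:
        raise ValueError(f"need at least n_lv + 2 = {A + 2} rows, got {n}")
    if p < A:
        raise ValueError(f"need at least n_lv = {A} columns, got {p}")
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if y_sd == 0:
        raise ValueError("y has zero variance")
    ys = (y - y_mean) / y_sd

    Xd = X.copy()
    yd = ys.copy()
    x_ss0 = max(float(np.sum(X ** 2)), _EPS)
    W, P, T, q = [], [], [], []
    truncated = False
    for _ in range(A):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw ** 2 < 1e-12 * x_ss0 * max(float(yd @ yd), _EPS) / max(n, 1):
            truncated = True
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12 * x_ss0:
            truncated = True
            break
        pvec = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd -= np.outer(t, pvec)
        yd -= qa * t
        W.append(w)
        P.append(pvec)
        T.append(t)
        q.append(qa)
    if not W:
        # y orthogonal to X: zero-coefficient model predicting mean(y)
        W = [np.zeros(p)]
        P = [np.zeros(p)]
        T = [np.zeros(n)]
        q = [0.0]
        truncated = True
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    Tm = np.column_stack(T)
    qv = np.asarray(q)
    b = _coefficients(Wm, Pm, qv)
    fitted = y_mean + y_sd * (X @ b)
    return PlsModel(
        n_lv=Wm.shape[1],
        x_weights=Wm,
        x_loadings=Pm,
        y_loadings=qv,
        x_scores=Tm,
        coefficients=b,
        y_mean=y_mean,
        y_sd=y_sd,
        fitted=fitted,
        scaling=scaling,
        variable_map=variable_map,
        truncated=truncated,
    )


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """b = W (P'W)^{-1} q, robust to a zero-factor placeholder."""
    PtW = P.T @ W
    if np.linalg.matrix_rank(PtW) < PtW.shape[0]:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(PtW, q)


def predict(model: PlsModel, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations (original y units) for new rows.

    If the model stores X scaling parameters, ``X_new`` is the raw unfolded
    matrix (original column count); otherwise it must already be scaled.
    """
    X_new = np.asarray(X_new, dtype=float)
    if model.scaling is not None:
        Xs = apply_scaling(model.scaling, X_new)
    else:
        Xs = X_new
    if Xs.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"column count {Xs.shape[1]} != model variables "
            f"{model.coefficients.shape[0]}"
        )
    return model.y_mean + model.y_sd * (Xs @ model.coefficients)


def _fold_assignments(y: np.ndarray, k_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold labels stratified by y quantile: shuffle within sorted blocks."""
    n = len(y)
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    labels = np.arange(k_folds)
    for block_start in range(0, n, k_folds):
        block = order[block_start:block_start + k_folds]
        folds[block] = rng.permutation(labels)[: len(block)]
    return folds


def _cv_press(X: np.ndarray, y: np.ndarray, max_a: int, folds: np.ndarray
              ) -> np.ndarray:
    """PRESS for each latent-variable count 1..max_a from pre-assigned folds."""
    press = np.zeros(max_a)
    for k in np.unique(folds):
        test = folds == k
        train = ~test
        model = fit_pls(X[train], y[train], max_a)
        Xs_test = X[test]
        for a in range(1, model.n_lv + 1):
            b_a = _coefficients(model.x_weights[:, :a],
                                model.x_loadings[:, :a],
                                model.y_loadings[:a])
            pred = model.y_mean + model.y_sd * (Xs_test @ b_a)
            press[a - 1] += float(np.sum((y[test] - pred) ** 2))
        for a in range(model.n_lv + 1, max_a + 1):
            press[a - 1] = press[model.n_lv - 1]  # rank exhausted: flat
    return press


def choose_components_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_a: int = 10,
    k_folds: int = 7,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Select the latent-variable count by k-fold cross-validated Q^2.

    Folds are seeded and stratified by y quantile.  Returns
    ``(A*, q2_per_a)`` with ``A* = argmax Q^2``, ties going to the smaller
    count.  ``Q^2_a = 1 - PRESS_a / SS_tot``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    max_fold = -(-n // k_folds)
    if n - max_fold < 4:
        raise ValueError(f"too few samples ({n}) for {k_folds}-fold CV")
    max_a = int(min(max_a, n - max_fold - 2, X.shape[1]))
    if max_a < 1:
        raise ValueError("no admissible latent-variable count")
    rng = np.random.default_rng(seed)
    folds = _fold_assignments(y, k_folds, rng)
    press = _cv_press(X, y, max_a, folds)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss_tot
    best = int(np.argmax(q2)) + 1  # argmax takes the first (smallest) maximiser
    return best, q2


@dataclass
class CalibrationMetrics:
    """Per-set calibration/validation quality indices (SIMCA conventions)."""

    r2_cal: float
    r2_val: float
    rmsee: float
    rmsep: float
    rpd: float
    n_cal: int
    n_val: int
    n_lv: int
    q2_cv: float | None = None
    r2_cal_alt: float = None  # 1 - SSE/SST variant
    r2_val_alt: float = None


def _r2_pearson(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(y) == 0 or np.std(yhat) == 0:
        return 0.0
    return float(stats.pearsonr(y, yhat)[0] ** 2)


def _r2_alt(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def compute_metrics(
    y_cal: np.ndarray,
    yhat_cal: np.ndarray,
    y_val: np.ndarray,
    yhat_val: np.ndarray,
    n_lv: int,
    q2_cv: float | None = None,
) -> CalibrationMetrics:
    """RMSEE, RMSEP, per-set R^2 and RPD.

    ``rmsee = sqrt(SSE_cal / (n_cal - 1 - A))``;
    ``rmsep = sqrt(mean((y_val - yhat_val)^2))``;
    ``rpd = SD(y_val; n-1) / rmsep`` (infinite for perfect prediction);
    R^2 is the squared Pearson correlation of observed vs predicted.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    yhat_cal = np.asarray(yhat_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    yhat_val = np.asarray(yhat_val, dtype=float).ravel()
    n_cal, n_val = len(y_cal), len(y_val)
    if n_cal <= n_lv + 1:
        raise ValueError("n_cal must exceed n_lv + 1 for the RMSEE denominator")
    if n_val == 0:
        raise ValueError("empty validation set")
    rmsee = float(np.sqrt(np.sum((y_cal - yhat_cal) ** 2) / (n_cal - 1 - n_lv)))
    rmsep = float(np.sqrt(np.mean((y_val - yhat_val) ** 2)))
    sd_val = float(np.std(y_val, ddof=1))
    rpd = float("inf") if rmsep == 0 else sd_val / rmsep
    return CalibrationMetrics(
        r2_cal=_r2_pearson(y_cal, yhat_cal),
        r2_val=_r2_pearson(y_val, yhat_val),
        rmsee=rmsee,
        rmsep=rmsep,
        rpd=rpd,
        n_cal=n_cal,
        n_val=n_val,
        n_lv=n_lv,
        q2_cv=q2_cv,
        r2_cal_alt=_r2_alt(y_cal, yhat_cal),
        r2_val_alt=_r2_alt(y_val, yhat_val),
    )


def interpret_rpd(rpd: float) -> str:
    """Band label for an RPD value.

    < 1.5 preliminary screening; 2.0-2.5 satisfactory; > 2.5 good.  The
    1.5-2.0 gap in that convention is labelled "intermediate".
    """
    if rpd <= 0:
        raise ValueError("rpd must be positive")
    if rpd < 1.5:
        return "preliminary"
    if rpd < 2.0:
        return "intermediate"
    if rpd <= 2.5:
        return "satisfactory"
    return "good"


@dataclass
class VipResult:
    """VIP scores with their contour map and extracted peaks."""

    vip: np.ndarray
    vip_map: np.ndarray | None
    important_mask: np.ndarray
    peaks: list[tuple[float, float]] = field(default_factory=list)


def vip_scores(
    model: PlsModel,
    peak_merge_ex_nm: float = 15.0,
    peak_merge_em_nm: float = 30.0,
) -> VipResult:
    """Variable importance in projection, refolded into a contour map.

    ``VIP_j = sqrt(p * sum_a(w_ja^2 SSY_a) / sum_a SSY_a)`` where ``SSY_a``
    is the y-variance explained by latent variable a (``q_a^2 t_a't_a``).
    mean(VIP^2) = 1 exactly.  Peaks are local maxima of the map restricted
    to VIP > 1, merged within a ``peak_merge_ex_nm x peak_merge_em_nm``
    neighbourhood and sorted by VIP descending.  The map and peaks require
    the model to carry a variable map.
    """
    W = model.x_weights
    p = W.shape[0]
    ssy = model.y_loadings ** 2 * np.sum(model.x_scores ** 2, axis=0)
    total = float(np.sum(ssy))
    if total <= 0:
        vip = np.zeros(p)
    else:
        vip = np.sqrt(p * (W ** 2 @ ssy) / total)
    important = vip > 1.0
    vmap = model.variable_map
    if vmap is None:
        return VipResult(vip=vip, vip_map=None, important_mask=important)
    vip_map = fold(vip, vmap)
    peaks = _map_peaks(vip_map, vmap, threshold=1.0,
                       merge_ex=peak_merge_ex_nm, merge_em=peak_merge_em_nm)
    return VipResult(vip=vip, vip_map=vip_map, important_mask=important,
                     peaks=peaks)


def _map_peaks(value_map: np.ndarray, vmap: VariableMap, threshold: float,
               merge_ex: float, merge_em: float) -> list[tuple[float, float]]:
    """Local maxima of an [em x ex] map above threshold, merged and sorted."""
    filled = np.where(np.isnan(value_map), -np.inf, value_map)
    n_em, n_ex = filled.shape
    padded = np.full((n_em + 2, n_ex + 2), -np.inf)
    padded[1:-1, 1:-1] = filled
    is_max = np.ones_like(filled, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_max &= filled >= padded[1 + di:1 + di + n_em,
                                       1 + dj:1 + dj + n_ex]
    is_max &= filled > threshold
    cand = np.argwhere(is_max)
    if cand.size == 0:
        return []
    values = filled[cand[:, 0], cand[:, 1]]
    order = np.argsort(-values)
    ex_vals = vmap.ex_grid.values
    em_vals = vmap.em_grid.values
    peaks: list[tuple[float, float]] = []
    for k in order:
        j, i = cand[k]
        ex, em = float(ex_vals[i]), float(em_vals[j])
        merged = any(abs(ex - px) <= merge_ex and abs(em - pm) <= merge_em
                     for px, pm in peaks)
        if not merged:
            peaks.append((ex, em))
    return peaks


def coefficient_map(model: PlsModel) -> np.ndarray:
    """Regression coefficients refolded into an [em x ex] map, sign preserved."""
    if model.variable_map is None:
        raise ValueError("model carries no variable map")
    return fold(model.coefficients, model.variable_map)


@dataclass
class PermutationResult:
    """Y-permutation validation of a PLS model.

    ``r2_intercept``/``q2_intercept`` are the intercepts at correlation 0 of
    the least-squares lines through the (|corr(y_perm, y)|, R^2) and
    (|corr|, Q^2) points, including the unpermuted anchor at correlation 1.
    Low intercepts (SIMCA guidance: R^2 < 0.3-0.4, Q^2 < 0.05) indicate the
    model did not arise by chance.
    """

    n_perm: int
    r2_intercept: float
    q2_intercept: float
    correlations: np.ndarray
    r2_values: np.ndarray
    q2_values: np.ndarray


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    n_perm: int = 100,
    seed: int = 0,
    k_folds: int = 7,
) -> PermutationResult:
    """Refit the model on permuted responses and extrapolate to correlation 0.

    For each seeded permutation of y the model is refit at ``n_lv`` latent
    variables; |corr(y_perm, y)|, the training R^2 and the k-fold Q^2 are
    recorded, together with the unpermuted anchor point at correlation 1.
    R^2 (and Q^2) are regressed on the correlation; the intercepts at
    correlation 0 are reported.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a stable intercept")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    rng = np.random.default_rng(seed)

    def _point(y_used: np.ndarray) -> tuple[float, float]:
        model = fit_pls(X, y_used, n_lv)
        r2 = _r2_pearson(y_used, model.fitted)
        folds = _fold_assignments(y_used, k_folds, rng)
        press = _cv_press(X, y_used, model.n_lv, folds)
        ss = float(np.sum((y_used - y_used.mean()) ** 2))
        q2 = 1.0 - press[-1] / ss
        return r2, q2

    corrs = [1.0]
    r2s, q2s = [], []
    r2_0, q2_0 = _point(y)
    r2s.append(r2_0)
    q2s.append(q2_0)
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        corrs.append(abs(float(stats.pearsonr(y_perm, y)[0])))
        r2_p, q2_p = _point(y_perm)
        r2s.append(r2_p)
        q2s.append(q2_p)
    corrs = np.asarray(corrs)
    r2s = np.asarray(r2s)
    q2s = np.asarray(q2s)
    design = np.column_stack([np.ones_like(corrs), corrs])
    r2_line, *_ = np.linalg.lstsq(design, r2s, rcond=None)
    q2_line, *_ = np.linalg.lstsq(design, q2s, rcond=None)
    return PermutationResult(
        n_perm=n_perm,
        r2_intercept=float(r2_line[0]),
        q2_intercept=float(q2_line[0]),
        correlations=corrs,
        r2_values=r2s,
        q2_values=q2s,
    )
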