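"""Presence–background suitability modelling.

The engine is a ridge-penalized logistic regression contrasting
presence cells (label 1) against random background cells (label 0) on
standardized linear + quadratic features of the chosen predictors.
Standardization constants come from the background sample, so the fit
is invariant to affine rescaling of the raw predictors. The model is
convex and fitted by damped Newton iterations to a gradient norm of
1e-8, making every fit deterministic.

Evaluation follows the field's presence–background workflow: spatial
block cross-validation (square blocks, default 250 km, greedily
balanced into k folds by presence count), the rank-based (Mann–Whitney)
AUC, an acceptance gate at mean AUC >= 0.70, binarization at the
threshold maximizing sensitivity + specificity, and permutation
importance per predictor (its linear and quadratic features permuted
jointly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geo import KM_PER_DEG_LAT
from .grid import GridSpec
from .world import EnvStack

__all__ = [
    "Standardization",
    "SuitabilityModel",
    "BlockAssignment",
    "sample_background",
    "fit_standardization",
    "build_features",
    "fit_model",
    "predict",
    "assign_blocks",
    "auc",
    "cross_validate",
    "select_threshold",
    "permutation_importance",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class Standardization:
    """Per-predictor mean/sd fitted on background values only.

    Predictors whose background sd is zero are dropped (with a warning):
    they carry no contrast between presence and background.
    """

    predictors: list[str]
    means: np.ndarray
    sds: np.ndarray


@dataclass
class SuitabilityModel:
    standardization: Standardization
    intercept: float
    coefficients: np.ndarray  # (2 * n_predictors,) — z then z^2 per predictor, interleaved
    lam: float
    cv_auc: list[float] = field(default_factory=list)
    mean_cv_auc: float = float("nan")
    accepted: bool = False
    threshold: float = float("nan")
    importances: dict[str, float] = field(default_factory=dict)

    @property
    def predictors(self) -> list[str]:
        return self.standardization.predictors

    def score_raw(self, raw: pd.DataFrame | dict[str, np.ndarray]) -> np.ndarray:
        X = build_features(raw, self.standardization)
        return _sigmoid(self.intercept + X @ self.coefficients)


@dataclass(frozen=True)
class BlockAssignment:
    block_id: np.ndarray  # per point
    fold_id: np.ndarray  # per point
    block_size_km: float
    k: int


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def sample_background(
    mask: np.ndarray, grid: GridSpec, n: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """n cell centers sampled uniformly with replacement from mask cells.

    Emulates drawing random background points within the species' known
    range. Returns a frame with row, col, lon, lat.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask not aligned to grid")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("background mask is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rows.size, size=n)
    lon_c = grid.lon_centers()
    lat_c = grid.lat_centers()
    return pd.DataFrame(
        {
            "row": rows[idx],
            "col": cols[idx],
            "lon": lon_c[cols[idx]],
            "lat": lat_c[rows[idx]],
        }
    )


def fit_standardization(background_values: pd.DataFrame, predictors: list[str]) -> Standardization:
    kept, means, sds = [], [], []
    for p in predictors:
        x = np.asarray(background_values[p], dtype=float)
        m, s = float(np.mean(x)), float(np.std(x))
        if s == 0.0:
            warnings.warn(f"predictor {p!r} constant on background; dropped", stacklevel=2)
            continue
        kept.append(p)
        means.append(m)
        sds.append(s)
    return Standardization(kept, np.asarray(means), np.asarray(sds))


def build_features(
    values: pd.DataFrame | dict[str, np.ndarray], standardization: Standardization
) -> np.ndarray:
    """Feature matrix [z_1, z_1^2, z_2, z_2^2, ...] for the kept predictors."""
    n_pred = len(standardization.predictors)
    cols = []
    for i, p in enumerate(standardization.predictors):
        x = np.asarray(values[p], dtype=float)
        if not np.isfinite(x).all():
            raise ValueError(f"missing values in predictor {p!r}")
        z = (x - standardization.means[i]) / standardization.sds[i]
        cols.append(z)
        cols.append(z * z)
    if not cols:
        raise ValueError("no usable predictors")
    X = np.column_stack(cols)
    assert X.shape[1] == 2 * n_pred
    return X


def _fit_ridge_logistic(
    X: np.ndarray, y: np.ndarray, lam: float, max_iter: int = 100, gtol: float = 1e-8
) -> tuple[float, np.ndarray]:
    """Damped Newton on the penalized logistic loss; intercept unpenalized."""
    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])
    pen = np.full(p + 1, lam)
    pen[0] = 0.0
    beta = np.zeros(p + 1)

    def loss_grad(b):
        eta = Xa @ b
        # log(1 + exp(eta)) - y*eta, numerically stable
        ll = np.sum(np.logaddexp(0.0, eta) - y * eta)
        mu = _sigmoid(eta)
        g = Xa.T @ (mu - y) + pen * b
        return ll + 0.5 * lam * np.sum(b[1:] ** 2), g, mu

    f, g, mu = loss_grad(beta)
    for _ in range(max_iter):
        if np.linalg.norm(g) <= gtol:
            return float(beta[0]), beta[1:]
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (Xa * w[:, None]).T @ Xa + np.diag(pen)
        step = np.linalg.solve(H, g)
        # full Newton step first: near the optimum the loss sits on a
        # floating-point plateau where Armijo cannot certify decrease,
        # but the gradient still contracts quadratically
        cand = beta - step
        f_new, g_new, mu_new = loss_grad(cand)
        if np.linalg.norm(g_new) < np.linalg.norm(g):
            beta, f, g, mu = cand, f_new, g_new, mu_new
            continue
        t = 0.5
        for _ in range(50):
            cand = beta - t * step
            f_new, g_new, mu_new = loss_grad(cand)
            if f_new <= f - 1e-4 * t * float(g @ step):
                beta, f, g, mu = cand, f_new, g_new, mu_new
                break
            t *= 0.5
        else:
            raise ConvergenceError(
                f"line search failed; |grad|={np.linalg.norm(g):.3e}, loss={f:.6e}"
            )
    if np.linalg.norm(g) <= gtol:
        return float(beta[0]), beta[1:]
    raise ConvergenceError(
        f"Newton did not reach |grad| <= {gtol} in {max_iter} iterations "
        f"(|grad|={np.linalg.norm(g):.3e})"
    )


def fit_model(
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    predictors: list[str],
    lam: float = 1.0,
    standardization: Standardization | None = None,
) -> SuitabilityModel:
    """Fit the penalized presence–background logistic model.

    ``lam`` is the ridge strength on the non-intercept coefficients.
    Standardization defaults to constants fitted on the supplied
    background (pass one explicitly to reuse training-fold constants).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    std = standardization or fit_standardization(background_values, predictors)
    Xp = build_features(presence_values, std)
    Xb = build_features(background_values, std)
    X = np.vstack([Xp, Xb])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
    intercept, coefs = _fit_ridge_logistic(X, y, lam)
    return SuitabilityModel(standardization=std, intercept=intercept, coefficients=coefs, lam=lam)


def predict(model: SuitabilityModel, env: EnvStack, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-cell suitability in (0,1); cells outside the mask are NaN."""
    missing = [p for p in model.predictors if p not in env.layers]
    if missing:
        raise ValueError(f"env stack lacks predictor layers {missing}")
    grid = env.grid
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    out = np.full(grid.shape, np.nan)
    sel = np.asarray(mask, dtype=bool)
    vals = {p: env.layers[p][sel] for p in model.predictors}
    out[sel] = model.score_raw(vals)
    return out


def assign_blocks(
    lon: np.ndarray,
    lat: np.ndarray,
    is_presence: np.ndarray,
    grid: GridSpec,
    block_size_km: float = 250.0,
    k: int = 5,
    seed: int = 0,
) -> BlockAssignment:
    """Square spatial blocks, greedily balanced into k folds.

    Blocks tile the grid extent with an edge of ``block_size_km``
    converted to degrees (latitude conversion, with the longitudinal
    edge widened by 1/cos(mid-latitude)). Blocks are processed in
    descending presence count — equal-count blocks in seeded random
    order — and each is assigned to the fold currently holding the
    fewest presences (ties to the lowest fold id), which bounds the
    fold-total spread by the largest single block.
    """
    if block_size_km <= 0:
        raise ValueError("block_size_km must be > 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    is_presence = np.asarray(is_presence, dtype=bool)
    lat_edge = block_size_km / KM_PER_DEG_LAT
    mid_lat = 0.5 * (grid.lat_min + grid.lat_max)
    lon_edge = lat_edge / max(np.cos(np.deg2rad(mid_lat)), 1e-6)
    bi = np.floor((lat - grid.lat_min) / lat_edge).astype(int)
    bj = np.floor((lon - grid.lon_min) / lon_edge).astype(int)
    n_bj = int(np.floor((grid.lon_max - grid.lon_min) / lon_edge)) + 1
    block = bi * n_bj + bj

    ids, inverse = np.unique(block, return_inverse=True)
    if ids.size < k:
        raise ValueError(f"only {ids.size} non-empty blocks for k={k} folds")
    pres_count = np.bincount(inverse, weights=is_presence.astype(float), minlength=ids.size)

    rng = np.random.default_rng(seed)
    shuffle_key = rng.permutation(ids.size)
    order = np.lexsort((ids, shuffle_key, -pres_count))

    fold_of_block = np.empty(ids.size, dtype=int)
    fold_load = np.zeros(k)
    for b in order:
        f = int(np.argmin(fold_load))  # argmin takes the lowest index on ties
        fold_of_block[b] = f
        fold_load[f] += pres_count[b]
    return BlockAssignment(
        block_id=ids[inverse],
        fold_id=fold_of_block[inverse],
        block_size_km=float(block_size_km),
        k=k,
    )


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Mann–Whitney AUC: P(presence score > background score) + 0.5 P(equal).

    Computed from midranks, which is algebraically the mean over all
    (presence, background) pairs of the indicator with half-credit ties.
    """
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def cross_validate(
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    predictors: list[str],
    presence_folds: np.ndarray,
    background_folds: np.ndarray,
    lam: float = 1.0,
    auc_min: float = 0.70,
) -> tuple[list[float], float, bool]:
    """Spatial-block k-fold CV: fit on k-1 folds, AUC on the held-out fold.

    Folds with no held-out presences or background are skipped with a
    warning; fewer than two usable folds is an error. The model is
    accepted when the mean fold AUC is at least ``auc_min``.
    """
    presence_folds = np.asarray(presence_folds)
    background_folds = np.asarray(background_folds)
    folds = np.unique(np.concatenate([presence_folds, background_folds]))
    aucs: list[float] = []
    for f in folds:
        test_p = presence_folds == f
        test_b = background_folds == f
        if test_p.sum() == 0 or test_b.sum() == 0 or test_p.all() or test_b.all():
            warnings.warn(f"fold {f} unusable (degenerate presence/background split); skipped", stacklevel=2)
            continue
        train_bg = background_values[~test_b]
        model = fit_model(presence_values[~test_p], train_bg, predictors, lam=lam)
        scores_p = model.score_raw(presence_values[test_p])
        scores_b = model.score_raw(background_values[test_b])
        aucs.append(auc(scores_p, scores_b))
    if len(aucs) < 2:
        raise ValueError(f"only {len(aucs)} usable CV folds; need at least 2")
    mean = float(np.mean(aucs))
    return aucs, mean, mean >= auc_min


def select_threshold(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Smallest observed score maximizing sensitivity + specificity.

    sensitivity(t) = P(presence >= t); specificity(t) = P(background < t);
    candidates are the sorted unique observed scores.
    """
    pos = np.sort(np.asarray(presence_scores, dtype=float))
    neg = np.sort(np.asarray(background_scores, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    cand = np.unique(np.concatenate([pos, neg]))
    # integer counts cross-multiplied by the set sizes keep the
    # objective exact, so ties break on the true smallest candidate
    n_sens = pos.size - np.searchsorted(pos, cand, side="left")
    n_spec = np.searchsorted(neg, cand, side="left")
    total = n_sens * neg.size + n_spec * pos.size
    return float(cand[np.argmax(total)])  # argmax -> first (smallest) maximizer


def marginal_optimum(model: SuitabilityModel, predictor: str, candidates: np.ndarray) -> float:
    """Raw predictor value maximizing suitability with the other
    predictors held at their background means (z = 0).

    Features are additive, so the profile over one predictor is
    b1*z + b2*z^2 regardless of the rest; used to compare the fitted
    niche optimum against a virtual species' true one.
    """
    if predictor not in model.predictors:
        raise ValueError(f"{predictor!r} not among model predictors")
    i = model.predictors.index(predictor)
    m, s = model.standardization.means[i], model.standardization.sds[i]
    b1 = model.coefficients[2 * i]
    b2 = model.coefficients[2 * i + 1]
    cand = np.asarray(candidates, dtype=float)
    if b2 < 0:
        z_star = -b1 / (2.0 * b2)
        lo, hi = (np.min(cand) - m) / s, (np.max(cand) - m) / s
        return float(m + s * np.clip(z_star, lo, hi))
    z = (cand - m) / s
    return float(cand[np.argmax(b1 * z + b2 * z * z)])


def permutation_importance(
    model: SuitabilityModel,
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    n_perm: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Mean AUC drop when a predictor's raw values are permuted
    (linear and quadratic features move together), floored at zero and
    normalized to sum to one when any predictor matters."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    p_full = model.score_raw(presence_values)
    b_full = model.score_raw(background_values)
    auc_full = auc(p_full, b_full)
    raw = {
        p: np.concatenate(
            [np.asarray(presence_values[p], float), np.asarray(background_values[p], float)]
        )
        for p in model.predictors
    }
    n_pres = len(p_full)
    drops = {}
    for p in model.predictors:
        drop = 0.0
        for _ in range(n_perm):
            perm = dict(raw)
            perm[p] = rng.permutation(raw[p])
            scores = model.score_raw(perm)
            drop += auc_full - auc(scores[:n_pres], scores[n_pres:])
        drops[p] = max(0.0, drop / n_perm)
    total = sum(drops.values())
    if total > 0:
        drops = {p: v / total for p, v in drops.items()}
    return drops
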