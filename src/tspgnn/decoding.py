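"""Behavior-driven Elastic-Net decoding of task-specific connectome edges.

The decoding model is penalized linear regression of a behavioral score y
on functional-connectivity edge features x:

    min_beta  sum_i (f(x_i) - y_i)^2
              + lambda * sum_j ( alpha * |beta_j| + 1/2 (1 - alpha) beta_j^2 )

so alpha = 1 is the lasso and alpha = 0 is ridge, with lambda weighting the
whole penalty. Fitting is delegated to scikit-learn's coordinate descent
after an exact rescaling of the objective (divide by 2n: sklearn's ``alpha``
is lambda/(2n) and ``l1_ratio`` is alpha).

The cross-validated decode is leak-free: edge screening, feature
standardization and penalty selection all happen inside each training fold.
Out-of-fold predictions are assembled over all subjects, evaluated with
r / R^2 / MSE / EVS / MAE, and the observed out-of-fold correlation is
ranked against decodes of permuted scores for a permutation p-value.
Edges with non-zero coefficients in a sufficient fraction of folds form the
task-specific subnetwork.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetConfig",
    "DecodingResult",
    "throughput_score",
    "delay_discount_score",
    "composite_score",
    "screen_edges",
    "fit_elastic_net",
    "lambda_max",
    "cross_validated_decode",
    "aggregate_edges",
    "permutation_test",
    "evaluate_predictions",
]

#: Mixing-parameter grid searched when ``alpha`` is not fixed.
ALPHA_GRID: tuple[float, ...] = (0.1, 0.5, 0.9)


@dataclass
class ElasticNetConfig:
    """Penalty configuration.

    ``lambda_`` is the overall penalty weight of the objective above;
    ``alpha`` mixes L1 (1.0) against L2 (0.0). Either may be ``None``, in
    which case it is selected by cross-validation inside each training fold
    (lambda over ``n_lambdas`` log-spaced values, alpha over ``ALPHA_GRID``).
    """

    lambda_: float | None = None
    alpha: float | None = 0.5
    max_iter: int = 5000
    tol: float = 1e-6
    standardize: bool = True
    n_lambdas: int = 20
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda_ is not None and self.lambda_ < 0:
            raise ValueError("lambda_ must be nonnegative")
        if self.lambda_ is not None and self.alpha is None:
            raise ValueError("a fixed lambda_ requires a fixed alpha")


@dataclass
class DecodingResult:
    """Output of one cross-validated decode."""

    screened_edges: list[np.ndarray]          # per-fold screened (original) indices
    nonzero_edges: list[np.ndarray]           # per-fold indices with beta != 0
    coefficients: list[np.ndarray]            # per-fold dense beta over screened edges
    oof_predictions: np.ndarray               # aligned to subjects, each exactly once
    y: np.ndarray
    fold_assignment: np.ndarray
    metrics: dict
    chosen_lambda: list[float] = field(default_factory=list)
    chosen_alpha: list[float] = field(default_factory=list)
    permutation_p: float | None = None
    n_permutations: int = 0

    @property
    def n_folds(self) -> int:
        return len(self.nonzero_edges)

    def edge_frequency(self) -> dict[int, float]:
        """Fraction of folds in which each edge had a non-zero coefficient."""
        freq: dict[int, float] = {}
        for idx in self.nonzero_edges:
            for e in idx:
                freq[int(e)] = freq.get(int(e), 0.0) + 1.0
        return {e: c / self.n_folds for e, c in sorted(freq.items())}


# ---------------------------------------------------------------------------
# behavioral scores
# ---------------------------------------------------------------------------

def throughput_score(accuracy: float, median_rt: float) -> float:
    """Speed-accuracy composite: accuracy divided by median response time."""
    if median_rt <= 0:
        raise ValueError("median_rt must be positive")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    return accuracy / median_rt


def delay_discount_score(auc_40k: float, auc_200: float) -> float:
    """Delay-discounting difference: AUC at the large minus small reward."""
    if not (np.isfinite(auc_40k) and np.isfinite(auc_200)):
        raise ValueError("AUC inputs must be finite")
    return auc_40k - auc_200


def composite_score(measures: np.ndarray) -> np.ndarray:
    """General-ability composite: first principal component of z-scored measures.

    Columns are z-scored, the leading PC score is rescaled to unit variance,
    and its sign is fixed so the sum of loadings is positive (a higher
    composite means doing better on the battery as a whole).
    """
    x = np.asarray(measures, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need at least 3 subjects and 2 measures")
    if not np.isfinite(x).all():
        raise ValueError("measures contain missing or non-finite values")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"constant measure column at index {int(np.flatnonzero(sd == 0)[0])}")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    load = vt[0]
    if load.sum() < 0:
        load = -load
    score = z @ load
    return score / score.std()


# ---------------------------------------------------------------------------
# screening and fitting
# ---------------------------------------------------------------------------

def screen_edges(x: np.ndarray, y: np.ndarray, top_k: int) -> np.ndarray:
    """Indices of the ``top_k`` edges by |Pearson r(edge, y)|, ties by index."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if top_k > x.shape[1]:
        raise ValueError("top_k exceeds the number of edges")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum(axis=0))
    sy = np.sqrt(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    dead = ~np.isfinite(r)
    if dead.any():
        logger.info("screen_edges: %d zero-variance edges assigned r = 0", int(dead.sum()))
        r = np.where(dead, 0.0, r)
    order = np.lexsort((np.arange(r.size), -np.abs(r)))
    return np.sort(order[:top_k])


def lambda_max(x: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty at which the solution is exactly beta = 0 (alpha > 0)."""
    if alpha <= 0:
        raise ValueError("lambda_max is defined for alpha > 0")
    yc = np.asarray(y, float) - np.mean(y)
    xc = np.asarray(x, float) - np.mean(x, axis=0)
    return 2.0 * float(np.abs(xc.T @ yc).max()) / alpha


def fit_elastic_net(
    x: np.ndarray,
    y: np.ndarray,
    cfg: ElasticNetConfig,
) -> tuple[np.ndarray, float]:
    """Minimize the penalized RSS objective; returns (beta, intercept).

    The intercept is unpenalized. ``cfg.standardize`` z-scores columns of x
    before fitting and reports coefficients on the *original* scale.
    Requires fixed ``lambda_`` and ``alpha`` (selection lives in
    :func:`cross_validated_decode`).
    """
    if cfg.lambda_ is None or cfg.alpha is None:
        raise ValueError("fit_elastic_net needs fixed lambda_ and alpha")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if cfg.standardize:
        mu, sd = x.mean(axis=0), x.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        xs = (x - mu) / sd
    else:
        mu, sd = np.zeros(x.shape[1]), np.ones(x.shape[1])
        xs = x

    if cfg.lambda_ == 0.0:
        beta_s, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(n), xs]), y, rcond=None
        )
        intercept_s, beta_s = beta_s[0], beta_s[1:]
    else:
        model = ElasticNet(
            alpha=cfg.lambda_ / (2.0 * n),
            l1_ratio=cfg.alpha,
            fit_intercept=True,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(xs, y)
        if model.n_iter_ is not None and model.n_iter_ >= cfg.max_iter:
            gap = getattr(model, "dual_gap_", np.nan)
            raise RuntimeError(
                f"elastic net did not converge in {cfg.max_iter} iterations "
                f"(final duality gap {gap:.3g})"
            )
        beta_s, intercept_s = model.coef_, float(model.intercept_)

    beta = beta_s / sd
    intercept = intercept_s - float(mu @ beta)
    return beta, intercept


def _select_penalty(
    x: np.ndarray, y: np.ndarray, cfg: ElasticNetConfig, seed: int
) -> tuple[float, float]:
    """Inner-CV choice of (lambda, alpha) on a training fold."""
    n = x.shape[0]
    l1_grid = [cfg.alpha] if cfg.alpha is not None else list(ALPHA_GRID)
    inner = KFold(n_splits=cfg.inner_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ElasticNetCV(
            l1_ratio=l1_grid,
            alphas=cfg.n_lambdas,
            cv=inner,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
        )
        model.fit(x, y)
    return float(model.alpha_ * 2.0 * n), float(model.l1_ratio_)


def cross_validated_decode(
    x: np.ndarray,
    y: np.ndarray,
    cfg: ElasticNetConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
    top_k: int = 500,
) -> DecodingResult:
    """Leak-free k-fold decode of behavior from edge features.

    Per fold: screen the ``top_k`` most behavior-correlated edges on the
    training subjects only, z-score with training statistics, select the
    penalty if unset, fit, and predict the held-out subjects. Out-of-fold
    predictions cover every subject exactly once; metrics are computed on
    the concatenated out-of-fold pairs.
    """
    cfg = cfg or ElasticNetConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n < n_folds:
        raise ValueError("fewer subjects than folds")
    top_k = min(top_k, p)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    screened, nonzero, coefs, lams, mixes = [], [], [], [], []
    for f, (tr, te) in enumerate(kf.split(x)):
        if te.size < 1 or tr.size < 2:
            raise ValueError(f"fold {f} too small")
        idx = screen_edges(x[tr], y[tr], top_k)
        xt = x[np.ix_(tr, idx)]
        mu, sd = xt.mean(axis=0), xt.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        xt = (xt - mu) / sd
        ym = y[tr].mean()
        yt = y[tr] - ym

        if cfg.lambda_ is None:
            lam, mix = _select_penalty(xt, yt, cfg, seed)
        else:
            lam, mix = cfg.lambda_, cfg.alpha
        fold_cfg = ElasticNetConfig(
            lambda_=lam, alpha=mix, max_iter=cfg.max_iter, tol=cfg.tol, standardize=False
        )
        beta, b0 = fit_elastic_net(xt, yt, fold_cfg)

        xe = (x[np.ix_(te, idx)] - mu) / sd
        oof[te] = xe @ beta + b0 + ym
        fold_of[te] = f
        screened.append(idx)
        nz = idx[np.flatnonzero(beta)]
        nonzero.append(nz)
        coefs.append(beta)
        lams.append(lam)
        mixes.append(mix)

    assert not np.isnan(oof).any()
    metrics = evaluate_predictions(y, oof)
    return DecodingResult(
        screened_edges=screened,
        nonzero_edges=nonzero,
        coefficients=coefs,
        oof_predictions=oof,
        y=y,
        fold_assignment=fold_of,
        metrics=metrics,
        chosen_lambda=lams,
        chosen_alpha=mixes,
    )


def aggregate_edges(result: DecodingResult, freq_threshold: float = 0.5) -> np.ndarray:
    """Edges non-zero in at least ``freq_threshold`` of folds (the subnetwork)."""
    if not 0.0 < freq_threshold <= 1.0:
        raise ValueError("freq_threshold must lie in (0, 1]")
    freq = result.edge_frequency()
    sel = np.array(sorted(e for e, f in freq.items() if f >= freq_threshold - 1e-12), dtype=int)
    if sel.size == 0:
        warnings.warn("no edges pass the aggregation threshold; empty subnetwork", stacklevel=2)
    return sel


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    cfg: ElasticNetConfig | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    n_folds: int = 10,
    top_k: int = 500,
    observed: DecodingResult | None = None,
) -> tuple[float, DecodingResult]:
    """Permutation p-value of the out-of-fold prediction correlation.

    The decode is re-run on randomly shuffled scores with the same fold
    assignment; the penalty is frozen at the values selected on the observed
    data (per-fold medians) so every permutation fits the same model family.
    p = (1 + #{perm r >= observed r}) / (1 + n_permutations), never zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    cfg = cfg or ElasticNetConfig()
    if observed is None:
        observed = cross_validated_decode(x, y, cfg, n_folds=n_folds, seed=seed, top_k=top_k)
    frozen = ElasticNetConfig(
        lambda_=float(np.median(observed.chosen_lambda)),
        alpha=float(np.median(observed.chosen_alpha)),
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        standardize=False,
    )
    r_obs = observed.metrics["r"]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        perm = cross_validated_decode(
            x, yp, frozen, n_folds=n_folds, seed=seed, top_k=top_k
        )
        if perm.metrics["r"] >= r_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    observed.permutation_p = p
    observed.n_permutations = n_permutations
    return p, observed


def evaluate_predictions(y: np.ndarray, y_hat: np.ndarray) -> dict:
    """Prediction quality: Pearson r, R^2, MSE, explained variance, MAE."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size or y.size < 3:
        raise ValueError("y and y_hat must have equal length >= 3")
    if y.std() == 0:
        raise ValueError("observed scores are constant")
    resid = y - y_hat
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if y_hat.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(y, y_hat)[0, 1])
    return {
        "r": r,
        "r2": 1.0 - float((resid**2).sum()) / ss_tot,
        "mse": float((resid**2).mean()),
        "evs": 1.0 - float(resid.var()) / float(y.var()),
        "mae": float(np.abs(resid).mean()),
    }
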