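"""Population-graph spectral GCN for subject classification.

Subjects are the nodes of a population graph whose edge weights combine
imaging-feature similarity with phenotype agreement:

    W(x, y) = Sim(A_x, A_y) * sum_h gamma(N_h(x), N_h(y))

where Sim is a Gaussian kernel on the correlation distance between feature
vectors, exp(-rho^2 / (2 sigma^2)), and gamma is a unit-step agreement
indicator per phenotype (|difference| < theta for continuous columns, exact
match for categorical ones). Spectral filtering operates on the symmetric
normalized Laplacian L = I - D^(-1/2) W D^(-1/2), whose spectrum lies in
[0, 2]; filters are order-K Chebyshev polynomials evaluated with the T_k
recurrence on the rescaled Laplacian 2L/lambda_max - I, so no
eigendecomposition is needed at train time.

The classifier itself is a small fully-convolutional network — Chebyshev
convolution layers with ReLU hidden activations and a softmax output —
trained transductively: the graph spans all subjects, but the masked
cross-entropy loss (and every fitted statistic upstream: z-scoring, RFE,
the similarity kernel width) only ever sees training subjects. The network
is implemented directly in numpy with hand-derived gradients and an Adam
optimizer; the model is tiny (hundreds of subjects, a few thousand
parameters) so this is both fast and exactly checkable against a
spectral-domain oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import rfe_ridge

__all__ = [
    "PhenotypeSpec",
    "SimilarityConfig",
    "GCNConfig",
    "PopulationGraph",
    "GCNModel",
    "phenotype_agreement",
    "feature_similarity",
    "build_population_graph",
    "normalized_laplacian",
    "chebyshev_conv",
    "train_gcn",
    "predict_proba",
    "evaluate_cv",
]

#: Default phenotype columns and agreement rules: (kind, theta).
DEFAULT_PHENOTYPE_SPEC: dict[str, tuple[str, float | None]] = {
    "age": ("continuous", 2.0),
    "sex": ("categorical", None),
    "site": ("categorical", None),
}

PhenotypeSpec = dict[str, tuple[str, float | None]]


@dataclass
class SimilarityConfig:
    """Gaussian kernel on correlation distance; sigma may be 'auto'
    (median pairwise correlation distance among training subjects)."""

    sigma: float | str = "auto"

    def __post_init__(self) -> None:
        if isinstance(self.sigma, str):
            if self.sigma != "auto":
                raise ValueError("sigma must be positive or 'auto'")
        elif self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class GCNConfig:
    chebyshev_order: int = 3
    hidden: tuple[int, ...] = (16,)
    dropout: float = 0.3
    learning_rate: float = 0.005
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chebyshev_order < 1:
            raise ValueError("chebyshev_order must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class PopulationGraph:
    w: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    sigma: float = float("nan")

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("population adjacency must be symmetric")
        if w.min() < 0:
            raise ValueError("population adjacency must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("population adjacency diagonal must be zero")
        self.w = w


@dataclass
class GCNModel:
    config: GCNConfig
    weights: list[list[np.ndarray]]   # per layer: K matrices (F_in x F_out)
    biases: list[np.ndarray]
    loss_trace: np.ndarray
    lambda_max: float


# ---------------------------------------------------------------------------
# population graph
# ---------------------------------------------------------------------------

def phenotype_agreement(a, b, theta: float | None = None, kind: str = "continuous") -> int:
    """Unit-step agreement: |a-b| < theta (continuous) or equality (categorical)."""
    if kind == "continuous":
        if theta is None or theta <= 0:
            raise ValueError("continuous phenotype needs theta > 0")
        return int(abs(float(a) - float(b)) < theta)
    if kind == "categorical":
        return int(a == b)
    raise ValueError(f"unknown phenotype kind {kind!r}")


def feature_similarity(fx: np.ndarray, fy: np.ndarray, sigma: float = 1.0) -> float:
    """exp(-rho^2 / (2 sigma^2)) with rho = 1 - Pearson(fx, fy)."""
    fx = np.asarray(fx, dtype=float).ravel()
    fy = np.asarray(fy, dtype=float).ravel()
    if fx.size != fy.size:
        raise ValueError("feature vectors must have equal length")
    if fx.std() == 0 or fy.std() == 0:
        raise ValueError("constant feature vector has undefined correlation distance")
    rho = 1.0 - float(np.corrcoef(fx, fy)[0, 1])
    return math.exp(-(rho**2) / (2.0 * sigma**2))


def _correlation_distances(features: np.ndarray) -> np.ndarray:
    sd = features.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant feature vector has undefined correlation distance")
    return 1.0 - np.corrcoef(features)


def resolve_sigma(
    features: np.ndarray,
    cfg: SimilarityConfig,
    train_idx: np.ndarray | None = None,
) -> float:
    """Fixed sigma, or the median training-pair correlation distance."""
    if cfg.sigma != "auto":
        return float(cfg.sigma)
    idx = np.arange(features.shape[0]) if train_idx is None else np.asarray(train_idx)
    rho = _correlation_distances(features[idx])
    iu = np.triu_indices(idx.size, k=1)
    med = float(np.median(rho[iu]))
    return med if med > 0 else 1.0


def build_population_graph(
    features: np.ndarray | pd.DataFrame,
    phenotypes: pd.DataFrame,
    labels: np.ndarray,
    sim_cfg: SimilarityConfig | None = None,
    phenotype_spec: PhenotypeSpec | None = None,
    train_idx: np.ndarray | None = None,
) -> PopulationGraph:
    """Assemble W(x,y) = Sim(x,y) * sum_h gamma_h(x,y) over all subject pairs."""
    sim_cfg = sim_cfg or SimilarityConfig()
    spec = phenotype_spec or DEFAULT_PHENOTYPE_SPEC
    if isinstance(features, pd.DataFrame):
        ids = list(features.index)
        fv = features.to_numpy(dtype=float)
    else:
        fv = np.asarray(features, dtype=float)
        ids = [f"sub-{s:04d}" for s in range(fv.shape[0])]
    if list(phenotypes.index) != ids:
        raise ValueError("subject ids of features and phenotypes do not match")
    n = fv.shape[0]

    sigma = resolve_sigma(fv, sim_cfg, train_idx)
    rho = _correlation_distances(fv)
    sim = np.exp(-(rho**2) / (2.0 * sigma**2))

    gamma = np.zeros((n, n))
    for col, (kind, theta) in spec.items():
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype column {col!r} missing")
        v = phenotypes[col].to_numpy()
        if kind == "continuous":
            if theta is None or theta <= 0:
                raise ValueError(f"continuous phenotype {col!r} needs theta > 0")
            agree = (np.abs(v[:, None].astype(float) - v[None, :].astype(float)) < theta)
        elif kind == "categorical":
            agree = v[:, None] == v[None, :]
        else:
            raise ValueError(f"unknown phenotype kind {kind!r}")
        gamma += agree.astype(float)

    w = sim * gamma
    np.fill_diagonal(w, 0.0)
    w = 0.5 * (w + w.T)
    return PopulationGraph(w, fv, np.asarray(labels).ravel(), ids, sigma)


def normalized_laplacian(w: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian I - D^(-1/2) W D^(-1/2).

    Isolated subjects (zero degree) keep an identity row, so the spectrum
    stays in [0, 2] and the matrix stays symmetric.
    """
    w = np.asarray(w, dtype=float)
    if w.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    deg = w.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    lap = -w * np.outer(inv_sqrt, inv_sqrt)
    np.fill_diagonal(lap, 1.0)
    return 0.5 * (lap + lap.T)


def _scaled_laplacian(lap: np.ndarray, lam_max: float) -> np.ndarray:
    if lam_max <= 0:
        raise ValueError("lambda_max must be positive")
    return 2.0 * lap / lam_max - np.eye(lap.shape[0])


def _cheb_basis(lhat: np.ndarray, x: np.ndarray, k: int) -> list[np.ndarray]:
    """[T_0(Lhat) X, ..., T_{K-1}(Lhat) X] by the Chebyshev recurrence."""
    zs = [x]
    if k > 1:
        zs.append(lhat @ x)
    for _ in range(2, k):
        zs.append(2.0 * (lhat @ zs[-1]) - zs[-2])
    return zs


def chebyshev_conv(
    lap: np.ndarray,
    x: np.ndarray,
    thetas: Sequence[np.ndarray],
    lam_max: float | None = None,
) -> np.ndarray:
    """Order-K Chebyshev spectral filter: sum_k T_k(2L/lam_max - I) X Theta_k.

    Equivalent to U g(Lambda) U^T X with the polynomial filter g evaluated on
    the rescaled eigenvalues, but computed without eigendecomposition.
    Linear in X and permutation-equivariant.
    """
    lap = np.asarray(lap, dtype=float)
    if lam_max is None:
        lam_max = float(np.linalg.eigvalsh(lap).max())
    lhat = _scaled_laplacian(lap, lam_max)
    zs = _cheb_basis(lhat, np.asarray(x, dtype=float), len(thetas))
    return sum(z @ th for z, th in zip(zs, thetas))


# ---------------------------------------------------------------------------
# the network (numpy, manual gradients, Adam)
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def _forward(
    lhat: np.ndarray,
    x: np.ndarray,
    weights: list[list[np.ndarray]],
    biases: list[np.ndarray],
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Returns logits and the per-layer cache needed for backprop."""
    h = x
    caches = []
    n_layers = len(weights)
    for l, (ths, b) in enumerate(zip(weights, biases)):
        zs = _cheb_basis(lhat, h, len(ths))
        s = sum(z @ th for z, th in zip(zs, ths)) + b
        last = l == n_layers - 1
        if last:
            a, mask = s, None
        else:
            a = np.maximum(s, 0.0)
            mask = None
            if dropout > 0.0 and rng is not None:
                mask = (rng.uniform(size=a.shape) >= dropout) / (1.0 - dropout)
                a = a * mask
        caches.append({"zs": zs, "s": s, "mask": mask})
        h = a
    return h, caches


def _backward(
    lhat: np.ndarray,
    dlogits: np.ndarray,
    weights: list[list[np.ndarray]],
    caches: list[dict],
) -> tuple[list[list[np.ndarray]], list[np.ndarray]]:
    dw = [[np.zeros_like(th) for th in ths] for ths in weights]
    db = [np.zeros_like(np.atleast_1d(c["s"][0])) for c in caches]
    da = dlogits
    for l in range(len(weights) - 1, -1, -1):
        cache = caches[l]
        if l == len(weights) - 1:
            ds = da
        else:
            if cache["mask"] is not None:
                da = da * cache["mask"]
            ds = da * (cache["s"] > 0)
        db[l] = ds.sum(axis=0)
        dh = np.zeros_like(cache["zs"][0])
        for k, th in enumerate(weights[l]):
            dw[l][k] = cache["zs"][k].T @ ds
            # T_k(Lhat) is symmetric, so the adjoint reuses the recurrence
            g = ds @ th.T
            dh += _cheb_basis(lhat, g, k + 1)[k]
        da = dh
    return dw, db


def _masked_softmax_ce(logits: np.ndarray, labels: np.ndarray, mask: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    idx = np.flatnonzero(mask)
    loss = -float(np.mean(np.log(p[idx, labels[idx]] + 1e-12)))
    dlogits = np.zeros_like(logits)
    dlogits[idx] = p[idx]
    dlogits[idx, labels[idx]] -= 1.0
    dlogits /= idx.size
    return loss, p, dlogits


def train_gcn(
    graph: PopulationGraph,
    cfg: GCNConfig | None = None,
    train_mask: np.ndarray | None = None,
    seed: int | None = None,
) -> GCNModel:
    """Fit the Chebyshev GCN transductively with a masked cross-entropy loss.

    The graph spans all subjects; gradients flow only from training-mask
    rows. Deterministic for a fixed seed (initialization and dropout share
    one seeded generator). Raises if the loss goes non-finite.
    """
    cfg = cfg or GCNConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    n = graph.w.shape[0]
    if train_mask is None:
        train_mask = np.ones(n, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    labels = graph.labels.astype(int)
    if len(np.unique(labels[train_mask])) < 2:
        raise ValueError("training mask must contain both classes")

    lap = normalized_laplacian(graph.w)
    lam_max = float(np.linalg.eigvalsh(lap).max())
    if lam_max <= 0:
        lam_max = 2.0
    lhat = _scaled_laplacian(lap, lam_max)

    rng = np.random.default_rng(cfg.seed)
    widths = [graph.features.shape[1], *cfg.hidden, 2]
    weights = [
        [_glorot(rng, widths[l], widths[l + 1]) for _ in range(cfg.chebyshev_order)]
        for l in range(len(widths) - 1)
    ]
    biases = [np.zeros(widths[l + 1]) for l in range(len(widths) - 1)]

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_w = [[np.zeros_like(th) for th in ths] for ths in weights]
    v_w = [[np.zeros_like(th) for th in ths] for ths in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]

    losses = np.empty(cfg.epochs)
    for t in range(1, cfg.epochs + 1):
        logits, caches = _forward(
            lhat, graph.features, weights, biases, dropout=cfg.dropout, rng=rng
        )
        loss, _, dlogits = _masked_softmax_ce(logits, labels, train_mask)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at epoch {t}: {loss}")
        losses[t - 1] = loss
        dw, db = _backward(lhat, dlogits, weights, caches)
        corr = math.sqrt(1 - beta2**t) / (1 - beta1**t)
        for l in range(len(weights)):
            for k in range(len(weights[l])):
                m_w[l][k] = beta1 * m_w[l][k] + (1 - beta1) * dw[l][k]
                v_w[l][k] = beta2 * v_w[l][k] + (1 - beta2) * dw[l][k] ** 2
                weights[l][k] -= cfg.learning_rate * corr * m_w[l][k] / (np.sqrt(v_w[l][k]) + eps)
            m_b[l] = beta1 * m_b[l] + (1 - beta1) * db[l]
            v_b[l] = beta2 * v_b[l] + (1 - beta2) * db[l] ** 2
            biases[l] -= cfg.learning_rate * corr * m_b[l] / (np.sqrt(v_b[l]) + eps)

    return GCNModel(cfg, weights, biases, losses, lam_max)


def predict_proba(model: GCNModel, graph: PopulationGraph) -> np.ndarray:
    """Softmax class probabilities for every subject (dropout disabled)."""
    lap = normalized_laplacian(graph.w)
    lhat = _scaled_laplacian(lap, model.lambda_max)
    logits, _ = _forward(lhat, graph.features, model.weights, model.biases, dropout=0.0)
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def evaluate_cv(
    features: np.ndarray | pd.DataFrame,
    phenotypes: pd.DataFrame,
    labels: np.ndarray,
    model_cfg: GCNConfig | None = None,
    k: int = 5,
    seed: int = 0,
    rfe_keep: int | None = 200,
    sim_cfg: SimilarityConfig | None = None,
    phenotype_spec: PhenotypeSpec | None = None,
) -> dict:
    """Stratified k-fold transductive evaluation.

    Per fold: features are z-scored with training statistics, reduced by
    ridge-RFE fit on training subjects only, the population graph is rebuilt
    over all subjects from the transformed features (kernel width from
    training pairs), and the GCN is trained with the training mask. AUC uses
    the softmax class-1 score on held-out subjects; ACC thresholds the
    posterior at 0.5.
    """
    model_cfg = model_cfg or GCNConfig()
    if isinstance(features, pd.DataFrame):
        fv = features.to_numpy(dtype=float)
        ids = list(features.index)
    else:
        fv = np.asarray(features, dtype=float)
        ids = [f"sub-{s:04d}" for s in range(fv.shape[0])]
    labels = np.asarray(labels).ravel().astype(int)
    n = fv.shape[0]

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs, accs = [], []
    for f, (tr, te) in enumerate(skf.split(fv, labels)):
        if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[te])) < 2:
            raise ValueError(f"fold {f} lacks a class")
        mu, sd = fv[tr].mean(axis=0), fv[tr].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        z = (fv - mu) / sd
        if rfe_keep is not None and rfe_keep < z.shape[1]:
            keep = rfe_ridge(z[tr], labels[tr], n_keep=rfe_keep)
            z = z[:, keep]
        ph = phenotypes.copy()
        ph.index = ids
        graph = build_population_graph(
            pd.DataFrame(z, index=ids),
            ph,
            labels,
            sim_cfg=sim_cfg,
            phenotype_spec=phenotype_spec,
            train_idx=tr,
        )
        mask = np.zeros(n, dtype=bool)
        mask[tr] = True
        model = train_gcn(graph, model_cfg, train_mask=mask, seed=model_cfg.seed + f)
        proba = predict_proba(model, graph)[:, 1]
        aucs.append(float(roc_auc_score(labels[te], proba[te])))
        accs.append(float(np.mean((proba[te] >= 0.5).astype(int) == labels[te])))

    return {
        "auc_per_fold": aucs,
        "acc_per_fold": accs,
        "auc_mean": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs)),
        "acc_mean": float(np.mean(accs)),
        "acc_sd": float(np.std(accs)),
    }
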