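"""Synthetic connectome cohorts with planted, recoverable structure.

The generator emulates the statistical situation the rest of the package
assumes: a population of subjects, each with a valid region-by-region
correlation matrix, where

* a small planted edge set carries a linear signal for a continuous
  behavioral score at a configurable R-squared, and
* a case group differs from controls by a mean shift on the planted
  subnetwork, and
* ordinary phenotypes (age, sex, site) ride along for population-graph
  construction.

Background connectivity comes from a shared rank-3 latent-factor model plus
subject noise, which gives realistic edge-edge correlation without copying
any real data. After assembling edge values, each matrix is projected to a
valid correlation matrix (eigenvalue clipping + diagonal renormalization);
the behavioral signal is computed from the *post-projection* edge values so
the planted linear model holds exactly in the emitted data. The noise added
to the behavioral score is decorrelated from the signal and rescaled so the
sample R-squared of the planted linear predictor equals the target.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .connectome import ConnectivityMatrix, save_matrix_tsv

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_fc_population",
    "generate_timeseries",
    "sample_timeseries",
]

_BACKGROUND_RANK = 3
_BACKGROUND_SCALE = 0.35  # typical magnitude of background correlations
_EDGE_NOISE_SD = 0.12     # subject-to-subject edge variability


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    ``n_timepoints = 0`` means FC matrices are emitted directly;
    a positive value asks :func:`generate_timeseries` for series whose
    population correlation equals each subject's FC.
    ``target_r2 = None`` with ``beta = 0`` gives a pure-noise (null)
    behavioral score.
    """

    n_subjects: int = 200
    n_nodes: int = 30
    n_timepoints: int = 0
    planted_edges: tuple[tuple[int, int], ...] = ()
    beta: float = 1.0
    target_r2: float | None = 0.5
    group_delta: float = 0.0
    age_range: tuple[float, float] = (18.0, 35.0)
    female_fraction: float = 0.5
    n_sites: int = 2
    case_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")
        edges = tuple((int(i), int(j)) for i, j in self.planted_edges)
        if len(set(edges)) != len(edges):
            raise ValueError("planted_edges must be distinct")
        for i, j in edges:
            if not 0 <= i < j < self.n_nodes:
                raise ValueError(f"planted edge ({i}, {j}) must satisfy 0 <= i < j < n_nodes")
        self.planted_edges = edges
        if self.target_r2 is not None and not 0.0 < self.target_r2 < 1.0:
            raise ValueError("target_r2 must lie in (0, 1)")
        if self.target_r2 is not None and (self.beta == 0 or not edges):
            raise ValueError("no signal configured: target_r2 set but beta is 0 or no planted edges")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_edges"] = [list(e) for e in self.planted_edges]
        d["age_range"] = list(self.age_range)
        return d


@dataclass
class SyntheticCohort:
    fc_stack: list[ConnectivityMatrix]
    behavior: np.ndarray
    phenotypes: "pd.DataFrame"  # noqa: F821 - imported lazily below
    labels: np.ndarray
    truth: dict

    @property
    def subject_ids(self) -> list[str]:
        return list(self.phenotypes.index)

    def edge_matrix(self) -> np.ndarray:
        """Subjects x edges matrix of upper-triangle FC values."""
        from .connectome import vectorize

        return np.vstack([vectorize(c).values for c in self.fc_stack])

    def save(self, outdir: str | Path) -> None:
        """Write fc/<subject>.tsv, phenotypes.tsv and truth.json."""
        outdir = Path(outdir)
        (outdir / "fc").mkdir(parents=True, exist_ok=True)
        for sid, c in zip(self.subject_ids, self.fc_stack):
            save_matrix_tsv(outdir / "fc" / f"{sid}.tsv", c.values, c.node_ids)
        ph = self.phenotypes.copy()
        ph["behavior"] = self.behavior
        ph["label"] = self.labels
        ph.to_csv(outdir / "phenotypes.tsv", sep="\t", float_format="%.10g")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _project_to_correlation(m: np.ndarray) -> np.ndarray:
    """Nearest-ish valid correlation matrix: clip eigenvalues, renormalize."""
    sym = 0.5 * (m + m.T)
    np.fill_diagonal(sym, 1.0)
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() < 1e-8:
        vals = np.clip(vals, 1e-8, None)
        sym = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(sym))
        sym = sym / np.outer(d, d)
    sym = np.clip(sym, -1.0, 1.0)
    np.fill_diagonal(sym, 1.0)
    return 0.5 * (sym + sym.T)


def generate_fc_population(cfg: SyntheticConfig) -> SyntheticCohort:
    """Generate a cohort of FC matrices, behavior, phenotypes and labels.

    Deterministic: the same config (including seed) reproduces the cohort
    byte-for-byte after serialization.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_subjects, cfg.n_nodes

    # shared latent-factor background -> baseline edge means
    load = rng.normal(size=(p, _BACKGROUND_RANK)) / np.sqrt(_BACKGROUND_RANK)
    base = _BACKGROUND_SCALE * (load @ load.T)
    np.fill_diagonal(base, 1.0)

    # labels: balanced split (within rounding), shuffled deterministically
    n_cases = int(round(cfg.case_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[:n_cases] = 1
    rng.shuffle(labels)

    planted = list(cfg.planted_edges)
    fc_stack: list[ConnectivityMatrix] = []
    signal = np.zeros(n)
    for s in range(n):
        noise = rng.normal(scale=_EDGE_NOISE_SD, size=(p, p))
        m = base + np.triu(noise, 1) + np.triu(noise, 1).T
        if cfg.group_delta != 0.0 and labels[s] == 1:
            for i, j in planted:
                m[i, j] += cfg.group_delta
                m[j, i] += cfg.group_delta
        m = np.clip(m, -0.99, 0.99)
        c = _project_to_correlation(m)
        fc_stack.append(ConnectivityMatrix(c))
        if planted and cfg.beta != 0.0:
            signal[s] = cfg.beta * sum(c[i, j] for i, j in planted)

    if cfg.target_r2 is None:
        behavior = rng.normal(size=n)
        realized_r2 = 0.0
    else:
        eps = rng.normal(size=n)
        sc = signal - signal.mean()
        var_s = float(sc @ sc) / n
        if var_s <= 0:
            raise ValueError("no signal configured: planted edges carry zero variance")
        # decorrelate noise from signal, then scale for an exact sample R^2
        eps = eps - eps.mean()
        eps = eps - (eps @ sc) / (sc @ sc) * sc
        eps *= np.sqrt(var_s * (1.0 - cfg.target_r2) / cfg.target_r2) / eps.std()
        behavior = signal + eps
        r = np.corrcoef(signal, behavior)[0, 1]
        realized_r2 = float(r * r)

    ages = rng.uniform(*cfg.age_range, size=n)
    sex = (rng.uniform(size=n) < cfg.female_fraction).astype(int)
    site = rng.integers(0, cfg.n_sites, size=n)
    ids = [f"sub-{s:04d}" for s in range(n)]
    phenotypes = pd.DataFrame(
        {"age": ages, "sex": sex, "site": site},
        index=pd.Index(ids, name="subject_id"),
    )

    truth = {
        "config": cfg.to_dict(),
        "planted_edges": [list(e) for e in planted],
        "realized_r2": realized_r2,
        "per_edge_beta": {f"{i}-{j}": cfg.beta for i, j in planted},
    }
    return SyntheticCohort(fc_stack, behavior, phenotypes, labels, truth)


def sample_timeseries(
    target_fc: np.ndarray, n_timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """T x N Gaussian series whose population correlation is ``target_fc``.

    A target that is not positive semi-definite is repaired by eigenvalue
    clipping (and the repair logged); the empirical correlation of the
    output converges to the (repaired) target as T grows.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be at least 2 to generate series")
    cov = np.asarray(target_fc, dtype=float)
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    if vals.min() < -1e-10:
        warnings.warn("target FC not positive semi-definite; repaired by eigenvalue clipping",
                      stacklevel=2)
        cov = _project_to_correlation(cov)
        vals, vecs = np.linalg.eigh(cov)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.normal(size=(n_timepoints, cov.shape[0]))
    return z @ root.T


def generate_timeseries(cfg: SyntheticConfig) -> tuple[SyntheticCohort, list[np.ndarray]]:
    """Cohort plus per-subject T x N series with the FC as population correlation.

    Series are multivariate Gaussian with covariance equal to each subject's
    (PSD-repaired) FC matrix, so the empirical correlation of the output
    converges to the target FC as the number of timepoints grows.
    """
    if cfg.n_timepoints < 2:
        raise ValueError("n_timepoints must be at least 2 to generate series")
    if cfg.n_timepoints < 2 * cfg.n_nodes:
        warnings.warn(
            f"n_timepoints = {cfg.n_timepoints} < 2 * n_nodes = {2 * cfg.n_nodes}; "
            "empirical FC will be a noisy estimate of the target",
            stacklevel=2,
        )
    cohort = generate_fc_population(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7515]))
    series = [sample_timeseries(c.values, cfg.n_timepoints, rng) for c in cohort.fc_stack]
    return cohort, series
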