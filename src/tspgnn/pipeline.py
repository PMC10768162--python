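"""End-to-end orchestration: simulate -> decode -> features -> classify.

Every stage writes its artifact under the run directory and the run ends
with a ``manifest.json`` recording the effective config, per-stage seeds and
a SHA-256 checksum of every file written — rerunning the same config
reproduces identical checksums. Stage seeds are derived deterministically
from the global seed and the stage name, so stages can be re-run in
isolation without perturbing each other.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import (
    ConnectivityMatrix,
    load_connectivity_tsv,
    threshold_graph,
    optimize_density,
)
from .decoding import ElasticNetConfig, cross_validated_decode, permutation_test, aggregate_edges
from .features import TaskPattern, build_features
from .graph_metrics import metric_table
from .population_gcn import GCNConfig, SimilarityConfig, evaluate_cv
from .synthetic import SyntheticConfig, generate_fc_population

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    elastic_net: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    decode_folds: int = 10
    decode_top_k: int = 500
    n_permutations: int = 200
    aggregate_threshold: float = 0.5
    graph_density: float | str = "auto"
    include_fc: bool = True
    include_metrics: bool = True
    gcn: GCNConfig = field(default_factory=GCNConfig)
    classify_folds: int = 5
    rfe_keep: int | None = 200
    sigma: float | str = "auto"
    seed: int = 0
    outdir: str = "tspgnn_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            if "planted_edges" in syn:
                syn["planted_edges"] = tuple(tuple(e) for e in syn["planted_edges"])
            if "age_range" in syn:
                syn["age_range"] = tuple(syn["age_range"])
            d["synthetic"] = SyntheticConfig(**syn)
        if "elastic_net" in d:
            d["elastic_net"] = ElasticNetConfig(**d["elastic_net"])
        if "gcn" in d:
            g = dict(d["gcn"])
            if "hidden" in g:
                g["hidden"] = tuple(g["hidden"])
            d["gcn"] = GCNConfig(**g)
        return cls(**d)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: RunConfig, quiet: bool = False) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    t0 = time.time()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log = logger.debug if quiet else logger.info

    def _stage(name):
        log("[%s] seed=%d t=%.1fs", name, stage_seed(cfg.seed, name), time.time() - t0)

    try:
        # --- simulate -----------------------------------------------------
        _stage("simulate")
        syn = dataclasses.replace(cfg.synthetic, seed=stage_seed(cfg.seed, "simulate"))
        cohort = generate_fc_population(syn)
        cohort.save(out)
        written += sorted((out / "fc").glob("*.tsv")) + [out / "phenotypes.tsv", out / "truth.json"]

        # --- decode -------------------------------------------------------
        _stage("decode")
        x = cohort.edge_matrix()
        y = cohort.behavior
        dec_seed = stage_seed(cfg.seed, "decode")
        result = cross_validated_decode(
            x, y, cfg.elastic_net, n_folds=cfg.decode_folds, seed=dec_seed,
            top_k=cfg.decode_top_k,
        )
        p_val, result = permutation_test(
            x, y, cfg.elastic_net, n_permutations=cfg.n_permutations,
            seed=dec_seed, n_folds=cfg.decode_folds, top_k=cfg.decode_top_k,
            observed=result,
        )
        selected = aggregate_edges(result, cfg.aggregate_threshold)
        from .connectome import edge_index_pairs

        pairs = edge_index_pairs(syn.n_nodes)
        decode_payload = {
            "selected_edges": [list(pairs[e]) for e in selected],
            "edge_frequency": {f"{pairs[e][0]}-{pairs[e][1]}": f
                               for e, f in result.edge_frequency().items()},
            "metrics": result.metrics,
            "permutation_p": p_val,
            "n_permutations": cfg.n_permutations,
            "chosen_lambda": result.chosen_lambda,
            "chosen_alpha": result.chosen_alpha,
            "seed": dec_seed,
            "config": dataclasses.asdict(cfg.elastic_net),
        }
        _json_dump(decode_payload, out / "decode.json")
        written.append(out / "decode.json")

        # --- features -----------------------------------------------------
        _stage("features")
        pattern = TaskPattern("synthetic", tuple(tuple(pairs[e]) for e in selected))
        if not pattern.edges:
            raise RuntimeError("decoded edge set is empty; nothing to classify on")
        tables = None
        if cfg.include_metrics:
            tables = []
            for c in cohort.fc_stack:
                if cfg.graph_density == "auto":
                    _, dens = optimize_density(c)
                else:
                    dens = float(cfg.graph_density)
                g_bin = threshold_graph(c, dens, "binary")
                g_wt = threshold_graph(c, dens, "weighted")
                tables.append(metric_table(g_bin, g_wt))
        feats = build_features(
            cohort.fc_stack, pattern, tables, cohort.subject_ids,
            include_fc=cfg.include_fc, include_metrics=cfg.include_metrics,
        )
        feats.to_csv(out / "features.tsv", sep="\t", float_format="%.10g")
        written.append(out / "features.tsv")

        # --- classify -----------------------------------------------------
        _stage("classify")
        gcn_cfg = dataclasses.replace(cfg.gcn, seed=stage_seed(cfg.seed, "classify"))
        results = evaluate_cv(
            feats, cohort.phenotypes, cohort.labels, gcn_cfg,
            k=cfg.classify_folds, seed=stage_seed(cfg.seed, "classify"),
            rfe_keep=cfg.rfe_keep, sim_cfg=SimilarityConfig(sigma=cfg.sigma),
        )
        _json_dump({**results, "config": dataclasses.asdict(gcn_cfg)}, out / "results.json")
        written.append(out / "results.json")
    except Exception as exc:  # annotate the failing stage, keep partial outputs
        raise RuntimeError(f"pipeline failed after writing {len(written)} artifacts: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("simulate", "decode", "features", "classify")},
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    _json_dump(manifest, out / "manifest.json")
    return manifest


def validate_inputs(fc_dir: str | Path | None = None,
                    phenotypes: str | Path | None = None) -> dict:
    """Structural checks on an input directory; returns a pass/fail report."""
    checks: list[dict] = []

    def add(name: str, ok: bool, detail: str = "") -> None:
        checks.append({"check": name, "status": "pass" if ok else "fail", "detail": detail})

    fc_ids: list[str] = []
    if fc_dir is not None:
        fc_dir = Path(fc_dir)
        files = sorted(fc_dir.glob("*.tsv"))
        add("fc_dir_nonempty", bool(files), f"{len(files)} matrix files")
        for f in files:
            try:
                c = load_connectivity_tsv(f)
                if not np.isfinite(c.values).all():
                    add(f"fc_finite:{f.name}", False, "non-finite entries")
                else:
                    fc_ids.append(f.stem)
            except ValueError as e:
                add(f"fc_valid:{f.name}", False, str(e))
        if len(fc_ids) == len(files) and files:
            add("fc_matrices_valid", True, f"{len(files)} symmetric unit-diagonal matrices")

    ph = None
    if phenotypes is not None:
        try:
            ph = pd.read_csv(phenotypes, sep="\t", index_col=0)
            add("phenotypes_readable", True, f"{len(ph)} subjects")
            add("phenotypes_complete", not ph.isna().any().any(),
                "missing values present" if ph.isna().any().any() else "")
            if "label" in ph.columns:
                ok = set(ph["label"].unique()) <= {0, 1}
                add("labels_binary", ok, "" if ok else f"values {sorted(ph['label'].unique())}")
        except Exception as e:  # unreadable file is a report entry, not a crash
            add("phenotypes_readable", False, str(e))

    if fc_ids and ph is not None:
        missing = sorted(set(fc_ids) - set(ph.index.astype(str)))
        extra = sorted(set(ph.index.astype(str)) - set(fc_ids))
        add("subject_alignment", not missing and not extra,
            f"fc-without-phenotype: {missing[:5]}; phenotype-without-fc: {extra[:5]}")

    passed = all(c["status"] == "pass" for c in checks)
    return {"passed": passed, "checks": checks}
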