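"""End-to-end orchestration: stats → correlation → PCA → score → cluster → RF.

One global seed drives every stochastic stage through a documented
derivation: ``stage_seed = sha256("{global_seed}:{stage_name}") mod 2^31``.
Changing the global seed changes every stage; the per-stage streams are
independent, so e.g. the random-forest stage can be reseeded without
touching the generated panel.

Each run writes a manifest (JSON) recording the tool version, the
configuration hash, the input hash and the artifact paths, so a re-run
with identical config and input provably reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import complete_linkage, cut, distances, profile, to_newick
from .correlation import correlate
from .io import read_trait_csv, write_trait_csv
from .rf import RFConfig, validate_groups
from .score import evaluate
from .simulate import GeneratorConfig, TraitMatrix, build_default_config, generate
from .stats import summarize

__all__ = ["PipelineConfig", "RunManifest", "stage_seed", "run_pipeline"]

STAGES = ("simulate", "stats", "correlate", "pca", "score", "cluster", "rf")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializes to a stable JSON hash."""

    seed: int = 0
    n_accessions: int = 113
    simulate: bool = True
    truncate_to_bounds: bool = False
    with_groups: bool = True
    eigenvalue_threshold: float = 1.0
    k_groups: int = 4
    cut_height: float | None = None
    standardize_distances: bool = True
    alpha: float = 0.05
    posthoc: str = "tukey"
    rf: RFConfig = field(default_factory=RFConfig)
    stages: tuple[str, ...] = STAGES
    out_dir: str = "phenodiv_out"

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        return json.dumps(doc, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one pipeline run: provenance hashes and artifact paths."""

    version: str
    config_hash: str
    input_hash: str
    seed: int
    artifacts: dict[str, str]
    timestamps: dict[str, float]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _hash_matrix(matrix: TraitMatrix) -> str:
    h = hashlib.sha256()
    h.update(",".join(matrix.accession_ids).encode())
    h.update(np.ascontiguousarray(matrix.values).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    matrix: TraitMatrix | None = None,
    input_path: str | Path | None = None,
) -> RunManifest:
    """Execute the requested stages in order, writing one artifact per stage.

    The panel comes from ``matrix``, from ``input_path`` (CSV) or — when
    ``config.simulate`` — from the synthetic generator.  Later stages
    consume earlier outputs (the composite score feeds the group profile;
    the cluster labels feed the random forest), so requesting a late stage
    pulls in its dependencies automatically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stamps: dict[str, float] = {}
    requested = set(config.stages)
    # dependency closure: cluster needs score (group mean D), rf needs cluster+score
    if "rf" in requested:
        requested |= {"cluster", "score"}
    if "cluster" in requested:
        requested |= {"score"}

    if matrix is None:
        if input_path is not None:
            matrix = read_trait_csv(input_path)
        elif config.simulate:
            gen_cfg = build_default_config(
                config.n_accessions,
                with_groups=config.with_groups,
                truncate_to_bounds=config.truncate_to_bounds,
            )
            matrix = generate(gen_cfg, seed=stage_seed(config.seed, "simulate"))
            p = out / "panel.csv"
            write_trait_csv(matrix, p, with_groups=True)
            artifacts["simulate"] = str(p)
            stamps["simulate"] = time.time()
        else:
            raise ValueError("no input: give a matrix, a CSV path, or enable simulate")

    if "stats" in requested:
        summary = summarize(matrix)
        tab = summary.table.round(2)
        tab.loc["Mean", "cv_percent"] = round(summary.mean_cv_percent, 2)
        p = out / "trait_summary.csv"
        tab.to_csv(p)
        artifacts["stats"] = str(p)
        stamps["stats"] = time.time()

    if "correlate" in requested:
        corr = correlate(matrix)
        p = out / "correlations.csv"
        corr.to_long().to_csv(p, index=False)
        artifacts["correlate"] = str(p)
        stamps["correlate"] = time.time()

    ev = None
    if requested & {"pca", "score", "cluster", "rf"}:
        ev = evaluate(matrix, eigenvalue_threshold=config.eigenvalue_threshold)

    if "pca" in requested:
        res = ev.pca_result
        tab = res.loadings.round(3).copy()
        tab.loc["Eigenvalue"] = np.round(res.eigenvalues, 3)
        tab.loc["Contribution rate"] = np.round(res.contribution_percent, 3)
        tab.loc["Cumulative contribution rate"] = np.round(res.cumulative_percent, 3)
        p = out / "pca_loadings.csv"
        tab.to_csv(p)
        pj = out / "pca.json"
        pj.write_text(json.dumps({
            "eigenvalues": [float(x) for x in res.eigenvalues],
            "contribution_percent": [float(x) for x in res.contribution_percent],
            "retained": ev.retained,
            "key_traits": ev.key_traits,
        }, indent=2))
        artifacts["pca"] = str(p)
        artifacts["pca_json"] = str(pj)
        stamps["pca"] = time.time()

    if "score" in requested:
        p = out / "d_values.csv"
        ev.table(matrix).to_csv(p, index=False)
        artifacts["score"] = str(p)
        stamps["score"] = time.time()

    labels = None
    if "cluster" in requested:
        dist = distances(matrix, standardized=config.standardize_distances)
        tree = complete_linkage(dist)
        if config.cut_height is not None:
            labels = cut(tree, height=config.cut_height)
        else:
            labels = cut(tree, k=config.k_groups)
        prof = profile(
            matrix, labels, ev.d_values, alpha=config.alpha, posthoc=config.posthoc
        )
        p = out / "groups.csv"
        pd.DataFrame(
            {"accession": matrix.accession_ids, "group": labels}
        ).to_csv(p, index=False)
        pp = out / "group_profile.csv"
        flat = prof.table.copy()
        flat.columns = ["_".join(c) for c in flat.columns]
        if prof.group_mean_d is not None:
            for g, v in prof.group_mean_d.items():
                flat.loc["D", f"{g}_mean"] = round(v, 2)
        flat.to_csv(pp)
        nwk = out / "dendrogram.nwk"
        nwk.write_text(to_newick(tree, matrix.accession_ids))
        artifacts["cluster"] = str(p)
        artifacts["cluster_profile"] = str(pp)
        artifacts["dendrogram"] = str(nwk)
        stamps["cluster"] = time.time()

    if "rf" in requested:
        rf_cfg = dataclasses.replace(config.rf, seed=stage_seed(config.seed, "rf"))
        report = validate_groups(matrix, labels, rf_cfg, features=tuple(ev.key_traits))
        p = out / "rf_report.json"
        p.write_text(json.dumps(report.to_dict(), indent=2))
        artifacts["rf"] = str(p)
        stamps["rf"] = time.time()

    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash,
        input_hash=_hash_matrix(matrix),
        seed=config.seed,
        artifacts=artifacts,
        timestamps=stamps,
    )
    manifest.write(out / "manifest.json")
    return manifest
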