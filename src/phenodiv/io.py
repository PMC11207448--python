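"""CSV / YAML / JSON input-output for trait panels and configurations.

The canonical panel format is a UTF-8 CSV with header
``accession,province,<28 trait abbreviations in catalog order>``.
Reading is strict: the full trait column set must be present, accession
ids must be unique, and every trait cell must parse as a dot-decimal
number (comma decimals are rejected, not silently mangled).  Extra
columns are allowed with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import CATALOG_BY_ABBREVIATION, DEFAULT_CATALOG, TRAIT_ORDER
from .simulate import GeneratorConfig, GroupSpec, CorrelationTarget, TraitMatrix

__all__ = ["read_trait_csv", "write_trait_csv", "config_to_yaml", "config_from_yaml"]


class SchemaError(ValueError):
    """The CSV does not match the expected panel schema."""


def read_trait_csv(path: str | Path, *, allow_extra: bool = True) -> TraitMatrix:
    """Read an accession × trait panel from CSV with strict schema checks."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("accession", "province"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    missing = [t for t in TRAIT_ORDER if t not in df.columns]
    if missing:
        raise SchemaError(f"missing trait column(s): {missing}")
    extra = [
        c for c in df.columns
        if c not in TRAIT_ORDER and c not in ("accession", "province", "group")
    ]
    if extra:
        if not allow_extra:
            raise SchemaError(f"unexpected column(s): {extra}")
        warnings.warn(f"ignoring unexpected column(s): {extra}", stacklevel=2)

    ids = df["accession"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate accession ids: {dupes}")

    values = np.empty((len(df), len(TRAIT_ORDER)))
    for j, trait in enumerate(TRAIT_ORDER):
        for i, cell in enumerate(df[trait]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise SchemaError(
                    f"row {i + 1}, column {trait!r}: cannot parse {cell!r} "
                    "as a dot-decimal number"
                ) from None
    groups = df["group"].tolist() if "group" in df.columns else None
    return TraitMatrix(
        accession_ids=ids,
        province=df["province"].tolist(),
        values=values,
        trait_catalog=DEFAULT_CATALOG,
        group_labels=groups,
    )


def write_trait_csv(matrix: TraitMatrix, path: str | Path, *, with_groups: bool = False) -> None:
    """Write a panel in the canonical CSV schema (full float precision)."""
    df = matrix.to_frame()
    if with_groups and matrix.group_labels is not None:
        df["group"] = matrix.group_labels
    df.to_csv(path, index=False)


def config_to_yaml(config: GeneratorConfig, path: str | Path) -> None:
    """Serialize a generator configuration to YAML."""
    doc = {
        "n_accessions": config.n_accessions,
        "seed": config.seed,
        "truncate_to_bounds": config.truncate_to_bounds,
        "trait_catalog": [
            {
                "abbreviation": t.abbreviation,
                "full_name": t.full_name,
                "units": t.units,
                "mean": t.mean,
                "sd": t.sd,
                "min_bound": t.min_bound,
                "max_bound": t.max_bound,
                "derived": t.derived,
            }
            for t in config.trait_catalog
        ],
        "correlation_targets": [
            {"trait_a": t.trait_a, "trait_b": t.trait_b, "rho": t.rho}
            for t in config.correlation_targets
        ],
        "group_spec": None
        if config.group_spec is None
        else {
            "labels": list(config.group_spec.labels),
            "sizes": list(config.group_spec.sizes),
            "offsets": config.group_spec.offsets,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


_KNOWN_KEYS = {
    "n_accessions", "seed", "truncate_to_bounds", "trait_catalog",
    "correlation_targets", "group_spec",
}


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    """Load a generator configuration; unknown keys are rejected."""
    doc = yaml.safe_load(Path(path).read_text())
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    from .catalog import TraitDefinition

    catalog = tuple(TraitDefinition(**t) for t in doc["trait_catalog"])
    targets = tuple(CorrelationTarget(**t) for t in doc.get("correlation_targets", []))
    gs = doc.get("group_spec")
    group_spec = None
    if gs is not None:
        group_spec = GroupSpec(
            labels=tuple(gs["labels"]),
            sizes=tuple(int(s) for s in gs["sizes"]),
            offsets={k: dict(v) for k, v in gs["offsets"].items()},
        )
    return GeneratorConfig(
        n_accessions=int(doc["n_accessions"]),
        trait_catalog=catalog,
        correlation_targets=targets,
        group_spec=group_spec,
        truncate_to_bounds=bool(doc.get("truncate_to_bounds", False)),
        seed=int(doc.get("seed", 0)),
    )
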