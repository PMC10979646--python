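"""Serialization glue: dataset CSV/JSON, config files, run manifests.

File formats
------------
Dataset CSV: header ``theory,phenomenon,a_score,r_score[,replication_count]``,
one row per evidence item, ordinal labels case-insensitive.  A single file
may hold several theories.

Dataset JSON, item form::

    {"theory": "A", "items": [{"phenomenon": "...", "a_score": "...",
                               "r_score": "..."}]}

Dataset JSON, matrix form (count table, rejected excluded)::

    {"theory": "A", "matrix": [[1,0,4],[1,7,8],[0,2,3]],
     "rows": ["high","medium","low"],
     "cols": ["accepted","coherent_testable","coherent_untestable"]}

Config files are YAML or JSON with the keys of
:meth:`qbe.quantify.QuantConfig.to_dict`; ``prior`` may be omitted to use
``1 / theory_count``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .core import (
    MATRIX_COLS,
    MATRIX_ROWS,
    EvidenceItem,
    TheoryDataset,
    expand_matrix,
)
from .quantify import PosteriorSet, QuantConfig

__all__ = [
    "read_datasets_csv",
    "write_datasets_csv",
    "read_dataset_json",
    "write_dataset_json",
    "read_posterior_set",
    "write_posterior_set",
    "load_config",
    "RunManifest",
    "build_manifest",
]

CSV_COLUMNS = ["theory", "phenomenon", "a_score", "r_score", "replication_count"]


def read_datasets_csv(path: str | Path) -> list[TheoryDataset]:
    """Read one or more theory datasets from a CSV file."""
    df = pd.read_csv(path, dtype={"theory": str, "phenomenon": str})
    missing = {"theory", "phenomenon", "a_score", "r_score"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing CSV column(s) {sorted(missing)}")
    datasets = []
    for theory, group in df.groupby("theory", sort=False):
        items = []
        for _, row in group.iterrows():
            rc = row.get("replication_count")
            items.append(
                EvidenceItem(
                    phenomenon=str(row["phenomenon"]),
                    a_score=str(row["a_score"]),
                    r_score=str(row["r_score"]),
                    replication_count=None if pd.isna(rc) else int(rc),
                )
            )
        datasets.append(TheoryDataset(name=str(theory), items=items))
    return datasets


def write_datasets_csv(datasets: Iterable[TheoryDataset], path: str | Path) -> None:
    rows = [
        {
            "theory": ds.name,
            "phenomenon": it.phenomenon,
            "a_score": it.a_score,
            "r_score": it.r_score,
            "replication_count": it.replication_count,
        }
        for ds in datasets
        for it in ds.items
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_dataset_json(path: str | Path) -> TheoryDataset:
    """Read a dataset from JSON, in either item form or matrix form."""
    with open(path) as fh:
        d = json.load(fh)
    if "matrix" in d:
        rows = tuple(d.get("rows", MATRIX_ROWS))
        cols = tuple(d.get("cols", MATRIX_COLS))
        return expand_matrix(d["matrix"], d["theory"], rows=rows, cols=cols)
    items = [
        EvidenceItem(
            phenomenon=e["phenomenon"],
            a_score=e["a_score"],
            r_score=e["r_score"],
            replication_count=e.get("replication_count"),
            note=e.get("note"),
        )
        for e in d["items"]
    ]
    return TheoryDataset(name=d["theory"], items=items)


def write_dataset_json(dataset: TheoryDataset, path: str | Path) -> None:
    d = {
        "theory": dataset.name,
        "items": [
            {
                k: v
                for k, v in (
                    ("phenomenon", it.phenomenon),
                    ("a_score", it.a_score),
                    ("r_score", it.r_score),
                    ("replication_count", it.replication_count),
                    ("note", it.note),
                )
                if v is not None
            }
            for it in dataset.items
        ],
    }
    Path(path).write_text(json.dumps(d, indent=2))


def read_posterior_set(path: str | Path) -> PosteriorSet:
    with open(path) as fh:
        return PosteriorSet.from_dict(json.load(fh))


def write_posterior_set(ps: PosteriorSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ps.to_dict(), indent=2))


def load_config(path: str | Path) -> QuantConfig:
    """Load a quantification config from a YAML or JSON file."""
    text = Path(path).read_text()
    d = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(d, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return QuantConfig.from_dict(d)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record: identical manifests imply identical outputs."""

    timestamp: str
    tool_version: str
    config_hash: str
    input_digests: dict[str, str]
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def build_manifest(
    inputs: Sequence[str | Path],
    config: QuantConfig,
    seed: int | None = None,
) -> RunManifest:
    from . import __version__

    return RunManifest(
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        tool_version=__version__,
        config_hash=config.config_hash(),
        input_digests={str(p): _digest(p) for p in inputs},
        seed=seed,
    )
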