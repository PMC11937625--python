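"""Reading and writing delimited-text count tables, metadata and results.

Tab-separated text is the canonical dialect (comma selectable).  A dataset
is stored as two files: a counts table (taxa rows x sample columns, first
column taxon ids) and a metadata table (one row per sample: group label and
covariates).  Simulation truth is a third table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CASE, CONTROL, GROUP_COLUMN, CountDataset, DataError, GroundTruth


def read_count_table(path, orientation: str = "taxa_by_samples", sep: str = "\t") -> pd.DataFrame:
    """Read a counts table with a header row and an id column.

    ``orientation="samples_by_taxa"`` transposes after reading.  Duplicate
    ids, ragged rows, negative or non-integer entries are rejected with a
    message naming the offender.
    """
    path = Path(path)
    raw = [line.rstrip("\n").split(sep) for line in path.read_text().splitlines() if line]
    if not raw:
        raise DataError(f"{path}: empty file")
    widths = {len(row) for row in raw}
    if len(widths) != 1:
        raise DataError(f"{path}: ragged rows (row widths {sorted(widths)})")
    table = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "samples_by_taxa":
        table = table.T
    elif orientation != "taxa_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate taxon ids {dup}")
    if table.columns.has_duplicates:
        dup = table.columns[table.columns.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate sample ids {dup}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataError(f"{path}: non-numeric entries present")
    neg = np.any(values < 0, axis=1)
    if neg.any():
        raise DataError(f"{path}: negative counts in rows {table.index[neg].tolist()}")
    if np.any(values != np.floor(values)):
        bad = table.index[np.any(values != np.floor(values), axis=1)].tolist()
        raise DataError(f"{path}: non-integer counts in rows {bad}")
    table = table.astype(np.int64)
    table.index.name = "taxon_id"
    table.columns = table.columns.rename(None)
    return table


def read_metadata(
    path,
    group_column: str = GROUP_COLUMN,
    case_label: str | None = None,
    covariate_columns=(),
    sep: str = "\t",
) -> pd.DataFrame:
    """Read per-sample metadata; recode the group column to case/control.

    ``case_label`` names the level coded as "case" (mandatory when the file
    does not already use case/control labels — silent level ordering would
    make the sign convention ambiguous).
    """
    meta = pd.read_csv(path, sep=sep, index_col=0)
    if group_column not in meta.columns:
        raise DataError(f"{path}: missing group column {group_column!r}")
    levels = sorted(map(str, meta[group_column].unique()))
    if len(levels) != 2:
        raise DataError(f"{path}: group column must have exactly two levels, got {levels}")
    if case_label is None:
        if set(levels) != {CASE, CONTROL}:
            raise DataError(
                f"{path}: group levels {levels} are not case/control; pass case_label"
            )
    else:
        if str(case_label) not in levels:
            raise DataError(f"{path}: case_label {case_label!r} not among levels {levels}")
        recoded = np.where(meta[group_column].astype(str) == str(case_label), CASE, CONTROL)
        meta = meta.copy()
        meta[group_column] = recoded
    for col in covariate_columns:
        if col not in meta.columns:
            raise DataError(f"{path}: covariate column {col!r} not found")
    keep = [group_column, *covariate_columns]
    meta = meta[keep].rename(columns={group_column: GROUP_COLUMN})
    return meta


def read_dataset(
    counts_path,
    metadata_path,
    group_column: str = GROUP_COLUMN,
    case_label: str | None = None,
    covariate_columns=(),
    orientation: str = "taxa_by_samples",
    sep: str = "\t",
) -> CountDataset:
    counts = read_count_table(counts_path, orientation=orientation, sep=sep)
    meta = read_metadata(
        metadata_path,
        group_column=group_column,
        case_label=case_label,
        covariate_columns=covariate_columns,
        sep=sep,
    )
    missing = counts.columns.difference(meta.index).tolist()
    if missing:
        raise DataError(f"samples in counts but not metadata: {missing}")
    extra = meta.index.difference(counts.columns).tolist()
    if extra:
        raise DataError(f"samples in metadata but not counts: {extra}")
    meta = meta.loc[counts.columns]
    return CountDataset(counts=counts, metadata=meta, provenance=str(counts_path))


def write_dataset(dataset: CountDataset, out_dir, prefix: str = "dataset", sep: str = "\t") -> dict:
    """Write counts and metadata as delimited text; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts_path = out_dir / f"{prefix}_counts.tsv"
    meta_path = out_dir / f"{prefix}_metadata.tsv"
    dataset.counts.to_csv(counts_path, sep=sep, index_label="taxon_id")
    dataset.metadata.to_csv(meta_path, sep=sep, index_label="sample_id")
    return {"counts": counts_path, "metadata": meta_path}


def write_ground_truth(truth: GroundTruth, out_dir, prefix: str = "dataset", sep: str = "\t") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{prefix}_truth.tsv"
    truth.table.to_csv(path, sep=sep, index_label="taxon_id")
    return path


def read_ground_truth(path, sep: str = "\t") -> GroundTruth:
    table = pd.read_csv(path, sep=sep, index_col="taxon_id")
    table["is_differential"] = table["is_differential"].astype(bool)
    return GroundTruth(table=table)


def write_manifest(path, config: dict) -> None:
    """Persist a run manifest (config + seeds + version) as JSON text."""
    from . import __version__

    payload = {"daarep_version": __version__, **config}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


@dataclass
class DatasetManifest:
    """Collection description for the separate-study protocol.

    Loaded from a YAML file with a ``datasets`` list; each entry gives
    ``id``, ``condition``, ``counts``, ``metadata`` and optionally
    ``group_column``, ``case_label``, ``covariates``.
    """

    entries: list[dict]

    @classmethod
    def from_yaml(cls, path) -> "DatasetManifest":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        entries = payload.get("datasets", [])
        ids = [e.get("id") for e in entries]
        if len(ids) != len(set(ids)):
            raise DataError(f"{path}: duplicate dataset ids in manifest")
        for e in entries:
            for key in ("id", "condition", "counts", "metadata"):
                if key not in e:
                    raise DataError(f"{path}: manifest entry missing {key!r}: {e}")
        return cls(entries=entries)

    def load(self, base_dir=None) -> tuple[dict[str, CountDataset], dict[str, str]]:
        base = Path(base_dir) if base_dir else Path(".")
        datasets = {}
        conditions = {}
        for e in self.entries:
            ds = read_dataset(
                base / e["counts"],
                base / e["metadata"],
                group_column=e.get("group_column", GROUP_COLUMN),
                case_label=e.get("case_label"),
                covariate_columns=e.get("covariates", ()),
            )
            ds.provenance = e["id"]
            datasets[e["id"]] = ds
            conditions[e["id"]] = e["condition"]
        return datasets, conditions
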