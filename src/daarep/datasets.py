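"""Core data containers for taxa-by-sample count data.

The central object is :class:`CountDataset`, a taxa-by-sample integer count
matrix with per-sample metadata.  The metadata always carries a ``group``
column with exactly the two levels ``"case"`` and ``"control"``; any further
columns are treated as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_COLUMN = "group"
CASE = "case"
CONTROL = "control"


class DataError(ValueError):
    """Raised when an input table violates the data contract."""


@dataclass
class CountDataset:
    """A taxa-by-sample count matrix plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, taxa as rows (index = taxon ids),
        samples as columns (columns = sample ids).
    metadata
        DataFrame indexed by sample id, containing a ``group`` column with
        values ``"case"``/``"control"`` and optional covariate columns.
    provenance
        Free-text tag describing where the data came from.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        # normalize axis labels so written/re-read datasets compare equal
        # (counts.columns may share an Index object with metadata.index)
        self.counts.index.name = "taxon_id"
        self.metadata.index = self.metadata.index.rename("sample_id")
        self.counts.columns = self.counts.columns.rename(None)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        counts, meta = self.counts, self.metadata
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate taxon ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        if not counts.columns.equals(meta.index):
            missing = counts.columns.difference(meta.index).tolist()
            extra = meta.index.difference(counts.columns).tolist()
            raise DataError(
                "sample ids of counts and metadata disagree "
                f"(missing from metadata: {missing}; extra: {extra})"
            )
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("counts must be numeric")
        if np.any(values < 0):
            bad = counts.columns[np.any(values < 0, axis=0)].tolist()
            raise DataError(f"negative counts in samples: {bad}")
        if np.any(values != np.floor(values)):
            raise DataError("counts must be integers")
        if GROUP_COLUMN not in meta.columns:
            raise DataError(f"metadata lacks a '{GROUP_COLUMN}' column")
        levels = set(meta[GROUP_COLUMN].unique())
        if levels != {CASE, CONTROL}:
            raise DataError(
                f"group must have exactly the levels {{'{CASE}', '{CONTROL}'}}, got {sorted(levels)}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def group(self) -> pd.Series:
        return self.metadata[GROUP_COLUMN]

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.metadata.columns if c != GROUP_COLUMN]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def case_mask(self) -> np.ndarray:
        """Boolean array over samples, True for case samples."""
        return (self.group == CASE).to_numpy()

    def group_sizes(self) -> dict[str, int]:
        vc = self.group.value_counts()
        return {CASE: int(vc.get(CASE, 0)), CONTROL: int(vc.get(CONTROL, 0))}

    def subset_samples(self, sample_ids) -> "CountDataset":
        sample_ids = pd.Index(sample_ids)
        return CountDataset(
            counts=self.counts.loc[:, sample_ids].copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
            provenance=self.provenance,
        )

    def subset_taxa(self, taxon_ids) -> "CountDataset":
        taxon_ids = pd.Index(taxon_ids)
        return CountDataset(
            counts=self.counts.loc[taxon_ids].copy(),
            metadata=self.metadata.copy(),
            provenance=self.provenance,
        )

    def with_group(self, group: pd.Series) -> "CountDataset":
        meta = self.metadata.copy()
        meta[GROUP_COLUMN] = group
        return CountDataset(counts=self.counts.copy(), metadata=meta, provenance=self.provenance)


@dataclass
class GroundTruth:
    """Per-taxon simulation truth.

    ``table`` is indexed by taxon id with columns:

    - ``is_differential`` : bool, whether a group effect was planted
    - ``true_direction``  : {-1, 0, +1}, sign of the planted log fold-change
    - ``true_log_fc``     : the applied log fold-change (0 for null taxa)
    - ``mean_control`` / ``mean_case`` : realized expected relative abundance
      per group, after compositional closure.  Because closure renormalizes
      the whole composition, the realized case/control log-ratio of every
      taxon is offset from ``true_log_fc`` by the common constant
      ``-log(closure_norm)``; ``realized_log_fc`` records the realized value.
    """

    table: pd.DataFrame
    closure_norm: float = 1.0

    def __post_init__(self) -> None:
        t = self.table
        null = ~t["is_differential"]
        if not np.all(t.loc[null, "true_log_fc"] == 0):
            raise DataError("non-differential taxa must have true_log_fc == 0")
        if not np.all(t.loc[null, "true_direction"] == 0):
            raise DataError("non-differential taxa must have true_direction == 0")

    @property
    def n_differential(self) -> int:
        return int(self.table["is_differential"].sum())

    @property
    def differential_taxa(self) -> pd.Index:
        return self.table.index[self.table["is_differential"]]

    @property
    def realized_log_fc(self) -> pd.Series:
        """Realized log fold-change of expected relative abundance."""
        with np.errstate(divide="ignore"):
            return np.log(self.table["mean_case"] / self.table["mean_control"])
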