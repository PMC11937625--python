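"""Prevalence filtering, TSS normalization, log transform, binarization.

These are the standard preprocessing steps applied before any differential
abundance method runs: taxa with prevalence below 10% are removed
(strictly below — a taxon at exactly the threshold is retained), counts are
total-sum scaled to relative abundances, and the log-linear method receives
log-transformed proportions with a configurable pseudocount policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CountDataset, DataError

#: pseudocount policies for :func:`log_transform`
PSEUDO_POLICIES = ("half-min-nonzero", "per-sample-half-min", "fixed")


@dataclass
class PrevalenceFilterReport:
    """Audit record of one prevalence-filter application."""

    threshold: float
    prevalence: pd.Series  # per input taxon: fraction of samples with count > 0
    retained_taxa: pd.Index
    removed_taxa: pd.Index

    @property
    def empty_result(self) -> bool:
        return len(self.retained_taxa) == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prevalence": self.prevalence,
                "retained": self.prevalence.index.isin(self.retained_taxa),
            }
        )


def prevalence(dataset: CountDataset) -> pd.Series:
    """Fraction of samples in which each taxon has a nonzero count."""
    return (dataset.counts > 0).mean(axis=1)


def group_prevalence(dataset: CountDataset) -> pd.DataFrame:
    """Per-taxon prevalence within each group (columns 'case', 'control')."""
    present = dataset.counts > 0
    case = dataset.case_mask()
    return pd.DataFrame(
        {
            "case": present.loc[:, case].mean(axis=1),
            "control": present.loc[:, ~case].mean(axis=1),
        }
    )


def filter_prevalence(
    dataset: CountDataset, threshold: float = 0.10
) -> tuple[CountDataset, PrevalenceFilterReport]:
    """Remove taxa with prevalence strictly below ``threshold``.

    Ties at exactly the threshold are retained.  Applied independently per
    dataset — a split pair is always filtered half by half, never jointly.
    An empty result is allowed and flagged in the report.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    prev = prevalence(dataset)
    keep = prev >= threshold
    report = PrevalenceFilterReport(
        threshold=threshold,
        prevalence=prev,
        retained_taxa=prev.index[keep],
        removed_taxa=prev.index[~keep],
    )
    filtered = CountDataset(
        counts=dataset.counts.loc[keep].copy(),
        metadata=dataset.metadata.copy(),
        provenance=dataset.provenance,
    )
    return filtered, report


def tss_normalize(dataset: CountDataset) -> pd.DataFrame:
    """Total-sum scaling: divide each sample's counts by its library size.

    Returns a taxa-by-sample DataFrame of proportions; each column sums to 1
    over the taxa present in the dataset at normalization time.
    """
    libs = dataset.library_sizes
    zero = libs[libs == 0]
    if len(zero):
        raise DataError(f"zero library size for samples: {zero.index.tolist()}")
    return dataset.counts / libs


def log_transform(
    relab: pd.DataFrame,
    pseudo_policy: str = "half-min-nonzero",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Natural log of proportions plus a pseudocount.

    Policies:

    - ``"half-min-nonzero"`` (default): half the smallest nonzero proportion
      in the whole matrix, one constant for the dataset;
    - ``"per-sample-half-min"``: half the smallest nonzero proportion of each
      sample, one constant per column;
    - ``"fixed"``: the supplied ``pseudocount``.
    """
    values = relab.to_numpy(dtype=float)
    if pseudo_policy == "half-min-nonzero":
        nz = values[values > 0]
        if nz.size == 0:
            raise DataError("matrix has no nonzero proportions")
        pc = nz.min() / 2.0
        out = np.log(values + pc)
    elif pseudo_policy == "per-sample-half-min":
        pc_col = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            col = values[:, j]
            nz = col[col > 0]
            if nz.size == 0:
                raise DataError(f"sample {relab.columns[j]!r} has no nonzero proportions")
            pc_col[j] = nz.min() / 2.0
        out = np.log(values + pc_col[None, :])
    elif pseudo_policy == "fixed":
        if pseudocount is None or pseudocount <= 0:
            raise ValueError("policy 'fixed' requires a positive pseudocount")
        out = np.log(values + pseudocount)
    else:
        raise ValueError(f"unknown pseudo_policy {pseudo_policy!r}; choose from {PSEUDO_POLICIES}")
    return pd.DataFrame(out, index=relab.index, columns=relab.columns)


def binarize(dataset: CountDataset) -> pd.DataFrame:
    """Presence/absence indicator: 1 where count > 0, else 0."""
    return (dataset.counts > 0).astype(np.int8)
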