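"""Split-data and separate-study replication protocols and their metrics.

The protocol: run a DAA method on an *exploratory* dataset, call taxa with
FDR-adjusted P < alpha significant, and re-test the resulting *candidate*
taxa (those also present, after prevalence filtering, in the validation
dataset) in the *validation* dataset at unadjusted P < .05.  A candidate is
*replicated* if significant in validation with the same direction and
*conflicting* if significant with the opposite direction.

Metrics pooled over all pairs (numerators and denominators summed before
dividing, never averaging per-pair ratios):

- Conflict%     — conflicting candidates / all candidates
- Replication%  — replicated candidates / all candidates
- NHits         — total significant taxa over exploratory datasets
- pooled Spearman correlation of effect estimates (Fisher-z pooled)
- CI%           — fraction of eligible candidates whose 83.4% confidence
  intervals in the two datasets overlap

For an ideal method the Conflict% has the approximate upper bound
``alpha * 0.50 * 0.05``: at most a fraction alpha of candidates are false
positives, each of which is validated at level 0.05 and lands on the
opposite side with probability one half.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CASE, CONTROL, CountDataset
from .methods import STATUS_FAILED, STATUS_OK, adjust_fdr_bh, run_method
from .preprocess import filter_prevalence, group_prevalence

logger = logging.getLogger(__name__)

OUTCOME_REPLICATED = "replicated"
OUTCOME_CONFLICTING = "conflicting"
OUTCOME_NOT_VALIDATED = "not_validated"
OUTCOME_ABSENT = "absent_in_validation"

OUTCOME_COLUMNS = [
    "taxon_id",
    "exploratory_direction",
    "exploratory_q",
    "validation_p",
    "validation_direction",
    "outcome",
    "replicated",
    "conflicting",
    "ci_overlap",
]


@dataclass
class SplitPair:
    """One exploratory/validation assignment (already prevalence-filtered)."""

    exploratory: CountDataset
    validation: list[CountDataset]
    replicate_index: int = 0
    origin: str = ""


@dataclass
class MetricsSummary:
    """Pooled metrics for one method at one nominal FDR level."""

    method_name: str
    alpha: float
    n_candidates: int
    conflict_pct: float
    replication_pct: float
    n_hits: int
    pooled_spearman: float
    ci_overlap_pct: float
    ideal_conflict_bound: float
    n_double_counted: int = 0


def ideal_conflict_bound(alpha: float) -> float:
    """Approximate upper limit of Conflict% for an ideal method.

    A fraction at most ``alpha`` of candidates are false positives; an
    ideally-behaved test validates a false positive with probability 0.05,
    on the wrong side with probability 0.50 — hence ``alpha * 0.50 * 0.05``.
    """
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * 0.50 * 0.05


# ---------------------------------------------------------------------------
# pairing protocols


def split_dataset(
    dataset: CountDataset,
    n_repeats: int = 5,
    min_group_size: int = 10,
    seed: int = 0,
    prevalence_threshold: float = 0.10,
) -> list[SplitPair]:
    """Randomly split a dataset into equal-sized halves, ``n_repeats`` times.

    Splits are stratified by group so that each half preserves the group
    sizes (within one sample; any odd extra goes to the exploratory half).
    Each group must contain at least ``2 * min_group_size`` samples.
    Prevalence filtering is applied to each half independently afterwards.
    """
    sizes = dataset.group_sizes()
    for grp in (CASE, CONTROL):
        if sizes[grp] < 2 * min_group_size:
            raise ValueError(
                f"group {grp!r} has {sizes[grp]} samples; needs at least "
                f"{2 * min_group_size} so that both halves hold >= {min_group_size}"
            )
    rng = np.random.default_rng(seed)
    group = dataset.group
    pairs = []
    for r in range(n_repeats):
        explor_ids, valid_ids = [], []
        for grp in (CASE, CONTROL):
            ids = group.index[group == grp].to_numpy()
            rng.shuffle(ids)
            half = (len(ids) + 1) // 2  # odd extra to the exploratory half
            explor_ids.extend(ids[:half])
            valid_ids.extend(ids[half:])
        explor = dataset.subset_samples(pd.Index(explor_ids))
        valid = dataset.subset_samples(pd.Index(valid_ids))
        explor, _ = filter_prevalence(explor, prevalence_threshold)
        valid, _ = filter_prevalence(valid, prevalence_threshold)
        pairs.append(
            SplitPair(
                exploratory=explor,
                validation=[valid],
                replicate_index=r,
                origin=dataset.provenance or "dataset",
            )
        )
    return pairs


def pair_separate_studies(
    datasets: dict[str, CountDataset],
    condition_map: dict[str, str],
    min_group_size: int = 10,
    prevalence_threshold: float = 0.10,
) -> list[SplitPair]:
    """Pair datasets from separate studies that share a condition label.

    Each dataset whose two groups both hold at least ``min_group_size``
    samples serves as the exploratory dataset, with every other eligible
    same-condition dataset as a validation dataset.  Datasets are
    prevalence-filtered independently.
    """
    eligible = {}
    for ds_id, ds in datasets.items():
        sizes = ds.group_sizes()
        if min(sizes.values()) < min_group_size:
            logger.info(
                "dataset %s excluded: smallest group has %d < %d samples",
                ds_id, min(sizes.values()), min_group_size,
            )
            continue
        filtered, _ = filter_prevalence(ds, prevalence_threshold)
        eligible[ds_id] = filtered
    pairs = []
    for ds_id, ds in eligible.items():
        cond = condition_map.get(ds_id)
        others = [
            eligible[o]
            for o in eligible
            if o != ds_id and condition_map.get(o) == cond
        ]
        if others:
            pairs.append(SplitPair(exploratory=ds, validation=others, origin=ds_id))
    if not pairs:
        logger.info("no eligible exploratory/validation pairs found")
    return pairs


# ---------------------------------------------------------------------------
# candidate classification


def identify_candidates(
    exploratory_results: pd.DataFrame,
    validation_dataset: CountDataset,
    alpha: float,
) -> pd.Index:
    """Taxa significant in the exploratory dataset (q < alpha) that are
    present in the (already prevalence-filtered) validation dataset."""
    q = exploratory_results["q"]
    sig = exploratory_results.index[(q < alpha).fillna(False)]
    return sig.intersection(validation_dataset.taxon_ids)


def classify_outcomes(
    candidates,
    exploratory_results: pd.DataFrame,
    validation_results: pd.DataFrame,
    validation_cutoff: float = 0.05,
    validation_adjust: str = "none",
) -> pd.DataFrame:
    """Label each candidate replicated / conflicting / not validated.

    Validation significance uses the unadjusted P-value by default;
    ``validation_adjust="bh"`` instead applies a BH adjustment across the
    candidate taxa within the validation results.
    """
    records = []
    candidates = pd.Index(candidates)
    present = candidates.intersection(validation_results.index)
    vp = validation_results.loc[present, "p"].copy()
    if validation_adjust == "bh" and len(present):
        finite = vp.notna()
        vp.loc[finite] = adjust_fdr_bh(vp[finite].to_numpy())
    elif validation_adjust not in ("none", "bh"):
        raise ValueError(f"validation_adjust must be 'none' or 'bh', got {validation_adjust!r}")
    for taxon in candidates:
        e_dir = int(exploratory_results.at[taxon, "direction"])
        e_q = float(exploratory_results.at[taxon, "q"])
        if taxon not in validation_results.index or (
            validation_results.at[taxon, "status"] == STATUS_FAILED
        ):
            logger.warning("candidate %s missing from validation results", taxon)
            records.append((taxon, e_dir, e_q, np.nan, 0, OUTCOME_ABSENT, False, False, np.nan))
            continue
        v_p = float(vp.at[taxon])
        v_dir = int(validation_results.at[taxon, "direction"])
        sig = v_p < validation_cutoff
        if sig and e_dir != 0 and v_dir == e_dir:
            outcome = OUTCOME_REPLICATED
        elif sig and e_dir != 0 and v_dir == -e_dir:
            outcome = OUTCOME_CONFLICTING
        else:
            outcome = OUTCOME_NOT_VALIDATED
        records.append(
            (
                taxon, e_dir, e_q, v_p, v_dir, outcome,
                outcome == OUTCOME_REPLICATED, outcome == OUTCOME_CONFLICTING, np.nan,
            )
        )
    return pd.DataFrame(records, columns=OUTCOME_COLUMNS)


def aggregate_multi_validation(
    outcome_tables: list[pd.DataFrame], policy: str = "any"
) -> pd.DataFrame:
    """Combine per-validation outcomes of one exploratory dataset.

    ``policy="any"``: a candidate counts as replicated if replicated in at
    least one validation dataset and as conflicting if conflicting in at
    least one; a taxon achieving both keeps both flags (double-count case,
    reported separately by :func:`pool_metrics`).  ``policy="first"`` keeps
    only the first validation dataset's outcome per taxon.
    """
    if not outcome_tables:
        return pd.DataFrame(columns=OUTCOME_COLUMNS)
    merged = pd.concat(outcome_tables, ignore_index=True)
    merged = merged[merged["outcome"] != OUTCOME_ABSENT]
    if policy == "first":
        return merged.drop_duplicates(subset="taxon_id", keep="first").reset_index(drop=True)
    if policy != "any":
        raise ValueError(f"policy must be 'any' or 'first', got {policy!r}")
    rows = []
    for taxon, grp in merged.groupby("taxon_id", sort=False):
        rep = bool(grp["replicated"].any())
        conf = bool(grp["conflicting"].any())
        if conf:
            outcome = OUTCOME_CONFLICTING
        elif rep:
            outcome = OUTCOME_REPLICATED
        else:
            outcome = OUTCOME_NOT_VALIDATED
        first = grp.iloc[0]
        rows.append(
            (
                taxon, first["exploratory_direction"], first["exploratory_q"],
                grp["validation_p"].min(), first["validation_direction"],
                outcome, rep, conf, first["ci_overlap"],
            )
        )
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


# ---------------------------------------------------------------------------
# pooled metrics


def pool_metrics(outcomes_by_pair: list[pd.DataFrame]) -> tuple[float, float, int]:
    """Pool Conflict% and Replication% over pairs.

    Numerators and denominators are summed across all pairs before dividing
    (e.g. pairs with 5/8 and 2/2 replicated give (5+2)/(8+2) = 0.70), never
    the mean of per-pair percentages.  With zero candidates the percentages
    are undefined and returned as NaN.
    """
    n_cand = 0
    n_rep = 0
    n_conf = 0
    for table in outcomes_by_pair:
        if table is None or not len(table):
            continue
        counted = table[table["outcome"] != OUTCOME_ABSENT]
        n_cand += len(counted)
        n_rep += int(counted["replicated"].sum())
        n_conf += int(counted["conflicting"].sum())
    if n_cand == 0:
        return math.nan, math.nan, 0
    return n_conf / n_cand, n_rep / n_cand, n_cand


def count_hits(results_by_exploratory: list[pd.DataFrame], alpha: float) -> int:
    """Total number of significant taxa (q < alpha) over exploratory sets."""
    return int(sum((res["q"] < alpha).fillna(False).sum() for res in results_by_exploratory))


def pool_estimate_correlation(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Fisher-z pooled Spearman correlation of estimates across pairs.

    Per-pair Spearman rho values are atanh-transformed, averaged, and mapped
    back with tanh; |rho| = 1 is clipped just inside the open interval.
    Pairs with fewer than three shared estimates are skipped.
    """
    zs = []
    for est_e, est_v in pairs:
        est_e = np.asarray(est_e, dtype=float)
        est_v = np.asarray(est_v, dtype=float)
        keep = np.isfinite(est_e) & np.isfinite(est_v)
        if keep.sum() < 3:
            logger.info("pair skipped: only %d shared estimates", int(keep.sum()))
            continue
        rho = stats.spearmanr(est_e[keep], est_v[keep]).statistic
        if np.isnan(rho):  # constant ranks
            continue
        rho = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
        zs.append(np.arctanh(rho))
    if not zs:
        return math.nan
    return float(np.tanh(np.mean(zs)))


def ci_overlap_pct(
    outcomes: pd.DataFrame,
    exploratory_results: pd.DataFrame,
    validation_results: pd.DataFrame,
    exploratory_dataset: CountDataset | None = None,
    validation_dataset: CountDataset | None = None,
    min_group_prevalence: float = 0.10,
) -> tuple[float, int]:
    """Fraction of eligible candidates whose CIs in the two datasets overlap.

    Intervals are closed — a shared endpoint counts as overlap.  Eligible
    candidates are those with at least ``min_group_prevalence`` prevalence in
    both experimental groups (checked in both datasets when provided).
    Returns ``(fraction, n_eligible)``; the fraction is NaN when no candidate
    is eligible or the method provides no CIs.
    """
    eligible = pd.Index(outcomes.loc[outcomes["outcome"] != OUTCOME_ABSENT, "taxon_id"])
    for ds in (exploratory_dataset, validation_dataset):
        if ds is None:
            continue
        gp = group_prevalence(ds)
        ok = gp.index[(gp["case"] >= min_group_prevalence) & (gp["control"] >= min_group_prevalence)]
        eligible = eligible.intersection(ok)
    n_overlap = 0
    n_eval = 0
    for taxon in eligible:
        if taxon not in exploratory_results.index or taxon not in validation_results.index:
            continue
        e_lo, e_hi = exploratory_results.at[taxon, "ci_low"], exploratory_results.at[taxon, "ci_high"]
        v_lo, v_hi = validation_results.at[taxon, "ci_low"], validation_results.at[taxon, "ci_high"]
        if any(not np.isfinite(v) for v in (e_lo, e_hi, v_lo, v_hi)):
            continue
        n_eval += 1
        if max(e_lo, v_lo) <= min(e_hi, v_hi):
            n_overlap += 1
    if n_eval == 0:
        return math.nan, 0
    return n_overlap / n_eval, n_eval


def ci_overlap_normal_mc(
    n_pairs: int = 100_000, ci_level: float = 0.834, seed: int = 0
) -> float:
    """Monte-Carlo overlap probability of two independent Wald CIs.

    Draws pairs of estimates from normal sampling distributions with a
    common mean and equal standard errors, forms ``ci_level`` Wald intervals
    and returns the fraction of pairs whose (closed) intervals intersect.
    At the 83.4% level this fraction is approximately 95% — the rationale
    for using 83.4% intervals in the overlap metric.  The closed form is
    ``2 * Phi(sqrt(2) * z) - 1`` with ``z`` the interval half-width in SE
    units.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    a = rng.standard_normal(n_pairs)
    b = rng.standard_normal(n_pairs)
    # equal SE = 1: intervals [x - z, x + z]; overlap iff |a - b| <= 2 z
    return float(np.mean(np.abs(a - b) <= 2.0 * z))


# ---------------------------------------------------------------------------
# calibration


def calibrate_alpha_for_nhits(
    results_by_exploratory: list[pd.DataFrame], target_nhits: int
) -> float:
    """Smallest nominal FDR level at which the pooled hit count reaches the
    target.

    NHits(alpha) = #{q < alpha} steps exactly on the sorted q-value grid, so
    the returned level is the value just above the target-th smallest
    q-value; equality NHits == target is achieved whenever the grid has no
    tie at that point.
    """
    qs = np.sort(
        np.concatenate([res["q"].dropna().to_numpy() for res in results_by_exploratory])
    )
    if target_nhits < 0:
        raise ValueError("target_nhits must be >= 0")
    if target_nhits == 0:
        return float(qs[0] / 2.0) if len(qs) else 0.0
    attainable = int((qs < 1.0).sum())
    if target_nhits > attainable:
        raise ValueError(
            f"target {target_nhits} unattainable: at most {attainable} hits at alpha -> 1"
        )
    return float(np.nextafter(qs[target_nhits - 1], 1.0))


def permutation_calibration(
    method: str,
    dataset: CountDataset,
    n_perms: int,
    seed: int = 0,
    covariate_names=(),
    cutoff: float = 0.05,
    prevalence_threshold: float = 0.10,
) -> float:
    """Pooled fraction of unadjusted P-values < ``cutoff`` over label
    permutations of one dataset — a Monte-Carlo type-I error check.

    Degenerate and failed taxa are excluded from the denominator.
    """
    from .simulate import permute_labels

    if n_perms < 1:
        raise ValueError(f"n_perms must be >= 1, got {n_perms}")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_perms)
    n_small = 0
    n_total = 0
    filtered, _ = filter_prevalence(dataset, prevalence_threshold)
    for s in child_seeds:
        permuted = permute_labels(filtered, int(s % (2**31)))
        res = run_method(method, permuted, covariate_names=covariate_names)
        usable = res.loc[res["status"] == STATUS_OK, "p"].dropna()
        n_small += int((usable < cutoff).sum())
        n_total += len(usable)
    if n_total == 0:
        return math.nan
    return n_small / n_total


# ---------------------------------------------------------------------------
# ranking


def rank_methods(summaries: list[MetricsSummary]) -> pd.DataFrame:
    """Rank methods by the mean of standardized metric values.

    For each nominal FDR level, sqrt(Conflict%) (sign flipped: lower is
    better), Replication% and NHits are standardized to zero mean and unit
    variance across methods; a method's score is the mean of its standardized
    values over all levels and metrics, and methods are returned in
    descending score order (ties keep input order).
    """
    if len({s.method_name for s in summaries}) < 2:
        raise ValueError("ranking requires at least two methods")
    table = pd.DataFrame(
        {
            "method": [s.method_name for s in summaries],
            "alpha": [s.alpha for s in summaries],
            "neg_sqrt_conflict": [-math.sqrt(s.conflict_pct) if not math.isnan(s.conflict_pct) else math.nan for s in summaries],
            "replication": [s.replication_pct for s in summaries],
            "n_hits": [float(s.n_hits) for s in summaries],
        }
    )
    z_cols = []
    for alpha, grp in table.groupby("alpha", sort=True):
        for metric in ("neg_sqrt_conflict", "replication", "n_hits"):
            col = grp[metric]
            if col.isna().any():
                logger.info("metric %s skipped at alpha=%s: missing for some method", metric, alpha)
                continue
            sd = col.std(ddof=0)
            z = (col - col.mean()) / sd if sd > 0 else col * 0.0
            z_cols.append(pd.Series(z.to_numpy(), index=grp["method"], name=f"{metric}@{alpha}"))
    if not z_cols:
        raise ValueError("no complete metric column available for ranking")
    zmat = pd.concat(z_cols, axis=1)
    methods_in_order = list(dict.fromkeys(table["method"]))
    scores = zmat.loc[methods_in_order].mean(axis=1)
    out = pd.DataFrame({"method": methods_in_order, "score": scores.to_numpy()})
    out = out.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# end-to-end protocols


def _estimate_pair(res_e: pd.DataFrame, res_v: pd.DataFrame, candidates_only=None):
    shared = res_e.index[res_e["status"] == STATUS_OK].intersection(
        res_v.index[res_v["status"] == STATUS_OK]
    )
    if candidates_only is not None:
        shared = shared.intersection(pd.Index(candidates_only))
    return (
        res_e.loc[shared, "estimate"].to_numpy(),
        res_v.loc[shared, "estimate"].to_numpy(),
    )


def evaluate_pairs(
    pairs: list[SplitPair],
    methods=("orm", "logtss-lm", "logr"),
    alphas=(0.01, 0.05, 0.10, 0.20),
    ci_level: float = 0.834,
    validation_cutoff: float = 0.05,
    validation_adjust: str = "none",
    covariate_names=(),
    multi_validation_policy: str = "any",
    spearman_candidates_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run methods over exploratory/validation pairs and pool all metrics.

    Returns ``(summary_table, outcome_table)``: one summary row per method
    per alpha, and the per-candidate outcome records with provenance.
    """
    summaries = []
    all_outcomes = []
    for method in methods:
        # fit every dataset once per method
        fits = []
        for pair in pairs:
            res_e = run_method(method, pair.exploratory, covariate_names=covariate_names, ci_level=ci_level)
            res_vs = [
                run_method(method, v, covariate_names=covariate_names, ci_level=ci_level)
                for v in pair.validation
            ]
            fits.append((pair, res_e, res_vs))

        corr_pairs = [
            _estimate_pair(res_e, res_v)
            for pair, res_e, res_vs in fits
            for res_v in res_vs
        ]
        pooled_rho = pool_estimate_correlation(corr_pairs)

        for alpha in alphas:
            per_pair_outcomes = []
            overlap_num = 0
            overlap_den = 0
            exploratory_results = []
            for pair, res_e, res_vs in fits:
                exploratory_results.append(res_e)
                tables = []
                for v_ds, res_v in zip(pair.validation, res_vs):
                    cands = identify_candidates(res_e, v_ds, alpha)
                    table = classify_outcomes(
                        cands, res_e, res_v,
                        validation_cutoff=validation_cutoff,
                        validation_adjust=validation_adjust,
                    )
                    frac, n_eval = ci_overlap_pct(
                        table, res_e, res_v,
                        exploratory_dataset=pair.exploratory,
                        validation_dataset=v_ds,
                    )
                    if n_eval:
                        overlap_num += int(round(frac * n_eval))
                        overlap_den += n_eval
                    tables.append(table)
                if len(tables) > 1:
                    agg = aggregate_multi_validation(tables, policy=multi_validation_policy)
                elif tables:
                    agg = tables[0]
                else:
                    agg = pd.DataFrame(columns=OUTCOME_COLUMNS)
                agg = agg.assign(
                    method=method, alpha=alpha,
                    origin=pair.origin, replicate=pair.replicate_index,
                )
                per_pair_outcomes.append(agg)
            conflict, replication, n_cand = pool_metrics(per_pair_outcomes)
            n_double = int(
                sum((t["replicated"] & t["conflicting"]).sum() for t in per_pair_outcomes if len(t))
            )
            summaries.append(
                MetricsSummary(
                    method_name=method,
                    alpha=alpha,
                    n_candidates=n_cand,
                    conflict_pct=conflict,
                    replication_pct=replication,
                    n_hits=count_hits(exploratory_results, alpha),
                    pooled_spearman=pooled_rho,
                    ci_overlap_pct=overlap_num / overlap_den if overlap_den else math.nan,
                    ideal_conflict_bound=ideal_conflict_bound(alpha),
                    n_double_counted=n_double,
                )
            )
            all_outcomes.extend(per_pair_outcomes)
    summary_table = pd.DataFrame([vars(s) for s in summaries])
    non_empty = [t for t in all_outcomes if len(t)]
    outcome_table = (
        pd.concat(non_empty, ignore_index=True)
        if non_empty
        else pd.DataFrame(columns=OUTCOME_COLUMNS + ["method", "alpha", "origin", "replicate"])
    )
    return summary_table, outcome_table


def evaluate_split(
    dataset: CountDataset,
    methods=("orm", "logtss-lm", "logr"),
    alphas=(0.01, 0.05, 0.10, 0.20),
    n_repeats: int = 5,
    min_group_size: int = 10,
    prevalence_threshold: float = 0.10,
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split-data protocol: random halves of one dataset, then evaluation."""
    pairs = split_dataset(
        dataset,
        n_repeats=n_repeats,
        min_group_size=min_group_size,
        seed=seed,
        prevalence_threshold=prevalence_threshold,
    )
    return evaluate_pairs(pairs, methods=methods, alphas=alphas, **kwargs)


def evaluate_separate_studies(
    datasets: dict[str, CountDataset],
    condition_map: dict[str, str],
    methods=("orm", "logtss-lm", "logr"),
    alphas=(0.01, 0.05, 0.10, 0.20),
    min_group_size: int = 10,
    prevalence_threshold: float = 0.10,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate-study protocol: same-condition datasets validate each other."""
    pairs = pair_separate_studies(
        datasets, condition_map,
        min_group_size=min_group_size,
        prevalence_threshold=prevalence_threshold,
    )
    return evaluate_pairs(pairs, methods=methods, alphas=alphas, **kwargs)
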