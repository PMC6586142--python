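"""Severity association, threshold derivation and stratified subset analyses.

This module ties biomarker scores to external per-sample measurements:

* `associate_biomarkers` — univariate linear fits of each severity covariate
  on each biomarker, plus joint (multivariate) fits for requested biomarker
  combinations, reporting the Pr(>|t|) of every coefficient;
* `derive_repression_threshold` — the data-driven cutoff on a repression
  score defined as its mean over samples with high activation scores;
* `stratified_activity_ratio` — among high-activation samples, the ratio of
  mean disease activity in the high-repression stratum (score strictly below
  the cutoff) to the low-repression stratum;
* `subset_roc_comparison` — restrict all biomarkers to signature-positive or
  -negative samples and re-run the paired AUC comparisons there.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import LinearFit, RocComparison, delong_paired_test, fit_ols, roc_curve
from .matrix import SigscoreError

logger = logging.getLogger("sigscore")

__all__ = [
    "AssociationResult",
    "StratificationResult",
    "SubsetComparison",
    "associate_biomarkers",
    "association_table",
    "derive_repression_threshold",
    "find_activation_threshold",
    "stratified_activity_ratio",
    "subset_roc_comparison",
]


@dataclass(frozen=True)
class AssociationResult:
    """One linear fit of a severity covariate on one or more biomarkers."""

    covariate: str
    biomarkers: tuple
    fit: LinearFit
    n_used: int

    @property
    def is_multivariate(self) -> bool:
        return len(self.biomarkers) > 1


@dataclass(frozen=True)
class StratificationResult:
    """Outcome of splitting high-activation samples by repression score."""

    activation_threshold: float
    repression_threshold: float
    high_repression_samples: tuple
    low_repression_samples: tuple
    mean_activity_high: float
    mean_activity_low: float
    activity_ratio: float
    ratio_defined: bool


@dataclass(frozen=True)
class SubsetComparison:
    """Re-scored ROC comparison on a positivity-defined sample subset."""

    which: str  # "positive" or "negative"
    sample_ids: tuple
    aucs: dict
    comparisons: list


def associate_biomarkers(
    biomarkers: pd.DataFrame,
    severity: pd.DataFrame,
    multivariate_sets=None,
    min_complete: int = 3,
) -> list[AssociationResult]:
    """Fit each severity covariate on each biomarker, and jointly if requested.

    Missing severity values are excluded pairwise (complete cases per fit);
    fits with fewer than ``min_complete`` complete pairs are skipped with a
    warning, never silently.  ``multivariate_sets`` is an iterable of
    biomarker-name tuples to fit jointly against every covariate.
    """
    score_cols = [c for c in biomarkers.columns if c != "group"]
    common = biomarkers.index.intersection(severity.index)
    if len(common) == 0:
        raise SigscoreError("biomarker and severity tables share no sample IDs")
    results: list[AssociationResult] = []

    requested: list[tuple] = [(c,) for c in score_cols]
    for ms in multivariate_sets or []:
        requested.append(tuple(ms))

    for cov in severity.columns:
        sev = severity.loc[common, cov]
        for bios in requested:
            missing = [b for b in bios if b not in biomarkers.columns]
            if missing:
                raise SigscoreError("unknown biomarker columns: " + ", ".join(missing))
            X = biomarkers.loc[common, list(bios)]
            mask = sev.notna() & X.notna().all(axis=1)
            n_used = int(mask.sum())
            if n_used < min_complete:
                logger.warning(
                    "skipping fit of %r on %s: only %d complete cases (< %d)",
                    cov, "+".join(bios), n_used, min_complete,
                )
                continue
            fit = fit_ols(sev[mask].to_numpy(), X.loc[mask])
            results.append(AssociationResult(covariate=cov, biomarkers=tuple(bios),
                                             fit=fit, n_used=n_used))
    return results


def association_table(results) -> pd.DataFrame:
    """Flatten association results into one row per fitted coefficient."""
    rows = []
    for res in results:
        model = "+".join(res.biomarkers)
        for term in res.fit.params.index:
            if term == "intercept":
                continue
            rows.append(
                {
                    "covariate": res.covariate,
                    "model": model,
                    "term": term,
                    "estimate": res.fit.params[term],
                    "std_error": res.fit.bse[term],
                    "t_value": res.fit.tvalues[term],
                    "p_value": res.fit.pvalues[term],
                    "r_squared": res.fit.rsquared,
                    "n": res.n_used,
                }
            )
    return pd.DataFrame(rows)


def derive_repression_threshold(
    biomarkers: pd.DataFrame,
    activation_column: str,
    repression_column: str,
    activation_threshold: float,
) -> float:
    """Mean repression score over samples with activation score strictly above
    the activation cutoff — the data-driven split point for stratification."""
    for col in (activation_column, repression_column):
        if col not in biomarkers.columns:
            raise SigscoreError(f"unknown biomarker column {col!r}")
    high = biomarkers[biomarkers[activation_column] > activation_threshold]
    if len(high) < 2:
        raise SigscoreError(
            f"need >=2 samples with {activation_column!r} > {activation_threshold} "
            f"(got {len(high)})"
        )
    return float(high[repression_column].mean())


def find_activation_threshold(scores: pd.Series, active: pd.Series) -> float:
    """Smallest cutoff above which every sample is disease-active.

    Returns the maximum activation score among inactive samples (ties broken
    toward the smaller threshold); ``-inf`` when every sample is active.
    """
    scores, active = scores.align(active, join="inner")
    inactive = scores[~active.astype(bool)]
    if inactive.empty:
        return float("-inf")
    return float(inactive.max())


def stratified_activity_ratio(
    biomarkers: pd.DataFrame,
    severity: pd.DataFrame,
    activation_column: str,
    repression_column: str,
    activation_threshold: float,
    repression_threshold: float,
    activity_column: str = "activity",
) -> StratificationResult:
    """Mean-activity ratio between repression strata of high-activation samples.

    Restricts to samples with activation score strictly above the cutoff,
    splits them at the repression cutoff (strictly below = high repression;
    equality falls in the low-repression stratum) and returns the ratio of
    stratum mean activities.  A zero low-stratum mean leaves the ratio
    undefined (NaN, flagged).
    """
    if activity_column not in severity.columns:
        raise SigscoreError(f"severity table lacks column {activity_column!r}")
    common = biomarkers.index.intersection(severity.index)
    table = biomarkers.loc[common]
    activity = severity.loc[common, activity_column]

    high_act = table[activation_column] > activation_threshold
    if not high_act.any():
        raise SigscoreError("no samples above the activation threshold")
    sub = table[high_act]
    sub_activity = activity[high_act]
    high_rep = sub[repression_column] < repression_threshold
    ids_high = tuple(sub.index[high_rep])
    ids_low = tuple(sub.index[~high_rep])
    if not ids_high or not ids_low:
        raise SigscoreError(
            "empty repression stratum among high-activation samples "
            f"({len(ids_high)} high, {len(ids_low)} low)"
        )
    mean_high = float(sub_activity[high_rep].mean())
    mean_low = float(sub_activity[~high_rep].mean())
    if mean_low == 0.0:
        logger.warning("low-repression stratum has zero mean activity; ratio undefined")
        ratio, defined = float("nan"), False
    else:
        ratio, defined = mean_high / mean_low, True
    return StratificationResult(
        activation_threshold=activation_threshold,
        repression_threshold=repression_threshold,
        high_repression_samples=ids_high,
        low_repression_samples=ids_low,
        mean_activity_high=mean_high,
        mean_activity_low=mean_low,
        activity_ratio=ratio,
        ratio_defined=defined,
    )


def subset_roc_comparison(
    biomarkers: pd.DataFrame,
    positivity: pd.DataFrame,
    which: str = "negative",
    directions: dict | None = None,
) -> SubsetComparison:
    """Paired AUC comparisons restricted to a positivity-defined subset.

    ``positivity`` is a `call_positivity` output aligned with the biomarker
    table.  ``which`` selects the signature-positive or -negative samples;
    the subset must retain both cases and controls.  All biomarker columns
    are re-scored on the subset (ROC + pairwise DeLong on identical
    samples); a biomarker constant on the subset keeps AUC 0.5 with a
    warning.
    """
    if which not in ("positive", "negative"):
        raise SigscoreError("which must be 'positive' or 'negative'")
    if "group" not in biomarkers.columns:
        raise SigscoreError("biomarker table needs a 'group' column")
    common = biomarkers.index.intersection(positivity.index)
    if len(common) != len(biomarkers.index):
        raise SigscoreError("positivity calls do not cover every scored sample")
    mask = positivity.loc[biomarkers.index, "is_positive"].astype(bool)
    if which == "negative":
        mask = ~mask
    sub = biomarkers[mask.to_numpy()]
    y = (sub["group"] == "case").astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise SigscoreError(
            f"the {which} subset lacks a class "
            f"({int(y.sum())} cases of {len(y)} samples)"
        )
    score_cols = [c for c in sub.columns if c != "group"]
    directions = directions or {}
    curves = {}
    for col in score_cols:
        curves[col] = roc_curve(sub[col].to_numpy(), y,
                                directions.get(col, "auto"))
    comparisons: list[RocComparison] = []
    for a, b in itertools.combinations(score_cols, 2):
        comparisons.append(
            delong_paired_test(
                sub[a].to_numpy(), sub[b].to_numpy(), y,
                direction_a=curves[a].positive_direction,
                direction_b=curves[b].positive_direction,
                name_a=a, name_b=b,
            )
        )
    return SubsetComparison(
        which=which,
        sample_ids=tuple(sub.index),
        aucs={c: curves[c].auc for c in score_cols},
        comparisons=comparisons,
    )
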