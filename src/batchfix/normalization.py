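"""Between-batch intensity normalisation with a per-feature heuristic.

After within-batch drift correction, batches still differ by systematic
intensity offsets.  Two standard remedies exist: divide each batch by the
mean intensity of the long-term reference (Ref) samples for the feature, or
by the median intensity of the batch's biological sample population.  The
reference route is more direct but is only trustworthy when the Ref samples
measure the feature precisely and consistently; otherwise it can inject
severe batch bias.  The choice is made feature-wise by a dual criterion:

* precision — the Ref-sample CV of the feature must be below ``cv_limit``
  (default 0.3, as a fraction) in *every* batch;
* accuracy proxy — for every batch pair (i, j), the feature's Ref intensity
  ratio between the batches must not deviate from the all-feature average
  intensity ratio by more than ``fold_limit`` (default 5) on the log scale:
  ``|log(FeatureIntensityRatio_ij / AverageFeatureIntensityRatio_ij)| <
  log(fold_limit)``.  The absolute value makes the criterion symmetric in
  (i, j) — fold changes are equidistant in log space.

Features passing both criteria are normalised by average Ref intensity per
batch; all others fall back to the population median over biological
samples.  Normalisation is restricted to *common features*, i.e. those that
survived per-batch drift correction in every batch.  Scale factors are
anchored to the first batch so output intensities stay in a familiar range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .peak_table import PeakTable

__all__ = [
    "NormalisationDecision",
    "NormalizationModel",
    "NormalizationResults",
    "common_features",
    "reference_suitability",
    "normalise",
]


def common_features(tables: Sequence[PeakTable]) -> list[str]:
    """Feature ids shared by all batches, in the first table's order."""
    if len(tables) < 2:
        raise ValueError("need at least 2 batches to normalise between")
    sets = [set(t.feature_ids) for t in tables]
    common = set.intersection(*sets)
    if not common:
        survivors = {
            str(t.batches[0] if t.batches else i): len(s)
            for i, (t, s) in enumerate(zip(tables, sets))
        }
        raise ValueError(
            f"no features are common to all batches; per-batch survivors: {survivors}"
        )
    return [f for f in tables[0].feature_ids if f in common]


def reference_suitability(
    ref_values: Sequence[np.ndarray],
    batch_averages: Sequence[float],
    *,
    cv_limit: float = 0.3,
    fold_limit: float = 5.0,
) -> tuple[bool, dict]:
    """Evaluate the dual criterion for reference-based normalisation.

    Parameters
    ----------
    ref_values : sequence of 1-D arrays
        The feature's Ref-sample intensities, one array per batch.
    batch_averages : sequence of float
        Mean Ref intensity over all common features, one value per batch
        (defines the average feature intensity ratio for each batch pair).
    cv_limit : float
        Ref CV limit as a fraction (criterion passes when CV < cv_limit in
        every batch, strictly).
    fold_limit : float
        Allowed fold deviation of the feature's between-batch ratio from the
        all-feature ratio (strict, on the log scale).

    Returns
    -------
    (suitable, diagnostics) where diagnostics holds the per-batch Ref CVs
    and the largest absolute log ratio deviation over batch pairs.
    """
    if fold_limit <= 1:
        raise ValueError("fold_limit must exceed 1")
    means, cvs = [], []
    for vals in ref_values:
        x = np.asarray(vals, dtype=float)
        if x.size < 2:
            raise ValueError("each batch needs at least 2 Ref samples")
        m = x.mean()
        means.append(m)
        cvs.append(x.std(ddof=1) / m if m > 0 else np.inf)
    diagnostics: dict = {"ref_cv_per_batch": tuple(cvs), "max_abs_log_deviation": np.nan}
    if any(m <= 0 or not np.isfinite(m) for m in means):
        return False, diagnostics  # degenerate Ref signal: population fallback
    max_dev = 0.0
    n = len(means)
    for i in range(n):
        for j in range(i + 1, n):
            fir = means[i] / means[j]
            afir = batch_averages[i] / batch_averages[j]
            max_dev = max(max_dev, abs(math.log(fir / afir)))
    diagnostics["max_abs_log_deviation"] = max_dev
    ok = all(c < cv_limit for c in cvs) and max_dev < math.log(fold_limit)
    return ok, diagnostics


@dataclass(frozen=True)
class NormalisationDecision:
    """Per-feature normalisation choice with its diagnostics and factors."""

    feature_id: str
    method: str  # 'reference' | 'population'
    ref_cv_per_batch: tuple[float, ...]
    max_abs_log_deviation: float
    scale_factors: tuple[float, ...]  # per batch, anchored to the first batch


def normalise(
    tables: Sequence[PeakTable], decisions: Sequence[NormalisationDecision]
) -> PeakTable:
    """Apply per-feature scale factors and merge batches into one table.

    Decisions must cover every common feature; output contains the common
    features only (first-table order) and all samples of all batches.
    """
    feats = common_features(tables)
    by_id = {d.feature_id: d for d in decisions}
    missing = [f for f in feats if f not in by_id]
    if missing:
        raise ValueError(f"decisions missing for features: {missing[:5]}")
    restricted = [t.select_features(feats) for t in tables]
    scaled = []
    for b, t in enumerate(restricted):
        factors = np.array([by_id[f].scale_factors[b] for f in feats])
        scaled.append(t.with_intensities(t.intensities * factors))
    return PeakTable.concat(scaled)


class NormalizationModel:
    """Between-batch normalisation over drift-corrected single-batch tables.

    Parameters
    ----------
    tables : sequence of PeakTable
        One table per batch; features need not agree — normalisation is
        restricted to the common feature set.
    cv_limit : float, default 0.3
        Ref CV limit (fraction) of the precision criterion.
    fold_limit : float, default 5.0
        Fold-deviation limit of the accuracy criterion; user-tunable, and
        raising it can only move features towards reference normalisation.
    """

    def __init__(
        self,
        tables: Sequence[PeakTable],
        *,
        cv_limit: float = 0.3,
        fold_limit: float = 5.0,
    ) -> None:
        self.tables = list(tables)
        for t in self.tables:
            if len(t.batches) != 1:
                raise ValueError("each table must hold a single batch")
        self.cv_limit = float(cv_limit)
        self.fold_limit = float(fold_limit)

    def fit(self) -> "NormalizationResults":
        feats = common_features(self.tables)
        n_batches = len(self.tables)

        ref_mat = np.zeros((n_batches, len(feats)))  # mean Ref intensity
        ref_cv = np.zeros((n_batches, len(feats)))
        pop_med = np.zeros((n_batches, len(feats)))  # biological-sample median
        ref_values: list[np.ndarray] = []
        for b, t in enumerate(self.tables):
            sub = t.select_features(feats)
            rmask = sub.sample_type_mask("Ref")
            if rmask.sum() < 2:
                raise ValueError(
                    f"batch {t.batches[0]!r} has fewer than 2 Ref samples"
                )
            refs = sub.intensities[rmask]
            ref_values.append(refs)
            with np.errstate(invalid="ignore", divide="ignore"):
                m = np.nanmean(refs, axis=0)
                sd = np.nanstd(refs, axis=0, ddof=1)
                ref_mat[b] = m
                ref_cv[b] = np.where(m > 0, sd / m, np.inf)
            bio = sub.intensities[sub.sample_type_mask("sample")]
            if bio.shape[0] == 0:
                raise ValueError(
                    f"batch {t.batches[0]!r} has no biological samples for "
                    "population normalisation"
                )
            pop_med[b] = np.nanmedian(bio, axis=0)
        batch_averages = np.nanmean(ref_mat, axis=1)

        log_fold = math.log(self.fold_limit)
        decisions: list[NormalisationDecision] = []
        for fi, fid in enumerate(feats):
            means = ref_mat[:, fi]
            valid = np.all(np.isfinite(means)) and np.all(means > 0)
            max_dev = np.nan
            if valid:
                with np.errstate(divide="ignore"):
                    lr = np.log(means) - np.log(batch_averages)
                max_dev = float(np.max(np.abs(lr[:, None] - lr[None, :])))
                suitable = bool(
                    np.all(ref_cv[:, fi] < self.cv_limit) and max_dev < log_fold
                )
            else:
                suitable = False
            if suitable:
                anchors = means
                method = "reference"
            else:
                anchors = pop_med[:, fi]
                method = "population"
            if np.any(~np.isfinite(anchors)) or np.any(anchors <= 0):
                raise ValueError(
                    f"feature {fid!r}: zero or undefined anchoring statistic "
                    f"for {method} normalisation"
                )
            factors = anchors[0] / anchors  # anchored to the first batch
            decisions.append(
                NormalisationDecision(
                    feature_id=fid,
                    method=method,
                    ref_cv_per_batch=tuple(float(c) for c in ref_cv[:, fi]),
                    max_abs_log_deviation=max_dev,
                    scale_factors=tuple(float(f) for f in factors),
                )
            )
        normalized = normalise(self.tables, decisions)
        return NormalizationResults(
            model=self,
            common=feats,
            decisions=decisions,
            normalized=normalized,
        )


@dataclass
class NormalizationResults:
    """Fitted normalisation: decisions, factors and the merged table."""

    model: NormalizationModel
    common: list[str]
    decisions: list[NormalisationDecision]
    normalized: PeakTable

    @property
    def n_reference(self) -> int:
        return sum(d.method == "reference" for d in self.decisions)

    def decision_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.decisions:
            row = {
                "feature_id": d.feature_id,
                "method": d.method,
                "max_ref_cv": max(d.ref_cv_per_batch),
                "max_abs_log_deviation": d.max_abs_log_deviation,
            }
            for b, (c, f) in enumerate(zip(d.ref_cv_per_batch, d.scale_factors)):
                row[f"ref_cv_b{b + 1}"] = c
                row[f"factor_b{b + 1}"] = f
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n = len(self.decisions)
        n_ref = self.n_reference
        lines = [
            "Between-batch normalisation",
            "=" * 47,
            f"Batches:              {len(self.model.tables)}",
            f"Common features:      {n}",
            f"Ref CV limit:         {self.model.cv_limit:g} (fraction)",
            f"Fold limit:           {self.model.fold_limit:g}",
            f"Reference-normalised: {n_ref} ({100 * n_ref / n:.1f} %)",
            f"Population-normalised:{n - n_ref:>5} ({100 * (n - n_ref) / n:.1f} %)",
        ]
        return "\n".join(lines)
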