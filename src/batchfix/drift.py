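"""Cluster-based within-batch signal-intensity drift correction.

LC-MS signal intensity drifts systematically with injection order within an
analytical batch, and different groups of features can follow distinctly
different drift patterns.  This module corrects one batch at a time:

1. *Scaling* — every feature is divided by its standard deviation over the
   QC injections, without centring, reflecting the predominantly
   multiplicative error structure of instrumental chemical analysis.
   Zero-variance features cannot be scaled; they are excluded from
   clustering and pass through uncorrected.
2. *Clustering in observation space* — features (not samples) are the
   observations, with the QC injections as coordinates, so features sharing
   a drift pattern sit close together.  A Gaussian-mixture model is fitted
   for each candidate cluster number in a grid (default 1, 4, ..., 52) and
   the number of clusters is chosen by BIC, removing operator bias.
3. *Drift function* — per cluster, a cubic smoothing spline is fitted to the
   pooled (injection order, scaled intensity) points of all member features
   over the QC injections; smoothing is chosen by generalised
   cross-validation unless a penalty is given.  The spline is evaluated at
   every injection order so non-QC injections are corrected by
   interpolation.
4. *Correction factors* — the cluster correction factor at injection ``n``
   is ``drift(first injection) / drift(n)``; the first injection is the
   reference level, so its factor is exactly 1.  Non-positive drift values
   mark a pathological fit and demote the cluster to ``no_action``.
5. *Fitness gate* — correction is applied only if it tightens the long-term
   reference (Ref) samples, which are of independent biological origin and
   held out of drift modelling: the root-mean-squared distance of the Ref
   samples from their centre point, over the cluster's scaled member
   features, must *strictly* decrease.  A cluster can improve QC precision
   yet fail this unbiased gate and remain uncorrected.
6. *CV filter* — after correction, features whose QC coefficient of
   variation strictly exceeds a limit (default 30 %) are removed batch-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline
from sklearn.mixture import GaussianMixture

from .peak_table import PeakTable

__all__ = [
    "DriftCluster",
    "FitnessReport",
    "DriftCorrectionModel",
    "DriftCorrectionResults",
    "scale_features",
    "cluster_drift_patterns",
    "fit_drift_function",
    "correction_factors",
    "fitness_gate",
    "ref_rmsd",
    "cv",
    "cv_filter",
    "DEFAULT_CLUSTER_GRID",
]

#: Default cluster-number grid: 1 to 52 in steps of three.
DEFAULT_CLUSTER_GRID: tuple[int, ...] = tuple(range(1, 53, 3))


def cv(values, *, ddof: int = 1) -> float:
    """Coefficient of variation in percent: 100 * sd / mean.

    Uses the sample standard deviation (ddof=1) by default, appropriate for
    the small QC/Ref series it is applied to.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("cv needs at least 2 values")
    m = x.mean()
    if m == 0:
        raise ValueError("cv undefined for zero mean")
    return float(100.0 * x.std(ddof=ddof) / m)


def _cv_columns(matrix: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Column-wise CV (%) without the scalar guard rails; NaN when mean is 0."""
    m = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * sd / m
    out[m == 0] = np.nan
    return out


def scale_features(
    table: PeakTable, basis_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Divide each feature by its standard deviation over the basis samples.

    No centring is applied.  Returns ``(scaled, scales, excluded)`` where
    ``excluded`` lists zero-variance feature ids; their columns are left
    unscaled (scale 1) and must be kept out of clustering and correction.
    """
    if not table.is_full:
        raise ValueError(
            "drift correction requires a full peak table (no missing values); "
            f"found {table.n_missing} missing cells"
        )
    if basis_mask is None:
        basis_mask = table.sample_type_mask("QC")
    basis_mask = np.asarray(basis_mask, dtype=bool)
    if basis_mask.sum() < 2:
        raise ValueError("scaling basis needs at least 2 samples")
    scales = table.intensities[basis_mask].std(axis=0, ddof=1)
    excluded = [f.id for f, s in zip(table.features, scales) if s == 0 or not np.isfinite(s)]
    safe = np.where((scales == 0) | ~np.isfinite(scales), 1.0, scales)
    return table.intensities / safe, safe, excluded


def cluster_drift_patterns(
    scaled_qc: np.ndarray,
    cluster_grid: Sequence[int] = DEFAULT_CLUSTER_GRID,
    seed: int = 0,
    *,
    covariance_type: str = "full",
    reg_covar: float = 1e-4,
    max_iter: int = 200,
) -> tuple[np.ndarray, int, pd.DataFrame]:
    """Cluster features by drift pattern in QC-observation space.

    Parameters
    ----------
    scaled_qc : ndarray, shape (n_qc, n_features)
        SD-scaled intensities of the QC injections (injection order along
        rows).  Features are the observations being clustered, so the matrix
        is transposed internally.
    cluster_grid : sequence of int
        Candidate numbers of clusters; values exceeding the feature count
        are skipped.
    seed : int
        Makes mixture initialisation deterministic.

    Returns
    -------
    labels : ndarray of int, shape (n_features,)
    k : int
        BIC-selected number of clusters.
    bic_table : DataFrame with columns ``n_clusters`` and ``bic``.
    """
    x = np.asarray(scaled_qc, dtype=float).T  # features as observations
    n_features = x.shape[0]
    if scaled_qc.shape[0] < 2:
        raise ValueError("clustering needs at least 2 QC injections")
    if n_features == 0:
        raise ValueError("no features to cluster")
    if np.allclose(x, x[:1]):
        # all features identical: a single cluster, no mixture fit needed
        return np.zeros(n_features, dtype=int), 1, pd.DataFrame(
            {"n_clusters": [1], "bic": [np.nan]}
        )
    grid = sorted({int(k) for k in cluster_grid if 1 <= int(k) <= n_features})
    if not grid:
        raise ValueError("cluster grid is empty after bounding by feature count")
    records = []
    best: tuple[float, int, GaussianMixture] | None = None
    for k in grid:
        gm = GaussianMixture(
            n_components=k,
            covariance_type=covariance_type,
            reg_covar=reg_covar,
            max_iter=max_iter,
            n_init=1,
            init_params="k-means++",
            random_state=seed,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(x)
            bic = gm.bic(x)  # lower is better
        except (ValueError, np.linalg.LinAlgError):
            records.append({"n_clusters": k, "bic": np.nan})
            continue
        records.append({"n_clusters": k, "bic": bic})
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    if best is None:
        raise RuntimeError("no mixture model could be fitted on the cluster grid")
    _, k, gm = best
    return gm.predict(x).astype(int), k, pd.DataFrame(records)


def fit_drift_function(
    scaled_members: np.ndarray,
    qc_injections: Sequence[int],
    eval_injections: Sequence[int],
    lam: float | None = None,
) -> np.ndarray:
    """Fit a cubic-spline drift function to pooled cluster data vs injection.

    All (injection order, scaled intensity) pairs of all member features are
    pooled; repeated abscissae are collapsed to their mean with the point
    count as weight, which leaves the penalised least-squares fit unchanged.
    With ``lam=None`` the smoothing penalty is chosen by generalised
    cross-validation.  Evaluation points outside the QC injection range are
    clamped to the range boundary rather than extrapolated.

    Parameters
    ----------
    scaled_members : ndarray, shape (n_qc, n_members)
        Scaled intensities of the cluster's member features at the QC
        injections (rows ordered like ``qc_injections``).
    qc_injections : sequence of int
        Injection orders of the QC rows; at least 4 distinct values.
    eval_injections : sequence of int
        Injection orders at which the drift function is evaluated.
    """
    y = np.atleast_2d(np.asarray(scaled_members, dtype=float))
    inj = np.asarray(qc_injections, dtype=float)
    if y.shape[0] != inj.size:
        raise ValueError("scaled_members rows must match qc_injections")
    order = np.argsort(inj)
    inj, y = inj[order], y[order]
    ux, inv = np.unique(inj, return_inverse=True)
    if ux.size < 4:
        raise ValueError(
            f"cubic drift fitting needs >= 4 distinct QC injections, got {ux.size}"
        )
    counts = np.bincount(inv) * y.shape[1]
    ybar = np.zeros(ux.size)
    for i in range(ux.size):
        ybar[i] = y[inv == i].mean()
    if ux.size >= 5:
        spline = make_smoothing_spline(ux, ybar, w=counts.astype(float), lam=lam)
    else:
        spline = CubicSpline(ux, ybar)  # too few anchors for GCV smoothing
    xe = np.clip(np.asarray(eval_injections, dtype=float), ux[0], ux[-1])
    return np.asarray(spline(xe), dtype=float)


def correction_factors(drift_values: np.ndarray, reference_index: int = 0) -> np.ndarray:
    """Per-injection correction factors: drift(reference) / drift(n).

    The reference point is the batch's first injection, whose factor is
    exactly 1.  Non-positive drift values signal a pathological fit and
    raise ValueError (callers demote the cluster to ``no_action``).
    """
    d = np.asarray(drift_values, dtype=float)
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("drift function non-positive at some injection")
    return d[reference_index] / d


def ref_rmsd(scaled_refs: np.ndarray) -> float:
    """Root-mean-squared distance of Ref samples from their centre point.

    ``scaled_refs`` has Ref samples as rows and the cluster's scaled member
    features as columns; the centre is the arithmetic mean over Ref samples.
    """
    x = np.atleast_2d(np.asarray(scaled_refs, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("ref_rmsd needs at least 2 reference samples")
    centre = x.mean(axis=0)
    sq = ((x - centre) ** 2).sum(axis=1)
    return float(np.sqrt(sq.mean()))


def fitness_gate(
    scaled_refs: np.ndarray, ref_factors: np.ndarray, cluster_id: int = 0
) -> tuple["FitnessReport", bool]:
    """Decide whether a correction may be applied, from Ref samples alone.

    ``scaled_refs`` holds the Ref samples over the cluster's scaled member
    features; ``ref_factors`` the correction factor at each Ref sample's
    injection.  Correction is allowed only when the Ref RMSD *strictly*
    decreases — factors that leave the Refs unchanged (e.g. all exactly 1)
    do not justify touching the data.
    """
    before = ref_rmsd(scaled_refs)
    after = ref_rmsd(scaled_refs * np.asarray(ref_factors, dtype=float)[:, None])
    report = FitnessReport(cluster_id, before, after)
    return report, report.improved


def cv_filter(
    table: PeakTable, limit: float = 30.0, *, qc_mask: np.ndarray | None = None
) -> tuple[PeakTable, list[str]]:
    """Remove features whose QC CV strictly exceeds ``limit`` percent.

    A CV exactly at the limit is kept.  Returns the filtered table and the
    removed feature ids.
    """
    if qc_mask is None:
        qc_mask = table.sample_type_mask("QC")
    qc = table.intensities[np.asarray(qc_mask, dtype=bool)]
    if qc.shape[0] < 2:
        raise ValueError("CV filter needs at least 2 QC samples")
    cvs = _cv_columns(qc)
    removed = [f.id for f, c in zip(table.features, cvs) if np.isfinite(c) and c > limit]
    return table.drop_features(removed), removed


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class DriftCluster:
    """One drift cluster: members, drift function, factors and decision."""

    cluster_id: int
    member_ids: tuple[str, ...]
    drift_values: np.ndarray  # per unique injection order, batch-wide
    correction_factors: np.ndarray | None  # None when action == 'no_action'
    action: str  # 'corrected' | 'no_action'
    qc_cv_before: np.ndarray  # per member feature, %
    qc_cv_during: np.ndarray  # per member, after correction regardless of gate
    qc_cv_after: np.ndarray  # per member, after the gate decision
    note: str = ""


@dataclass(frozen=True)
class FitnessReport:
    """Ref-sample RMSD with and without correction, in scaled space."""

    cluster_id: int
    rmsd_before: float
    rmsd_after: float

    def __post_init__(self) -> None:
        if self.rmsd_before < 0 or self.rmsd_after < 0:
            raise ValueError("rmsd values must be non-negative")

    @property
    def improved(self) -> bool:
        return self.rmsd_after < self.rmsd_before


class DriftCorrectionModel:
    """Within-batch drift-correction model for one full single-batch table.

    Parameters
    ----------
    table : PeakTable
        Single batch, no missing values, with >= 2 QC and (for the fitness
        gate) >= 2 Ref injections.
    cv_limit : float, default 30.0
        QC CV (%) above which (strictly) features are removed post-correction.
        20 % is the common bioanalytical validation limit but discards far
        more features; 30 % suits exploratory untargeted work.
    cluster_grid : sequence of int, default 1:52:3
        Candidate cluster numbers for BIC selection.
    lam : float or None
        Spline smoothing penalty; None selects it by GCV.
    seed : int
        Deterministic mixture initialisation.
    """

    def __init__(
        self,
        table: PeakTable,
        *,
        cv_limit: float = 30.0,
        cluster_grid: Sequence[int] = DEFAULT_CLUSTER_GRID,
        lam: float | None = None,
        seed: int = 1234,
        covariance_type: str = "full",
    ) -> None:
        if len(table.batches) != 1:
            raise ValueError(
                f"drift correction works batch-wise; table spans {table.batches}"
            )
        if not table.is_full:
            raise ValueError(
                "drift correction requires a full peak table (no missing values)"
            )
        if table.sample_type_mask("QC").sum() < 2:
            raise ValueError("drift correction needs at least 2 QC injections")
        self.table = table
        self.cv_limit = float(cv_limit)
        self.cluster_grid = tuple(cluster_grid)
        self.lam = lam
        self.seed = int(seed)
        self.covariance_type = covariance_type

    def fit(self) -> "DriftCorrectionResults":
        t = self.table
        qc_mask = t.sample_type_mask("QC")
        ref_mask = t.sample_type_mask("Ref")
        inj = t.injection_orders()
        uniq_inj = np.unique(inj)
        first_idx = 0  # uniq_inj is sorted: reference point = first injection
        inj_pos = np.searchsorted(uniq_inj, inj)  # sample -> drift index

        scaled, scales, excluded = scale_features(t, qc_mask)
        fids = list(t.feature_ids)
        usable = [i for i, f in enumerate(fids) if f not in set(excluded)]
        if not usable:
            raise ValueError("all features have zero QC variance; nothing to model")

        qc_order = np.argsort(inj[qc_mask])
        qc_rows = np.flatnonzero(qc_mask)[qc_order]
        qc_inj = inj[qc_rows]

        labels_usable, k, bic_table = cluster_drift_patterns(
            scaled[np.ix_(qc_rows, usable)],
            self.cluster_grid,
            self.seed,
            covariance_type=self.covariance_type,
        )
        labels = np.full(len(fids), -1, dtype=int)
        labels[usable] = labels_usable

        n_ref = int(ref_mask.sum())
        if n_ref < 2:
            warnings.warn(
                "fewer than 2 Ref samples: fitness gate cannot be evaluated; "
                "no cluster will be corrected",
                stacklevel=2,
            )
        ref_rows = np.flatnonzero(ref_mask)

        corrected = t.intensities.copy()
        clusters: list[DriftCluster] = []
        fitness: list[FitnessReport] = []
        qc_cv_before_all = _cv_columns(t.intensities[qc_mask])

        for c in range(k):
            members = [i for i in usable if labels[i] == c]
            if not members:
                continue
            member_ids = tuple(fids[i] for i in members)
            drift_vals = fit_drift_function(
                scaled[np.ix_(qc_rows, members)], qc_inj, uniq_inj, lam=self.lam
            )
            note = ""
            factors: np.ndarray | None
            try:
                factors = correction_factors(drift_vals, first_idx)
            except ValueError as exc:
                factors, note = None, str(exc)

            cv_before = qc_cv_before_all[members]
            if factors is not None:
                fac_per_sample = factors[inj_pos]
                corrected_block = t.intensities[:, members] * fac_per_sample[:, None]
                cv_during = _cv_columns(corrected_block[qc_mask])
                if n_ref >= 2:
                    report, apply_it = fitness_gate(
                        scaled[np.ix_(ref_rows, members)],
                        factors[inj_pos[ref_rows]],
                        cluster_id=c,
                    )
                    fitness.append(report)
                    if not apply_it:
                        note = "ref RMSD not strictly decreased"
                else:
                    apply_it = False
                    note = "fewer than 2 Ref samples"
            else:
                cv_during = np.full(len(members), np.nan)
                apply_it = False

            if apply_it:
                corrected[:, members] = corrected_block
                action = "corrected"
                cv_after = cv_during
            else:
                action = "no_action"
                cv_after = cv_before
            clusters.append(
                DriftCluster(
                    cluster_id=c,
                    member_ids=member_ids,
                    drift_values=drift_vals,
                    correction_factors=factors if action == "corrected" else None,
                    action=action,
                    qc_cv_before=cv_before,
                    qc_cv_during=cv_during,
                    qc_cv_after=cv_after,
                    note=note,
                )
            )

        corrected_table = t.with_intensities(corrected)
        filtered_table, removed = cv_filter(corrected_table, self.cv_limit, qc_mask=qc_mask)
        return DriftCorrectionResults(
            model=self,
            clusters=clusters,
            fitness=fitness,
            labels={fids[i]: int(labels[i]) for i in usable},
            n_clusters=k,
            bic_table=bic_table,
            excluded_features=tuple(excluded),
            corrected=corrected_table,
            filtered=filtered_table,
            removed_features=tuple(removed),
            scales=scales,
            injection_orders=uniq_inj,
        )


@dataclass
class DriftCorrectionResults:
    """Fitted drift correction for one batch."""

    model: DriftCorrectionModel
    clusters: list[DriftCluster]
    fitness: list[FitnessReport]
    labels: dict[str, int]
    n_clusters: int
    bic_table: pd.DataFrame
    excluded_features: tuple[str, ...]
    corrected: PeakTable  # all features, gated corrections applied
    filtered: PeakTable  # after the QC CV filter
    removed_features: tuple[str, ...]
    scales: np.ndarray = field(repr=False, default=None)
    injection_orders: np.ndarray = field(repr=False, default=None)

    def qc_cv(self, which: str = "after") -> pd.Series:
        """Per-feature QC CV (%) before or after the gated correction."""
        t = {"before": self.model.table, "after": self.corrected}[which]
        qc = t.intensities[t.sample_type_mask("QC")]
        return pd.Series(_cv_columns(qc), index=list(t.feature_ids), name=f"qc_cv_{which}")

    def cluster_report(self) -> pd.DataFrame:
        """Per-cluster report: action, feature counts and mean QC CVs.

        ``qc_cv_correction`` is the mean member CV after correction whether
        or not the gate let the correction through; ``qc_cv_after`` reflects
        the actual decision and is computed over the features surviving the
        CV filter (NaN when none survive).
        """
        removed = set(self.removed_features)
        rows = []
        for c in self.clusters:
            survivors = [i for i, f in enumerate(c.member_ids) if f not in removed]
            rows.append(
                {
                    "cluster": c.cluster_id,
                    "action": c.action,
                    "n_features_before": len(c.member_ids),
                    "n_features_after": len(survivors),
                    "qc_cv_before": float(np.nanmean(c.qc_cv_before)),
                    "qc_cv_correction": float(np.nanmean(c.qc_cv_during))
                    if np.any(np.isfinite(c.qc_cv_during))
                    else np.nan,
                    "qc_cv_after": float(np.nanmean(c.qc_cv_after[survivors]))
                    if survivors
                    else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def fitness_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster": f.cluster_id,
                    "rmsd_before": f.rmsd_before,
                    "rmsd_after": f.rmsd_after,
                    "improved": f.improved,
                }
                for f in self.fitness
            ]
        )

    def summary(self) -> str:
        t = self.model.table
        n_corr = sum(c.action == "corrected" for c in self.clusters)
        before = self.qc_cv("before")
        after = self.qc_cv("after")
        lines = [
            f"Within-batch drift correction - batch {t.batches[0]}",
            "=" * 47,
            f"Samples:                 {t.n_samples} "
            f"({int(t.sample_type_mask('QC').sum())} QC, "
            f"{int(t.sample_type_mask('Ref').sum())} Ref)",
            f"Features:                {t.n_features} "
            f"({len(self.excluded_features)} zero-variance excluded)",
            f"Clusters (BIC-selected): {self.n_clusters}",
            f"Clusters corrected:      {n_corr} / {len(self.clusters)}",
            f"Median QC CV before:     {np.nanmedian(before):.1f} %",
            f"Median QC CV after:      {np.nanmedian(after):.1f} %",
            f"CV filter (> {self.model.cv_limit:g} %):    "
            f"{len(self.removed_features)} features removed, "
            f"{self.filtered.n_features} kept",
        ]
        return "\n".join(lines)
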