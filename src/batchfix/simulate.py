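"""Synthetic multi-batch LC-MS peak tables with known ground truth.

The generator emulates the study design the correction method targets:
several analytical batches, each a sequence of injections where pooled QC
samples and long-term reference (Ref) samples are interleaved at regular
intervals among the biological samples (a QC or a Ref roughly every 7th
injection, i.e. each type about every 14th, plus anchors at the start and
end of the batch).  Intensities follow a multiplicative error model:

    intensity = base * batch_offset * drift(injection) * (1 + eps),
    eps ~ Normal(0, noise_cv)

QC samples share the batch pool mean (the feature base intensity);
Ref samples share a batch-independent pool of different biological origin
(a fixed per-feature shift from the base); biological samples add
per-sample multiplicative biological variation.  Features are assigned to a
small library of distinct drift patterns (exponential decay, linear,
sinusoidal, step), mirroring the distinctly diverse within-batch drift
behaviours seen in real data.  Batch-systematic feature splitting is
planted by registering the same underlying compound under two ids with
small m/z and rt offsets in disjoint batch subsets; optional "ambiguous
quadruples" plant two co-eluting split compounds within one m/z-rt box so
that the recursive deconvolution, not mere proximity, is required to pair
them correctly.  All randomness comes from a single seeded generator, so a
fixed seed reproduces tables exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .peak_table import FeatureKey, PeakTable, SampleRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "score_against_truth",
    "drift_pattern_curve",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Counts are per batch.  ``noise_cv`` and ``biological_cv`` are percent;
    ``drift_amplitude`` is the relative peak-to-trough size of the drift
    patterns; ``batch_offset_range`` is the largest fold offset between
    batches; split offsets must stay within the alignment tolerances for
    the planted splits to be recoverable.
    """

    n_batches: int = 3
    n_features: int = 300
    n_bio_samples: int = 84
    n_qc: int = 16
    n_ref: int = 14
    qc_interval: int = 14
    n_drift_patterns: int = 4
    drift_amplitude: float = 0.30
    noise_cv: float = 10.0
    biological_cv: float = 25.0
    batch_offset_range: float = 2.0
    n_split_features: int = 20
    split_mz_offset: float = 0.001
    split_rt_offset: float = 5.0
    n_ambiguous_quads: int = 0
    missing_rate: float = 0.0
    ref_drift: str = "shared"  # 'shared' | 'none' | 'opposite'
    mz_range: tuple[float, float] = (100.0, 1000.0)
    rt_range: tuple[float, float] = (30.0, 930.0)
    seed: int = 1

    def validate(self) -> None:
        n_inj = self.n_bio_samples + self.n_qc + self.n_ref
        if min(self.n_batches, self.n_features, self.n_bio_samples) < 1:
            raise ValueError("batch, feature and sample counts must be positive")
        if self.n_qc < 2 or self.n_ref < 2:
            raise ValueError("need at least 2 QC and 2 Ref injections per batch")
        if self.qc_interval < 1 or self.qc_interval > n_inj:
            raise ValueError(
                f"qc_interval {self.qc_interval} exceeds batch length {n_inj}"
            )
        if self.n_drift_patterns < 1 or self.n_drift_patterns > 8:
            raise ValueError("n_drift_patterns must be between 1 and 8")
        if not 0 <= self.drift_amplitude < 1:
            raise ValueError("drift_amplitude must be in [0, 1)")
        if self.ref_drift not in {"shared", "none", "opposite"}:
            raise ValueError(f"unknown ref_drift mode {self.ref_drift!r}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_split_features + 2 * self.n_ambiguous_quads > self.n_features:
            raise ValueError("more planted split compounds than features")
        if self.n_batches < 2 and (self.n_split_features or self.n_ambiguous_quads):
            raise ValueError("split features need at least 2 batches")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring pipeline output against."""

    alias_groups: tuple[frozenset[str], ...]
    alias_parent: dict[str, str]  # alias id -> underlying compound id
    drift_pattern: dict[str, int]  # compound id -> pattern index
    batch_offsets: dict[str, float]
    drift_curves: dict[int, np.ndarray]  # pattern -> value per injection
    noise_cv: float
    config: SimulationConfig = field(repr=False, default=None)

    def pattern_of(self, feature_id: str) -> int:
        """Drift pattern of a feature id, alias or merged ('a+b') alike."""
        first = feature_id.split("+")[0]
        parent = self.alias_parent.get(first, first)
        return self.drift_pattern[parent]


def drift_pattern_curve(pattern: int, n_injections: int, amplitude: float) -> np.ndarray:
    """Multiplicative drift curve for one pattern, evaluated at 1..n.

    Library: exponential decay, linear increase, sinusoidal, downward step,
    then phase/sign variants; all curves start near 1 at the first injection
    and stay within ``1 +/- amplitude``.
    """
    t = np.linspace(0.0, 1.0, n_injections)
    a = amplitude
    forms = [
        1.0 - a * (1.0 - np.exp(-3.0 * t)),          # exponential decay
        1.0 + a * t,                                  # linear increase
        1.0 + a * np.sin(1.5 * math.pi * t),          # sinusoidal
        np.where(t < 0.5, 1.0, 1.0 - a),              # downward step
        1.0 - a * t,                                  # linear decrease
        1.0 + a * (1.0 - np.exp(-3.0 * t)),           # saturating increase
        1.0 - a * np.sin(1.5 * math.pi * t),          # inverted sinusoidal
        np.where(t < 0.5, 1.0, 1.0 + a),              # upward step
    ]
    return np.asarray(forms[pattern % len(forms)], dtype=float)


def _injection_layout(config: SimulationConfig) -> list[str]:
    """Sample type per injection position (1-based order = list index + 1).

    QC and Ref anchors are spread evenly and offset from one another, with a
    QC first and both types near the end of the sequence, approximating the
    'beginning, end and every 14th injection' design.
    """
    n = config.n_bio_samples + config.n_qc + config.n_ref
    types = ["sample"] * n
    qc_pos = np.unique(np.round(np.linspace(0, n - 2, config.n_qc)).astype(int))
    ref_pos = np.unique(np.round(np.linspace(1, n - 1, config.n_ref)).astype(int))

    def place(positions: np.ndarray, label: str) -> None:
        for p in positions:
            q = int(p)
            while types[q] != "sample":  # collision: shift to next free slot
                q = (q + 1) % n
            types[q] = label

    place(qc_pos, "QC")
    place(ref_pos, "Ref")
    return types


def simulate(config: SimulationConfig) -> tuple[list[PeakTable], GroundTruth]:
    """Generate per-batch peak tables and the matching ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_feat = config.n_features
    n_inj = config.n_bio_samples + config.n_qc + config.n_ref
    batches = [f"B{b + 1}" for b in range(config.n_batches)]

    # feature coordinates: generous m/z spacing so only planted splits fall
    # within alignment tolerances of one another
    lo, hi = config.mz_range
    grid = np.linspace(lo, hi, n_feat)
    jitter = rng.uniform(-0.2, 0.2, n_feat) * min(1.0, (hi - lo) / max(n_feat, 1))
    mz = np.sort(grid + jitter)
    rt = rng.uniform(*config.rt_range, n_feat)
    compound_ids = [f"F{i + 1:04d}" for i in range(n_feat)]

    base = 10.0 ** rng.uniform(4.0, 7.0, n_feat)
    patterns = rng.integers(0, config.n_drift_patterns, n_feat)
    curves = {
        p: drift_pattern_curve(p, n_inj, config.drift_amplitude)
        for p in range(config.n_drift_patterns)
    }
    offsets = np.ones(config.n_batches)
    if config.n_batches > 1 and config.batch_offset_range > 1:
        span = math.log(config.batch_offset_range)
        offsets[1:] = np.exp(rng.uniform(-span, span, config.n_batches - 1))
    ref_shift = np.exp(rng.normal(0.0, 0.3, n_feat))  # independent Ref pool
    layout = _injection_layout(config)

    # choose split compounds and ambiguous quadruple partners
    order = rng.permutation(n_feat)
    quad_primary = list(order[: config.n_ambiguous_quads])
    split_single = list(
        order[config.n_ambiguous_quads : config.n_ambiguous_quads + config.n_split_features]
    )

    # batch subsets for each split: contiguous cut keeps both sides non-empty
    def random_cut() -> int:
        return int(rng.integers(1, config.n_batches))

    alias_groups: list[frozenset[str]] = []
    alias_parent: dict[str, str] = {}
    # feature columns per batch: list of (column id, mz, rt, compound index)
    per_batch_cols: list[list[tuple[str, float, float, int]]] = [
        [] for _ in batches
    ]
    split_side: dict[tuple[int, str], int] = {}  # (compound idx, batch) -> side

    plain = sorted(set(range(n_feat)) - set(split_single) - set(quad_primary))
    quad_partner: dict[int, int] = {}
    for fi in quad_primary:
        quad_partner[fi] = plain.pop()
    partner_set = set(quad_partner.values())

    def plant_split(
        fi: int, mz0: float, rt0: float, cut: int, dmz: float, drt: float
    ) -> None:
        cid = compound_ids[fi]
        a, b = f"{cid}a", f"{cid}b"
        alias_groups.append(frozenset({a, b}))
        alias_parent[a] = alias_parent[b] = cid
        for bi in range(config.n_batches):
            if bi < cut:
                per_batch_cols[bi].append((a, mz0, rt0, fi))
                split_side[(fi, batches[bi])] = 0
            else:
                per_batch_cols[bi].append((b, mz0 + dmz, rt0 + drt, fi))
                split_side[(fi, batches[bi])] = 1

    split_single_set, quad_primary_set = set(split_single), set(quad_primary)
    for fi in range(n_feat):
        if fi in split_single_set:
            plant_split(
                fi, mz[fi], rt[fi], random_cut(),
                config.split_mz_offset, config.split_rt_offset,
            )
        elif fi in partner_set:  # planted alongside its quad primary below
            continue
        elif fi in quad_primary_set:
            cut = random_cut()
            # two co-eluting compounds inside one m/z-rt box: intra-compound
            # offsets small, cross-compound offsets larger but in-tolerance
            plant_split(fi, mz[fi], rt[fi], cut, 0.0002, 1.0)
            pj = quad_partner[fi]
            plant_split(pj, mz[fi] + 0.0012, rt[fi] + 8.0, cut, 0.0002, 1.0)
        else:
            for bi in range(config.n_batches):
                per_batch_cols[bi].append((compound_ids[fi], mz[fi], rt[fi], fi))

    tables: list[PeakTable] = []
    for bi, bname in enumerate(batches):
        cols = per_batch_cols[bi]
        features = [FeatureKey(cid, m, r) for cid, m, r, _ in cols]
        comp_idx = np.array([c[-1] for c in cols])
        samples = []
        bio_counter = qc_counter = ref_counter = 0
        for pos, stype in enumerate(layout, start=1):
            if stype == "QC":
                qc_counter += 1
                sid = f"{bname}_QC{qc_counter:02d}"
            elif stype == "Ref":
                ref_counter += 1
                sid = f"{bname}_REF{ref_counter:02d}"
            else:
                bio_counter += 1
                sid = f"{bname}_S{bio_counter:03d}"
            samples.append(SampleRecord(sid, bname, pos, stype))

        bio_sigma = math.log1p(config.biological_cv / 100.0)
        type_arr = np.array([s.sample_type for s in samples])
        bio_rows = type_arr == "sample"
        ref_rows = type_arr == "Ref"
        drift = np.stack([curves[p] for p in sorted(curves)])[
            patterns[comp_idx]
        ].T  # (n_inj, n_cols)
        level = (base[comp_idx] * offsets[bi])[None, :] * drift
        if config.ref_drift == "none":
            level[ref_rows] /= drift[ref_rows]
        elif config.ref_drift == "opposite":
            level[ref_rows] /= drift[ref_rows] ** 2
        level[ref_rows] *= ref_shift[comp_idx][None, :]
        level[bio_rows] *= np.exp(
            rng.normal(0.0, bio_sigma, (int(bio_rows.sum()), len(cols)))
        )
        eps = rng.normal(0.0, config.noise_cv / 100.0, level.shape)
        x = np.maximum(level * (1.0 + eps), 1.0)

        if config.missing_rate > 0:
            bio_rows = np.array([s.sample_type == "sample" for s in samples])
            miss = rng.random(x.shape) < config.missing_rate
            miss[~bio_rows] = False  # keep QC/Ref anchors intact by default
            x[miss] = np.nan
        tables.append(PeakTable(features, samples, x))

    truth = GroundTruth(
        alias_groups=tuple(alias_groups),
        alias_parent=alias_parent,
        drift_pattern={compound_ids[i]: int(patterns[i]) for i in range(n_feat)},
        batch_offsets={b: float(o) for b, o in zip(batches, offsets)},
        drift_curves=curves,
        noise_cv=config.noise_cv,
        config=config,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Scoring pipeline output against the planted truth


def _pair_set(groups) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    for g in groups:
        members = sorted(g)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pairs.add(frozenset({a, b}))
    return pairs


def score_against_truth(
    truth: GroundTruth,
    *,
    merged_groups=None,
    cluster_labels: dict[str, int] | None = None,
    qc_cv_before=None,
    qc_cv_after=None,
    tables_before: Sequence[PeakTable] | None = None,
    tables_after: PeakTable | Sequence[PeakTable] | None = None,
) -> dict:
    """Score result artifacts against the generator's ground truth.

    Any subset of artifacts may be supplied; only the corresponding metrics
    are computed.  Metrics:

    * ``merge_precision`` / ``merge_recall`` — pair-level agreement of the
      alignment groups with the planted alias groups;
    * ``clustering_ari`` — adjusted Rand index of drift-cluster labels
      against the planted drift-pattern assignment;
    * ``median_cv_before`` / ``median_cv_after`` — medians of supplied QC
      CV vectors (%);
    * ``between_batch_variance_ratio`` — ratio (after/before) of the median
      per-feature variance of batch mean log-intensities over biological
      samples; 1 - ratio is the fraction of batch effect removed.
    """
    out: dict[str, float] = {}
    if merged_groups is not None:
        pred = _pair_set(merged_groups)
        true = _pair_set(truth.alias_groups)
        tp = len(pred & true)
        out["merge_precision"] = tp / len(pred) if pred else float("nan")
        out["merge_recall"] = tp / len(true) if true else float("nan")
    if cluster_labels is not None:
        from sklearn.metrics import adjusted_rand_score

        fids = sorted(cluster_labels)
        try:
            true_labels = [truth.pattern_of(f) for f in fids]
        except KeyError as exc:
            raise ValueError(f"feature id not in ground truth: {exc}") from exc
        out["clustering_ari"] = float(
            adjusted_rand_score(true_labels, [cluster_labels[f] for f in fids])
        )
    if qc_cv_before is not None:
        out["median_cv_before"] = float(np.nanmedian(np.asarray(qc_cv_before, float)))
    if qc_cv_after is not None:
        out["median_cv_after"] = float(np.nanmedian(np.asarray(qc_cv_after, float)))
    if tables_before is not None and tables_after is not None:
        out["between_batch_variance_ratio"] = _batch_variance_ratio(
            tables_before, tables_after
        )
    return out


def _batch_means(tables: Sequence[PeakTable]) -> "np.ndarray | None":
    common = set.intersection(*[set(t.feature_ids) for t in tables])
    feats = sorted(common)
    rows = []
    for t in tables:
        sub = t.select_features(feats)
        bio = sub.intensities[sub.sample_type_mask("sample")]
        with np.errstate(invalid="ignore"):
            rows.append(np.nanmean(np.log(np.maximum(bio, 1e-12)), axis=0))
    return np.array(rows)


def _batch_variance_ratio(before, after) -> float:
    if isinstance(after, PeakTable):
        after = list(after.split_batches().values())
    mb = _batch_means(list(before))
    ma = _batch_means(list(after))
    var_b = np.median(mb.var(axis=0, ddof=1))
    var_a = np.median(ma.var(axis=0, ddof=1))
    return float(var_a / var_b) if var_b > 0 else float("nan")


def config_with(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Convenience wrapper over dataclasses.replace."""
    return replace(config, **kwargs)
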