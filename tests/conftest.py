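"""Shared fixtures and table-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from batchfix.alignment import PresenceMatrix
from batchfix.peak_table import FeatureKey, PeakTable, SampleRecord


def make_table(batch, feature_specs, sample_specs, intensities):
    """Build a PeakTable from compact specs.

    feature_specs: list of (id, mz, rt); sample_specs: list of
    (sample_id, injection_order, sample_type); intensities: 2-D list/array.
    """
    features = [FeatureKey(i, mz, rt) for i, mz, rt in feature_specs]
    samples = [SampleRecord(s, batch, o, t) for s, o, t in sample_specs]
    return PeakTable(features, samples, np.asarray(intensities, dtype=float))


def make_presence(vectors, coords=None, threshold=0.8, basis="Ref"):
    """PresenceMatrix from {feature_id: 0/1 vector}; coords optional (mz, rt)."""
    fids = list(vectors)
    n_batches = len(next(iter(vectors.values())))
    coords = coords or {}
    features = tuple(
        FeatureKey(f, *(coords.get(f, (100.0 + i, 50.0 + i)))) for i, f in enumerate(fids)
    )
    present = np.array([vectors[f] for f in fids], dtype=bool)
    prop = np.where(present, 0.0, 1.0)
    return PresenceMatrix(
        features=features,
        batches=tuple(f"B{i + 1}" for i in range(n_batches)),
        present=present,
        proportion_na=prop,
        threshold=threshold,
        basis=basis,
    )


def random_table(rng, batch="B1", n_features=5, n_samples=6, missing_rate=0.1):
    """Random valid PeakTable with QC/Ref anchors and optional missingness."""
    feats = [
        (f"F{i}", float(100 + 10 * i + rng.uniform(0, 1)), float(rng.uniform(10, 900)))
        for i in range(n_features)
    ]
    types = ["QC", "QC", "Ref", "Ref"] + ["sample"] * (n_samples - 4)
    samples = [(f"{batch}_s{j}", j + 1, types[j % len(types)]) for j in range(n_samples)]
    x = rng.lognormal(10, 1, (n_samples, n_features))
    x[rng.random(x.shape) < missing_rate] = np.nan
    return make_table(batch, feats, samples, x)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sim():
    """Small 3-batch simulation with splits, cached per session."""
    from batchfix.simulate import SimulationConfig, simulate

    cfg = SimulationConfig(
        n_features=120, seed=101, n_split_features=6, n_ambiguous_quads=2
    )
    return simulate(cfg)
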