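"""Peak-table data model and plain-text I/O.

An untargeted LC-MS *feature* is a mass-spectral peak — a molecular entity
(metabolite ion, isotope, adduct, fragment or noise) characterised by a
mass-to-charge ratio (m/z, in Da) and a retention time (rt).  A
:class:`PeakTable` holds one or more analytical batches of such features: an
``(n_samples, n_features)`` intensity matrix with missing measurements stored
as NaN, plus a :class:`FeatureKey` per column and a :class:`SampleRecord` per
row.

Samples carry a batch id, a 1-based batch-local injection order, and a type:

``sample``
    biological study sample;
``QC``
    batch-specific pooled quality-control sample, injected at regular
    intervals and used to model within-batch intensity drift;
``Ref``
    long-term reference sample of independent biological origin, shared
    across batches and *held out* of drift modelling so it can serve as an
    unbiased fitness measure.

On disk a table is three plain CSV/TSV files: a wide intensity matrix
(samples as rows), a sample metadata table, and an optional feature sidecar
(id, mz, rt).  Without a sidecar, column headers of the form ``M<mz>T<rt>``
are parsed for the feature coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureKey",
    "SampleRecord",
    "PeakTable",
    "read_peak_table",
    "write_peak_table",
    "SAMPLE_TYPES",
]

SAMPLE_TYPES = ("sample", "QC", "Ref")

_HEADER_RE = re.compile(r"^M(?P<mz>\d+(?:\.\d+)?)T(?P<rt>\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class FeatureKey:
    """Identity of a molecular feature: stable id plus m/z and rt coordinates."""

    id: str
    mz: float
    rt: float

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("feature id must be a non-empty string")
        if not np.isfinite(self.mz) or self.mz <= 0:
            raise ValueError(f"feature {self.id!r}: mz must be positive, got {self.mz}")
        if not np.isfinite(self.rt) or self.rt < 0:
            raise ValueError(f"feature {self.id!r}: rt must be >= 0, got {self.rt}")


@dataclass(frozen=True)
class SampleRecord:
    """One injection: sample id, batch, 1-based batch-local order and type."""

    sample_id: str
    batch: str
    injection_order: int
    sample_type: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be a non-empty string")
        if int(self.injection_order) != self.injection_order or self.injection_order < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: injection_order must be a positive "
                f"integer, got {self.injection_order}"
            )
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown sample_type "
                f"{self.sample_type!r}; expected one of {SAMPLE_TYPES}"
            )


class PeakTable:
    """Intensity matrix plus feature keys and sample metadata.

    Parameters
    ----------
    features : sequence of FeatureKey
        Column identities, ordered.
    samples : sequence of SampleRecord
        Row identities, ordered.
    intensities : array-like, shape (n_samples, n_features)
        Non-negative intensities; missing values as NaN.
    """

    def __init__(
        self,
        features: Sequence[FeatureKey],
        samples: Sequence[SampleRecord],
        intensities,
    ) -> None:
        self.features: tuple[FeatureKey, ...] = tuple(features)
        self.samples: tuple[SampleRecord, ...] = tuple(samples)
        x = np.asarray(intensities, dtype=float)
        if x.ndim != 2 or x.shape != (len(self.samples), len(self.features)):
            raise ValueError(
                f"intensity matrix shape {x.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        with np.errstate(invalid="ignore"):
            if np.any(x[~np.isnan(x)] < 0):
                raise ValueError("intensities must be non-negative (or NaN)")
        self.intensities: np.ndarray = x.copy()
        self._validate_ids()

    def _validate_ids(self) -> None:
        fids = [f.id for f in self.features]
        if len(set(fids)) != len(fids):
            dup = sorted({i for i in fids if fids.count(i) > 1})
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            dup = sorted({i for i in sids if sids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        seen: dict[tuple[str, int], str] = {}
        for s in self.samples:
            key = (s.batch, s.injection_order)
            if key in seen:
                raise ValueError(
                    f"injection order {s.injection_order} duplicated within batch "
                    f"{s.batch!r} (samples {seen[key]!r} and {s.sample_id!r})"
                )
            seen[key] = s.sample_id

    # -- basic views ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.features)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)

    @property
    def batches(self) -> tuple[str, ...]:
        """Batch ids in order of first appearance."""
        out: list[str] = []
        for s in self.samples:
            if s.batch not in out:
                out.append(s.batch)
        return tuple(out)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.intensities).sum())

    @property
    def is_full(self) -> bool:
        """True if the matrix contains no missing values."""
        return self.n_missing == 0

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in table") from None

    def sample_type_mask(self, sample_type: str) -> np.ndarray:
        if sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {sample_type!r}")
        return np.array([s.sample_type == sample_type for s in self.samples])

    def injection_orders(self) -> np.ndarray:
        return np.array([s.injection_order for s in self.samples], dtype=int)

    # -- subsetting ----------------------------------------------------------

    def select_features(self, feature_ids: Iterable[str]) -> "PeakTable":
        ids = list(feature_ids)
        idx = [self.feature_index(i) for i in ids]
        return PeakTable(
            [self.features[i] for i in idx], self.samples, self.intensities[:, idx]
        )

    def drop_features(self, feature_ids: Iterable[str]) -> "PeakTable":
        drop = set(feature_ids)
        keep = [i for i, f in enumerate(self.features) if f.id not in drop]
        return PeakTable(
            [self.features[i] for i in keep], self.samples, self.intensities[:, keep]
        )

    def select_samples(self, mask: np.ndarray) -> "PeakTable":
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        return PeakTable(
            self.features, [self.samples[i] for i in idx], self.intensities[idx]
        )

    def split_batches(self) -> dict[str, "PeakTable"]:
        """One single-batch PeakTable per batch, in batch order."""
        out = {}
        for b in self.batches:
            mask = np.array([s.batch == b for s in self.samples])
            out[b] = self.select_samples(mask)
        return out

    def with_intensities(self, intensities) -> "PeakTable":
        return PeakTable(self.features, self.samples, intensities)

    @staticmethod
    def concat(tables: Sequence["PeakTable"]) -> "PeakTable":
        """Stack tables sample-wise; all tables must share the feature list."""
        if not tables:
            raise ValueError("no tables to concatenate")
        ref = tables[0].feature_ids
        for t in tables[1:]:
            if t.feature_ids != ref:
                raise ValueError("tables do not share an identical feature list")
        samples = [s for t in tables for s in t.samples]
        x = np.vstack([t.intensities for t in tables])
        return PeakTable(tables[0].features, samples, x)

    # -- dataframe views -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(self.feature_ids),
        )

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "batch": [s.batch for s in self.samples],
                "injection_order": [s.injection_order for s in self.samples],
                "sample_type": [s.sample_type for s in self.samples],
            }
        )

    def feature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [f.id for f in self.features],
                "mz": [f.mz for f in self.features],
                "rt": [f.rt for f in self.features],
            }
        )

    def equals(self, other: "PeakTable", atol: float = 0.0, rtol: float = 0.0) -> bool:
        if self.feature_ids != other.feature_ids or self.sample_ids != other.sample_ids:
            return False
        return np.allclose(
            self.intensities, other.intensities, atol=atol, rtol=rtol, equal_nan=True
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PeakTable(n_samples={self.n_samples}, n_features={self.n_features}, "
            f"batches={list(self.batches)}, missing={self.n_missing})"
        )


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parse_feature_header(name: str) -> FeatureKey:
    m = _HEADER_RE.match(str(name))
    if m is None:
        raise ValueError(
            f"cannot parse m/z and rt from column header {name!r}; use M<mz>T<rt> "
            "headers or provide a feature sidecar table"
        )
    return FeatureKey(id=str(name), mz=float(m.group("mz")), rt=float(m.group("rt")))


def read_peak_table(
    path,
    metadata_path,
    features_path=None,
    *,
    zero_as_missing: bool = True,
) -> PeakTable:
    """Read a wide peak table (samples as rows) plus sample metadata.

    Parameters
    ----------
    path : path-like
        CSV/TSV intensity matrix; first column is the sample id, remaining
        columns are features.
    metadata_path : path-like
        CSV/TSV with columns ``sample_id``, ``batch``, ``injection_order``,
        ``sample_type``; must cover exactly the samples in the matrix.
    features_path : path-like, optional
        Sidecar CSV/TSV with columns ``feature_id``, ``mz``, ``rt``.  When
        absent, feature coordinates are parsed from ``M<mz>T<rt>`` headers.
    zero_as_missing : bool, default True
        Treat exact zeros as missing values (common in exports where absent
        peaks are written as 0).  Empty cells are always missing.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    data = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    data.index = data.index.astype(str)
    x = data.to_numpy(dtype=float)
    if zero_as_missing:
        x = np.where(x == 0.0, np.nan, x)

    if features_path is not None:
        features_path = Path(features_path)
        fdf = pd.read_csv(features_path, sep=_sep_for(features_path))
        required = {"feature_id", "mz", "rt"}
        if not required.issubset(fdf.columns):
            raise ValueError(
                f"feature sidecar must have columns {sorted(required)}, "
                f"got {list(fdf.columns)}"
            )
        keys = {
            str(r.feature_id): FeatureKey(str(r.feature_id), float(r.mz), float(r.rt))
            for r in fdf.itertuples()
        }
        missing = [c for c in data.columns if str(c) not in keys]
        if missing:
            raise ValueError(f"feature sidecar is missing ids: {missing[:5]}")
        features = [keys[str(c)] for c in data.columns]
    else:
        features = [_parse_feature_header(c) for c in data.columns]

    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path))
    required = {"sample_id", "batch", "injection_order", "sample_type"}
    if not required.issubset(meta.columns):
        raise ValueError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    meta["sample_id"] = meta["sample_id"].astype(str)
    records = {
        r.sample_id: SampleRecord(
            r.sample_id, str(r.batch), int(r.injection_order), str(r.sample_type)
        )
        for r in meta.itertuples()
    }
    absent = [s for s in records if s not in set(data.index)]
    if absent:
        raise ValueError(f"metadata lists samples absent from the table: {absent[:5]}")
    unlisted = [s for s in data.index if s not in records]
    if unlisted:
        raise ValueError(f"table samples missing from metadata: {unlisted[:5]}")
    samples = [records[s] for s in data.index]
    return PeakTable(features, samples, x)


def write_peak_table(table: PeakTable, path, metadata_path=None, features_path=None) -> None:
    """Write a PeakTable as wide CSV/TSV plus metadata and feature sidecars.

    Missing values are serialised as empty cells, never as 0.  Default sidecar
    paths are derived from ``path`` by appending ``_meta`` / ``_features``.
    """
    if table.n_features == 0:
        raise ValueError("refusing to write a peak table with no features")
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_name(path.stem + "_meta" + path.suffix)
    if features_path is None:
        features_path = path.with_name(path.stem + "_features" + path.suffix)
    sep = _sep_for(path)
    table.to_frame().to_csv(path, sep=sep, na_rep="")
    table.metadata_frame().to_csv(Path(metadata_path), sep=sep, index=False)
    table.feature_frame().to_csv(Path(features_path), sep=sep, index=False)
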