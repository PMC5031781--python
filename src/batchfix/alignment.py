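"""Between-batch feature alignment via batch-level presence orthogonality.

When peak tables from several analytical batches are combined, the same
compound is frequently registered under slightly different m/z and rt in
different batches and ends up as two (or more) batch-specific features, each
systematically missing wherever the other is present.  This module detects
and merges such artificially split features:

1. *Presence aggregation* — per feature and batch, the proportion of missing
   values among the basis samples (long-term reference samples by default,
   QCs optionally) is computed; the feature is flagged absent from a batch
   when that proportion strictly exceeds a threshold (default 0.80, an
   extension of the classic 80 % rule).  This filters out sample-level
   random missingness and leaves only batch-systematic structure.
2. *Candidates* — features present in some but not all batches (row sum of
   the presence vector strictly between 0 and the number of batches) can
   possibly be aligned; features present everywhere or nowhere cannot.
3. *Events* — ordered pairs of candidates that are close (|dmz| <= mz_tol and
   |drt| <= rt_tol) **and** whose presence vectors are orthogonal: two
   features present in the same batch cannot be the same compound.
4. *Event clustering* — events sharing a candidate are grouped (connected
   components of the candidate/event graph).
5. *Recursive deconvolution* — a cluster whose members are all mutually
   orthogonal is one correspondence and is merged outright.  Otherwise the
   largest event distances are removed iteratively until unambiguous
   sub-clusters (unique correspondences) separate out; the remaining
   candidates, with their original events restored, are re-processed
   recursively until no further sub-clustering is possible.  The naive
   alternative — greedily pairing nearest candidates — is implemented only
   as a test foil, since it is known to misalign near-coincident compounds
   such as stereoisomer pairs.

Merging takes, for each batch, the intensities of the single group member
present there (guaranteed unique by orthogonality), so no intensity value is
ever invented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .peak_table import FeatureKey, PeakTable

__all__ = [
    "PresenceMatrix",
    "AlignmentEvent",
    "EventCluster",
    "AlignmentMap",
    "BatchAlignment",
    "AlignmentResults",
    "aggregate_presence",
    "find_candidates",
    "detect_events",
    "cluster_events",
    "deconvolute",
    "merge_features",
    "MERGE_SEPARATOR",
]

#: Separator used to compose merged feature ids from their member ids.
MERGE_SEPARATOR = "+"


@dataclass(frozen=True)
class PresenceMatrix:
    """Per-feature, per-batch presence flags and missingness proportions."""

    features: tuple[FeatureKey, ...]
    batches: tuple[str, ...]
    present: np.ndarray  # bool, (n_features, n_batches)
    proportion_na: np.ndarray  # float in [0, 1], same shape
    threshold: float
    basis: str

    def __post_init__(self) -> None:
        if self.present.shape != (len(self.features), len(self.batches)):
            raise ValueError("presence matrix shape mismatch")
        if self.present.shape != self.proportion_na.shape:
            raise ValueError("present / proportion_na shape mismatch")

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.features)

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def index_of(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in presence matrix") from None

    def row(self, feature_id: str) -> np.ndarray:
        return self.present[self.index_of(feature_id)]

    def key(self, feature_id: str) -> FeatureKey:
        return self.features[self.index_of(feature_id)]

    def orthogonal(self, a: str, b: str) -> bool:
        """True if features a and b are never present in the same batch."""
        return not bool(np.any(self.row(a) & self.row(b)))


@dataclass(frozen=True)
class AlignmentEvent:
    """A pair of candidates close in m/z-rt and batch-orthogonal."""

    a: str
    b: str
    d_mz: float
    d_rt: float
    distance: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


@dataclass(frozen=True)
class EventCluster:
    """Connected component of the candidate/event graph."""

    members: frozenset[str]
    events: tuple[AlignmentEvent, ...]


@dataclass(frozen=True)
class AlignmentMap:
    """Resolved correspondences: groups of batch-orthogonal features to merge.

    ``merged_keys`` holds the recomputed identity of each merged feature
    (id composed of the member ids, m/z and rt as presence-weighted means);
    ``sources`` records, per group and batch, the member whose intensities
    are used there.
    """

    groups: tuple[frozenset[str], ...]
    unresolved: tuple[str, ...]
    log: tuple[dict, ...]
    merged_keys: tuple[FeatureKey, ...] = ()
    sources: tuple[dict[str, str], ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if seen & g:
                raise ValueError("alignment groups are not disjoint")
            seen |= g

    @property
    def n_merges(self) -> int:
        """Net reduction in feature count implied by the map."""
        return sum(len(g) - 1 for g in self.groups)


# ---------------------------------------------------------------------------
# Stage operations


def aggregate_presence(
    tables: Sequence[PeakTable],
    basis: str = "Ref",
    threshold: float = 0.80,
) -> PresenceMatrix:
    """Aggregate per-sample missingness into per-batch presence flags.

    A feature is absent from a batch when the proportion of missing values
    among that batch's basis samples is *strictly* greater than ``threshold``
    (so a proportion exactly at the threshold still counts as present).  A
    feature id that does not occur in a batch's table has proportion 1 there.
    """
    if basis not in {"Ref", "QC"}:
        raise ValueError(f"basis must be 'Ref' or 'QC', got {basis!r}")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    per_batch: list[tuple[str, PeakTable]] = []
    for t in tables:
        for b, sub in t.split_batches().items():
            per_batch.append((b, sub))
    batches = [b for b, _ in per_batch]
    if len(set(batches)) != len(batches):
        raise ValueError(f"duplicate batch ids across tables: {batches}")
    if len(batches) < 2:
        raise ValueError("presence aggregation needs at least 2 batches")

    keys: dict[str, FeatureKey] = {}
    for _, sub in per_batch:
        for f in sub.features:
            keys.setdefault(f.id, f)
    fids = list(keys)
    fidx = {fid: i for i, fid in enumerate(fids)}

    prop = np.ones((len(fids), len(batches)))
    for j, (b, sub) in enumerate(per_batch):
        mask = sub.sample_type_mask(basis)
        n_basis = int(mask.sum())
        if n_basis == 0:
            raise ValueError(f"batch {b!r} has no {basis} samples")
        basis_rows = sub.intensities[mask]
        frac_na = np.isnan(basis_rows).sum(axis=0) / n_basis
        for f, p in zip(sub.features, frac_na):
            prop[fidx[f.id], j] = p
    present = ~(prop > threshold)  # absent iff proportion strictly exceeds
    return PresenceMatrix(
        features=tuple(keys[f] for f in fids),
        batches=tuple(batches),
        present=present,
        proportion_na=prop,
        threshold=threshold,
        basis=basis,
    )


def find_candidates(presence: PresenceMatrix) -> list[FeatureKey]:
    """Features present in some but not all batches: 0 < row sum < n_batches."""
    sums = presence.present.sum(axis=1)
    mask = (sums > 0) & (sums < presence.n_batches)
    return [f for f, m in zip(presence.features, mask) if m]


def detect_events(
    candidates: Sequence[FeatureKey],
    presence: PresenceMatrix,
    mz_tol: float = 0.002,
    rt_tol: float = 15.0,
) -> list[AlignmentEvent]:
    """Pairs of candidates within the m/z-rt box with orthogonal presence.

    The event distance is the tolerance-normalised Euclidean distance
    ``sqrt((d_mz/mz_tol)**2 + (d_rt/rt_tol)**2)``, so both axes contribute
    on the same scale and any in-box pair has distance <= sqrt(2).
    """
    if mz_tol <= 0 or rt_tol <= 0:
        raise ValueError("mz_tol and rt_tol must be positive")
    cands = sorted(candidates, key=lambda f: (f.mz, f.id))
    rows = {f.id: presence.row(f.id) for f in cands}
    events: list[AlignmentEvent] = []
    for i, fa in enumerate(cands):
        for fb in cands[i + 1 :]:
            d_mz = fb.mz - fa.mz
            if d_mz > mz_tol:
                break  # sorted by mz
            d_rt = abs(fb.rt - fa.rt)
            if d_rt > rt_tol:
                continue
            if np.any(rows[fa.id] & rows[fb.id]):
                continue  # co-present in a batch: cannot be one compound
            a, b = sorted((fa.id, fb.id))
            events.append(
                AlignmentEvent(
                    a=a,
                    b=b,
                    d_mz=float(d_mz),
                    d_rt=float(d_rt),
                    distance=float(math.hypot(d_mz / mz_tol, d_rt / rt_tol)),
                )
            )
    events.sort(key=lambda e: e.pair)
    return events


def cluster_events(events: Sequence[AlignmentEvent]) -> list[EventCluster]:
    """Group events sharing candidates: connected components of the graph."""
    g = nx.Graph()
    for e in events:
        g.add_edge(e.a, e.b)
    clusters = []
    for comp in nx.connected_components(g):
        comp_events = tuple(e for e in events if e.a in comp and e.b in comp)
        clusters.append(EventCluster(members=frozenset(comp), events=comp_events))
    clusters.sort(key=lambda c: min(c.members))
    return clusters


def _mutually_orthogonal(members: Iterable[str], presence: PresenceMatrix) -> bool:
    rows = np.array([presence.row(m) for m in members], dtype=int)
    # all pairwise orthogonal <=> no batch hosts more than one member
    return bool(np.all(rows.sum(axis=0) <= 1))


def _components(
    members: set[str], events: Sequence[AlignmentEvent]
) -> list[tuple[set[str], list[AlignmentEvent]]]:
    g = nx.Graph()
    g.add_nodes_from(members)
    for e in events:
        g.add_edge(e.a, e.b)
    out = []
    for comp in nx.connected_components(g):
        out.append((set(comp), [e for e in events if e.a in comp and e.b in comp]))
    out.sort(key=lambda c: min(c[0]))
    return out


def deconvolute(
    cluster: EventCluster, presence: PresenceMatrix
) -> list[frozenset[str]]:
    """Disentangle a multi-candidate cluster into unique correspondences.

    A component whose members are all mutually orthogonal is one
    correspondence.  Otherwise the largest event distances are removed (ties
    removed together, deterministically) until one or more orthogonal
    sub-components separate out; those are extracted, and the remaining
    candidates — with every original event among them restored — are
    re-processed recursively until no further sub-clustering is achieved.
    Members of the cluster not in any returned group are unresolved.
    """
    groups, _ = _resolve(set(cluster.members), list(cluster.events), presence)
    groups.sort(key=min)
    return [frozenset(g) for g in groups]


def _resolve(
    members: set[str], events: list[AlignmentEvent], presence: PresenceMatrix
) -> tuple[list[set[str]], list[str]]:
    groups: list[set[str]] = []
    unresolved: list[str] = []
    for comp, comp_events in _components(members, events):
        if len(comp) < 2:
            unresolved.extend(comp)
            continue
        if _mutually_orthogonal(comp, presence):
            groups.append(comp)
            continue
        # strip largest distances until an orthogonal sub-component appears
        remaining = list(comp_events)
        found: list[set[str]] = []
        while remaining:
            max_d = max(e.distance for e in remaining)
            remaining = [e for e in remaining if e.distance < max_d]
            for sub, _ in _components(comp, remaining):
                if len(sub) >= 2 and _mutually_orthogonal(sub, presence):
                    found.append(sub)
            if found:
                break
        if not found:
            unresolved.extend(sorted(comp))
            continue
        groups.extend(found)
        resolved = set().union(*found)
        rest = comp - resolved
        rest_events = [e for e in comp_events if e.a in rest and e.b in rest]
        sub_groups, sub_unresolved = _resolve(rest, rest_events, presence)
        groups.extend(sub_groups)
        unresolved.extend(sub_unresolved)
    return groups, unresolved


def nearest_pairing(
    cluster: EventCluster, presence: PresenceMatrix
) -> list[frozenset[str]]:
    """Naive shortest-distance greedy pairing (known to misalign).

    Provided only as a comparison foil for the recursive deconvolution; it
    repeatedly accepts the globally shortest remaining event between unused
    candidates.
    """
    used: set[str] = set()
    out: list[frozenset[str]] = []
    for e in sorted(cluster.events, key=lambda e: (e.distance, e.pair)):
        if e.a in used or e.b in used:
            continue
        out.append(frozenset({e.a, e.b}))
        used |= {e.a, e.b}
    return out


def _build_map(
    presence: PresenceMatrix, clusters: Sequence[EventCluster]
) -> AlignmentMap:
    groups: list[frozenset[str]] = []
    unresolved: list[str] = []
    log: list[dict] = []
    for ci, cluster in enumerate(clusters):
        resolved = deconvolute(cluster, presence)
        in_groups: set[str] = set()
        for g in resolved:
            in_groups |= g
            ev = [e for e in cluster.events if e.a in g and e.b in g]
            log.append(
                {
                    "group_id": len(groups),
                    "cluster_id": ci,
                    "members": MERGE_SEPARATOR.join(sorted(g)),
                    "n_members": len(g),
                    "n_events": len(ev),
                    "max_d_mz": max((e.d_mz for e in ev), default=np.nan),
                    "max_d_rt": max((e.d_rt for e in ev), default=np.nan),
                    "max_distance": max((e.distance for e in ev), default=np.nan),
                    "ambiguous_cluster": not _mutually_orthogonal(
                        cluster.members, presence
                    ),
                }
            )
            groups.append(g)
        unresolved.extend(sorted(cluster.members - in_groups))

    merged_keys: list[FeatureKey] = []
    sources: list[dict[str, str]] = []
    for g in groups:
        members = sorted(g)
        weights = np.array([presence.row(m).sum() for m in members], dtype=float)
        if weights.sum() == 0:
            weights[:] = 1.0
        mzs = np.array([presence.key(m).mz for m in members])
        rts = np.array([presence.key(m).rt for m in members])
        merged_keys.append(
            FeatureKey(
                id=MERGE_SEPARATOR.join(members),
                mz=float(np.average(mzs, weights=weights)),
                rt=float(np.average(rts, weights=weights)),
            )
        )
        src: dict[str, str] = {}
        for j, batch in enumerate(presence.batches):
            present_members = [m for m in members if presence.row(m)[j]]
            if len(present_members) > 1:
                raise ValueError(
                    f"orthogonality violated at merge time in batch {batch!r}: "
                    f"{present_members}"
                )
            if present_members:
                src[batch] = present_members[0]
            else:
                # no member passes the presence rule here; fall back to the
                # member with the least missingness in this batch
                na = [(presence.proportion_na[presence.index_of(m), j], m) for m in members]
                src[batch] = min(na)[1]
        sources.append(src)
    return AlignmentMap(
        groups=tuple(groups),
        unresolved=tuple(unresolved),
        log=tuple(log),
        merged_keys=tuple(merged_keys),
        sources=tuple(sources),
    )


def merge_features(
    tables: Sequence[PeakTable], amap: AlignmentMap
) -> list[PeakTable]:
    """Merge each alignment group into a single feature across batch tables.

    Within each group and batch, intensities come from the single member
    present in that batch (unique by orthogonality; the map's precomputed
    per-batch sources encode this).  The merged feature takes the map's
    recomputed key and sits at the position of the group's first member in
    each table; other members are dropped.  Features outside any group pass
    through unchanged.
    """
    member_to_group: dict[str, int] = {}
    for gi, g in enumerate(amap.groups):
        for m in g:
            if m in member_to_group:
                raise ValueError(f"feature {m!r} occurs in two alignment groups")
            member_to_group[m] = gi

    out: list[PeakTable] = []
    for t in tables:
        t_batches = t.batches
        if len(t_batches) != 1:
            raise ValueError("merge_features expects single-batch tables")
        batch = t_batches[0]
        new_features: list[FeatureKey] = []
        new_cols: list[np.ndarray] = []
        emitted: set[int] = set()
        in_table = set(t.feature_ids)
        for f in t.features:
            gi = member_to_group.get(f.id)
            if gi is None:
                new_features.append(f)
                new_cols.append(t.intensities[:, t.feature_index(f.id)])
                continue
            if gi in emitted:
                continue  # another member of the group already emitted it
            emitted.add(gi)
            source = amap.sources[gi].get(batch)
            if source not in in_table:
                # designated source has no column in this batch: use the
                # member with a column, preferring lower missingness order
                present_here = [m for m in sorted(amap.groups[gi]) if m in in_table]
                source = present_here[0]
            new_features.append(amap.merged_keys[gi])
            new_cols.append(t.intensities[:, t.feature_index(source)])
        out.append(
            PeakTable(new_features, t.samples, np.column_stack(new_cols))
            if new_cols
            else t
        )
    return out


# ---------------------------------------------------------------------------
# Model / Results


class BatchAlignment:
    """Between-batch alignment model over a set of single-batch peak tables.

    Parameters
    ----------
    tables : sequence of PeakTable
        One table per batch (multi-batch tables are split internally).
    mz_tol : float, default 0.002
        Largest allowed |dmz| in Da; set from instrument resolution.
    rt_tol : float, default 15.0
        Largest allowed |drt|, in the rt units of the tables; set from the
        maximum between-batch retention drift.
    threshold : float, default 0.80
        Missingness proportion above which (strictly) a feature is flagged
        absent from a batch.  Results are robust over roughly 0.60-0.85.
    basis : {'Ref', 'QC'}, default 'Ref'
        Sample type whose missingness defines batch presence.
    """

    def __init__(
        self,
        tables: Sequence[PeakTable],
        *,
        mz_tol: float = 0.002,
        rt_tol: float = 15.0,
        threshold: float = 0.80,
        basis: str = "Ref",
    ) -> None:
        self.tables = list(tables)
        self.mz_tol = float(mz_tol)
        self.rt_tol = float(rt_tol)
        self.threshold = float(threshold)
        self.basis = basis

    def fit(self) -> "AlignmentResults":
        presence = aggregate_presence(self.tables, self.basis, self.threshold)
        candidates = find_candidates(presence)
        events = detect_events(candidates, presence, self.mz_tol, self.rt_tol)
        clusters = cluster_events(events)
        amap = _build_map(presence, clusters)
        return AlignmentResults(
            model=self,
            presence=presence,
            candidates=tuple(candidates),
            events=tuple(events),
            clusters=tuple(clusters),
            map=amap,
        )


@dataclass
class AlignmentResults:
    """Fitted alignment: presence matrix, events, clusters and the merge map."""

    model: BatchAlignment
    presence: PresenceMatrix
    candidates: tuple[FeatureKey, ...]
    events: tuple[AlignmentEvent, ...]
    clusters: tuple[EventCluster, ...]
    map: AlignmentMap
    _merged: list[PeakTable] | None = field(default=None, repr=False)

    def apply(self, tables: Sequence[PeakTable] | None = None) -> list[PeakTable]:
        """Merge the mapped groups in ``tables`` (default: the model's)."""
        if tables is None:
            if self._merged is None:
                self._merged = merge_features(self.model.tables, self.map)
            return self._merged
        return merge_features(list(tables), self.map)

    def log_frame(self) -> pd.DataFrame:
        """Per-group provenance: members, event counts, distances."""
        if not self.map.log:
            return pd.DataFrame(
                columns=[
                    "group_id",
                    "cluster_id",
                    "members",
                    "n_members",
                    "n_events",
                    "max_d_mz",
                    "max_d_rt",
                    "max_distance",
                    "ambiguous_cluster",
                ]
            )
        return pd.DataFrame(list(self.map.log))

    def summary(self) -> str:
        m = self.model
        p = self.presence
        lines = [
            "Between-batch feature alignment",
            "=" * 47,
            f"Batches:                {p.n_batches} ({', '.join(p.batches)})",
            f"Features (union):       {len(p.features)}",
            f"Presence basis:         {p.basis} (missingness > {p.threshold:g} = absent)",
            f"Tolerances:             |dmz| <= {m.mz_tol:g} Da, |drt| <= {m.rt_tol:g}",
            f"Alignment candidates:   {len(self.candidates)}",
            f"Events (orthogonal):    {len(self.events)}",
            f"Event clusters:         {len(self.clusters)}",
            f"Merged groups:          {len(self.map.groups)}",
            f"Features merged away:   {self.map.n_merges}",
            f"Unresolved candidates:  {len(self.map.unresolved)}",
        ]
        return "\n".join(lines)
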