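"""Threshold clustering of barcode sequences into lineages.

Specimens are partitioned by single linkage at a divergence threshold
(default 10% of K2P divergence): two specimens fall in the same lineage iff
they are connected by a chain of pairs each at or below the threshold.
Genus-specific overrides (by default 8% for *Nais* and *Uncinais*) are
applied as a second pass inside each block, so the result is always a true
partition.

Splits whose between-lineage single-link distance falls inside a doubtful
zone (default 10-13.5%) and that are not supported by morphology are
flagged and can be resolved with a secondary marker: identical (or
near-identical, per a configurable tolerance) ITS2 across the split merges
the lineages; divergent ITS2 keeps them separate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from barcodelim.distances import DistanceMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Clustering thresholds, all as fractions (0.10 = 10%).

    ``genus_overrides`` maps genus names to replacement thresholds applied
    within blocks that contain the genus.  ``doubtful_zone`` is the
    half-open interval ``(low, high]`` of between-lineage single-link
    distances that require secondary-marker confirmation.
    ``secondary_merge_tolerance`` is the maximum secondary-marker
    cross-divergence still counted as "identical" (default 0: strictly
    identical sequences).
    """

    default_threshold: float = 0.10
    genus_overrides: Mapping[str, float] = field(
        default_factory=lambda: {"Nais": 0.08, "Uncinais": 0.08}
    )
    doubtful_zone: tuple[float, float] = (0.10, 0.135)
    secondary_merge_tolerance: float = 0.0
    linkage_method: Literal["single", "complete"] = "single"

    def __post_init__(self) -> None:
        for t in (self.default_threshold, *self.genus_overrides.values()):
            if not 0.0 < t < 1.0:
                raise ValueError(f"threshold {t} outside (0, 1)")
        low, high = self.doubtful_zone
        if not low < high:
            raise ValueError("doubtful zone must satisfy low < high")
        if self.secondary_merge_tolerance < 0:
            raise ValueError("secondary_merge_tolerance must be >= 0")


@dataclass
class LineageStats:
    n_specimens: int = 0
    n_morpho_identified: int = 0
    max_intra: float | None = None      # None = NC (singleton)
    min_inter: float | None = None      # None = NA (single lineage)
    its2_max_intra: float | None = None
    taxon_label: str = ""
    new: bool | None = None             # None = no reference comparison run


@dataclass
class LineageSet:
    """A partition of specimens into named lineages, with statistics.

    ``lineages`` maps canonical lineage ids to member specimen ids (member
    order follows the dataset).  ``provenance`` records thresholds used and
    every merge applied.
    """

    lineages: dict[str, list[str]]
    stats: dict[str, LineageStats] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.lineages)

    def lineage_of(self, specimen_id: str) -> str:
        for lid, members in self.lineages.items():
            if specimen_id in members:
                return lid
        raise KeyError(specimen_id)

    def as_partition(self) -> dict[str, str]:
        return {m: lid for lid, members in self.lineages.items() for m in members}


@dataclass
class DoubtfulPair:
    """A between-lineage split inside the doubtful zone, pending confirmation."""

    lineage_a: str
    lineage_b: str
    link_distance: float
    morphologically_distinct: bool
    resolution: Literal["merged", "kept_separate", "unresolved", "pending"] = "pending"
    evidence: str = ""


def _blocks_from_labels(ids: Sequence[str], labels: np.ndarray) -> list[list[str]]:
    """Group ids by component label; blocks ordered by first member, members in input order."""
    order: dict[int, list[str]] = {}
    for sid, lab in zip(ids, labels):
        order.setdefault(int(lab), []).append(sid)
    return list(order.values())


def single_linkage_partition(
    dm: DistanceMatrix,
    threshold: float,
    *,
    method: Literal["single", "complete"] = "single",
) -> list[list[str]]:
    """Partition ids into blocks chained at distance <= threshold.

    Saturated pairs (``inf``) never link.  With ``method='complete'`` the
    blocks are instead complete-linkage clusters cut at the threshold
    (saturated distances are treated as larger than any finite one).
    Blocks are returned in input order of their first member.
    """
    n = len(dm)
    if method == "single":
        adj = csr_matrix((dm.d <= threshold) & np.isfinite(dm.d))
        _, labels = connected_components(adj, directed=False)
        return _blocks_from_labels(dm.ids, labels)
    if method == "complete":
        d = dm.d.copy()
        finite_max = np.nanmax(np.where(np.isfinite(d), d, 0.0))
        d[~np.isfinite(d)] = finite_max + threshold + 1.0
        if n == 1:
            return [[dm.ids[0]]]
        z = linkage(squareform(d, checks=False), method="complete")
        labels = fcluster(z, t=threshold, criterion="distance")
        return _blocks_from_labels(dm.ids, labels)
    raise ValueError(f"unknown linkage method {method!r}")


def _canonical_ids(blocks: Iterable[Sequence[str]]) -> dict[str, list[str]]:
    """Assign deterministic lineage ids: 'L' + zero-padded rank of the
    lexicographically smallest member id."""
    ordered = sorted(blocks, key=lambda b: min(b))
    width = max(2, len(str(len(ordered))))
    return {f"L{rank:0{width}d}": list(b) for rank, b in enumerate(ordered, start=1)}


def apply_policy(
    dm: DistanceMatrix, dataset, policy: ThresholdPolicy
) -> LineageSet:
    """Two-pass threshold clustering with genus-specific overrides.

    Pass 1 partitions all specimens at the default threshold.  Pass 2
    re-partitions, internally, every block containing at least one
    specimen of an override genus, at the minimum applicable override
    threshold; blocks without override genera are untouched.
    """
    genus_of = {s.specimen_id: s.genus for s in dataset}
    provenance = [
        f"threshold default={policy.default_threshold:.4f} "
        f"linkage={policy.linkage_method}"
    ]
    blocks = single_linkage_partition(
        dm, policy.default_threshold, method=policy.linkage_method
    )

    final_blocks: list[list[str]] = []
    for block in blocks:
        overrides = sorted(
            {
                (genus_of.get(sid, ""), policy.genus_overrides[genus_of.get(sid, "")])
                for sid in block
                if genus_of.get(sid, "") in policy.genus_overrides
            }
        )
        if not overrides:
            final_blocks.append(block)
            continue
        t_override = min(t for _, t in overrides)
        if len({t for _, t in overrides}) > 1:
            log.warning(
                "block %s mixes override genera %s; using minimum threshold %.4f",
                block, [g for g, _ in overrides], t_override,
            )
        provenance.append(
            f"override block[{min(block)}] genera={[g for g, _ in overrides]} "
            f"threshold={t_override:.4f}"
        )
        sub = dm.subset(block)
        final_blocks.extend(
            single_linkage_partition(sub, t_override, method=policy.linkage_method)
        )

    return LineageSet(lineages=_canonical_ids(final_blocks), provenance=provenance)


def _majority_label(values: list[str]) -> str:
    values = [v for v in values if v]
    if not values:
        return ""
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return max(sorted(counts), key=lambda k: counts[k])


def lineage_stats(
    lineages: LineageSet,
    dm: DistanceMatrix,
    dataset,
    secondary_dm: DistanceMatrix | None = None,
) -> LineageSet:
    """Fill per-lineage statistics from the distance matrix.

    ``max_intra`` is the maximum pairwise divergence among members (None
    for singletons, printed "NC"); ``min_inter`` the minimum divergence
    from any member to any non-member (None with a single lineage);
    ``n_morpho_identified`` counts mature members with a non-empty
    morphospecies label.  If a secondary-marker matrix is given, the
    intra-lineage maximum on that marker is reported where at least two
    members carry it.
    """
    meta = {s.specimen_id: s for s in dataset}
    idx = {sid: i for i, sid in enumerate(dm.ids)}
    all_stats: dict[str, LineageStats] = {}
    for lid, members in lineages.lineages.items():
        mi = np.array([idx[m] for m in members])
        st = LineageStats(n_specimens=len(members))
        st.n_morpho_identified = sum(
            1 for m in members if meta[m].morphospecies and meta[m].mature
        )
        st.taxon_label = _majority_label(
            [meta[m].morphospecies for m in members]
        ) or _majority_label([meta[m].genus for m in members])
        if len(members) > 1:
            sub = dm.d[np.ix_(mi, mi)]
            st.max_intra = float(sub[np.triu_indices(len(mi), k=1)].max())
        if len(lineages.lineages) > 1:
            rest = np.array([i for sid, i in idx.items() if sid not in members])
            st.min_inter = float(dm.d[np.ix_(mi, rest)].min())
        if secondary_dm is not None:
            have = [m for m in members if m in secondary_dm.ids]
            if len(have) >= 2:
                si = np.array([secondary_dm.index(m) for m in have])
                sub2 = secondary_dm.d[np.ix_(si, si)]
                st.its2_max_intra = float(sub2[np.triu_indices(len(si), k=1)].max())
        all_stats[lid] = st
    lineages.stats = all_stats
    return lineages


def _link_distance(dm: DistanceMatrix, members_a: Sequence[str], members_b: Sequence[str]) -> float:
    ia = np.array([dm.index(m) for m in members_a])
    ib = np.array([dm.index(m) for m in members_b])
    return float(dm.d[np.ix_(ia, ib)].min())


def _morphologically_distinct(dataset, members_a, members_b) -> bool:
    """Distinct iff the two sides carry different non-empty morphospecies labels.

    Sharing a non-empty label, or a joint absence of labels on both sides,
    counts as "no morphological difference".
    """
    meta = {s.specimen_id: s for s in dataset}
    labels_a = {meta[m].morphospecies for m in members_a if meta[m].morphospecies}
    labels_b = {meta[m].morphospecies for m in members_b if meta[m].morphospecies}
    if not labels_a and not labels_b:
        return False
    if labels_a & labels_b:
        return False
    return True


def detect_doubtful(
    lineages: LineageSet,
    dm: DistanceMatrix,
    dataset,
    policy: ThresholdPolicy,
) -> list[DoubtfulPair]:
    """Emit lineage pairs whose split needs secondary-marker confirmation.

    A pair is doubtful iff its single-link distance d satisfies
    ``zone.low < d <= zone.high`` and the lineages show no morphological
    difference (shared morphospecies label, or all members unidentifiable
    on both sides).
    """
    low, high = policy.doubtful_zone
    pairs: list[DoubtfulPair] = []
    lids = sorted(lineages.lineages)
    for i, la in enumerate(lids):
        for lb in lids[i + 1 :]:
            d = _link_distance(dm, lineages.lineages[la], lineages.lineages[lb])
            if not (low < d <= high):
                continue
            distinct = _morphologically_distinct(
                dataset, lineages.lineages[la], lineages.lineages[lb]
            )
            if distinct:
                continue
            pairs.append(
                DoubtfulPair(
                    lineage_a=la, lineage_b=lb, link_distance=d,
                    morphologically_distinct=False,
                )
            )
    return pairs


def resolve_doubtful(
    pair: DoubtfulPair,
    lineages: LineageSet,
    secondary_dm: DistanceMatrix | None,
    policy: ThresholdPolicy,
) -> DoubtfulPair:
    """Decide a doubtful split from the secondary marker.

    Merged iff the maximum secondary-marker divergence across the split is
    at or below the merge tolerance (default 0: identical sequences);
    kept separate when it exceeds it; unresolved when either side lacks
    secondary-marker data.
    """
    members_a = lineages.lineages[pair.lineage_a]
    members_b = lineages.lineages[pair.lineage_b]
    if secondary_dm is None:
        return replace(pair, resolution="unresolved", evidence="no secondary marker")
    have_a = [m for m in members_a if m in secondary_dm.ids]
    have_b = [m for m in members_b if m in secondary_dm.ids]
    if not have_a or not have_b:
        return replace(pair, resolution="unresolved", evidence="no secondary marker")
    ia = np.array([secondary_dm.index(m) for m in have_a])
    ib = np.array([secondary_dm.index(m) for m in have_b])
    cross_max = float(secondary_dm.d[np.ix_(ia, ib)].max())
    tol = policy.secondary_merge_tolerance
    if cross_max <= tol:
        evidence = (
            "ITS2 identical" if cross_max == 0.0
            else f"ITS2 cross-divergence {100 * cross_max:.2f}% <= tolerance"
        )
        return replace(pair, resolution="merged", evidence=evidence)
    return replace(
        pair,
        resolution="kept_separate",
        evidence=f"ITS2 cross-divergence {100 * cross_max:.2f}% > tolerance",
    )


def finalize(
    lineages: LineageSet,
    resolutions: Sequence[DoubtfulPair],
    dm: DistanceMatrix,
    dataset,
    secondary_dm: DistanceMatrix | None = None,
) -> LineageSet:
    """Apply merge decisions (transitively), recompute ids and statistics.

    Only ``merged`` resolutions union lineages; every decision is retained
    in the provenance log.
    """
    parent: dict[str, str] = {lid: lid for lid in lineages.lineages}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    provenance = list(lineages.provenance)
    for pair in resolutions:
        provenance.append(
            f"doubtful {pair.lineage_a}~{pair.lineage_b} "
            f"link={100 * pair.link_distance:.2f}% -> {pair.resolution} "
            f"({pair.evidence})"
        )
        if pair.resolution == "merged":
            ra, rb = find(pair.lineage_a), find(pair.lineage_b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    merged_members: dict[str, list[str]] = {}
    for lid, members in lineages.lineages.items():
        merged_members.setdefault(find(lid), []).extend(members)

    out = LineageSet(
        lineages=_canonical_ids(merged_members.values()), provenance=provenance
    )
    return lineage_stats(out, dm, dataset, secondary_dm=secondary_dm)
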