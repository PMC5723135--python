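"""Matching delimited lineages against a labelled reference library.

Replaces live BLAST/BOLD lookups with a local comparison: a query lineage
is considered the same species as a reference lineage when their minimum
K2P divergence is at or below a match threshold (default 10%).  Lineages
beyond the threshold from every reference are flagged new.  The module
also reports cryptic complexes: morphospecies labels spanning two or more
delimited lineages.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from barcodelim.distances import cross_distances
from barcodelim.io import FormatError, normalize_sequence


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference sequence with its database lineage and taxon labels."""

    ref_id: str
    lineage_label: str
    taxon_label: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.lineage_label:
            raise ValueError(f"reference {self.ref_id} has an empty lineage label")


@dataclass
class LineageMatch:
    best_ref_label: str
    best_taxon: str
    best_distance: float
    is_new: bool
    ambiguous: bool = False
    matched_labels: list[str] = field(default_factory=list)


@dataclass
class MatchReport:
    per_lineage: dict[str, LineageMatch]
    match_threshold: float
    n_references: int

    @property
    def n_query_lineages(self) -> int:
        return len(self.per_lineage)

    @property
    def n_new(self) -> int:
        return sum(m.is_new for m in self.per_lineage.values())

    @property
    def n_matched(self) -> int:
        return self.n_query_lineages - self.n_new


def read_reference_fasta(
    path: str | Path, sidecar: str | Path | None = None
) -> list[ReferenceEntry]:
    """Read a reference library from FASTA.

    Headers are either pipe-delimited ``ref_id|lineage_label|taxon_label``,
    or a bare id with the labels supplied in a tab-separated sidecar table
    (columns ``ref_id``, ``lineage_label``, ``taxon_label``).
    """
    labels: dict[str, tuple[str, str]] = {}
    if sidecar is not None:
        with Path(sidecar).open(newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                labels[row["ref_id"]] = (
                    row["lineage_label"], row.get("taxon_label", "")
                )
    entries: list[ReferenceEntry] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        if "|" in header:
            # pipe-delimited labels; the taxon field may contain spaces
            parts = header.split("|")
            if len(parts) < 2:
                raise FormatError(f"malformed reference header {header!r}")
            ref_id, lineage_label = parts[0], parts[1].strip()
            taxon = parts[2].strip() if len(parts) > 2 else ""
        elif rec.id in labels:
            ref_id = rec.id
            lineage_label, taxon = labels[rec.id]
        else:
            raise FormatError(
                f"reference {header!r} has neither a pipe-delimited header "
                "nor a sidecar entry"
            )
        entries.append(
            ReferenceEntry(
                ref_id=ref_id,
                lineage_label=lineage_label,
                taxon_label=taxon,
                sequence=normalize_sequence(str(rec.seq), where=f"reference {ref_id}"),
            )
        )
    if not entries:
        raise FormatError(f"no reference records found in {path}")
    return entries


def match_lineages(
    lineages,
    dataset,
    refs: Sequence[ReferenceEntry],
    match_threshold: float = 0.10,
) -> MatchReport:
    """Best-match every query lineage against the reference library.

    ``best_distance`` is the minimum K2P divergence over all
    (member, reference) pairs; ties between reference labels break
    lexicographically.  A lineage within the threshold of two or more
    distinct reference labels is flagged ambiguous.  With an empty
    reference set every lineage is new.
    """
    seqs = dataset.sequences("COI")
    report: dict[str, LineageMatch] = {}
    if not refs:
        for lid in lineages.lineages:
            report[lid] = LineageMatch(
                best_ref_label="", best_taxon="", best_distance=float("inf"),
                is_new=True,
            )
        return MatchReport(per_lineage=report, match_threshold=match_threshold,
                           n_references=0)

    ref_seqs = [r.sequence for r in refs]
    frame = len(ref_seqs[0])
    query_len = {len(s) for s in seqs.values()}
    if query_len and query_len != {frame}:
        raise ValueError(
            f"query alignment length {sorted(query_len)} differs from "
            f"reference frame {frame}"
        )
    for lid, members in lineages.lineages.items():
        member_seqs = [seqs[m] for m in members if m in seqs]
        d = cross_distances(member_seqs, ref_seqs)  # members x refs
        per_ref = d.min(axis=0)
        # deterministic tie-break: smallest distance, then lexicographic label
        order = sorted(
            range(len(refs)), key=lambda j: (per_ref[j], refs[j].lineage_label)
        )
        best = order[0]
        best_distance = float(per_ref[best])
        within = sorted(
            {refs[j].lineage_label for j in range(len(refs))
             if per_ref[j] <= match_threshold}
        )
        report[lid] = LineageMatch(
            best_ref_label=refs[best].lineage_label,
            best_taxon=refs[best].taxon_label,
            best_distance=best_distance,
            is_new=not np.isfinite(best_distance) or best_distance > match_threshold,
            ambiguous=len(within) > 1,
            matched_labels=within,
        )
    return MatchReport(
        per_lineage=report, match_threshold=match_threshold, n_references=len(refs)
    )


def detect_cryptic(lineages, dataset) -> dict[str, list[str]]:
    """Morphospecies labels spanning two or more delimited lineages.

    Returns ``{label: [lineage ids]}`` for every non-empty label carried by
    members of at least two distinct lineages — the operational signature
    of a cryptic species complex.
    """
    label_of = {s.specimen_id: s.morphospecies for s in dataset}
    spread: dict[str, set[str]] = {}
    for lid, members in lineages.lineages.items():
        for m in members:
            label = label_of.get(m, "")
            if label:
                spread.setdefault(label, set()).add(lid)
    return {
        label: sorted(lids)
        for label, lids in sorted(spread.items())
        if len(lids) >= 2
    }


def write_match_report(report: MatchReport, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["lineage_id", "best_ref_label", "best_taxon", "best_distance_pct",
             "is_new", "ambiguous", "matched_labels"]
        )
        for lid in sorted(report.per_lineage):
            m = report.per_lineage[lid]
            dist = "" if not np.isfinite(m.best_distance) else f"{100 * m.best_distance:.2f}"
            writer.writerow(
                [lid, m.best_ref_label, m.best_taxon, dist,
                 int(m.is_new), int(m.ambiguous), ",".join(m.matched_labels)]
            )
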