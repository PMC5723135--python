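"""Readers and writers for the pipeline's external representations.

Sequences travel as plain FASTA (one file per marker), specimen metadata as
a tab-separated table keyed on ``specimen_id``, and the lineage inventory as
a tab-separated report mirroring the columns of a barcode-database summary
table (specimen counts, maximum intra-lineage and minimum inter-lineage
divergence, secondary-marker variability, new-lineage flag).

All sequences are normalised on read: upper-cased and RNA-style ``U``
mapped to ``T``.  Inputs must be pre-aligned — every sequence of a marker
has to have the same length; the pipeline never aligns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

#: IUPAC nucleotide codes (after U->T normalisation) plus the gap character.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}
_FALSE_STRINGS = {"0", "false", "no", "n", "f", ""}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SpecimenRecord:
    """One sequenced specimen: a barcode record plus curator metadata.

    ``morphospecies`` empty means the specimen could not be identified
    morphologically (e.g. immature); ``mature`` marks specimens whose
    morphological identification is considered reliable.
    """

    specimen_id: str
    coi_seq: str = ""
    its2_seq: str = ""
    genus: str = ""
    morphospecies: str = ""
    higher_taxon: str = ""
    mature: bool = False
    site: str = ""


@dataclass
class Dataset:
    """An ordered collection of specimens on a common alignment frame."""

    specimens: list[SpecimenRecord] = field(default_factory=list)
    marker_lengths: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self):
        return iter(self.specimens)

    @property
    def ids(self) -> list[str]:
        return [s.specimen_id for s in self.specimens]

    def get(self, specimen_id: str) -> SpecimenRecord:
        for s in self.specimens:
            if s.specimen_id == specimen_id:
                return s
        raise KeyError(specimen_id)

    def sequences(self, marker: str = "COI") -> dict[str, str]:
        """Mapping specimen_id -> sequence, skipping specimens lacking the marker."""
        attr = _marker_attr(marker)
        return {
            s.specimen_id: getattr(s, attr)
            for s in self.specimens
            if getattr(s, attr)
        }


def _marker_attr(marker: str) -> str:
    key = marker.strip().upper()
    if key == "COI":
        return "coi_seq"
    if key == "ITS2":
        return "its2_seq"
    raise ValueError(f"unknown marker {marker!r} (expected 'COI' or 'ITS2')")


def normalize_sequence(seq: str, *, where: str = "sequence") -> str:
    """Upper-case, map U->T and validate against the IUPAC alphabet."""
    out = seq.upper().replace("U", "T")
    for pos, ch in enumerate(out):
        if ch not in IUPAC_CHARS:
            raise FormatError(
                f"non-IUPAC character {ch!r} at position {pos + 1} in {where}"
            )
    return out


def read_fasta(path: str | Path, marker: str = "COI") -> dict[str, str]:
    """Read an aligned FASTA file into an ordered ``{id: sequence}`` mapping.

    The specimen id is the first whitespace-delimited token of the header;
    the remainder of the header is ignored.  Duplicate ids, empty files and
    non-IUPAC characters are hard errors.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in seqs:
            raise FormatError(f"duplicate id {sid} in {path}")
        seqs[sid] = normalize_sequence(str(rec.seq), where=f"{marker} record {sid}")
    if not seqs:
        raise FormatError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE_STRINGS:
        return True
    if v in _FALSE_STRINGS:
        return False
    raise FormatError(f"cannot interpret {value!r} as a boolean")


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read the tab-separated specimen metadata table.

    Required column: ``specimen_id``.  Optional: ``genus``,
    ``morphospecies``, ``higher_taxon``, ``mature``, ``site``; missing
    optional fields default to empty/false.
    """
    path = Path(path)
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "specimen_id" not in reader.fieldnames:
            raise FormatError(f"metadata table {path} lacks a 'specimen_id' column")
        for row in reader:
            sid = (row.get("specimen_id") or "").strip()
            if not sid:
                raise FormatError(f"empty specimen_id in metadata table {path}")
            if sid in seen:
                raise FormatError(f"duplicate specimen_id {sid} in metadata table")
            seen.add(sid)
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    genus=(row.get("genus") or "").strip(),
                    morphospecies=(row.get("morphospecies") or "").strip(),
                    higher_taxon=(row.get("higher_taxon") or "").strip(),
                    mature=parse_bool(row.get("mature") or "0"),
                    site=(row.get("site") or "").strip(),
                )
            )
    return records


def write_metadata(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    path = Path(path)
    cols = ["specimen_id", "genus", "morphospecies", "higher_taxon", "mature", "site"]
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            writer.writerow(
                [r.specimen_id, r.genus, r.morphospecies, r.higher_taxon,
                 "1" if r.mature else "0", r.site]
            )


def assemble_dataset(
    seqs_by_marker: Mapping[str, Mapping[str, str]],
    metadata: Sequence[SpecimenRecord] | None = None,
    *,
    primary_marker: str = "COI",
    strict: bool = False,
) -> Dataset:
    """Join per-marker sequence mappings with the metadata table.

    Every specimen must carry the primary marker.  Under ``strict``,
    sequence ids absent from the metadata are a hard error; otherwise such
    specimens get empty metadata fields.  Alignment lengths are checked per
    marker and violations reported with the offending ids.
    """
    markers = {m.strip().upper(): dict(s) for m, s in seqs_by_marker.items()}
    if primary_marker.upper() not in markers:
        raise FormatError(f"primary marker {primary_marker!r} missing from inputs")
    primary = markers[primary_marker.upper()]

    marker_lengths: dict[str, int] = {}
    for marker, seqs in markers.items():
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            ref_len = len(next(iter(seqs.values())))
            bad = sorted(sid for sid, s in seqs.items() if len(s) != ref_len)
            raise FormatError(
                f"unequal {marker} alignment lengths {sorted(lengths)}; "
                f"offending ids (vs first record): {', '.join(bad)}"
            )
        marker_lengths[marker] = next(iter(lengths)) if lengths else 0

    meta_by_id = {r.specimen_id: r for r in (metadata or [])}
    if strict:
        missing = sorted(set(primary) - set(meta_by_id))
        if missing:
            raise FormatError(
                "ids present in FASTA but missing from metadata: " + ", ".join(missing)
            )

    specimens: list[SpecimenRecord] = []
    its2 = markers.get("ITS2", {})
    for sid, seq in primary.items():  # insertion order = input order
        meta = meta_by_id.get(sid, SpecimenRecord(specimen_id=sid))
        specimens.append(
            SpecimenRecord(
                specimen_id=sid,
                coi_seq=seq,
                its2_seq=its2.get(sid, ""),
                genus=meta.genus,
                morphospecies=meta.morphospecies,
                higher_taxon=meta.higher_taxon,
                mature=meta.mature,
                site=meta.site,
            )
        )
    return Dataset(specimens=specimens, marker_lengths=marker_lengths)


def _fmt_pct(value: float | None, precision: int, undefined: str) -> str:
    if value is None:
        return undefined
    return f"{100.0 * value:.{precision}f}"


def write_inventory(lineages, path: str | Path, *, precision: int = 2) -> None:
    """Write the lineage inventory table.

    One row per lineage: id, taxon label, specimen counts, maximum
    intra-lineage and minimum inter-lineage COI divergence (percent),
    secondary-marker intra-lineage divergence where available, and the
    new-lineage flag.  Singletons print ``NC`` (not calculated) for the
    intra-lineage maximum; with a single lineage the inter-lineage minimum
    is ``NA``.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["lineage_id", "taxon_label", "n_specimens", "n_morpho_identified",
             "max_intra_pct", "min_inter_pct", "its2_intra_pct", "new_lineage"]
        )
        for lid in sorted(lineages.lineages):
            st = lineages.stats[lid]
            writer.writerow(
                [
                    lid,
                    st.taxon_label,
                    st.n_specimens,
                    st.n_morpho_identified,
                    _fmt_pct(st.max_intra, precision, "NC"),
                    _fmt_pct(st.min_inter, precision, "NA"),
                    _fmt_pct(st.its2_max_intra, precision, ""),
                    "" if st.new is None else ("*" if st.new else ""),
                ]
            )
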