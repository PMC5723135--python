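"""Pairwise Kimura two-parameter (K2P) distances over aligned barcodes.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the proportions of compared sites differing by a transition
and a transversion respectively, the corrected distance is

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites are compared under *pairwise deletion*: for each sequence pair only
sites where both sequences carry an unambiguous A/C/G/T are counted;
gaps, Ns and IUPAC ambiguity codes are masked per pair.  When a log
argument is non-positive the correction diverges (saturation) and the
distance is carried as ``+inf`` — such pairs can never link two clusters.

Distances are fractional throughout; conversion to percent happens only at
the reporting boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

log = logging.getLogger(__name__)

# A,C,G,T -> 0..3; everything else (gap, N, ambiguity) -> 4 = missing.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


class UndefinedDistanceError(ValueError):
    """No comparable sites: the distance is undefined (distinct from saturation)."""


@dataclass(frozen=True)
class PairCounts:
    """Site-comparison counts for one sequence pair (pairwise deletion)."""

    n_sites: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_transitions + self.n_transversions <= self.n_sites:
            raise ValueError("inconsistent pair counts")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes (A=0, C=1, G=2, T=3, missing=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pair_counts(seq_a: str, seq_b: str) -> PairCounts:
    """Count compared sites, transitions and transversions for one pair."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"unequal sequence lengths {len(seq_a)} vs {len(seq_b)}"
        )
    a, b = encode(seq_a), encode(seq_b)
    valid = (a < 4) & (b < 4)
    diff = valid & (a != b)
    # purines encode to even numbers (A=0, G=2): same parity = transition
    ts = diff & ((a % 2) == (b % 2))
    n_ts = int(ts.sum())
    return PairCounts(int(valid.sum()), n_ts, int(diff.sum()) - n_ts)


def k2p(counts: PairCounts) -> tuple[float, bool]:
    """K2P distance for one pair: ``(distance, saturated)``.

    Returns ``(inf, True)`` when the correction is undefined
    (1 - 2P - Q <= 0 or 1 - 2Q <= 0).
    """
    if counts.n_sites == 0:
        raise UndefinedDistanceError("no comparable sites between the sequences")
    p = counts.n_transitions / counts.n_sites
    q = counts.n_transversions / counts.n_sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf, True
    # +0.0 canonicalizes the -0.0 arising from log(1.0)
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0, False


def p_distance(counts: PairCounts) -> float:
    """Uncorrected proportion of differing sites (diagnostic companion)."""
    if counts.n_sites == 0:
        raise UndefinedDistanceError("no comparable sites between the sequences")
    return (counts.n_transitions + counts.n_transversions) / counts.n_sites


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with per-pair bookkeeping.

    ``d`` holds fractional distances (``inf`` where saturated), ``sites``
    the per-pair compared-site counts, ``saturated`` / ``low_coverage``
    boolean flags.  Order of ``ids`` is the input order and is preserved
    by every downstream stage.
    """

    ids: list[str]
    d: np.ndarray
    sites: np.ndarray
    saturated: np.ndarray
    low_coverage: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.low_coverage is None:
            self.low_coverage = np.zeros((n, n), dtype=bool)
        assert self.d.shape == (n, n)

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.index(id_a), self.index(id_b)])

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self.index(i) for i in ids])
        return DistanceMatrix(
            ids=list(ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            sites=self.sites[np.ix_(idx, idx)].copy(),
            saturated=self.saturated[np.ix_(idx, idx)].copy(),
            low_coverage=self.low_coverage[np.ix_(idx, idx)].copy(),
        )


def _counts_arrays(
    codes_a: np.ndarray, codes_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised site/transition/transversion counts: rows of a vs rows of b."""
    va, vb = codes_a < 4, codes_b < 4
    n_a, n_b = codes_a.shape[0], codes_b.shape[0]
    n_sites = np.zeros((n_a, n_b), dtype=np.int64)
    n_ts = np.zeros((n_a, n_b), dtype=np.int64)
    n_tv = np.zeros((n_a, n_b), dtype=np.int64)
    for i in range(n_a):
        valid = va[i] & vb
        diff = valid & (codes_a[i] != codes_b)
        ts = diff & ((codes_a[i] % 2) == (codes_b % 2))
        n_sites[i] = valid.sum(axis=1)
        n_ts[i] = ts.sum(axis=1)
        n_tv[i] = diff.sum(axis=1) - n_ts[i]
    return n_sites, n_ts, n_tv


def _k2p_from_counts(
    n_sites: np.ndarray, n_ts: np.ndarray, n_tv: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_sites > 0, n_ts / np.maximum(n_sites, 1), 0.0)
        q = np.where(n_sites > 0, n_tv / np.maximum(n_sites, 1), 0.0)
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        saturated = (w1 <= 0.0) | (w2 <= 0.0) | (n_sites == 0)
        d = np.where(
            saturated,
            np.inf,
            -0.5 * np.log(np.where(saturated, 1.0, w1))
            - 0.25 * np.log(np.where(saturated, 1.0, w2)),
        )
    d = d + 0.0  # canonicalize -0.0 from log(1.0)
    return d, saturated


def build_matrix(
    dataset,
    marker: str = "COI",
    *,
    min_sites: int = 100,
    deletion: Literal["pairwise", "complete"] = "pairwise",
) -> DistanceMatrix:
    """All-against-all K2P distances for one marker of a dataset.

    Pairs sharing fewer than ``min_sites`` comparable sites are flagged
    low-coverage (and a warning logged); pairs with no comparable sites or
    a saturated correction carry ``inf``.  ``deletion='complete'`` drops
    every column with any missing state before comparing.
    """
    seqs = dataset.sequences(marker)
    if len(seqs) < 2:
        raise ValueError(f"need at least 2 specimens with marker {marker}")
    ids = list(seqs)
    codes = np.stack([encode(seqs[i]) for i in ids])
    if deletion == "complete":
        keep = (codes < 4).all(axis=0)
        codes = codes[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")

    n_sites, n_ts, n_tv = _counts_arrays(codes, codes)
    d, saturated = _k2p_from_counts(n_sites, n_ts, n_tv)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(saturated, False)
    low = n_sites < min_sites
    np.fill_diagonal(low, False)
    if low.any():
        n_low = int(low.sum()) // 2
        log.warning(
            "%d %s pair(s) share fewer than %d comparable sites; flagged low-coverage",
            n_low, marker, min_sites,
        )
    return DistanceMatrix(
        ids=ids, d=d, sites=n_sites, saturated=saturated, low_coverage=low
    )


def cross_distances(seqs_a: Sequence[str], seqs_b: Sequence[str]) -> np.ndarray:
    """K2P distance matrix between two sequence collections (rows a, cols b)."""
    lengths = {len(s) for s in list(seqs_a) + list(seqs_b)}
    if len(lengths) > 1:
        raise ValueError(f"sequences not on a common alignment frame: lengths {sorted(lengths)}")
    ca = np.stack([encode(s) for s in seqs_a])
    cb = np.stack([encode(s) for s in seqs_b])
    d, _ = _k2p_from_counts(*_counts_arrays(ca, cb))
    return d


def write_square_tsv(dm: DistanceMatrix, path: str | Path, precision: int = 6) -> None:
    """Square tab-separated matrix with an id header row and column."""
    with Path(path).open("w") as fh:
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, sid in enumerate(dm.ids):
            row = "\t".join(f"{dm.d[i, j]:.{precision}f}" for j in range(len(dm)))
            fh.write(f"{sid}\t{row}\n")


def write_phylip_lower(dm: DistanceMatrix, path: str | Path, precision: int = 6) -> None:
    """PHYLIP-style lower-triangle export for external tree programs."""
    with Path(path).open("w") as fh:
        fh.write(f"{len(dm)}\n")
        for i, sid in enumerate(dm.ids):
            cells = "".join(f"  {dm.d[i, j]:.{precision}f}" for j in range(i))
            fh.write(f"{sid:<10s}{cells}\n")
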