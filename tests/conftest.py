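"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from barcodelim.distances import DistanceMatrix
from barcodelim.io import Dataset, SpecimenRecord

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def oracle_k2p(seq_a: str, seq_b: str) -> tuple[float, bool]:
    """Brute-force per-site recount + closed-form K2P, independent of the
    vectorised implementation under test."""
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper(), strict=True):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        both_purine = x in PURINES and y in PURINES
        both_pyrimidine = x in PYRIMIDINES and y in PYRIMIDINES
        if both_purine or both_pyrimidine:
            ts += 1
        else:
            tv += 1
    assert n > 0
    p, q = ts / n, tv / n
    w1, w2 = 1 - 2 * p - q, 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        return math.inf, True
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), False


def oracle_closure(ids, d, threshold, strict=False):
    """Transitive closure over the <=threshold (or <threshold) graph, by
    naive repeated merging; returns a set of frozensets."""
    blocks = [{i} for i in range(len(ids))]
    changed = True
    while changed:
        changed = False
        for a in range(len(blocks)):
            for b in range(a + 1, len(blocks)):
                linked = any(
                    (d[i, j] < threshold if strict else d[i, j] <= threshold)
                    and np.isfinite(d[i, j])
                    for i in blocks[a]
                    for j in blocks[b]
                )
                if linked:
                    blocks[a] |= blocks[b]
                    del blocks[b]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(ids[i] for i in block) for block in blocks}


def make_dm(ids, pairs, default=0.5):
    """Build a DistanceMatrix from {(a, b): distance} with a fill value."""
    n = len(ids)
    d = np.full((n, n), default, dtype=float)
    np.fill_diagonal(d, 0.0)
    index = {sid: i for i, sid in enumerate(ids)}
    for (a, b), dist in pairs.items():
        d[index[a], index[b]] = d[index[b], index[a]] = dist
    return DistanceMatrix(
        ids=list(ids),
        d=d,
        sites=np.full((n, n), 658, dtype=np.int64),
        saturated=~np.isfinite(d),
    )


def random_symmetric_dm(rng, n, p_inf=0.0, scale=0.3):
    d = rng.random((n, n)) * scale
    d = (d + d.T) / 2.0
    if p_inf:
        mask = rng.random((n, n)) < p_inf
        mask |= mask.T
        d[mask] = np.inf
    np.fill_diagonal(d, 0.0)
    ids = [f"s{i:02d}" for i in range(n)]
    return DistanceMatrix(
        ids=ids,
        d=d,
        sites=np.full((n, n), 658, dtype=np.int64),
        saturated=~np.isfinite(d),
    )


def make_dataset(rows):
    """Dataset from (id, coi, genus, morphospecies[, its2[, mature]]) tuples."""
    specimens = []
    for row in rows:
        sid, coi, genus, morpho = row[:4]
        its2 = row[4] if len(row) > 4 else ""
        mature = row[5] if len(row) > 5 else True
        specimens.append(
            SpecimenRecord(
                specimen_id=sid, coi_seq=coi, its2_seq=its2,
                genus=genus, morphospecies=morpho, mature=mature,
            )
        )
    lengths = {"COI": len(specimens[0].coi_seq)}
    its2_len = {len(s.its2_seq) for s in specimens if s.its2_seq}
    if its2_len:
        lengths["ITS2"] = its2_len.pop()
    return Dataset(specimens=specimens, marker_lengths=lengths)


def random_seq(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
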