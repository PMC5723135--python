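"""Dereplication for compact tree display and a convenience NJ tree.

Reference-database figures typically show only sequences separated by at
least some divergence cutoff (e.g. 5% or 1%), each representative carrying
an "N ind" annotation for the number of near-identical sequences it stands
for.  ``dereplicate`` reproduces that collapsing: single-link blocks at
strictly-less-than-cutoff linkage, so sequences separated by >= cutoff are
all retained.  ``nj_tree`` builds a plain neighbor-joining tree as a
sanity visualisation; likelihood inference and bootstrapping are left to
dedicated external programs, fed via the FASTA/PHYLIP exports.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from barcodelim.distances import DistanceMatrix

log = logging.getLogger(__name__)


@dataclass
class DereplicationResult:
    """Outcome of collapsing near-identical sequences at a cutoff."""

    representatives: list[str]
    collapsed_counts: dict[str, int]
    members: dict[str, list[str]]
    cutoff: float

    def label(self, rep: str) -> str:
        """Figure-style label: the representative id plus an 'N ind' count
        (count includes the representative itself) when it stands for >1."""
        k = self.collapsed_counts[rep]
        return rep if k == 1 else f"{rep} {k} ind"


def dereplicate(dm: DistanceMatrix, cutoff: float) -> DereplicationResult:
    """Collapse ids linked by chains of pairs at distance < cutoff (strict).

    One representative per block — the lexicographically smallest id — with
    the block size as its collapsed count.  Representatives are returned in
    the matrix's input order.
    """
    adj = csr_matrix((dm.d < cutoff) & np.isfinite(dm.d))
    _, labels = connected_components(adj, directed=False)
    blocks: dict[int, list[str]] = {}
    for sid, lab in zip(dm.ids, labels):
        blocks.setdefault(int(lab), []).append(sid)
    reps: list[str] = []
    counts: dict[str, int] = {}
    members: dict[str, list[str]] = {}
    first_index = {sid: i for i, sid in enumerate(dm.ids)}
    for block in sorted(blocks.values(), key=lambda b: min(first_index[m] for m in b)):
        rep = min(block)
        reps.append(rep)
        counts[rep] = len(block)
        members[rep] = block
    return DereplicationResult(
        representatives=reps, collapsed_counts=counts, members=members, cutoff=cutoff
    )


def nj_tree(
    dm: DistanceMatrix,
    restricted_to: Sequence[str] | None = None,
    precision: int = 6,
) -> str:
    """Neighbor-joining tree over the (sub)matrix, serialized as newick.

    Negative branch lengths are clamped to zero (with a log note); branch
    lengths are written with ``precision`` decimals (default 6).
    Saturated pairs make NJ meaningless, so their presence is a hard error
    naming the pair.
    """
    sub = dm.subset(list(restricted_to)) if restricted_to is not None else dm
    if len(sub) < 3:
        raise ValueError(f"need at least 3 ids for a NJ tree, got {len(sub)}")
    if not np.all(np.isfinite(sub.d)):
        i, j = np.argwhere(~np.isfinite(sub.d))[0]
        raise ValueError(
            f"saturated/undefined distance between {sub.ids[i]} and {sub.ids[j]}; "
            "cannot build a NJ tree"
        )
    tree = _skbio_nj(_SkbioDM(sub.d, sub.ids))  # clamps negatives to 0 by default
    if any(n.length is not None and n.length == 0.0 for n in tree.traverse()):
        log.info("NJ produced zero-length (possibly clamped) branches")
    buf = _io.StringIO()
    tree.write(buf)
    newick = buf.getvalue().strip()
    return re.sub(
        r":(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)",
        lambda m: f":{float(m.group(1)):.{precision}f}",
        newick,
    )


def write_derep_fasta(
    result: DereplicationResult, seqs: Mapping[str, str], path: str | Path
) -> None:
    """Write representatives with figure-style '<id> <k> ind' headers."""
    with Path(path).open("w") as fh:
        for rep in result.representatives:
            fh.write(f">{result.label(rep)}\n{seqs[rep]}\n")
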