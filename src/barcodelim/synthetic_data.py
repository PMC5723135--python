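"""Simulation of barcode datasets with known lineage structure.

Sequences evolve under the two-parameter substitution process that the K2P
estimator inverts: one rate for transitions, one for transversions, with
the transition/transversion rate ratio ``kappa`` and branch lengths in
expected substitutions per site.  Site outcomes are drawn from the exact
closed-form transition probabilities (no discretised simulation), so the
estimator-consistency checks have a clean forward model.

Lineages follow a star-within-star genealogy: one random root, per-lineage
ancestors at ``inter_depth/2`` from the root, and member tips at
``intra_depth/2`` from their ancestor.  Expected pairwise divergence is
then ~``intra_depth`` within lineages and ~``inter_depth`` (plus the small
intra contribution) between them, giving direct control over where the
data sit relative to a clustering threshold.  Optional features place a
pair of lineages at a configurable "doubtful" divergence with a shared
morphospecies label and identical-or-divergent ITS2, and spread one label
over several lineages to emulate cryptic complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from barcodelim.io import Dataset, SpecimenRecord, write_fasta, write_metadata

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DoubtfulPairConfig:
    """Place the last two lineages at a target link divergence.

    Both lineages receive ``label`` as morphospecies, emulating a split
    with no morphological support; their members get ITS2 sequences that
    are byte-identical (``its2_identical=True``) or diverged by
    ``its2_divergence``.
    """

    target_divergence: float = 0.12
    label: str = "doubtful sp"
    its2_identical: bool = True
    its2_divergence: float = 0.05
    its2_length: int = 300
    #: realized-link acceptance half-width around the target (see module docs)
    link_tolerance: float = 0.01
    max_tries: int = 2000


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the seed is mandatory (no implicit randomness)."""

    seed: int
    n_lineages: int = 5
    members_per_lineage: int | Sequence[int] = 4
    seq_length: int = 658
    kappa: float = 2.0
    intra_depth: float = 0.02
    inter_depth: float = 0.18
    doubtful_pair: DoubtfulPairConfig | None = None
    cryptic_labels: Mapping[str, int] | None = None
    genus_assignment: Mapping[int, str] | None = None

    def member_counts(self) -> list[int]:
        if isinstance(self.members_per_lineage, int):
            return [self.members_per_lineage] * self.n_lineages
        counts = list(self.members_per_lineage)
        if len(counts) != self.n_lineages:
            raise ValueError("members_per_lineage list length != n_lineages")
        return counts

    def __post_init__(self) -> None:
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if not 0 < self.intra_depth < self.inter_depth:
            raise ValueError("require 0 < intra_depth < inter_depth")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.doubtful_pair is not None:
            if self.n_lineages < 2:
                raise ValueError("doubtful pair needs n_lineages >= 2")
            if self.doubtful_pair.target_divergence <= self.intra_depth:
                raise ValueError(
                    "doubtful target divergence must exceed intra_depth"
                )


@dataclass
class TruthRecord:
    """Generating truth for a simulated dataset."""

    true_partition: dict[str, int]
    true_labels: dict[str, str]
    lineage_depths: dict[int, float] = field(default_factory=dict)


def transition_probs(distance: float, kappa: float) -> tuple[float, float, float]:
    """Exact K2P site-substitution probabilities after ``distance``
    expected substitutions per site.

    Returns ``(p_same, p_transition, p_each_transversion)``; the two
    transversion targets are equiprobable.  Derived from the closed-form
    exponential of the two-parameter rate generator with the transition
    rate ``kappa`` times each transversion rate, scaled so the expected
    number of substitutions per site equals ``distance``.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    beta_t = distance / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e1 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * (alpha_t + beta_t))
    p_tv = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 1.0 - p_ts - 2.0 * p_tv
    return float(p_same), float(p_ts), float(p_tv)


def evolve(seq: str, distance: float, kappa: float, rng: np.random.Generator) -> str:
    """Mutate every site independently under the exact K2P process.

    With codes A=0, C=1, G=2, T=3, the transition partner of ``x`` is
    ``(x+2) % 4`` and its transversion partners ``(x+1) % 4`` and
    ``(x+3) % 4``.
    """
    p_same, p_ts, p_tv = transition_probs(distance, kappa)
    codes = np.array([_code(ch) for ch in seq], dtype=np.int64)
    u = rng.random(len(codes))
    out = codes.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    out[ts_mask] = (codes[ts_mask] + 2) % 4
    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    out[tv1_mask] = (codes[tv1_mask] + 1) % 4
    tv2_mask = u >= p_same + p_ts + p_tv
    out[tv2_mask] = (codes[tv2_mask] + 3) % 4
    return "".join(_BASES[out])


def _code(ch: str) -> int:
    try:
        return "ACGT".index(ch)
    except ValueError:
        raise ValueError(f"cannot evolve non-ACGT character {ch!r}") from None


def random_root(length: int, rng: np.random.Generator) -> str:
    """Uniform A/C/G/T root (the stationary distribution of the process)."""
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _lineage_labels(config: SimConfig) -> list[str]:
    """Morphospecies label per lineage index, honouring cryptic complexes
    and the doubtful-pair shared label."""
    labels = [f"sp{i + 1:02d}" for i in range(config.n_lineages)]
    i = 0
    for label, n_shared in (config.cryptic_labels or {}).items():
        if i + n_shared > config.n_lineages:
            raise ValueError("cryptic_labels demand more lineages than configured")
        for j in range(n_shared):
            labels[i + j] = label
        i += n_shared
    if config.doubtful_pair is not None:
        labels[-1] = config.doubtful_pair.label
        labels[-2] = config.doubtful_pair.label
    return labels


def _doubtful_tips(
    sub_ancestor: str,
    n_a: int,
    n_b: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]]:
    """Tips for the doubtful lineage pair, conditioned on the realized link.

    The single-link distance between the lineages is the *minimum* over all
    cross pairs, so placing the two ancestors at
    ``(target - intra_depth) / 2`` from the shared sub-ancestor makes the
    link undershoot the target on average.  The pair is therefore redrawn
    until the realized minimum cross K2P distance falls within
    ``link_tolerance`` of the target — the scenario states a link
    divergence, and the generator delivers exactly that.
    """
    from barcodelim.distances import cross_distances

    doubtful = config.doubtful_pair
    assert doubtful is not None
    half_split = (doubtful.target_divergence - config.intra_depth) / 2.0
    for _ in range(doubtful.max_tries):
        anc_a = evolve(sub_ancestor, half_split, config.kappa, rng)
        anc_b = evolve(sub_ancestor, half_split, config.kappa, rng)
        tips_a = [evolve(anc_a, config.intra_depth / 2.0, config.kappa, rng)
                  for _ in range(n_a)]
        tips_b = [evolve(anc_b, config.intra_depth / 2.0, config.kappa, rng)
                  for _ in range(n_b)]
        link = float(cross_distances(tips_a, tips_b).min())
        if abs(link - doubtful.target_divergence) <= doubtful.link_tolerance:
            return tips_a, tips_b
    raise RuntimeError(
        f"could not realize a doubtful link within {doubtful.link_tolerance} "
        f"of {doubtful.target_divergence} in {doubtful.max_tries} tries; "
        "the configuration is likely unreachable"
    )


def simulate_dataset(config: SimConfig) -> tuple[Dataset, TruthRecord]:
    """Generate a dataset plus its generating truth.

    Deterministic for a fixed config (including seed).  When a doubtful
    pair is requested, the last two lineages share a sub-ancestor placed
    so that the expected tip-to-tip divergence across them equals the
    configured target, carry the same morphospecies label, and emit ITS2.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.member_counts()
    labels = _lineage_labels(config)
    genus_of = dict(config.genus_assignment or {})
    root = random_root(config.seq_length, rng)

    # tips per lineage
    doubtful = config.doubtful_pair
    n_regular = config.n_lineages - (2 if doubtful is not None else 0)
    tips_by_lineage: list[list[str]] = []
    for li in range(n_regular):
        ancestor = evolve(root, config.inter_depth / 2.0, config.kappa, rng)
        tips_by_lineage.append(
            [evolve(ancestor, config.intra_depth / 2.0, config.kappa, rng)
             for _ in range(counts[li])]
        )
    if doubtful is not None:
        sub_ancestor = evolve(root, config.inter_depth / 2.0, config.kappa, rng)
        tips_a, tips_b = _doubtful_tips(
            sub_ancestor, counts[-2], counts[-1], config, rng
        )
        tips_by_lineage.extend([tips_a, tips_b])

    its2_root = ""
    its2_other = ""
    if doubtful is not None:
        its2_root = random_root(doubtful.its2_length, rng)
        its2_other = (
            its2_root
            if doubtful.its2_identical
            else evolve(its2_root, doubtful.its2_divergence, config.kappa, rng)
        )

    specimens: list[SpecimenRecord] = []
    partition: dict[str, int] = {}
    true_labels: dict[str, str] = {}
    counter = 0
    for li in range(config.n_lineages):
        for tip in tips_by_lineage[li]:
            counter += 1
            sid = f"S{counter:03d}"
            its2 = ""
            if doubtful is not None and li >= config.n_lineages - 2:
                its2 = its2_root if li == config.n_lineages - 2 else its2_other
            specimens.append(
                SpecimenRecord(
                    specimen_id=sid,
                    coi_seq=tip,
                    its2_seq=its2,
                    genus=genus_of.get(li, ""),
                    morphospecies=labels[li],
                    higher_taxon="simulated",
                    mature=True,
                    site="in silico",
                )
            )
            partition[sid] = li
            true_labels[sid] = labels[li]

    marker_lengths = {"COI": config.seq_length}
    if doubtful is not None:
        marker_lengths["ITS2"] = doubtful.its2_length
    dataset = Dataset(specimens=specimens, marker_lengths=marker_lengths)
    truth = TruthRecord(
        true_partition=partition,
        true_labels=true_labels,
        lineage_depths={i: config.inter_depth / 2.0 for i in range(config.n_lineages)},
    )
    return dataset, truth


def write_fixture(dataset: Dataset, truth: TruthRecord, outdir: str | Path) -> dict[str, Path]:
    """Emit the standard pipeline inputs: per-marker FASTA, metadata table
    and a truth table, so fixtures and tutorials share one path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    coi = dataset.sequences("COI")
    paths["coi"] = outdir / "coi.fasta"
    write_fasta(coi, paths["coi"])
    its2 = dataset.sequences("ITS2")
    if its2:
        paths["its2"] = outdir / "its2.fasta"
        write_fasta(its2, paths["its2"])
    paths["metadata"] = outdir / "metadata.tsv"
    write_metadata(dataset.specimens, paths["metadata"])
    paths["truth"] = outdir / "truth.tsv"
    with paths["truth"].open("w") as fh:
        fh.write("specimen_id\ttrue_lineage\ttrue_label\n")
        for sid, li in truth.true_partition.items():
            fh.write(f"{sid}\t{li}\t{truth.true_labels[sid]}\n")
    return paths
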