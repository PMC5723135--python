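"""Threshold clustering, doubtful-zone handling and lineage statistics."""

import numpy as np
import pytest

from barcodelim.delimitation import (
    DoubtfulPair,
    ThresholdPolicy,
    apply_policy,
    detect_doubtful,
    finalize,
    lineage_stats,
    resolve_doubtful,
    single_linkage_partition,
)

from conftest import make_dataset, make_dm, oracle_closure, random_symmetric_dm


def blocks_as_sets(blocks):
    return {frozenset(b) for b in blocks}


class TestSingleLinkage:
    def test_chaining(self):
        dm = make_dm(["a", "b", "c"], {("a", "b"): 0.02, ("b", "c"): 0.02,
                                       ("a", "c"): 0.04})
        assert blocks_as_sets(single_linkage_partition(dm, 0.03)) == {
            frozenset({"a", "b", "c"})
        }

    def test_all_singletons_below_every_link(self):
        dm = make_dm(["a", "b", "c"], {("a", "b"): 0.02, ("b", "c"): 0.02,
                                       ("a", "c"): 0.04})
        assert blocks_as_sets(single_linkage_partition(dm, 0.01)) == {
            frozenset({"a"}), frozenset({"b"}), frozenset({"c"})
        }

    def test_threshold_is_inclusive(self):
        dm = make_dm(["a", "b"], {("a", "b"): 0.10})
        assert blocks_as_sets(single_linkage_partition(dm, 0.10)) == {
            frozenset({"a", "b"})
        }

    def test_saturated_pairs_never_link(self):
        dm = make_dm(["a", "b"], {("a", "b"): np.inf})
        assert len(single_linkage_partition(dm, 0.99)) == 2

    def test_matches_brute_force_closure(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            dm = random_symmetric_dm(rng, n, p_inf=0.1)
            t = float(rng.random() * 0.3)
            got = blocks_as_sets(single_linkage_partition(dm, t))
            assert got == oracle_closure(dm.ids, dm.d, t)

    def test_refinement_monotonicity(self, rng):
        """partition at t1 <= t2 refines partition at t2."""
        for _ in range(30):
            dm = random_symmetric_dm(rng, int(rng.integers(3, 9)))
            t1, t2 = sorted(rng.random(2) * 0.3)
            fine = single_linkage_partition(dm, float(t1))
            coarse = blocks_as_sets(single_linkage_partition(dm, float(t2)))
            for block in fine:
                assert any(frozenset(block) <= big for big in coarse)

    def test_complete_linkage_option(self):
        # chain a-b-c links under single but not complete linkage at 0.03
        dm = make_dm(["a", "b", "c"], {("a", "b"): 0.02, ("b", "c"): 0.02,
                                       ("a", "c"): 0.05})
        single = blocks_as_sets(single_linkage_partition(dm, 0.03))
        complete = blocks_as_sets(
            single_linkage_partition(dm, 0.03, method="complete")
        )
        assert single == {frozenset({"a", "b", "c"})}
        assert frozenset({"a", "b", "c"}) not in complete


class TestThresholdPolicy:
    def test_defaults(self):
        p = ThresholdPolicy()
        assert p.default_threshold == 0.10
        assert p.genus_overrides == {"Nais": 0.08, "Uncinais": 0.08}
        assert p.doubtful_zone == (0.10, 0.135)

    @pytest.mark.parametrize("kwargs", [
        {"default_threshold": 0.0},
        {"default_threshold": 1.5},
        {"doubtful_zone": (0.2, 0.1)},
        {"secondary_merge_tolerance": -0.1},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ThresholdPolicy(**kwargs)


class TestApplyPolicy:
    def _two_groups(self, genus, gap=0.085):
        ds = make_dataset([
            ("a1", "ACGT", genus, "sp1"), ("a2", "ACGT", genus, "sp1"),
            ("b1", "ACGT", genus, "sp2"), ("b2", "ACGT", genus, "sp2"),
        ])
        dm = make_dm(
            ["a1", "a2", "b1", "b2"],
            {("a1", "a2"): 0.01, ("b1", "b2"): 0.01,
             ("a1", "b1"): gap, ("a1", "b2"): gap,
             ("a2", "b1"): gap, ("a2", "b2"): gap},
        )
        return ds, dm

    def test_override_genus_splits_at_lower_threshold(self):
        ds, dm = self._two_groups("Nais")
        lineages = apply_policy(dm, ds, ThresholdPolicy())
        assert len(lineages) == 2

    def test_plain_genus_merges_at_default(self):
        ds, dm = self._two_groups("Tubifex")
        lineages = apply_policy(dm, ds, ThresholdPolicy())
        assert len(lineages) == 1

    def test_empty_overrides_degenerate_to_plain_partition(self):
        ds, dm = self._two_groups("Nais")
        policy = ThresholdPolicy(genus_overrides={})
        lineages = apply_policy(dm, ds, policy)
        expected = blocks_as_sets(single_linkage_partition(dm, 0.10))
        assert {frozenset(m) for m in lineages.lineages.values()} == expected

    def test_partition_property(self, rng):
        dm = random_symmetric_dm(rng, 8)
        ds = make_dataset([(sid, "ACGT", "Nais" if i % 2 else "", "")
                           for i, sid in enumerate(dm.ids)])
        lineages = apply_policy(dm, ds, ThresholdPolicy())
        members = sorted(m for ms in lineages.lineages.values() for m in ms)
        assert members == sorted(dm.ids)

    def test_input_order_invariance(self, rng):
        dm = random_symmetric_dm(rng, 7)
        ds = make_dataset([(sid, "ACGT", "", "") for sid in dm.ids])
        lineages = apply_policy(dm, ds, ThresholdPolicy())
        perm = list(rng.permutation(len(dm)))
        dm2 = dm.subset([dm.ids[i] for i in perm])
        ds2 = make_dataset([(sid, "ACGT", "", "") for sid in dm2.ids])
        lineages2 = apply_policy(dm2, ds2, ThresholdPolicy())
        # same blocks AND same canonical ids, regardless of input order
        assert {k: sorted(v) for k, v in lineages.lineages.items()} == \
               {k: sorted(v) for k, v in lineages2.lineages.items()}


class TestLineageStats:
    def test_exhaustive_scan_oracle(self, rng):
        dm = random_symmetric_dm(rng, 8)
        ds = make_dataset([(sid, "ACGT", "", f"sp{i % 3}")
                           for i, sid in enumerate(dm.ids)])
        lineages = apply_policy(dm, ds, ThresholdPolicy(default_threshold=0.15))
        lineages = lineage_stats(lineages, dm, ds)
        for lid, members in lineages.lineages.items():
            st = lineages.stats[lid]
            others = [i for i in dm.ids if i not in members]
            if len(members) > 1:
                expected_intra = max(
                    dm.get(a, b) for a in members for b in members if a < b
                )
                assert st.max_intra == pytest.approx(expected_intra)
            else:
                assert st.max_intra is None
            if others:
                expected_inter = min(dm.get(a, b) for a in members for b in others)
                assert st.min_inter == pytest.approx(expected_inter)

    def test_singleton_nc_and_single_lineage_na(self):
        ds = make_dataset([("a", "ACGT", "", "sp1")])
        dm = make_dm(["a"], {})
        lineages = apply_policy(dm, ds, ThresholdPolicy())
        lineages = lineage_stats(lineages, dm, ds)
        st = lineages.stats["L01"]
        assert st.max_intra is None and st.min_inter is None

    def test_morpho_identified_requires_label_and_maturity(self):
        ds = make_dataset([
            ("a", "ACGT", "", "sp1", "", True),
            ("b", "ACGT", "", "sp1", "", False),   # immature
            ("c", "ACGT", "", "", "", True),       # unlabelled
        ])
        dm = make_dm(["a", "b", "c"], {("a", "b"): 0.0, ("a", "c"): 0.0,
                                       ("b", "c"): 0.0})
        lineages = lineage_stats(apply_policy(dm, ds, ThresholdPolicy()), dm, ds)
        assert lineages.stats["L01"].n_specimens == 3
        assert lineages.stats["L01"].n_morpho_identified == 1


class TestDoubtfulZone:
    def _scenario(self, link, label_a="Limnodrilus udekemianus",
                  label_b="Limnodrilus udekemianus"):
        ds = make_dataset([
            ("a1", "ACGT", "Limnodrilus", label_a),
            ("a2", "ACGT", "Limnodrilus", label_a),
            ("b1", "ACGT", "Limnodrilus", label_b),
        ])
        dm = make_dm(["a1", "a2", "b1"],
                     {("a1", "a2"): 0.02, ("a1", "b1"): link,
                      ("a2", "b1"): link + 0.01})
        policy = ThresholdPolicy()
        lineages = lineage_stats(apply_policy(dm, ds, policy), dm, ds)
        return ds, dm, policy, lineages

    def test_shared_label_in_zone_is_doubtful(self):
        ds, dm, policy, lineages = self._scenario(0.107)
        pairs = detect_doubtful(lineages, dm, ds, policy)
        assert len(pairs) == 1
        assert pairs[0].link_distance == pytest.approx(0.107)
        assert not pairs[0].morphologically_distinct

    def test_distinct_labels_not_doubtful(self):
        ds, dm, policy, lineages = self._scenario(0.12, label_b="Tubifex tubifex")
        assert detect_doubtful(lineages, dm, ds, policy) == []

    def test_outside_zone_not_doubtful(self):
        ds, dm, policy, lineages = self._scenario(0.14)
        assert detect_doubtful(lineages, dm, ds, policy) == []

    def test_all_unlabelled_is_doubtful(self):
        ds, dm, policy, lineages = self._scenario(0.12, label_a="", label_b="")
        assert len(detect_doubtful(lineages, dm, ds, policy)) == 1

    def test_zone_lower_bound_exclusive(self):
        # exactly 10% links at the threshold already; the zone is (low, high]
        ds, dm, policy, lineages = self._scenario(0.1349)
        assert len(detect_doubtful(lineages, dm, ds, policy)) == 1


class TestResolveAndFinalize:
    def _with_its2(self, its2_cross):
        ds = make_dataset([
            ("a1", "ACGT", "", "spX", "AAAA"),
            ("b1", "ACGT", "", "spX", "AAAA"),
        ])
        dm = make_dm(["a1", "b1"], {("a1", "b1"): 0.107})
        sdm = make_dm(["a1", "b1"], {("a1", "b1"): its2_cross})
        policy = ThresholdPolicy()
        lineages = lineage_stats(apply_policy(dm, ds, policy), dm, ds)
        pairs = detect_doubtful(lineages, dm, ds, policy)
        assert len(pairs) == 1
        return ds, dm, sdm, policy, lineages, pairs[0]

    def test_identical_its2_merges(self):
        ds, dm, sdm, policy, lineages, pair = self._with_its2(0.0)
        resolved = resolve_doubtful(pair, lineages, sdm, policy)
        assert resolved.resolution == "merged"
        assert "identical" in resolved.evidence
        final = finalize(lineages, [resolved], dm, ds)
        assert len(final) == len(lineages) - 1

    def test_divergent_its2_keeps_separate(self):
        ds, dm, sdm, policy, lineages, pair = self._with_its2(0.04)
        resolved = resolve_doubtful(pair, lineages, sdm, policy)
        assert resolved.resolution == "kept_separate"
        final = finalize(lineages, [resolved], dm, ds)
        assert len(final) == len(lineages)

    def test_missing_secondary_is_unresolved(self):
        ds, dm, sdm, policy, lineages, pair = self._with_its2(0.0)
        resolved = resolve_doubtful(pair, lineages, None, policy)
        assert resolved.resolution == "unresolved"
        assert "no secondary marker" in resolved.evidence

    def test_tolerance_configurable(self):
        ds, dm, sdm, policy, lineages, pair = self._with_its2(0.005)
        tolerant = ThresholdPolicy(secondary_merge_tolerance=0.01)
        assert resolve_doubtful(pair, lineages, sdm, tolerant).resolution == "merged"

    def test_transitive_merge_chain(self):
        ds = make_dataset([
            ("a1", "ACGT", "", "spX"), ("b1", "ACGT", "", "spX"),
            ("c1", "ACGT", "", "spX"),
        ])
        dm = make_dm(["a1", "b1", "c1"],
                     {("a1", "b1"): 0.11, ("b1", "c1"): 0.11, ("a1", "c1"): 0.13})
        policy = ThresholdPolicy()
        lineages = lineage_stats(apply_policy(dm, ds, policy), dm, ds)
        assert len(lineages) == 3
        merged = [
            DoubtfulPair("L01", "L02", 0.11, False, "merged", "ITS2 identical"),
            DoubtfulPair("L02", "L03", 0.11, False, "merged", "ITS2 identical"),
        ]
        final = finalize(lineages, merged, dm, ds)
        assert len(final) == 1

    def test_no_resolutions_is_identity(self):
        ds = make_dataset([("a1", "ACGT", "", ""), ("b1", "ACGT", "", "")])
        dm = make_dm(["a1", "b1"], {("a1", "b1"): 0.2})
        lineages = lineage_stats(apply_policy(dm, ds, ThresholdPolicy()), dm, ds)
        final = finalize(lineages, [], dm, ds)
        assert final.lineages == lineages.lineages

    def test_provenance_records_decisions(self):
        ds, dm, sdm, policy, lineages, pair = self._with_its2(0.0)
        resolved = resolve_doubtful(pair, lineages, sdm, policy)
        final = finalize(lineages, [resolved], dm, ds)
        assert any("ITS2" in line for line in final.provenance)
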