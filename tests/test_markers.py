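"""Cross-mode pairing, marker status judgement, and signature categories."""

import pytest

from formulanet.annotation import PROTON, AnchorPoint, AnnotationCandidate
from formulanet.elsd import ElsdAssignment
from formulanet.io import FeatureTable
from formulanet.markers import (
    STATUS_NON_SPECIFIC,
    STATUS_NON_SPECIFIC_RETAINED,
    STATUS_NOT_IN_FORMULA,
    STATUS_SPECIFIC,
    classify_signature_clusters,
    extract_signature,
    pair_cross_mode,
    select_markers,
)
from formulanet.network import MolecularNetwork, SpectralEdge
from formulanet.specificity import (
    ConfigurationError,
    SpecificityParams,
    cluster_specificity,
    compute_specificity,
)

from conftest import make_feature


def tables_for(small_manifest, pi_rows, ni_rows):
    zeros = {s: 0.0 for s in small_manifest.sample_ids}
    pi = FeatureTable("PI", [make_feature(fid, mz, rt, {**zeros, "F": 1.0, **h})
                             for fid, mz, rt, h in pi_rows])
    ni = FeatureTable("NI", [make_feature(fid, mz, rt, {**zeros, "F": 1.0, **h})
                             for fid, mz, rt, h in ni_rows])
    spec_pi = compute_specificity(pi, small_manifest)
    spec_ni = compute_specificity(ni, small_manifest)
    return pi, spec_pi, ni, spec_ni


class TestPairCrossMode:
    def test_proton_arithmetic_pairs(self, small_manifest):
        # [M+H]+ 303.0499 and [M-H]- 301.0354 both imply neutral ~302.0427
        pi, spec_pi, ni, spec_ni = tables_for(
            small_manifest,
            [(1, 303.0499, 5.0, {"hA": 10.0})],
            [(11, 301.0354, 5.0, {"hA": 10.0})])
        pairs = pair_cross_mode(pi, spec_pi, ni, spec_ni)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.feature_id_pi, p.feature_id_ni) == (1, 11)
        assert abs(p.neutral_mass_delta_ppm) < 10.0
        # oracle: explicit proton-mass arithmetic
        assert (303.0499 - PROTON) - (301.0354 + PROTON) == pytest.approx(
            (p.neutral_mass_delta_ppm * 1e-6) * (301.0354 + PROTON), abs=1e-6)

    def test_rt_apart_unpaired(self, small_manifest):
        pi, spec_pi, ni, spec_ni = tables_for(
            small_manifest,
            [(1, 303.0499, 5.0, {"hA": 10.0})],
            [(11, 301.0354, 5.5, {"hA": 10.0})])
        assert pair_cross_mode(pi, spec_pi, ni, spec_ni, rt_tol=0.1) == []

    def test_empty_ni_all_unpaired(self, small_manifest):
        pi, spec_pi, ni, spec_ni = tables_for(
            small_manifest, [(1, 303.0499, 5.0, {"hA": 10.0})], [])
        assert pair_cross_mode(pi, spec_pi, ni, spec_ni) == []

    def test_one_to_one_by_distance(self, small_manifest):
        # two NI features both mass-compatible; the closer RT wins
        pi, spec_pi, ni, spec_ni = tables_for(
            small_manifest,
            [(1, 303.0499, 5.00, {"hA": 10.0})],
            [(11, 301.0354, 5.04, {"hA": 10.0}),
             (12, 301.0354, 5.01, {"hA": 10.0})])
        pairs = pair_cross_mode(pi, spec_pi, ni, spec_ni)
        assert [(p.feature_id_pi, p.feature_id_ni) for p in pairs] == [(1, 12)]


class TestSelectMarkers:
    def _assignment(self, label="A1", herb="A", fid_pi=1, fid_ni=11, area=0.05):
        return ElsdAssignment(label, herb, 5.0, area,
                              feature_id_pi=fid_pi, feature_id_ni=fid_ni)

    def test_specific_both_modes(self, small_manifest):
        _, spec_pi, _, spec_ni = tables_for(
            small_manifest,
            [(1, 303.0, 5.0, {"hA": 10.0})],
            [(11, 301.0, 5.0, {"hA": 10.0})])
        out = select_markers([self._assignment()], spec_pi, spec_ni)
        assert out[0].status == STATUS_SPECIFIC
        assert out[0].min_share == pytest.approx(100.0)
        assert not out[0].single_mode

    def test_ubiquitous_feature_non_specific(self, small_manifest):
        # spread across herbs like a common amino acid
        _, spec_pi, _, spec_ni = tables_for(
            small_manifest,
            [(1, 175.1, 0.5, {"hA": 5.0, "hB": 4.0, "hC": 4.0})],
            [(11, 173.1, 0.5, {"hA": 5.0, "hB": 4.0, "hC": 4.0})])
        out = select_markers([self._assignment(label="I1", herb="A")], spec_pi, spec_ni)
        assert out[0].status == STATUS_NON_SPECIFIC

    def test_unmatched_is_not_in_formula(self, small_manifest):
        _, spec_pi, _, spec_ni = tables_for(small_manifest, [], [])
        a = ElsdAssignment("A1", "A", 5.0, 0.05)
        out = select_markers([a], spec_pi, spec_ni)
        assert out[0].status == STATUS_NOT_IN_FORMULA

    def test_single_mode_judged_and_flagged(self, small_manifest):
        _, spec_pi, _, spec_ni = tables_for(
            small_manifest, [(1, 303.0, 5.0, {"hA": 10.0})], [])
        a = ElsdAssignment("A1", "A", 5.0, 0.05, feature_id_pi=1)
        out = select_markers([a], spec_pi, spec_ni)
        assert out[0].status == STATUS_SPECIFIC
        assert out[0].single_mode

    def test_min_share_is_worst_mode(self, small_manifest):
        _, spec_pi, _, spec_ni = tables_for(
            small_manifest,
            [(1, 303.0, 5.0, {"hA": 94.0, "hB": 6.0})],
            [(11, 301.0, 5.0, {"hA": 83.0, "hB": 17.0})])
        out = select_markers([self._assignment()], spec_pi, spec_ni)
        assert out[0].min_share == pytest.approx(83.0)
        assert out[0].status == STATUS_NON_SPECIFIC

    def test_lowering_threshold_never_removes_specific(self, small_manifest):
        _, spec_pi, _, spec_ni = tables_for(
            small_manifest,
            [(1, 303.0, 5.0, {"hA": 92.0, "hB": 8.0})],
            [(11, 301.0, 5.0, {"hA": 95.0, "hB": 5.0})])
        a = [self._assignment()]
        for lo, hi in [(50.0, 90.0), (70.0, 92.0)]:
            hi_set = {m.elsd_label for m in select_markers(
                a, spec_pi, spec_ni, SpecificityParams(node_threshold=hi))
                if m.status == STATUS_SPECIFIC}
            lo_set = {m.elsd_label for m in select_markers(
                a, spec_pi, spec_ni, SpecificityParams(node_threshold=lo))
                if m.status == STATUS_SPECIFIC}
            assert hi_set <= lo_set

    def test_abundance_override_retains_top_peaks(self, small_manifest):
        """A sub-threshold but most-abundant peak is labeled retained, not
        silently specific (the SC1/SC2 situation)."""
        _, spec_pi, _, spec_ni = tables_for(
            small_manifest,
            [(1, 303.0, 5.0, {"hA": 85.0, "hB": 15.0}),
             (2, 353.0, 7.0, {"hA": 80.0, "hB": 20.0})],
            [])
        a = [ElsdAssignment("A1", "A", 5.0, 0.4, feature_id_pi=1),
             ElsdAssignment("A2", "A", 7.0, 0.01, feature_id_pi=2)]
        out = select_markers(a, spec_pi, spec_ni, abundance_override_top_n=1)
        by_label = {m.elsd_label: m.status for m in out}
        assert by_label["A1"] == STATUS_NON_SPECIFIC_RETAINED
        assert by_label["A2"] == STATUS_NON_SPECIFIC


def two_cluster_network():
    return MolecularNetwork(
        "PI", [1, 2, 3, 4, 5, 6],
        [SpectralEdge(1, 2, 0.9, 7), SpectralEdge(2, 3, 0.9, 7),
         SpectralEdge(4, 5, 0.9, 7), SpectralEdge(5, 6, 0.9, 7)],
        {1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2},
    )


class TestSignatureClusters:
    def _setup(self, small_manifest, rows):
        zeros = {s: 0.0 for s in small_manifest.sample_ids}
        table = FeatureTable("PI", [
            make_feature(fid, 300.0 + fid, rt, {**zeros, "F": fh, **h})
            for fid, rt, fh, h in rows])
        spec = compute_specificity(table, small_manifest)
        net = two_cluster_network()
        ct = cluster_specificity(spec, net)
        return table, spec, net, ct

    def test_category_1_specific_cluster_with_anchor(self, small_manifest):
        rows = [(f, float(f), 1.0, {"hA": 10.0}) for f in (1, 2, 3)] + \
               [(f, float(f), 1.0, {"hB": 10.0}) for f in (4, 5, 6)]
        table, spec, net, ct = self._setup(small_manifest, rows)
        anchor = AnchorPoint(1, "A1", "", "A", "classX")
        sigs = classify_signature_clusters(ct, net, [anchor], spec)
        assert len(sigs) == 1
        assert (sigs[0].cluster_id, sigs[0].category, sigs[0].herb_code) == (1, 1, "A")
        assert sigs[0].anchor_ids == [1]

    def test_category_2_mixed_cluster_extracts_specific_subnodes(self, small_manifest):
        # cluster 1 averages ~68.9% for A -> not dominant; anchor inside
        rows = [(1, 1.0, 1.0, {"hA": 10.0}),
                (2, 2.0, 1.0, {"hA": 689.0, "hB": 311.0}),
                (3, 3.0, 1.0, {"hA": 3.78, "hB": 6.22}),
                (4, 4.0, 1.0, {"hB": 10.0}), (5, 5.0, 1.0, {"hB": 10.0}),
                (6, 6.0, 1.0, {"hB": 10.0})]
        table, spec, net, ct = self._setup(small_manifest, rows)
        assert ct.get(1).dominant_herb is None
        anchor = AnchorPoint(1, "PR1", "", "A", "classY")
        sigs = classify_signature_clusters(ct, net, [anchor], spec)
        sig1 = next(s for s in sigs if s.cluster_id == 1)
        assert sig1.category == 2
        assert sig1.member_ids == [1]  # only the >=90% node for herb A

    def test_category_3_specific_cluster_taxonomic_annotation(self, small_manifest):
        rows = [(f, float(f), 1.0, {"hA": 10.0}) for f in (1, 2, 3)] + \
               [(f, float(f), 1.0, {"hA": 1.0, "hB": 1.0, "hC": 1.0}) for f in (4, 5, 6)]
        table, spec, net, ct = self._setup(small_manifest, rows)
        cands = {2: [AnnotationCandidate(2, "e", "x", 0.5, 1, taxon_level="species")]}
        sigs = classify_signature_clusters(ct, net, [], spec, candidates=cands)
        assert [(s.cluster_id, s.category) for s in sigs] == [(1, 3)]

    def test_specific_cluster_without_anchor_or_annotation_omitted(self, small_manifest):
        rows = [(f, float(f), 1.0, {"hA": 10.0}) for f in (1, 2, 3)] + \
               [(f, float(f), 1.0, {"hA": 1.0, "hB": 1.0, "hC": 1.0}) for f in (4, 5, 6)]
        table, spec, net, ct = self._setup(small_manifest, rows)
        assert classify_signature_clusters(ct, net, [], spec) == []

    def test_unknown_anchor_raises(self, small_manifest):
        rows = [(f, float(f), 1.0, {"hA": 10.0}) for f in (1, 2, 3, 4, 5, 6)]
        table, spec, net, ct = self._setup(small_manifest, rows)
        bad = AnchorPoint(99, "ghost", "", "A", "")
        with pytest.raises(ConfigurationError, match="ghost"):
            classify_signature_clusters(ct, net, [bad], spec)

    def test_categories_deterministic_under_permutation(self, small_manifest):
        rows = [(1, 1.0, 1.0, {"hA": 10.0}), (2, 2.0, 1.0, {"hA": 10.0}),
                (3, 3.0, 1.0, {"hA": 10.0}), (4, 4.0, 1.0, {"hB": 10.0}),
                (5, 5.0, 1.0, {"hB": 10.0}), (6, 6.0, 1.0, {"hB": 10.0})]
        table, spec, net, ct = self._setup(small_manifest, rows)
        anchors = [AnchorPoint(1, "A1", "", "A", ""), AnchorPoint(4, "B1", "", "B", "")]
        s1 = classify_signature_clusters(ct, net, anchors, spec)
        s2 = classify_signature_clusters(ct, net, list(reversed(anchors)), spec)
        assert [(s.cluster_id, s.category, s.herb_code) for s in s1] == \
               [(s.cluster_id, s.category, s.herb_code) for s in s2]


class TestExtractSignature:
    def _cluster(self, members):
        from formulanet.markers import SignatureCluster

        return SignatureCluster(1, "A", 1, member_ids=members, anchor_ids=[])

    def test_same_rt_members_collapse_to_highest(self, small_manifest):
        zeros = {s: 0.0 for s in small_manifest.sample_ids}
        table = FeatureTable("PI", [
            make_feature(1, 300.0, 2.00, {**zeros, "F": 5.0, "hA": 1.0}),
            make_feature(2, 318.0, 2.01, {**zeros, "F": 9.0, "hA": 1.0}),
            make_feature(3, 400.0, 5.00, {**zeros, "F": 3.0, "hA": 1.0}),
        ])
        spec = compute_specificity(table, small_manifest)
        df = extract_signature(self._cluster([1, 2, 3]), spec, table, small_manifest)
        assert len(df) == 2
        assert df["height"].tolist() == [9.0, 3.0]  # max of the co-eluting pair, then 5.0 min

    def test_distinct_rts_identity(self, small_manifest):
        zeros = {s: 0.0 for s in small_manifest.sample_ids}
        table = FeatureTable("PI", [
            make_feature(f, 300.0 + f, float(f), {**zeros, "F": 1.0, "hA": 1.0})
            for f in (1, 2, 3, 4)])
        spec = compute_specificity(table, small_manifest)
        df = extract_signature(self._cluster([1, 2, 3, 4]), spec, table, small_manifest)
        assert df["feature_id"].tolist() == [1, 2, 3, 4]

    def test_at_least_one_bar_remains(self, small_manifest):
        zeros = {s: 0.0 for s in small_manifest.sample_ids}
        table = FeatureTable("PI", [
            make_feature(f, 300.0 + f, 2.0 + 0.001 * f, {**zeros, "F": float(f), "hA": 1.0})
            for f in (1, 2, 3)])
        spec = compute_specificity(table, small_manifest)
        df = extract_signature(self._cluster([1, 2, 3]), spec, table, small_manifest)
        assert len(df) == 1
        assert df["height"].iloc[0] == 3.0
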