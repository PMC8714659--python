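"""Pair intersection, curated cross-validation, correlation filtering and
network assembly."""

import numpy as np
import pandas as pd
import pytest

from cernet import (
    CuratedMiRNA,
    DEFAULT_CURATED,
    ExpressionMatrix,
    assemble_network,
    cross_validate,
    filter_correlation,
    intersect_pairs,
    pearson_r,
)
from cernet.errors import ConfigurationError, MissingFeatureError, ValidationError
from cernet.expression import DERecord
from cernet.network import CandidateTriple, match_curated
from cernet.targeting import TargetPair


def _pair(mirna, target, kind="lncRNA"):
    return TargetPair(mirna, target, kind, 1, "6mer")


class TestIntersectPairs:
    def test_disjoint_mirnas_empty(self):
        ce = [_pair("m1", "lnc1")]
        mr = [_pair("m2", "g1", "mRNA")]
        assert intersect_pairs(ce, mr) == []

    def test_product_count(self):
        ce = [_pair("m1", "lnc1"), _pair("m1", "circ1", "circRNA")]
        mr = [_pair("m1", f"g{i}", "mRNA") for i in range(3)]
        out = intersect_pairs(ce, mr)
        assert len(out) == 6
        assert out == sorted(out)

    def test_matches_nested_loop_join(self):
        rng = np.random.default_rng(3)
        ce = [
            _pair(f"m{rng.integers(4)}", f"lnc{rng.integers(6)}") for _ in range(15)
        ]
        mr = [
            _pair(f"m{rng.integers(4)}", f"g{rng.integers(6)}", "mRNA")
            for _ in range(15)
        ]
        got = set(intersect_pairs(ce, mr))
        want = {
            CandidateTriple(c.target_id, c.mirna_id, m.target_id)
            for c in ce
            for m in mr
            if c.mirna_id == m.mirna_id
        }
        assert got == want


class TestCrossValidate:
    def test_mature_arm_matches_curated_stem(self):
        cand = [CandidateTriple("lnc1", "hsa-miR-27b-3p", "FPR2")]
        assert cross_validate(cand, DEFAULT_CURATED) == cand

    def test_unlisted_mirna_removed(self):
        cand = [CandidateTriple("lnc1", "miR-999", "g1")]
        assert cross_validate(cand, DEFAULT_CURATED) == []

    def test_empty_curated_list_is_config_error(self):
        with pytest.raises(ConfigurationError):
            cross_validate([CandidateTriple("a", "b", "c")], [])

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("miR-21", "miR-21"),
            ("hsa-miR-21-5p", "miR-21"),
            ("MIR-146A", "miR-146a"),
            ("hsa-miR-27a-3p", "miR-27a"),
            ("miR-210", None),  # stem must match exactly, not by prefix
        ],
    )
    def test_name_matching_rules(self, name, expected):
        entry = match_curated(name, DEFAULT_CURATED)
        assert (entry.name if entry else None) == expected


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_first_principles_formula(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        mx, my = sum(x) / 6, sum(y) / 6
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sx = sum((a - mx) ** 2 for a in x) ** 0.5
        sy = sum((b - my) ** 2 for b in y) ** 0.5
        assert pearson_r(x, y) == pytest.approx(cov / (sx * sy), abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_is_error(self):
        with pytest.raises(ValidationError):
            pearson_r([1.0, 2.0], [3.0, 4.0])


def _expr_for(profiles: dict[str, list[float]]) -> ExpressionMatrix:
    values = pd.DataFrame(profiles).T
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    kinds = pd.Series(
        ["lncRNA" if f.startswith("lnc") else "mRNA" for f in values.index],
        index=values.index,
    )
    groups = pd.Series(
        ["case"] * 3 + ["control"] * (values.shape[1] - 3), index=values.columns
    )
    return ExpressionMatrix(values, kinds, groups)


def _de(fid, fc):
    return DERecord(fid, "mRNA", 0, 0, fc, 0, 0.0, is_de=True)


class TestFilterCorrelation:
    CURATED = [CuratedMiRNA("miR-1", "down")]

    def test_identical_vectors_kept(self):
        expr = _expr_for({"lnc1": [10, 11, 12, 8, 7, 6], "g1": [10, 11, 12, 8, 7, 6]})
        cands = [CandidateTriple("lnc1", "miR-1", "g1")]
        de = [_de("lnc1", 2.0), _de("g1", 2.0)]
        out = filter_correlation(cands, expr, de, self.CURATED)
        assert len(out) == 1 and out[0].r == pytest.approx(1.0)

    def test_sub_threshold_correlation_removed(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 3.0, 2.0, 5.5, 3.5, 6.0])
        assert 0.5 < pearson_r(x, y) < 0.95
        expr = _expr_for({"lnc1": list(x), "g1": list(y)})
        de = [_de("lnc1", 2.0), _de("g1", 2.0)]
        out = filter_correlation(
            [CandidateTriple("lnc1", "miR-1", "g1")], expr, de, self.CURATED
        )
        assert out == []

    def test_direction_consistency_rule(self):
        expr = _expr_for({"lnc1": [10, 11, 12, 8, 7, 6], "g1": [10, 11, 12, 8, 7, 6]})
        cands = [CandidateTriple("lnc1", "miR-1", "g1")]
        de_up = [_de("lnc1", 2.0), _de("g1", 2.0)]
        de_down = [_de("lnc1", -2.0), _de("g1", -2.0)]
        # curated miR-1 is down => ceRNA and mRNA must be up
        assert len(filter_correlation(cands, expr, de_up, self.CURATED)) == 1
        assert filter_correlation(cands, expr, de_down, self.CURATED) == []
        # with the rule off, the direction no longer matters
        assert (
            len(
                filter_correlation(
                    cands, expr, de_down, self.CURATED,
                    require_direction_consistency=False,
                )
            )
            == 1
        )

    def test_missing_member_raises_with_id(self):
        expr = _expr_for({"lnc1": [1, 2, 3, 4, 5, 6]})
        with pytest.raises(MissingFeatureError, match="g-missing"):
            filter_correlation(
                [CandidateTriple("lnc1", "miR-1", "g-missing")],
                expr,
                [],
                self.CURATED,
            )

    def test_raising_threshold_never_adds_triples(self):
        rng = np.random.default_rng(5)
        profiles = {}
        cands = []
        de = []
        base = rng.normal(0, 1, 6)
        for i in range(12):
            profiles[f"lnc{i}"] = list(base + rng.normal(0, 0.3, 6))
            profiles[f"g{i}"] = list(base + rng.normal(0, 0.3, 6))
            cands.append(CandidateTriple(f"lnc{i}", "miR-1", f"g{i}"))
            de += [_de(f"lnc{i}", 2.0), _de(f"g{i}", 2.0)]
        expr = _expr_for(profiles)
        counts = [
            len(filter_correlation(cands, expr, de, self.CURATED, r_threshold=r))
            for r in (0.0, 0.5, 0.9, 0.95, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAssembleNetwork:
    def _triple(self, c, m, g):
        from cernet import CeRNATriple

        return CeRNATriple(c, m, g, 0.99, "up", "up")

    def test_single_triple_three_nodes_two_edges(self):
        g = assemble_network([self._triple("lnc1", "miR-21", "g1")])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert g.nodes["miR-21"]["regulation"] == "up"  # curated direction
        assert g.nodes["lnc1"]["kind"] == "lncRNA"

    def test_shared_mirna_deduplicates(self):
        g = assemble_network(
            [
                self._triple("lnc1", "miR-21", "g1"),
                self._triple("lnc2", "miR-21", "g2"),
            ]
        )
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 4

    def test_every_edge_traces_to_a_triple(self):
        triples = [
            self._triple("lnc1", "miR-21", "g1"),
            self._triple("lnc1", "miR-21", "g2"),
        ]
        g = assemble_network(triples)
        keys = {t.key() for t in triples}
        for _, _, data in g.edges(data=True):
            assert set(data["triples"]) <= keys
        # shared ceRNA-miRNA edge carries both source triples
        assert len(g.edges["lnc1", "miR-21"]["triples"]) == 2

    def test_node_kind_counts_match_truth(self, zero_noise_dataset):
        _, expr, transcripts, truth = zero_noise_dataset
        kinds = {t.id: t.kind for t in transcripts}
        triples = [
            self._triple(c, m, g) for c, m, g in truth.planted_triples
        ]
        g = assemble_network(triples, kinds, curated=truth.curated_mirnas())
        got = {}
        for _, d in g.nodes(data=True):
            got[d["kind"]] = got.get(d["kind"], 0) + 1
        want_cerna_kinds = [kinds[c] for c, _, _ in truth.planted_triples]
        assert got["mRNA"] == len(truth.planted_triples)
        assert got["miRNA"] == len({m for _, m, _ in truth.planted_triples})
        assert got.get("lncRNA", 0) == want_cerna_kinds.count("lncRNA")
        assert got.get("circRNA", 0) == want_cerna_kinds.count("circRNA")
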