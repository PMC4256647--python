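"""RBH ortholog detection, site-to-column mapping, RCS_Y, class comparison."""

import math

import numpy as np
import pytest

from ptmcross import simulate as sim
from ptmcross.conservation import (
    ContractError,
    IntegrityError,
    OrthologGroup,
    build_groups,
    column_to_position,
    conservation_comparison,
    map_site_to_column,
    rcs_y,
    reciprocal_best_hits,
)
from ptmcross.io import BlastHit, ProteinRecord, read_newick_string


def _hit(q, s, bitscore, evalue=1e-30):
    return BlastHit(q, s, 90.0, 100, 1, 0, 1, 100, 1, 100, evalue, bitscore)


class TestReciprocalBestHits:
    def test_symmetric_one_to_one_recovered(self):
        fwd = [_hit("a1", "b1", 300), _hit("a2", "b2", 250)]
        rev = [_hit("b1", "a1", 300), _hit("b2", "a2", 250)]
        assert reciprocal_best_hits(fwd, rev) == [("a1", "b1"), ("a2", "b2")]

    def test_asymmetric_best_excluded(self):
        fwd = [_hit("a", "b", 300)]
        rev = [_hit("b", "a", 100), _hit("b", "a_prime", 200)]
        assert reciprocal_best_hits(fwd, rev) == []

    def test_tie_breaks_lexicographic_after_score_and_evalue(self):
        fwd = [_hit("a", "b2", 300), _hit("a", "b1", 300)]
        rev = [_hit("b1", "a", 300), _hit("b2", "a", 300)]
        assert reciprocal_best_hits(fwd, rev) == [("a", "b1")]

    def test_synthetic_proteomes_recovered_exactly(self, ortholog_bundle):
        hits = ortholog_bundle["hits"]
        n = len(ortholog_bundle["groups"])
        for sp, tables in hits.items():
            pairs = reciprocal_best_hits(tables["fwd"], tables["rev"])
            assert len(pairs) == n
            assert all(a.split("_")[0] == b.split("_")[0] for a, b in pairs)

    def test_build_groups_star_topology(self):
        rbh = {"MOUSE": [("h1", "m1"), ("h2", "m2")], "RAT": [("h1", "r1")]}
        groups = build_groups(rbh)
        assert groups["h1"] == {"MOUSE": "m1", "RAT": "r1"}
        assert groups["h2"] == {"MOUSE": "m2"}
        assert "h3" not in groups


def _group(rows: dict[str, str]) -> OrthologGroup:
    members = {
        sp: ProteinRecord(f"g_{sp}", seq, species=sp) for sp, seq in rows.items()
    }
    return OrthologGroup(f"g_HUMAN", "HUMAN", members)


class TestSiteToColumn:
    def test_gapless_alignment_is_identity(self):
        g = _group({"HUMAN": "MAYD", "MOUSE": "MAYD"})
        for pos in range(1, 5):
            assert map_site_to_column(g, pos) == pos

    def test_gapped_human_row(self):
        g = _group({"HUMAN": "M-AY", "MOUSE": "MKAY"})
        assert map_site_to_column(g, 3) == 4

    def test_position_beyond_length_raises(self):
        g = _group({"HUMAN": "M-AY", "MOUSE": "MKAY"})
        with pytest.raises(IntegrityError):
            map_site_to_column(g, 4)

    def test_round_trip_over_fixture_alignment(self, ortholog_bundle):
        group = ortholog_bundle["groups"][0]
        ungapped_len = len(group.anchor_row.replace("-", ""))
        for pos in range(1, ungapped_len + 1):
            assert column_to_position(group, map_site_to_column(group, pos)) == pos


@pytest.fixture(scope="module")
def species_tree():
    return read_newick_string(sim.SPECIES_TREE_NEWICK)


def _full_group(y_species, filler="A"):
    rows = {}
    for sp in sim.SPECIES:
        aa = "Y" if sp in y_species else "F"
        rows[sp] = filler * 3 + aa + filler * 3
    return _group(rows)


class TestRcsY:
    def test_tyrosine_in_all_species(self, species_tree):
        res = rcs_y(_full_group(set(sim.SPECIES)), 4, species_tree)
        assert (res.n_y, res.n, res.rcs) == (8, 8, 1.0)
        assert res.conserved and not res.degenerate

    def test_human_only_degenerate(self, species_tree):
        res = rcs_y(_full_group({"HUMAN"}), 4, species_tree)
        assert (res.n_y, res.n, res.rcs) == (1, 1, 1.0)
        assert res.degenerate

    def test_hand_walked_three_species_span(self, species_tree):
        # tyrosines in human, mouse, zebrafish: the MBL pair is
        # (DANRE, MOUSE) and its smallest clade is the root -> all 8 species
        res = rcs_y(_full_group({"HUMAN", "MOUSE", "DANRE"}), 4, species_tree)
        assert set(res.mbl_pair) == {"DANRE", "MOUSE"}
        assert (res.n_y, res.n) == (3, 8)
        assert res.rcs == pytest.approx(3 / 8)
        assert not res.conserved

    def test_mammal_only_span_excludes_outgroups(self, species_tree):
        # tyrosines in the five mammals only: MBL clade = mammal clade (5+1
        # human... the clade containing CANFA and MOUSE spans all 6 mammals)
        mammals = {"HUMAN", "MOUSE", "RAT", "CANFA", "BOVIN", "PIG"}
        res = rcs_y(_full_group(mammals), 4, species_tree)
        assert res.n == 6
        assert res.n_y == 6
        assert res.conserved

    def test_no_tyrosine_rejected(self, species_tree):
        with pytest.raises(ContractError):
            rcs_y(_full_group(set()), 4, species_tree)

    def test_non_tyrosine_anchor_rejected(self, species_tree):
        g = _group({sp: "AAAFAAA" if sp == "HUMAN" else "AAAYAAA" for sp in sim.SPECIES})
        with pytest.raises(ContractError):
            rcs_y(g, 4, species_tree)

    def test_invariant_to_member_ordering(self, species_tree):
        rows = {sp: "DEAYGLK" if sp in {"HUMAN", "DANRE", "RAT"} else "DEAFGLK"
                for sp in sim.SPECIES}
        g1 = _group(rows)
        g2 = _group(dict(reversed(list(rows.items()))))
        r1, r2 = rcs_y(g1, 4, species_tree), rcs_y(g2, 4, species_tree)
        assert (r1.n_y, r1.n, r1.rcs) == (r2.n_y, r2.n, r2.rcs)

    def test_threshold_monotonicity(self, ortholog_bundle):
        tree = ortholog_bundle["tree"]
        groups = ortholog_bundle["groups"][:30]
        counts = []
        for thr in (0.625, 0.75, 0.875, 1.0):
            conserved = 0
            for g in groups:
                row = g.anchor_row
                for col, aa in enumerate(row, start=1):
                    if aa == "Y" and rcs_y(g, col, tree, thr).conserved:
                        conserved += 1
            counts.append(conserved)
        assert counts == sorted(counts, reverse=True)


class TestConservationComparison:
    def test_identical_fractions_give_unit_ratio(self):
        res = conservation_comparison([True] * 5 + [False] * 5, [True] * 4 + [False] * 4)
        assert res.e_ratio == pytest.approx(1.0)

    def test_disjoint_extremes(self):
        res = conservation_comparison([True] * 10, [False] * 10)
        assert math.isinf(res.e_ratio)
        assert res.p_value == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    def test_empty_class_rejected(self):
        with pytest.raises(ContractError):
            conservation_comparison([], [True])

    def test_planted_rates_recovered(self, ortholog_bundle):
        tree = ortholog_bundle["tree"]
        by_anchor = {g.anchor: g for g in ortholog_bundle["groups"]}
        flags = {"modified": [], "unmodified": []}
        for site in ortholog_bundle["truth"]["sites"]:
            g = by_anchor[site["group"]]
            res = rcs_y(g, map_site_to_column(g, site["position"]), tree)
            flags[site["class"]].append(res.conserved)
        frac_mod = np.mean(flags["modified"])
        frac_unmod = np.mean(flags["unmodified"])
        assert abs(frac_mod - 0.8) <= 0.05
        assert abs(frac_unmod - 0.5) <= 0.05
        comp = conservation_comparison(flags["modified"], flags["unmodified"])
        assert abs(comp.e_ratio - 1.6) <= 0.1
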