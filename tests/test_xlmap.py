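"""Crosslink mapping: classification, homodimer detection, crosstabs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from condensekit import synthgen
from condensekit.xlmap import (
    PGL3_DOMAINS,
    CompatClass,
    CrosslinkRecord,
    DomainMap,
    PeptideInterval,
    SchemaError,
    StructureModel,
    ValidationError,
    assign_domains,
    ca_distance,
    classify_compatibility,
    classify_records,
    condition_difference,
    condition_overlap,
    crosstab,
    detect_homodimer,
    merge_domains,
    read_crosslink_table,
)
from conftest import make_record

PGL3_MAP = DomainMap(PGL3_DOMAINS)


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------

class TestReadCrosslinkTable:
    HEADER = (
        "protein,res_a,aa_a,pep_a_start,pep_a_end,"
        "res_b,aa_b,pep_b_start,pep_b_end,condition,replicate,n_xsm\n"
    )

    def test_well_formed_rows(self, tmp_path):
        csv = tmp_path / "links.csv"
        csv.write_text(
            self.HEADER
            + "P,5,K,1,12,134,K,130,140,125mM,1,3\n"
            + "P,10,S,8,20,50,T,45,60,125mM,1,1\n"
            + "P,5,K,1,12,5,K,1,12,500mM,2,2\n"
        )
        records = read_crosslink_table(csv)
        assert len(records) == 3
        assert records[0].n_xsm == 3

    def test_residue_outside_peptide_names_row(self, tmp_path):
        csv = tmp_path / "bad.csv"
        csv.write_text(self.HEADER + "P,99,K,1,12,134,K,130,140,125mM,1,1\n")
        with pytest.raises(ValidationError, match="row 0"):
            read_crosslink_table(csv)

    def test_missing_column_is_schema_error(self, tmp_path):
        csv = tmp_path / "short.csv"
        csv.write_text("protein,res_a\nP,5\n")
        with pytest.raises(SchemaError, match="res_b"):
            read_crosslink_table(csv)

    def test_zero_based_positions_shifted(self, tmp_path):
        csv = tmp_path / "zb.csv"
        csv.write_text(self.HEADER + "P,4,K,0,11,133,K,129,139,125mM,1,1\n")
        (rec,) = read_crosslink_table(csv, zero_based=True)
        assert rec.res_a == 5 and rec.res_b == 134
        assert rec.pep_a == PeptideInterval(1, 12)

    def test_dialect_rename(self, tmp_path):
        csv = tmp_path / "renamed.csv"
        csv.write_text(
            "prot,ra,aa_a,pep_a_start,pep_a_end,res_b,aa_b,pep_b_start,pep_b_end\n"
            "P,5,K,1,12,134,K,130,140\n"
        )
        (rec,) = read_crosslink_table(csv, rename={"prot": "protein", "ra": "res_a"})
        assert rec.protein_id == "P" and rec.res_a == 5
        assert rec.n_xsm == 1  # default when the column is absent


# ---------------------------------------------------------------------------
# Homodimer detection
# ---------------------------------------------------------------------------

class TestDetectHomodimer:
    @pytest.mark.parametrize(
        "res_a,res_b,pep_a,pep_b,expected",
        [
            (5, 5, (1, 12), (1, 12), True),  # same residue: canonical case
            (5, 134, (1, 12), (130, 140), False),  # disjoint peptides
            (272, 277, (265, 280), (270, 285), True),  # overlapping peptides
        ],
    )
    def test_overlap_rule(self, res_a, res_b, pep_a, pep_b, expected):
        rec = make_record(res_a, res_b, pep_a, pep_b, aa_a="S", aa_b="K")
        assert detect_homodimer([rec]) == [expected]

    def test_same_residue_always_implies_homodimer(self):
        # res_a == res_b forces both peptides to contain that residue,
        # hence to overlap
        for pep_a, pep_b in [((1, 12), (3, 15)), ((5, 20), (1, 8))]:
            rec = make_record(6, 6, pep_a, pep_b)
            assert detect_homodimer([rec]) == [True]

    def test_symmetric_under_side_swap(self):
        a = make_record(272, 277, (265, 280), (270, 285))
        b = make_record(277, 272, (270, 285), (265, 280))
        assert detect_homodimer([a]) == detect_homodimer([b])


# ---------------------------------------------------------------------------
# Distances & compatibility
# ---------------------------------------------------------------------------

class TestCaDistance:
    def test_intra_identity_is_zero(self, toy_monomer):
        assert ca_distance(toy_monomer, "intra", 7, 7) == pytest.approx(0.0)

    def test_inter_equals_rigid_offset(self, toy_dimer):
        for i in (1, 10, 30):
            assert ca_distance(toy_dimer, "inter", i, i) == pytest.approx(20.0)

    def test_missing_residue_returns_none(self, toy_monomer):
        assert ca_distance(toy_monomer, "intra", 1, 999) is None


def _monomer_from(dimer: StructureModel) -> StructureModel:
    chain = dimer.chains[dimer.chain_labels[0]]
    return StructureModel(chains={"A": dict(chain)}, role="monomer")


class TestClassifyCompatibility:
    def test_intra_only(self, toy_dimer):
        # residues 1 and 7: intra 6*3.8=22.8 <= 30; inter sqrt(22.8^2+400)=30.3 > 30
        rec = make_record(1, 7, (1, 8), (1, 8))
        cls = classify_compatibility(rec, _monomer_from(toy_dimer), toy_dimer)
        assert cls is CompatClass.INTRA_ONLY

    def test_both(self, toy_dimer):
        # residues 2 and 4: intra 7.6; inter sqrt(7.6^2+400)=21.4 — both <= 30
        rec = make_record(2, 4, (1, 8), (1, 8))
        cls = classify_compatibility(rec, _monomer_from(toy_dimer), toy_dimer)
        assert cls is CompatClass.BOTH

    def test_neither(self, toy_dimer):
        rec = make_record(1, 40, (1, 8), (33, 40))
        cls = classify_compatibility(rec, _monomer_from(toy_dimer), toy_dimer)
        assert cls is CompatClass.NEITHER

    def test_no_structure_when_unresolved_everywhere(self, toy_dimer):
        rec = make_record(100, 120, (97, 104), (113, 120))
        cls = classify_compatibility(rec, _monomer_from(toy_dimer), toy_dimer)
        assert cls is CompatClass.NO_STRUCTURE

    def test_one_sided_missing_uses_available_model(self, toy_dimer):
        # drop residue 4 from the monomer; the dimer still resolves it
        monomer = _monomer_from(toy_dimer)
        del monomer.chains["A"][4]
        rec = make_record(2, 4, (1, 8), (1, 8))
        cls = classify_compatibility(rec, monomer, toy_dimer)
        assert cls is CompatClass.INTER_ONLY  # inter 21.4 <= 30, intra missing

    def test_tie_at_cutoff_is_compatible(self):
        st = StructureModel(
            chains={"A": {1: np.zeros(3), 2: np.array([30.0, 0, 0])}}, role="monomer"
        )
        rec = make_record(1, 2, (1, 6), (1, 6))
        assert classify_compatibility(rec, st, None, cutoff=30.0) is CompatClass.INTRA_ONLY

    def test_nonpositive_cutoff_rejected(self, toy_dimer):
        rec = make_record(1, 2, (1, 8), (1, 8))
        with pytest.raises(ValueError):
            classify_compatibility(rec, _monomer_from(toy_dimer), toy_dimer, cutoff=0)

    def test_chain_swap_invariance(self, toy_dimer):
        swapped = StructureModel(
            chains={"A": toy_dimer.chains["B"], "B": toy_dimer.chains["A"]},
            role="dimer",
        )
        for i, j in [(1, 7), (2, 4), (1, 40), (3, 3)]:
            rec = make_record(i, j, (1, 64), (1, 64))
            assert classify_compatibility(
                rec, _monomer_from(toy_dimer), toy_dimer
            ) is classify_compatibility(rec, _monomer_from(toy_dimer), swapped)

    def test_cutoff_monotonicity(self, toy_dimer):
        """Raising the cutoff never demotes a record out of compatibility."""
        compatible = {CompatClass.INTRA_ONLY, CompatClass.INTER_ONLY, CompatClass.BOTH}
        monomer = _monomer_from(toy_dimer)
        rng = np.random.default_rng(0)
        pairs = [(int(a), int(b)) for a, b in rng.integers(1, 65, size=(20, 2))]
        for cutoff_lo, cutoff_hi in [(10, 20), (20, 30), (30, 45)]:
            for i, j in pairs:
                rec = make_record(i, j, (1, 64), (1, 64))
                lo = classify_compatibility(rec, monomer, toy_dimer, cutoff_lo)
                hi = classify_compatibility(rec, monomer, toy_dimer, cutoff_hi)
                if lo in compatible:
                    assert hi in compatible

    def test_oracle_equivalence_with_generator_ground_truth(self, toy_dimer):
        """Classification reproduces the generator's labels for all records."""
        tab, gt = synthgen.simulate_crosslinks(
            toy_dimer,
            {"intra_only": 5, "both": 5, "neither": 5, "homodimer": 3},
            cutoff=30.0,
            seed=11,
        )
        monomer = _monomer_from(toy_dimer)
        for (_, row), label in zip(tab.iterrows(), gt.params["true_class"]):
            rec = make_record(
                row.res_a,
                row.res_b,
                (row.pep_a_start, row.pep_a_end),
                (row.pep_b_start, row.pep_b_end),
                aa_a=row.aa_a,
                aa_b=row.aa_b,
            )
            assert classify_compatibility(rec, monomer, toy_dimer).value == label
        flags = detect_homodimer(
            [
                make_record(
                    r.res_a,
                    r.res_b,
                    (r.pep_a_start, r.pep_a_end),
                    (r.pep_b_start, r.pep_b_end),
                )
                for r in tab.itertuples()
            ]
        )
        # every generated homodimer record is flagged
        for flag, truth in zip(flags, gt.params["homodimer"]):
            if truth:
                assert flag

    def test_classify_records_table(self, toy_dimer):
        recs = [make_record(2, 4, (1, 8), (1, 8)), make_record(1, 40, (1, 8), (33, 40))]
        df = classify_records(recs, _monomer_from(toy_dimer), toy_dimer)
        assert list(df["class"]) == ["both", "neither"]
        assert not df["one_sided"].any()


# ---------------------------------------------------------------------------
# Domains & crosstabs
# ---------------------------------------------------------------------------

class TestDomains:
    def test_default_map_assignments(self):
        rec = make_record(5, 134, (1, 12), (130, 140))
        assert assign_domains(rec, PGL3_MAP) == ("D1", "D1")
        rec = make_record(100, 650, (95, 105), (645, 655))
        assert assign_domains(rec, PGL3_MAP) == ("D1", "RGG")
        assert PGL3_MAP.assign(448) == "IDR"  # closed-interval boundary
        assert PGL3_MAP.assign(447) == "D2"

    def test_swap_invariance(self):
        a = make_record(100, 650, (95, 105), (645, 655))
        b = make_record(650, 100, (645, 655), (95, 105))
        assert assign_domains(a, PGL3_MAP) == assign_domains(b, PGL3_MAP)

    def test_residue_beyond_length_rejected(self):
        rec = make_record(5, 700, (1, 12), (695, 705))
        with pytest.raises(ValueError, match="outside"):
            assign_domains(rec, PGL3_MAP)

    def test_map_must_partition(self):
        with pytest.raises(ValueError, match="gap"):
            DomainMap([("D1", 1, 10), ("D2", 12, 20)])


class TestCrosstab:
    def test_counts_and_frequencies_example(self):
        recs = [
            make_record(5, 134, (1, 12), (130, 140), n_xsm=3),
            make_record(100, 650, (95, 105), (645, 655), n_xsm=1),
        ]
        counts = crosstab(recs, PGL3_MAP, mode="counts")
        assert counts.value("D1", "D1") == 3
        assert counts.value("D1", "RGG") == 1
        assert counts.total_xsm == 4
        freqs = crosstab(recs, PGL3_MAP, mode="frequencies")
        assert freqs.value("D1", "D1") == pytest.approx(0.75)
        assert freqs.value("D1", "RGG") == pytest.approx(0.25)

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 693), st.integers(1, 693), st.integers(1, 10)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_conservation_and_normalization(self, raw):
        recs = [
            make_record(a, b, (a, a), (b, b), n_xsm=n) for a, b, n in raw
        ]
        counts = crosstab(recs, PGL3_MAP, mode="counts")
        assert counts.upper_triangle_sum() == sum(n for _, _, n in raw)
        freqs = crosstab(recs, PGL3_MAP, mode="frequencies")
        assert freqs.upper_triangle_sum() == pytest.approx(1.0)

    def test_unique_pairs_mode(self):
        recs = [
            make_record(5, 134, (1, 12), (130, 140), n_xsm=3),
            make_record(5, 134, (1, 12), (130, 140), n_xsm=2),
            make_record(100, 650, (95, 105), (645, 655), n_xsm=1),
        ]
        tab = crosstab(recs, PGL3_MAP, mode="counts", unique_pairs=True)
        assert tab.value("D1", "D1") == 1
        assert tab.total_xsm == 2

    def test_condition_filter(self):
        recs = [
            make_record(5, 134, (1, 12), (130, 140), n_xsm=3, condition="125mM"),
            make_record(5, 134, (1, 12), (130, 140), n_xsm=7, condition="500mM"),
        ]
        tab = crosstab(recs, PGL3_MAP, mode="counts", condition="125mM")
        assert tab.total_xsm == 3

    def test_empty_frequencies_error(self):
        with pytest.raises(ValueError, match="normalize"):
            crosstab([], PGL3_MAP, mode="frequencies")

    def test_super_domain_merge_conserves_totals(self):
        recs = [
            make_record(5, 650, (1, 12), (645, 655), n_xsm=4),  # D1 x RGG
            make_record(300, 500, (295, 305), (495, 505), n_xsm=2),  # D2 x IDR
            make_record(460, 650, (455, 465), (645, 655), n_xsm=5),  # IDR x RGG
            make_record(5, 134, (1, 12), (130, 140), n_xsm=1),  # D1 x D1
        ]
        tab = crosstab(recs, PGL3_MAP, mode="counts")
        merged = merge_domains(tab, {"D1": "D1-D2", "D2": "D1-D2", "IDR": "IDR-RGG", "RGG": "IDR-RGG"})
        assert merged.value("D1-D2", "IDR-RGG") == 6
        assert merged.value("IDR-RGG", "IDR-RGG") == 5
        assert merged.value("D1-D2", "D1-D2") == 1
        assert merged.upper_triangle_sum() == tab.upper_triangle_sum()


class TestConditionComparison:
    def _freq(self, recs):
        return crosstab(recs, PGL3_MAP, mode="frequencies")

    def test_identical_tables_difference_is_zero(self):
        recs = [make_record(5, 134, (1, 12), (130, 140), n_xsm=3)]
        diff = condition_difference(self._freq(recs), self._freq(recs))
        assert np.allclose(diff.table.to_numpy(), 0.0)

    def test_difference_sums_to_zero(self):
        a = [
            make_record(5, 134, (1, 12), (130, 140), n_xsm=3),
            make_record(100, 650, (95, 105), (645, 655), n_xsm=2),
        ]
        b = [
            make_record(300, 500, (295, 305), (495, 505), n_xsm=4),
            make_record(5, 650, (1, 12), (645, 655), n_xsm=1),
        ]
        diff = condition_difference(self._freq(a), self._freq(b))
        assert diff.upper_triangle_sum() == pytest.approx(0.0, abs=1e-12)
        assert diff.mode == "difference"

    def test_mismatched_maps_rejected(self):
        other = DomainMap([("N", 1, 350), ("C", 351, 693)])
        recs = [make_record(5, 134, (1, 12), (130, 140))]
        with pytest.raises(ValueError, match="domain maps"):
            condition_difference(
                self._freq(recs), crosstab(recs, other, mode="frequencies")
            )

    def test_condition_overlap_partition(self):
        a = [
            make_record(1, 2, (1, 6), (1, 6)),
            make_record(3, 4, (1, 6), (1, 6)),
        ]
        b = [
            make_record(3, 4, (1, 6), (1, 6)),
            make_record(5, 6, (1, 8), (1, 8)),
        ]
        shared, only_a, only_b = condition_overlap(a, b)
        assert shared == {(3, 4)}
        assert only_a == {(1, 2)}
        assert only_b == {(5, 6)}

    def test_disjoint_sets_share_nothing(self):
        a = [make_record(1, 2, (1, 6), (1, 6))]
        b = [make_record(5, 6, (1, 8), (1, 8))]
        shared, only_a, only_b = condition_overlap(a, b)
        assert shared == set()
        assert only_a and only_b
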