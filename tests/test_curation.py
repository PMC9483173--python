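import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from hergml import curation as cu


def rec(**kw):
    base = dict(
        smiles="CCO", standard_type="IC50", standard_value=100.0,
        standard_units="nM", target_organism="Homo sapiens", assay_type="B",
        data_validity_comment="", activity_comment="",
    )
    base.update(kw)
    return cu.ActivityRecord(**base)


class TestEntryFilters:
    def test_each_rule_rejects_exactly_its_violator(self):
        records = [rec() for _ in range(7)]
        records.insert(2, rec(assay_type="F"))
        records.insert(5, rec(target_organism="Rattus norvegicus"))
        records.insert(8, rec(standard_type="Ki"))
        kept, rejections = cu.filter_activity_entries(records)
        assert len(kept) == 7
        assert [r for _, r in rejections] == ["assay_type", "target_organism", "standard_type"]

    def test_conforming_record_retained_unchanged(self):
        r = rec()
        kept, _ = cu.filter_activity_entries([r])
        assert kept == [r]

    def test_functional_assay_dropped(self):
        with pytest.raises(cu.EmptyDatasetError):
            cu.filter_activity_entries([rec(assay_type="F")])

    def test_validity_warning_dropped(self):
        kept, rejections = cu.filter_activity_entries(
            [rec(), rec(data_validity_comment="Outside typical range")]
        )
        assert len(kept) == 1 and rejections[0][1] == "data_validity_comment"

    def test_comment_inactive_passes_type_filter(self):
        r = rec(standard_type="", standard_value=None, standard_units="",
                activity_comment="Not Active")
        kept, _ = cu.filter_activity_entries([r, rec()])
        assert r in kept

    def test_output_is_subsequence_of_input(self):
        records = [rec(standard_value=float(i + 1)) for i in range(5)]
        records[1] = rec(assay_type="F")
        kept, _ = cu.filter_activity_entries(records)
        positions = [records.index(k) for k in kept]
        assert positions == sorted(positions)


class TestStandardize:
    def test_salt_stripped_and_stereo_removed(self):
        expected = Chem.MolToSmiles(Chem.MolFromSmiles("CC(N)C(=O)O"))
        assert cu.standardize_structure("C[C@H](N)C(=O)O.Cl") == expected

    def test_already_standard_unchanged(self):
        assert cu.standardize_structure("CCO") == "CCO"

    def test_inorganic_salt_rejected(self):
        with pytest.raises(cu.StructureRejected) as exc:
            cu.standardize_structure("[Fe+2].[O-]S([O-])(=O)=O")
        assert exc.value.reason == "inorganic"

    def test_organometallic_rejected(self):
        with pytest.raises(cu.StructureRejected) as exc:
            cu.standardize_structure("CC[Sn](CC)CC")
        assert exc.value.reason == "element"

    def test_unparseable_rejected(self):
        with pytest.raises(cu.StructureRejected) as exc:
            cu.standardize_structure("not-a-smiles")
        assert exc.value.reason == "unparseable"

    def test_true_mixture_rejected(self):
        # two organic fragments, both larger than a counterion
        with pytest.raises(cu.StructureRejected) as exc:
            cu.standardize_structure("c1ccccc1CCCC.c1ccncc1CCCC")
        assert exc.value.reason == "mixture"

    def test_charge_neutralized(self):
        assert cu.standardize_structure("CC(=O)[O-]") == "CC(=O)O"

    @pytest.mark.parametrize(
        "smiles",
        ["C[C@H](N)C(=O)O.Cl", "CCO", "c1ccccc1", "CC(=O)[O-].[Na+]",
         "O=C(O)c1ccccc1OC(C)=O", "CN1CCC[C@H]1c1cccnc1"],
    )
    def test_idempotent(self, smiles):
        once = cu.standardize_structure(smiles)
        assert cu.standardize_structure(once) == once


class TestPIC50:
    def test_molar(self):
        assert cu.to_pic50(1e-6, "M") == pytest.approx(6.0)

    def test_micromolar(self):
        assert cu.to_pic50(10, "uM") == pytest.approx(5.0)

    def test_known_experimental_value_round_trip(self):
        # a withdrawn drug with experimental pIC50 = 6.24
        assert cu.to_pic50(10 ** (-6.24), "M") == pytest.approx(6.24)

    @pytest.mark.parametrize("value,units", [(-1.0, "M"), (0.0, "nM"), (1.0, "furlongs")])
    def test_rejections(self, value, units):
        with pytest.raises(cu.CurationError):
            cu.to_pic50(value, units)

    @given(st.floats(min_value=2.0, max_value=9.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, p):
        assert cu.to_pic50(10 ** (-p), "M") == pytest.approx(p, abs=1e-9)


class TestAggregate:
    def test_triplicate(self):
        mean, sigma, kept = cu.aggregate_duplicates([6.0, 6.2, 6.4])
        assert (mean, kept) == (pytest.approx(6.2), True)
        assert sigma == pytest.approx(0.2)

    def test_single_replicate(self):
        assert cu.aggregate_duplicates([7.1]) == (7.1, 0.0, True)

    def test_high_spread_excluded(self):
        mean, sigma, kept = cu.aggregate_duplicates([4.0, 9.0])
        assert sigma == pytest.approx(5 / math.sqrt(2), abs=1e-3)
        assert not kept


class TestLabels:
    @pytest.mark.parametrize(
        "pic50,threshold,expected",
        [(6.24, 6, "ACT"), (4.2, 5, "INA"), (6.0, 6, "ACT"), (5.0, 5, "ACT"),
         (5.99, 6, "INA"), (None, 6, "INA"), (None, 5, "INA")],
    )
    def test_boundary_convention(self, pic50, threshold, expected):
        assert cu.assign_label(pic50, threshold) == expected


class TestCurate:
    def test_uniqueness_sigma_and_label_nesting(self, activity_fixture):
        table, _ = activity_fixture
        records, _ = _records_from(table)
        compounds, log = cu.curate(records)
        smiles = [c.canonical_smiles for c in compounds]
        assert len(smiles) == len(set(smiles))
        assert all(c.sigma <= 2 for c in compounds if c.pic50 is not None)
        act6 = {c.canonical_smiles for c in compounds if c.label_t6 == "ACT"}
        act5 = {c.canonical_smiles for c in compounds if c.label_t5 == "ACT"}
        assert act6 <= act5

    def test_numeric_records_win_over_comment(self):
        records = [
            rec(smiles="c1ccccc1CCN", standard_value=10.0, standard_units="nM"),
            rec(smiles="c1ccccc1CCN", standard_type="", standard_value=None,
                standard_units="", activity_comment="Not Active"),
        ]
        compounds, _ = cu.curate(records)
        (c,) = compounds
        assert c.pic50 == pytest.approx(8.0)
        assert c.label_t6 == "ACT"


def _records_from(table):
    import pandas as pd

    records = []
    for r in table.itertuples():
        records.append(
            cu.ActivityRecord(
                smiles=str(r.canonical_smiles),
                standard_type="" if pd.isna(r.standard_type) else str(r.standard_type),
                standard_value=None if pd.isna(r.standard_value) else float(r.standard_value),
                standard_units="" if pd.isna(r.standard_units) else str(r.standard_units),
                target_organism=str(r.target_organism),
                assay_type=str(r.assay_type),
                data_validity_comment="" if pd.isna(r.data_validity_comment) else str(r.data_validity_comment),
                activity_comment="" if pd.isna(r.activity_comment) else str(r.activity_comment),
            )
        )
    return records, None
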