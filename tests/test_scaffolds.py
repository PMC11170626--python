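"""Bemis-Murcko extraction, scaffold frequency tables, and CSR diversity."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epichem.errors import UndefinedCurveError
from epichem.scaffolds import (
    ALL_COMPOUNDS,
    EMPTY,
    RING_BEARING_ONLY,
    CSRCurve,
    ScaffoldTable,
    bemis_murcko,
    csr_curve,
    scaffold_table,
)

from conftest import make_library

APIGENIN = "O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12"
FLAVONE_SCAFFOLD = "O=c1cc(-c2ccccc2)oc2ccccc12"  # 2-phenyl-chromen-4-one


def _table_from_counts(counts):
    """Build a ScaffoldTable directly from counts (placeholder scaffolds)."""
    df = pd.DataFrame(
        {
            "scaffold_smiles": [f"S{i:03d}" for i in range(len(counts))],
            "count": sorted(counts, reverse=True),
        }
    )
    df["fraction"] = df["count"] / df["count"].sum()
    return ScaffoldTable(
        rows=df,
        denominator_convention=RING_BEARING_ONLY,
        n_compounds=int(sum(counts)),
        n_ring_bearing=int(sum(counts)),
        n_acyclic=0,
        n_unique_scaffolds=len(counts),
    )


def _brute_force_auc(counts):
    """Trapezoid AUC computed from first principles."""
    counts = sorted(counts, reverse=True)
    m, n = len(counts), sum(counts)
    xs = [i / m for i in range(m + 1)]
    ys = [sum(counts[:i]) / n for i in range(m + 1)]
    return sum((xs[i + 1] - xs[i]) * (ys[i + 1] + ys[i]) / 2 for i in range(m))


class TestBemisMurcko:
    def test_side_chain_removed(self):
        assert bemis_murcko("Cc1ccccc1") == "c1ccccc1"

    def test_acyclic_is_empty(self):
        assert bemis_murcko("CCCCCC") == EMPTY

    def test_apigenin_gives_flavone(self):
        assert bemis_murcko(APIGENIN) == FLAVONE_SCAFFOLD

    def test_invariant_to_input_form(self):
        assert bemis_murcko("C1=CC=C(C)C=C1") == bemis_murcko("Cc1ccccc1")


class TestScaffoldTable:
    def test_single_scaffold_library(self):
        lib = make_library([(s, [1, 0, 0, 0]) for s in
                            ["Cc1ccccc1", "Oc1ccccc1", "Fc1ccccc1", "c1ccccc1", "COc1ccccc1"]])
        table = scaffold_table(lib)
        assert table.n_unique_scaffolds == 1
        assert table.rows["fraction"].iloc[0] == 1.0

    def test_acyclic_conventions(self):
        lib = make_library(
            [("CCO", [1, 0, 0, 0]), ("CCC", [0, 1, 0, 0]), ("c1ccccc1", [0, 0, 1, 0])]
        )
        ring_only = scaffold_table(lib, RING_BEARING_ONLY)
        assert ring_only.n_acyclic == 2
        assert ring_only.rows["fraction"].sum() == pytest.approx(1.0)
        assert EMPTY not in set(ring_only.rows["scaffold_smiles"])
        everything = scaffold_table(lib, ALL_COMPOUNDS)
        assert EMPTY in set(everything.rows["scaffold_smiles"])
        assert everything.rows["fraction"].sum() == pytest.approx(1.0)

    def test_counts_sum_and_sorting(self, small_synthetic):
        table = scaffold_table(small_synthetic)
        rows = table.rows
        assert rows["count"].sum() == table.n_ring_bearing
        assert (rows["count"].diff().dropna() <= 0).all()

    def test_top_coverage(self):
        table = _table_from_counts([4, 3, 2, 1])
        assert table.top_coverage(2) == pytest.approx(0.7)


class TestCSRCurve:
    def test_unique_scaffolds_diagonal_auc_half(self):
        curve = csr_curve(_table_from_counts([1] * 25))
        assert curve.auc == 0.5

    def test_two_scaffold_example(self):
        curve = csr_curve(_table_from_counts([4, 1]))
        assert np.allclose(curve.points, [[0, 0], [0.5, 0.8], [1, 1]])
        assert curve.auc == pytest.approx(0.65)

    def test_single_scaffold_convention(self):
        curve = csr_curve(_table_from_counts([7]))
        assert curve.auc == 1.0

    def test_no_ring_bearing_is_error(self):
        lib = make_library([("CCO", [1, 0, 0, 0]), ("CCC", [0, 1, 0, 0])])
        with pytest.raises(UndefinedCurveError):
            csr_curve(scaffold_table(lib, ALL_COMPOUNDS))

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=30), min_size=2, max_size=25))
    def test_auc_matches_brute_force_and_bounds(self, counts):
        curve = csr_curve(_table_from_counts(counts))
        assert curve.auc == pytest.approx(_brute_force_auc(counts))
        assert 0.5 - 1e-12 <= curve.auc <= 1.0
        if all(c == 1 for c in counts):
            assert curve.auc == 0.5
        y = curve.points[:, 1]
        assert (np.diff(y) >= -1e-12).all()
        assert (np.diff(np.diff(y)) <= 1e-12).all()  # concave: sorted desc

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=20), min_size=3, max_size=15))
    def test_concentrating_compounds_never_decreases_auc(self, counts):
        """At fixed scaffold and compound totals, moving one compound from a
        poorer scaffold to a richer one (majorization step) can only raise the
        AUC.  Note that *merging* two scaffolds does not share this property:
        it shrinks the x-axis grid and can lower the AUC (e.g. counts [5,1,1]
        -> [6,1] drops from 29/42 to 19/28)."""
        from hypothesis import assume

        counts = sorted(counts, reverse=True)
        donors = [i for i in range(1, len(counts)) if counts[i] >= 2]
        assume(donors)
        donor = donors[-1]
        base = csr_curve(_table_from_counts(counts)).auc
        moved = list(counts)
        moved[0] += 1
        moved[donor] -= 1
        assert csr_curve(_table_from_counts(moved)).auc >= base

    def test_merging_two_scaffolds_can_lower_auc(self):
        assert csr_curve(_table_from_counts([5, 1, 1])).auc == pytest.approx(29 / 42)
        assert csr_curve(_table_from_counts([6, 1])).auc == pytest.approx(19 / 28)
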