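"""Bemis-Murcko scaffold content and cyclic-system-recovery (CSR) diversity.

A Bemis-Murcko scaffold is the ring systems of a molecule plus the linkers
connecting them, with all side chains removed.  Acyclic molecules have no
scaffold and are represented by the EMPTY marker (an empty string).

The CSR curve plots, as scaffolds are accumulated in descending frequency
order, the fraction of scaffolds consumed (x) against the fraction of
compounds recovered (y).  Its trapezoidal AUC summarises scaffold diversity:
0.5 when every compound carries a distinct scaffold (the diagonal) and
approaching 1.0 as one scaffold dominates.  The degenerate single-scaffold
library is assigned AUC = 1.0 by convention (the curve is a vertical line).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import ContractError, StructureError, UndefinedCurveError
from .types import CompoundLibrary

#: Marker for acyclic molecules (no ring system, hence no scaffold).
EMPTY = ""

RING_BEARING_ONLY = "ring_bearing_only"
ALL_COMPOUNDS = "all_compounds"


def bemis_murcko(smiles: str) -> str:
    """Canonical SMILES of the Bemis-Murcko scaffold, or EMPTY for acyclic."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return EMPTY
    return Chem.MolToSmiles(scaffold)


@dataclass
class ScaffoldTable:
    """Scaffold frequency table.

    ``rows`` columns: ``scaffold_smiles`` (EMPTY for the pooled acyclic
    compounds, present only under the ``all_compounds`` convention),
    ``count``, ``fraction``.  Rows are sorted by descending count, ties by
    ascending scaffold SMILES.
    """

    rows: pd.DataFrame
    denominator_convention: str
    n_compounds: int
    n_ring_bearing: int
    n_acyclic: int
    n_unique_scaffolds: int

    def top_coverage(self, k: int) -> float:
        """Sum of the top-k scaffold fractions (EMPTY row excluded)."""
        nonempty = self.rows[self.rows["scaffold_smiles"] != EMPTY]
        return float(nonempty["fraction"].head(k).sum())


def scaffold_table(
    library: CompoundLibrary, denominator_convention: str = RING_BEARING_ONLY
) -> ScaffoldTable:
    """Count Bemis-Murcko scaffolds over a library.

    Under ``ring_bearing_only`` (default) acyclic compounds are excluded from
    the table and the fraction denominator; under ``all_compounds`` they are
    pooled into an EMPTY row and the denominator is the full library.
    """
    if len(library) == 0:
        raise ContractError("library is empty")
    if denominator_convention not in (RING_BEARING_ONLY, ALL_COMPOUNDS):
        raise ContractError(f"unknown denominator convention {denominator_convention!r}")
    scaffolds = [bemis_murcko(s) for s in library.smiles]
    counts = pd.Series(scaffolds).value_counts()
    n_acyclic = int(counts.get(EMPTY, 0))
    nonempty = counts.drop(index=EMPTY, errors="ignore")
    n_ring = int(nonempty.sum())

    df = nonempty.rename_axis("scaffold_smiles").reset_index(name="count")
    if denominator_convention == ALL_COMPOUNDS and n_acyclic:
        df = pd.concat(
            [df, pd.DataFrame([{"scaffold_smiles": EMPTY, "count": n_acyclic}])],
            ignore_index=True,
        )
    denom = len(library) if denominator_convention == ALL_COMPOUNDS else n_ring
    df = df.sort_values(
        ["count", "scaffold_smiles"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["fraction"] = df["count"] / denom if denom else 0.0
    return ScaffoldTable(
        rows=df,
        denominator_convention=denominator_convention,
        n_compounds=len(library),
        n_ring_bearing=n_ring,
        n_acyclic=n_acyclic,
        n_unique_scaffolds=int(len(nonempty)),
    )


@dataclass
class CSRCurve:
    """CSR curve points and trapezoidal AUC.

    ``points`` is an (M+1, 2) array from (0, 0) to (1, 1); x is the fraction
    of scaffolds consumed, y the cumulative fraction of ring-bearing
    compounds recovered.
    """

    points: np.ndarray
    auc: float
    n_scaffolds: int
    n_compounds: int


def csr_curve(table: ScaffoldTable) -> CSRCurve:
    """Cyclic-system-recovery curve of a scaffold table.

    Scaffolds are taken in descending count (ties by ascending SMILES, the
    table's order); acyclic compounds never enter the curve.  AUC is computed
    by the trapezoidal rule; a single-scaffold table returns 1.0 by the
    stated limiting convention.
    """
    nonempty = table.rows[table.rows["scaffold_smiles"] != EMPTY]
    m = len(nonempty)
    if m == 0:
        raise UndefinedCurveError("no ring-bearing compounds: CSR curve undefined")
    counts = nonempty["count"].to_numpy()
    n = int(counts.sum())
    cumulative = np.concatenate([[0], np.cumsum(counts)])
    x = np.arange(m + 1) / m
    y = cumulative / n
    if m == 1:
        return CSRCurve(points=np.column_stack([x, y]), auc=1.0, n_scaffolds=1, n_compounds=n)
    # trapezoidal rule on the uniform x grid, in exact integer arithmetic:
    # sum_i (1/m)(Y_i + Y_{i+1})/2 = (2*sum(C_1..C_{m-1}) + N) / (2mN)
    auc = (2 * int(cumulative[1:-1].sum()) + n) / (2 * m * n)
    return CSRCurve(points=np.column_stack([x, y]), auc=auc, n_scaffolds=m, n_compounds=n)


def csr_points_frame(curve: CSRCurve) -> pd.DataFrame:
    return pd.DataFrame(curve.points, columns=["scaffold_fraction", "compound_fraction"])
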