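"""Statistics over binary multi-target activity profiles.

The activity profile of a compound is a bit vector over the target panel:
1 = reported activity against that target, 0 = no report (which may mean
untested rather than inactive).  Family-level "general" flags are excluded
from all statistics here; compounds carrying only general flags are counted
as a separate population.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .errors import ContractError
from .fingerprints import is_undefined_pair, tanimoto
from .panel import TargetPanel
from .types import CompoundLibrary


@dataclass
class ActivityMatrix:
    """n_compounds x n_targets binary matrix with compound/target labels."""

    matrix: np.ndarray
    compound_ids: List[int]
    compound_names: List[str]
    panel: TargetPanel

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape != (
            len(self.compound_ids),
            len(self.panel),
        ):
            raise ContractError("activity matrix shape inconsistent with labels")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ContractError("activity matrix entries must be 0 or 1")

    @classmethod
    def from_library(cls, library: CompoundLibrary) -> "ActivityMatrix":
        return cls(
            matrix=library.activity_matrix(),
            compound_ids=list(library.compound_ids),
            compound_names=list(library.names),
            panel=library.panel,
        )

    @property
    def row_margins(self) -> np.ndarray:
        """Targets per compound."""
        return self.matrix.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        """Compounds per target."""
        return self.matrix.sum(axis=0)


def target_frequency(am: ActivityMatrix) -> pd.DataFrame:
    """Per-target compound counts, descending; ties keep panel order."""
    df = pd.DataFrame({"target": am.panel.names, "count": am.col_margins})
    return df.sort_values("count", ascending=False, kind="mergesort").reset_index(drop=True)


@dataclass
class SingleTargetResult:
    total: int
    per_target: Dict[str, int] = field(default_factory=dict)


def single_target_compounds(am: ActivityMatrix) -> SingleTargetResult:
    """Compounds active against exactly one target, grouped by that target."""
    if am.matrix.shape[0] == 0:
        return SingleTargetResult(total=0)
    mask = am.row_margins == 1
    per: Dict[str, int] = {}
    for row in am.matrix[mask]:
        target = am.panel.names[int(np.argmax(row))]
        per[target] = per.get(target, 0) + 1
    per = dict(sorted(per.items(), key=lambda kv: (-kv[1], am.panel.index(kv[0]))))
    return SingleTargetResult(total=int(mask.sum()), per_target=per)


def multi_target_ranking(am: ActivityMatrix, k: int) -> pd.DataFrame:
    """Top-k compounds by number of targets hit; ties by compound name."""
    if k < 1:
        raise ContractError(f"k must be >= 1, got {k}")
    df = pd.DataFrame(
        {
            "compound_id": am.compound_ids,
            "name": am.compound_names,
            "n_targets": am.row_margins,
        }
    )
    df = df.sort_values(["n_targets", "name"], ascending=[False, True], kind="mergesort")
    return df.head(k).reset_index(drop=True)


def profile_similarity(row_i: np.ndarray, row_j: np.ndarray) -> float:
    """Jaccard-Tanimoto similarity of two binary activity profiles.

    Shares the fingerprint Tanimoto implementation, including the flagged
    0.0 convention for two all-zero profiles (see
    :func:`epichem.fingerprints.is_undefined_pair`).
    """
    return tanimoto(row_i, row_j)


def population_summary(library: CompoundLibrary) -> Dict[str, int]:
    """Counts of the specific / general-only / unannotated populations."""
    am = library.activity_matrix()
    gm = library.general_matrix()
    specific = am.sum(axis=1) > 0 if len(library) else np.zeros(0, dtype=bool)
    general = (gm.sum(axis=1) > 0) if gm.size else np.zeros(len(library), dtype=bool)
    return {
        "n_compounds": len(library),
        "n_specific": int(specific.sum()),
        "n_general_only": int((~specific & general).sum()),
        "n_unannotated": int((~specific & ~general).sum()),
    }


__all__ = [
    "ActivityMatrix",
    "SingleTargetResult",
    "target_frequency",
    "single_target_compounds",
    "multi_target_ranking",
    "profile_similarity",
    "population_summary",
    "is_undefined_pair",
]
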