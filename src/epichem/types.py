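"""Core in-memory containers: a compound record and a compound library."""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .panel import TargetPanel, default_panel

#: Sentinel text used in the published table for compounds absent from FooDB.
FOODB_ABSENT_SENTINEL = "Not in database"

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


@dataclass
class CompoundRecord:
    """One curated compound: structure, provenance, and its binary activity
    profile over the target panel.

    ``specific_profile`` holds one bit per panel target (1 = reported
    activity).  ``general_flags`` holds family-level flags for compounds whose
    literature report names only a target family.  A compound with an all-zero
    specific profile and no general flag is marked ``profile_incomplete``
    rather than rejected: in this data model a 0 means "no reported activity",
    not "inactive".
    """

    compound_id: int
    name: str
    smiles: str
    specific_profile: np.ndarray
    general_flags: np.ndarray
    inchi: Optional[str] = None
    inchikey: Optional[str] = None
    food_sources: List[str] = field(default_factory=list)
    foodb_id: Optional[str] = None
    coconut_id: Optional[str] = None
    doi: List[str] = field(default_factory=list)
    profile_incomplete: bool = False

    def __post_init__(self):
        self.specific_profile = np.asarray(self.specific_profile, dtype=np.uint8)
        self.general_flags = np.asarray(self.general_flags, dtype=np.uint8)
        for vec in (self.specific_profile, self.general_flags):
            if not np.isin(vec, (0, 1)).all():
                raise ValueError("activity profile entries must be 0 or 1")
        if self.specific_profile.sum() == 0 and self.general_flags.sum() == 0:
            self.profile_incomplete = True

    @property
    def n_targets_hit(self) -> int:
        return int(self.specific_profile.sum())

    def inchikey_well_formed(self) -> Optional[bool]:
        """True/False for a present InChIKey, None when absent."""
        if not self.inchikey:
            return None
        return bool(INCHIKEY_RE.match(self.inchikey))


@dataclass
class CompoundLibrary:
    """A validated set of compound records sharing one target panel."""

    records: List[CompoundRecord]
    panel: TargetPanel = field(default_factory=default_panel)
    provenance: str = ""

    def __post_init__(self):
        ids = [r.compound_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("compound_ids must be unique")
        n = len(self.panel)
        for r in self.records:
            if r.specific_profile.shape != (n,):
                raise ValueError(
                    f"record {r.compound_id}: profile length "
                    f"{r.specific_profile.shape[0]} != panel size {n}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def compound_ids(self) -> List[int]:
        return [r.compound_id for r in self.records]

    @property
    def names(self) -> List[str]:
        return [r.name for r in self.records]

    @property
    def smiles(self) -> List[str]:
        return [r.smiles for r in self.records]

    def activity_matrix(self) -> np.ndarray:
        """n_compounds x n_targets binary matrix of the specific profiles."""
        if not self.records:
            return np.zeros((0, len(self.panel)), dtype=np.uint8)
        return np.vstack([r.specific_profile for r in self.records])

    def general_matrix(self) -> np.ndarray:
        n_gen = len(self.panel.general_families)
        if not self.records:
            return np.zeros((0, n_gen), dtype=np.uint8)
        return np.vstack([r.general_flags for r in self.records])

    def subset(self, ids: Sequence[int]) -> "CompoundLibrary":
        keep = set(ids)
        return CompoundLibrary(
            records=[r for r in self.records if r.compound_id in keep],
            panel=self.panel,
            provenance=self.provenance + " (subset)",
        )
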