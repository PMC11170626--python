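"""Epigenetic target panel: the ordered targets, their mechanistic class, and
family groupings.

The default panel covers 46 targets split into the three canonical mechanistic
classes — 8 writers, 37 erasers, and 1 reader (BET/BRD4) — which is the panel
used for the curated food-chemical activity profiles this package analyses.
Family-level ("general") activity flags are kept separate from the per-protein
profile because they lack protein resolution.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

WRITER = "writer"
ERASER = "eraser"
READER = "reader"

_WRITERS: List[str] = [
    "DNMT1", "DNMT3a", "DNMT3b",
    "HAT/Ep300", "HAT2B/Ep300", "HAT3B/p300",
    "EZH2", "PRMT1",
]

_ERASERS: List[str] = [
    "HDAC1", "HDAC2", "HDAC3", "HDAC4", "HDAC5", "HDAC6",
    "HDAC7", "HDAC8", "HDAC9", "HDAC10", "HDAC11",
    "SIRT1", "SIRT2", "SIRT3", "SIRT4", "SIRT5", "SIRT6", "SIRT7",
    "LSD1",
    "KDM1A", "KDM1B", "KDM2A", "KDM2B", "KDM3A", "KDM3B",
    "KDM4A", "KDM4B", "KDM4C", "KDM4D",
    "KDM5A", "KDM5B", "KDM5C", "KDM5D",
    "KDM6A", "KDM6B", "KDM7A", "KDM8",
]

_READERS: List[str] = ["BET/BRD4"]

#: Default family-level ("general activity") flag columns.  The published
#: table encodes 49 activity columns for 46 targets; the three extra columns
#: are read as family-level flags.  Which three families they cover is not
#: printed, so this default is overridable via the reader's column map.
DEFAULT_GENERAL_FAMILIES: List[str] = ["DNMT (general)", "HDAC (general)", "SIRT (general)"]


@dataclass(frozen=True)
class TargetPanel:
    """Ordered list of epigenetic targets with class and family annotations.

    Parameters
    ----------
    targets
        Ordered ``(target_name, target_class)`` pairs; class is one of
        ``"writer"``, ``"eraser"``, ``"reader"``.
    families
        Mapping from family name (e.g. ``"DNMT"``) to its member targets.
    general_families
        Names of the family-level general-activity flag columns.
    """

    targets: Tuple[Tuple[str, str], ...]
    families: Dict[str, List[str]] = field(default_factory=dict)
    general_families: Tuple[str, ...] = ()

    def __post_init__(self):
        names = [t for t, _ in self.targets]
        if len(names) != len(set(names)):
            raise ValueError("target names must be unique")
        for _, cls in self.targets:
            if cls not in (WRITER, ERASER, READER):
                raise ValueError(f"unknown target class {cls!r}")

    @property
    def names(self) -> List[str]:
        return [t for t, _ in self.targets]

    @property
    def classes(self) -> List[str]:
        return [c for _, c in self.targets]

    def __len__(self) -> int:
        return len(self.targets)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def class_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for _, c in self.targets:
            out[c] = out.get(c, 0) + 1
        return out


def _family_of(name: str) -> str:
    for prefix in ("DNMT", "HDAC", "SIRT", "KDM", "HAT", "BET"):
        if name.upper().startswith(prefix):
            return prefix
    return name


def default_panel() -> TargetPanel:
    """The 46-target epigenetic panel: 8 writers, 37 erasers, 1 reader."""
    targets = (
        [(t, WRITER) for t in _WRITERS]
        + [(t, ERASER) for t in _ERASERS]
        + [(t, READER) for t in _READERS]
    )
    families: Dict[str, List[str]] = {}
    for name, _ in targets:
        families.setdefault(_family_of(name), []).append(name)
    return TargetPanel(
        targets=tuple(targets),
        families=families,
        general_families=tuple(DEFAULT_GENERAL_FAMILIES),
    )


def generic_panel(n_targets: int) -> TargetPanel:
    """A neutral panel of ``n_targets`` placeholder targets (synthetic use)."""
    if n_targets == 46:
        return default_panel()
    width = max(2, len(str(n_targets)))
    targets = tuple((f"T{i + 1:0{width}d}", ERASER) for i in range(n_targets))
    return TargetPanel(targets=targets, families={}, general_families=())
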