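"""Structure-activity similarity (SAS) maps and pseudo-activity-cliff search.

For every compound pair, a SAS map plots activity-profile similarity (y)
against structural fingerprint similarity (x).  Two thresholds partition the
plane into four regions:

* region I  — low structure, high activity similarity (scaffold hops);
* region II — high structure, high activity similarity (smooth SAR);
* region III — low structure, low activity similarity;
* region IV — high structure, low activity similarity (activity cliffs).

The structural threshold is data-driven: mean + 2 x sample SD of the
pairwise similarity distribution for that fingerprint (self-pairs excluded).
The activity threshold is fixed at 0.1.  Region II/IV require strictly
greater structural similarity; activity uses > 0.1 for II and <= 0.1 for IV.

Because a 0 in the activity profile means "no report" rather than "inactive",
region-IV pairs are *pseudo* activity cliffs; pairs involving a compound with
an all-zero specific profile are classified normally but carried in a
separate profile-incomplete annex.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateDistributionError
from .types import CompoundLibrary

DEFAULT_ACTIVITY_THRESHOLD = 0.1
REGIONS = ("I", "II", "III", "IV")


@dataclass
class SASThresholds:
    """Per-fingerprint structural thresholds plus the fixed activity threshold."""

    structural: Dict[str, float]
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD
    sd_kind: str = "sample"
    distribution_scope: str = "without_self"
    capped: Dict[str, bool] = field(default_factory=dict)


def compute_thresholds(
    similarities: Mapping[str, np.ndarray],
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> SASThresholds:
    """Structural threshold = mean + 2 x sample SD, per fingerprint.

    Values above 1.0 are capped at 1.0 with a warning (similarity domain
    bound).  A zero-variance distribution is an error: no meaningful
    threshold exists.
    """
    if not 0.0 < activity_threshold < 1.0:
        raise ContractError("activity threshold must be in (0, 1)")
    structural: Dict[str, float] = {}
    capped: Dict[str, bool] = {}
    for kind, values in similarities.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ContractError(f"{kind}: need >= 2 similarity values")
        sd = float(values.std(ddof=1))
        if sd == 0.0:
            raise DegenerateDistributionError(
                f"{kind}: constant similarity distribution, threshold undefined"
            )
        threshold = float(values.mean()) + 2.0 * sd
        if threshold > 1.0:
            warnings.warn(
                f"{kind}: mean + 2*SD = {threshold:.4f} exceeds 1; capped at 1.0",
                stacklevel=2,
            )
            threshold = 1.0
            capped[kind] = True
        else:
            capped[kind] = False
        structural[kind] = threshold
    return SASThresholds(
        structural=structural, activity_threshold=activity_threshold, capped=capped
    )


def _classify(structural: np.ndarray, activity: np.ndarray, s_thr: float, a_thr: float) -> np.ndarray:
    high_s = structural > s_thr
    high_a = activity > a_thr
    out = np.empty(structural.shape, dtype=object)
    out[~high_s & high_a] = "I"
    out[high_s & high_a] = "II"
    out[~high_s & ~high_a] = "III"
    out[high_s & ~high_a] = "IV"
    return out


@dataclass
class SASClassification:
    """Region labels per pair per fingerprint, plus consensus flags.

    ``table`` carries the input pair table extended with ``region_<kind>``
    columns and ``consensus_II`` / ``consensus_IV`` booleans (pair falls in
    that region under *every* fingerprint).
    """

    table: pd.DataFrame
    thresholds: SASThresholds
    kinds: List[str]

    def region_counts(self, kind: str) -> Dict[str, int]:
        col = self.table[f"region_{kind}"]
        return {r: int((col == r).sum()) for r in REGIONS}


def classify_regions(
    pair_table: pd.DataFrame, thresholds: SASThresholds
) -> SASClassification:
    """Assign each pair to a SAS region per fingerprint and flag consensus pairs."""
    if "activity_similarity" not in pair_table.columns:
        raise ContractError("pair table lacks an 'activity_similarity' column")
    kinds = sorted(thresholds.structural)
    missing = [k for k in kinds if f"sim_{k}" not in pair_table.columns]
    if missing:
        raise ContractError(f"pair table lacks structural columns for: {missing}")
    df = pair_table.copy()
    activity = df["activity_similarity"].to_numpy(dtype=float)
    for kind in kinds:
        df[f"region_{kind}"] = _classify(
            df[f"sim_{kind}"].to_numpy(dtype=float),
            activity,
            thresholds.structural[kind],
            thresholds.activity_threshold,
        )
    for region in ("II", "IV"):
        flags = np.ones(len(df), dtype=bool)
        for kind in kinds:
            flags &= (df[f"region_{kind}"] == region).to_numpy()
        df[f"consensus_{region}"] = flags
    return SASClassification(table=df, thresholds=thresholds, kinds=kinds)


def consensus_pairs(
    classification: SASClassification,
    region: str,
    library: Optional[CompoundLibrary] = None,
) -> pd.DataFrame:
    """Pairs assigned ``region`` under every fingerprint, sorted by mean
    structural similarity (descending).  Adds compound names when a library
    is supplied."""
    if region not in ("II", "IV"):
        raise ContractError("consensus region must be 'II' or 'IV'")
    df = classification.table
    out = df[df[f"consensus_{region}"]].copy()
    sim_cols = [f"sim_{k}" for k in classification.kinds]
    out["mean_structural_similarity"] = out[sim_cols].mean(axis=1)
    out = out.sort_values(
        "mean_structural_similarity", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    if library is not None:
        names = {r.compound_id: r.name for r in library.records}
        incomplete = {r.compound_id: r.profile_incomplete for r in library.records}
        out.insert(2, "name_i", out["id_i"].map(names))
        out.insert(3, "name_j", out["id_j"].map(names))
        out["profile_incomplete"] = out["id_i"].map(incomplete) | out["id_j"].map(incomplete)
    keep = ["id_i", "id_j"]
    if library is not None:
        keep += ["name_i", "name_j"]
    keep += sim_cols + ["activity_similarity", "mean_structural_similarity"]
    if library is not None:
        keep += ["profile_incomplete"]
    return out[keep]


def sas_points(
    classification: SASClassification, kind: str
) -> pd.DataFrame:
    """Plottable point set for one fingerprint's SAS map.

    One row per pair: x = structural similarity, y = activity-profile
    similarity, with the region label and consensus flags.
    """
    if kind not in classification.kinds:
        raise ContractError(f"no classification for fingerprint {kind!r}")
    df = classification.table
    return pd.DataFrame(
        {
            "id_i": df["id_i"],
            "id_j": df["id_j"],
            "structural_similarity": df[f"sim_{kind}"],
            "activity_similarity": df["activity_similarity"],
            "region": df[f"region_{kind}"],
            "consensus_II": df["consensus_II"],
            "consensus_IV": df["consensus_IV"],
        }
    )


_REGION_COLORS = {"I": "#888888", "II": "#e0218a", "III": "#bbbbbb", "IV": "#2e8b57"}


def write_sas_html(points: pd.DataFrame, path, title: str = "SAS map") -> None:
    """Write a small self-contained HTML/SVG scatter of a SAS map.

    Points carry their pair ids and region as hover tooltips; no external
    assets, so the file opens anywhere.
    """
    w = h = 640
    pad = 50
    circles = []
    for _, row in points.iterrows():
        x = pad + row["structural_similarity"] * (w - 2 * pad)
        y = h - pad - row["activity_similarity"] * (h - 2 * pad)
        color = _REGION_COLORS.get(row["region"], "#000000")
        tip = f"({int(row['id_i'])},{int(row['id_j'])}) region {row['region']}"
        circles.append(
            f'<circle cx="{x:.1f}" cy="{y:.1f}" r="3" fill="{color}" '
            f'fill-opacity="0.55"><title>{tip}</title></circle>'
        )
    axes = (
        f'<line x1="{pad}" y1="{h-pad}" x2="{w-pad}" y2="{h-pad}" stroke="black"/>'
        f'<line x1="{pad}" y1="{pad}" x2="{pad}" y2="{h-pad}" stroke="black"/>'
        f'<text x="{w//2}" y="{h-10}" text-anchor="middle">structural similarity</text>'
        f'<text x="15" y="{h//2}" transform="rotate(-90 15 {h//2})" '
        f'text-anchor="middle">activity profile similarity</text>'
    )
    html = (
        f"<!DOCTYPE html><html><head><meta charset='utf-8'><title>{title}</title>"
        f"</head><body><h3>{title}</h3>"
        f'<svg width="{w}" height="{h}" viewBox="0 0 {w} {h}">{axes}'
        + "".join(circles)
        + "</svg></body></html>"
    )
    from pathlib import Path

    Path(path).write_text(html)
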