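"""Structural fingerprints and all-pairs Jaccard-Tanimoto similarity.

Four fingerprints are supported, matching standard diversity-analysis
practice: MACCS keys (dictionary substructure keys; RDKit materialises them
as a 167-bit vector with bit 0 unused), Morgan/ECFP at radius 2 (ECFP4) and
radius 3 (ECFP6), and the RDKit path-based topological fingerprint.  Hashed
kinds use 2048 bits, the common default; at library sizes of a few hundred
compounds hash collisions are negligible.

The Jaccard-Tanimoto coefficient |a AND b| / |a OR b| is the single
similarity metric, shared with the binary activity profiles.  The degenerate
all-zero vs all-zero case is defined as 0.0 and flagged, so that pairs
involving compounds without any set bit remain representable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .errors import ContractError
from .types import CompoundLibrary

#: Supported fingerprint kinds (canonical short names).
FINGERPRINT_KINDS = ("maccs", "ecfp4", "ecfp6", "rdkit")

#: Aliases accepted on input.
_KIND_ALIASES = {
    "maccs": "maccs",
    "maccs_166": "maccs",
    "ecfp4": "ecfp4",
    "ecfp_r2": "ecfp4",
    "morgan2": "ecfp4",
    "ecfp6": "ecfp6",
    "ecfp_r3": "ecfp6",
    "morgan3": "ecfp6",
    "rdkit": "rdkit",
    "path": "rdkit",
    "path_topological": "rdkit",
}

DEFAULT_N_BITS = 2048


def normalize_kind(kind: str) -> str:
    key = kind.strip().lower()
    if key not in _KIND_ALIASES:
        raise ContractError(f"unknown fingerprint kind {kind!r}; expected one of {FINGERPRINT_KINDS}")
    return _KIND_ALIASES[key]


@dataclass
class FingerprintSet:
    """Bit-vector fingerprints for a library, one row per compound."""

    kind: str
    compound_ids: List[int]
    matrix: np.ndarray  # (n_compounds, n_bits) uint8
    n_bits: int

    def __post_init__(self):
        if self.matrix.shape != (len(self.compound_ids), self.n_bits):
            raise ContractError("fingerprint matrix shape inconsistent with ids/n_bits")

    def vector(self, compound_id: int) -> np.ndarray:
        return self.matrix[self.compound_ids.index(compound_id)]


def _fp_to_array(fp, n_bits: int) -> np.ndarray:
    arr = np.zeros(n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def compute_fingerprints(
    library: CompoundLibrary, kind: str, n_bits: int = DEFAULT_N_BITS
) -> FingerprintSet:
    """Compute one fingerprint vector per compound; deterministic."""
    kind = normalize_kind(kind)
    mols = [Chem.MolFromSmiles(s) for s in library.smiles]
    if any(m is None for m in mols):
        bad = [library.smiles[i] for i, m in enumerate(mols) if m is None]
        raise ContractError(f"library contains unparseable SMILES: {bad[:3]}")

    if kind == "maccs":
        fps = [MACCSkeys.GenMACCSKeys(m) for m in mols]
        width = 167  # RDKit MACCS: 166 keys, bit 0 unused
    else:
        if kind == "ecfp4":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        elif kind == "ecfp6":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=n_bits)
        else:  # path-based topological, paths 1-7
            gen = rdFingerprintGenerator.GetRDKitFPGenerator(
                minPath=1, maxPath=7, fpSize=n_bits
            )
        fps = [gen.GetFingerprint(m) for m in mols]
        width = n_bits
    matrix = (
        np.vstack([_fp_to_array(fp, width) for fp in fps])
        if fps
        else np.zeros((0, width), dtype=np.uint8)
    )
    return FingerprintSet(kind=kind, compound_ids=list(library.compound_ids), matrix=matrix, n_bits=width)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard-Tanimoto coefficient of two equal-length binary vectors.

    Tanimoto(0, 0) is defined as 0.0 (see :func:`is_undefined_pair`).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ContractError(f"length mismatch: {a.shape} vs {b.shape}")
    ab = a.astype(bool)
    bb = b.astype(bool)
    union = int(np.logical_or(ab, bb).sum())
    if union == 0:
        return 0.0
    return float(np.logical_and(ab, bb).sum()) / union


def is_undefined_pair(a: np.ndarray, b: np.ndarray) -> bool:
    """True when both vectors are all-zero, i.e. the Tanimoto value is a
    convention (0.0) rather than a measurement."""
    return not np.asarray(a).any() and not np.asarray(b).any()


def count_pairs(n: int) -> Tuple[int, int]:
    """Number of pairwise comparisons for ``n`` compounds.

    Returns ``(with_self, without_self)`` = ``(n(n+1)/2, n(n-1)/2)``.
    """
    if n < 1:
        raise ContractError(f"library size must be >= 1, got {n}")
    return n * (n + 1) // 2, n * (n - 1) // 2


def _pairwise_tanimoto_matrix(matrix: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Full symmetric Tanimoto matrix plus an undefined-pair mask."""
    x = matrix.astype(np.int64)
    inter = x @ x.T
    ones = x.sum(axis=1)
    union = ones[:, None] + ones[None, :] - inter
    undefined = union == 0
    sim = np.divide(inter, union, out=np.zeros_like(inter, dtype=float), where=~undefined)
    return sim, undefined


def all_pairs_similarity(fps: FingerprintSet) -> pd.DataFrame:
    """Tanimoto similarity for all unordered pairs (i < j), self-pairs excluded.

    Returns a DataFrame ``(id_i, id_j, similarity, undefined)`` with exactly
    n(n-1)/2 rows.
    """
    n = len(fps.compound_ids)
    if n < 2:
        raise ContractError("at least 2 compounds required for pairwise similarity")
    sim, undefined = _pairwise_tanimoto_matrix(fps.matrix)
    iu, ju = np.triu_indices(n, k=1)
    ids = np.asarray(fps.compound_ids)
    return pd.DataFrame(
        {
            "id_i": ids[iu],
            "id_j": ids[ju],
            "similarity": sim[iu, ju],
            "undefined": undefined[iu, ju],
        }
    )


def pairwise_table(
    library: CompoundLibrary,
    kinds: Sequence[str] = FINGERPRINT_KINDS,
    n_bits: int = DEFAULT_N_BITS,
    activity_matrix: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """All-pairs similarity table with one structural column per fingerprint.

    Columns: ``id_i, id_j, sim_<kind>...`` and, when ``activity_matrix`` is
    given, ``activity_similarity`` plus ``activity_undefined`` (the flagged
    all-zero-profile convention).
    """
    kinds = [normalize_kind(k) for k in kinds]
    n = len(library)
    if n < 2:
        raise ContractError("at least 2 compounds required")
    iu, ju = np.triu_indices(n, k=1)
    ids = np.asarray(library.compound_ids)
    out: Dict[str, np.ndarray] = {"id_i": ids[iu], "id_j": ids[ju]}
    for kind in kinds:
        fps = compute_fingerprints(library, kind, n_bits=n_bits)
        sim, _ = _pairwise_tanimoto_matrix(fps.matrix)
        out[f"sim_{kind}"] = sim[iu, ju]
    if activity_matrix is not None:
        if activity_matrix.shape[0] != n:
            raise ContractError("activity matrix row count != library size")
        sim, undefined = _pairwise_tanimoto_matrix(activity_matrix)
        out["activity_similarity"] = sim[iu, ju]
        out["activity_undefined"] = undefined[iu, ju]
    return pd.DataFrame(out)
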