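"""Physicochemical descriptors and 2-D chemical-space embedding.

Compounds are characterised by the full canonical RDKit descriptor list
(molecular weight, logP, H-bond donors/acceptors, TPSA, ring and heteroatom
counts, ...; around 210 descriptors depending on the RDKit release).  The
matrix is z-scored column-wise before embedding — descriptor units are wildly
heterogeneous and would otherwise dominate distances — and embedded with
t-SNE under a fixed seed.  An optional reference SMILES set is overlaid by
fitting the standardisation on the union and carrying a set-membership label
to the output for two-colour plotting.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import ContractError, ParameterError, StructureError


@dataclass
class DescriptorMatrix:
    """Numeric descriptor matrix with row labels and standardisation state."""

    values: pd.DataFrame             # rows: compounds; columns: descriptors
    set_labels: List[str]            # e.g. "library" / "reference"
    dropped_constant: List[str] = field(default_factory=list)
    imputed: Dict[str, int] = field(default_factory=dict)  # descriptor -> n imputed
    failures: List[Tuple[int, str]] = field(default_factory=list)
    standardized: bool = False
    mean_: Optional[pd.Series] = None
    sd_: Optional[pd.Series] = None

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]


def compute_descriptors(
    smiles: Sequence[str], set_labels: Optional[Sequence[str]] = None
) -> DescriptorMatrix:
    """Compute the full RDKit descriptor set for each structure.

    Descriptor evaluations that fail or return non-finite values are imputed
    by the column median and logged per descriptor; structures that fail to
    parse raise :class:`StructureError` (they should have been filtered by
    the reader).
    """
    if not smiles:
        raise ContractError("no structures supplied")
    labels = list(set_labels) if set_labels is not None else ["library"] * len(smiles)
    if len(labels) != len(smiles):
        raise ContractError("set_labels length != smiles length")
    rows = []
    failures: List[Tuple[int, str]] = []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise StructureError(smi)
        try:
            rows.append(Descriptors.CalcMolDescriptors(mol))
        except Exception as exc:  # descriptor-level failure for this molecule
            failures.append((i, str(exc)))
            rows.append({})
    df = pd.DataFrame(rows).apply(pd.to_numeric, errors="coerce")
    df = df.replace([np.inf, -np.inf], np.nan)
    if df.dropna(axis=1, how="all").empty:
        raise ContractError("descriptor computation failed for every structure")
    imputed: Dict[str, int] = {}
    for col in df.columns:
        n_missing = int(df[col].isna().sum())
        if n_missing:
            imputed[col] = n_missing
            median = df[col].median()
            df[col] = df[col].fillna(0.0 if np.isnan(median) else median)
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    df = df.drop(columns=constant)
    return DescriptorMatrix(
        values=df,
        set_labels=labels,
        dropped_constant=constant,
        imputed=imputed,
        failures=failures,
    )


def standardize(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Z-score every descriptor column in place (fit on all rows)."""
    if matrix.standardized:
        return matrix
    mean = matrix.values.mean()
    sd = matrix.values.std(ddof=1)
    sd = sd.replace(0.0, 1.0)
    matrix.values = (matrix.values - mean) / sd
    matrix.mean_, matrix.sd_ = mean, sd
    matrix.standardized = True
    return matrix


@dataclass
class EmbeddingResult:
    """2-D coordinates plus the exact parameters that produced them."""

    coordinates: pd.DataFrame  # columns: set_label, x, y
    perplexity: float
    max_iter: int
    learning_rate: object
    seed: int
    pca_components: Optional[int] = None
    kl_divergence: Optional[float] = None


def embed(
    matrix: DescriptorMatrix,
    seed: int = 42,
    perplexity: float = 30.0,
    max_iter: int = 1000,
    pca_components: Optional[int] = None,
) -> EmbeddingResult:
    """t-SNE embedding of a (standardised) descriptor matrix.

    Deterministic for a fixed seed and input order (PCA initialisation).  An
    optional PCA pre-reduction speeds up large inputs without changing the
    contract.
    """
    n = matrix.values.shape[0]
    if n < 4:
        raise ParameterError(f"need >= 4 rows to embed, got {n}")
    if perplexity >= n:
        raise ParameterError(f"perplexity ({perplexity}) must be < number of rows ({n})")
    if not matrix.standardized:
        matrix = standardize(matrix)
    x = matrix.values.to_numpy(dtype=float)
    if pca_components is not None and 0 < pca_components < x.shape[1]:
        x = PCA(n_components=pca_components, random_state=seed).fit_transform(x)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max_iter,
        init="pca",
        learning_rate="auto",
        random_state=seed,
    )
    coords = tsne.fit_transform(x)
    df = pd.DataFrame(
        {"set_label": matrix.set_labels, "x": coords[:, 0], "y": coords[:, 1]}
    )
    return EmbeddingResult(
        coordinates=df,
        perplexity=perplexity,
        max_iter=max_iter,
        learning_rate="auto",
        seed=seed,
        pca_components=pca_components,
        kl_divergence=float(getattr(tsne, "kl_divergence_", np.nan)),
    )


def write_embedding_html(result: EmbeddingResult, path, title: str = "chemical space") -> None:
    """Self-contained HTML/SVG scatter of an embedding, coloured by set label."""
    df = result.coordinates
    w = h = 640
    pad = 40
    xs, ys = df["x"].to_numpy(), df["y"].to_numpy()
    span = lambda v: (v.min(), max(v.max() - v.min(), 1e-9))  # noqa: E731
    (x0, xr), (y0, yr) = span(xs), span(ys)
    palette = {}
    colors = ["#d63384", "#b9a7d8", "#2e8b57", "#1f77b4"]
    for label in df["set_label"].unique():
        palette[label] = colors[len(palette) % len(colors)]
    circles = []
    for _, row in df.iterrows():
        cx = pad + (row["x"] - x0) / xr * (w - 2 * pad)
        cy = h - pad - (row["y"] - y0) / yr * (h - 2 * pad)
        circles.append(
            f'<circle cx="{cx:.1f}" cy="{cy:.1f}" r="3" '
            f'fill="{palette[row["set_label"]]}" fill-opacity="0.6">'
            f'<title>{row["set_label"]}</title></circle>'
        )
    legend = "".join(
        f'<text x="{pad}" y="{20 + 16 * i}" fill="{c}">{label}</text>'
        for i, (label, c) in enumerate(palette.items())
    )
    html = (
        f"<!DOCTYPE html><html><head><meta charset='utf-8'><title>{title}</title></head>"
        f"<body><h3>{title}</h3><svg width='{w}' height='{h}'>{legend}"
        + "".join(circles)
        + "</svg></body></html>"
    )
    from pathlib import Path

    Path(path).write_text(html)
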