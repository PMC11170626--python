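"""End-to-end pipeline: validate -> fingerprints -> scaffolds/CSR ->
profiles -> SAS -> embed -> report, driven by one declarative config."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import activity, fingerprints, sas, scaffolds, space
from .errors import ConfigurationError, StageError
from .io import read_database, read_smiles_list, write_library, write_report
from .synthetic import SyntheticSpec, generate_library
from .types import CompoundLibrary


@dataclass
class PipelineConfig:
    """Declarative run configuration; every stage reads only from here."""

    input_path: Optional[str] = None
    synthetic: Optional[dict] = None           # SyntheticSpec kwargs
    column_map: Optional[Dict[str, str]] = None
    fingerprint_kinds: Sequence[str] = fingerprints.FINGERPRINT_KINDS
    n_bits: int = fingerprints.DEFAULT_N_BITS
    scaffold_denominator: str = scaffolds.RING_BEARING_ONLY
    activity_threshold: float = sas.DEFAULT_ACTIVITY_THRESHOLD
    reference_smiles: Optional[str] = None
    perplexity: float = 30.0
    tsne_max_iter: int = 1000
    run_embedding: bool = True
    out_dir: str = "epichem_out"
    seed: int = 42
    report_formats: Sequence[str] = ("csv",)

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of input_path / synthetic must be given"
            )
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ConfigurationError(f"input file not found: {self.input_path}")
        kinds = [fingerprints.normalize_kind(k) for k in self.fingerprint_kinds]
        if len(set(kinds)) != len(kinds):
            raise ConfigurationError("duplicate fingerprint kinds")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_library(config: PipelineConfig):
    if config.synthetic is not None:
        spec_kwargs = dict(config.synthetic)
        spec_kwargs.setdefault("seed", config.seed)
        library = generate_library(SyntheticSpec(**spec_kwargs))
        return library, None
    library, report = read_database(config.input_path, column_map=config.column_map)
    return library, report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the manifest (also written to the output dir).

    A stage failure aborts the run with :class:`StageError`; outputs written
    so far are retained next to a ``FAILED`` marker naming the stage.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kinds = [fingerprints.normalize_kind(k) for k in config.fingerprint_kinds]
    tables: Dict[str, pd.DataFrame] = {}
    summary: dict = {"seed": config.seed}
    stages_done: List[str] = []

    def _fail(stage: str, exc: BaseException):
        (out_dir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise StageError(stage, exc)

    # validate / load
    try:
        library, read_report = _load_library(config)
        if config.synthetic is not None:
            write_library(library, out_dir / "library.csv")
        summary["n_compounds"] = len(library)
        summary.update(activity.population_summary(library))
        if read_report is not None:
            summary["n_rows_read"] = read_report.n_rows
            summary["n_rows_skipped"] = len(read_report.errors)
            summary["n_empty_activity_cells"] = read_report.n_empty_activity_cells
    except StageError:
        raise
    except Exception as exc:
        _fail("validate", exc)
    stages_done.append("validate")

    # fingerprints + pairwise similarity
    try:
        am = activity.ActivityMatrix.from_library(library)
        pair_table = fingerprints.pairwise_table(
            library, kinds=kinds, n_bits=config.n_bits, activity_matrix=am.matrix
        )
        tables["pairwise_similarity"] = pair_table
        with_self, without_self = fingerprints.count_pairs(len(library))
        summary["n_pairs_with_self"] = with_self
        summary["n_pairs_without_self"] = without_self
    except Exception as exc:
        _fail("fingerprints", exc)
    stages_done.append("fingerprints")

    # scaffolds + CSR
    try:
        stable = scaffolds.scaffold_table(library, config.scaffold_denominator)
        tables["scaffold_table"] = stable.rows
        curve = scaffolds.csr_curve(stable)
        tables["csr_points"] = scaffolds.csr_points_frame(curve)
        summary["n_unique_scaffolds"] = stable.n_unique_scaffolds
        summary["n_acyclic"] = stable.n_acyclic
        summary["csr_auc"] = curve.auc
        summary["top10_scaffold_coverage"] = stable.top_coverage(10)
    except Exception as exc:
        _fail("scaffolds", exc)
    stages_done.append("scaffolds")

    # activity profiles
    try:
        tables["target_frequency"] = activity.target_frequency(am)
        single = activity.single_target_compounds(am)
        tables["single_target"] = pd.DataFrame(
            list(single.per_target.items()), columns=["target", "count"]
        )
        tables["multi_target_ranking"] = activity.multi_target_ranking(
            am, k=min(10, len(library))
        )
        summary["n_single_target_compounds"] = single.total
    except Exception as exc:
        _fail("profiles", exc)
    stages_done.append("profiles")

    # SAS maps
    try:
        thresholds = sas.compute_thresholds(
            {k: pair_table[f"sim_{k}"].to_numpy() for k in kinds},
            activity_threshold=config.activity_threshold,
        )
        classification = sas.classify_regions(pair_table, thresholds)
        for k in kinds:
            points = sas.sas_points(classification, k)
            tables[f"sas_points_{k}"] = points
            sas.write_sas_html(points, out_dir / f"sas_map_{k}.html", title=f"SAS map ({k})")
        tables["consensus_region_II"] = sas.consensus_pairs(classification, "II", library)
        tables["consensus_region_IV"] = sas.consensus_pairs(classification, "IV", library)
        summary["sas_thresholds"] = {k: thresholds.structural[k] for k in kinds}
        summary["region_counts"] = {k: classification.region_counts(k) for k in kinds}
        summary["n_consensus_region_II"] = int(classification.table["consensus_II"].sum())
        summary["n_consensus_region_IV"] = int(classification.table["consensus_IV"].sum())
    except Exception as exc:
        _fail("sas", exc)
    stages_done.append("sas")

    # chemical-space embedding
    if config.run_embedding:
        try:
            smiles = list(library.smiles)
            labels = ["library"] * len(smiles)
            if config.reference_smiles:
                ref = read_smiles_list(config.reference_smiles)
                smiles += list(ref["smiles"])
                labels += ["reference"] * len(ref)
            matrix = space.compute_descriptors(smiles, labels)
            summary["n_descriptors"] = matrix.n_descriptors
            perplexity = min(config.perplexity, max(1.0, (len(smiles) - 1) / 3))
            result = space.embed(
                matrix,
                seed=config.seed,
                perplexity=perplexity,
                max_iter=config.tsne_max_iter,
            )
            coords = result.coordinates.copy()
            coords.insert(0, "row", range(len(coords)))
            tables["embedding"] = coords
            space.write_embedding_html(result, out_dir / "chemical_space.html")
            summary["tsne"] = {
                "perplexity": result.perplexity,
                "max_iter": result.max_iter,
                "seed": result.seed,
            }
        except Exception as exc:
            _fail("embed", exc)
        stages_done.append("embed")

    # report
    try:
        manifest_rows = write_report(tables, out_dir, formats=config.report_formats)
        summary_path = out_dir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=1, default=str))
        manifest = {
            "stages": stages_done + ["report"],
            "config": asdict(config),
            "summary": summary,
            "files": [
                {**row, "sha256": _sha256(Path(row["path"]))} for row in manifest_rows
            ]
            + [
                {
                    "table": "summary",
                    "format": "json",
                    "path": str(summary_path),
                    "rows": None,
                    "sha256": _sha256(summary_path),
                }
            ],
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    except Exception as exc:
        _fail("report", exc)
    return manifest
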