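"""Reading, validating, and writing the annotated compound-table CSV dialect.

The expected table has one row per compound: a block of general-information
columns (name, SMILES, InChI, InChIKey, food source, FooDB and COCONUT
cross-references, DOI) followed by binary activity columns.  Activity columns
whose header matches a panel target name populate the per-protein profile;
any remaining activity column is treated as a family-level "general activity"
flag.  Exact header text varies between releases of such tables, so all
general-information columns are resolved through a user-overridable
``column_map``.

Validation is total: every input row either becomes a record or is reported
as a :class:`RowIssue` with its row number and reason, and the two counts sum
to the row count.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .errors import ConfigurationError, StructureError
from .panel import TargetPanel, default_panel
from .types import FOODB_ABSENT_SENTINEL, CompoundLibrary, CompoundRecord

RDLogger.DisableLog("rdApp.error")

#: Default mapping from logical field -> CSV header.
DEFAULT_COLUMN_MAP: Dict[str, str] = {
    "name": "Name",
    "smiles": "SMILES",
    "inchi": "InChI",
    "inchikey": "InChIKey",
    "food_source": "Food source",
    "foodb_id": "FooDB ID",
    "coconut_id": "COCONUT ID",
    "doi": "DOI",
}

_MANDATORY_FIELDS = ("name", "smiles")
_LIST_SEPARATOR = ";"


@dataclass
class RowIssue:
    """One skipped row or warning produced during validation."""

    row: int  # 0-based data row index (header excluded)
    reason: str
    severity: str = "error"  # "error" rows are skipped; "warning" rows are kept


@dataclass
class ReadReport:
    """Accounting of a read: issues, empty-cell counts, and totals."""

    n_rows: int = 0
    n_records: int = 0
    issues: List[RowIssue] = field(default_factory=list)
    n_empty_activity_cells: int = 0

    @property
    def errors(self) -> List[RowIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> List[RowIssue]:
        return [i for i in self.issues if i.severity == "warning"]


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES of ``smiles``.

    Idempotent; two SMILES of the same molecule map to the same string.
    Raises :class:`StructureError` on unparseable input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureError(str(smiles), "empty or non-text input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles)
    return Chem.MolToSmiles(mol)


def _parse_activity_cell(value) -> Tuple[Optional[int], bool]:
    """Return ``(bit, was_empty)`` or raise ValueError for a domain violation."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return 0, True
    text = str(value).strip()
    if text == "" or text.lower() == "nan":
        return 0, True
    if text in ("0", "0.0"):
        return 0, False
    if text in ("1", "1.0"):
        return 1, False
    raise ValueError(f"activity value {value!r} not in {{0, 1, empty}}")


def _split_list_cell(value) -> List[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return []
    return [part.strip() for part in text.split(_LIST_SEPARATOR) if part.strip()]


def _optional_text(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return None
    return text


def read_database(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    panel: Optional[TargetPanel] = None,
) -> Tuple[CompoundLibrary, ReadReport]:
    """Read and validate a compound-table CSV.

    Parameters
    ----------
    path
        CSV file (UTF-8, comma-separated, header row).
    column_map
        Logical field -> header overrides, merged over
        :data:`DEFAULT_COLUMN_MAP`.
    panel
        Target panel; default is the 46-target epigenetic panel.  Activity
        columns not matching a panel target are read as family-level general
        flags, in header order.

    Returns
    -------
    (library, report)
        The validated library and a :class:`ReadReport`.  Rows with an
        unparseable SMILES or an out-of-domain activity cell are skipped and
        reported; the run continues.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    panel = panel or default_panel()
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    for field_name in _MANDATORY_FIELDS:
        if cmap[field_name] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {cmap[field_name]!r} (field {field_name!r}) "
                f"missing from {path.name}"
            )

    meta_headers = set(cmap.values())
    target_names = set(panel.names)
    specific_cols = [c for c in df.columns if c in target_names]
    general_cols = [
        c for c in df.columns if c not in meta_headers and c not in target_names
    ]
    missing_targets = [t for t in panel.names if t not in specific_cols]
    if specific_cols and missing_targets:
        raise ConfigurationError(
            f"activity columns present but panel targets missing: {missing_targets[:5]} ..."
            if len(missing_targets) > 5
            else f"activity columns present but panel targets missing: {missing_targets}"
        )
    if not specific_cols:
        raise ConfigurationError("no activity columns matching the target panel found")
    specific_cols = list(panel.names)  # panel order, not header order

    report = ReadReport(n_rows=len(df))
    records: List[CompoundRecord] = []
    for idx, row in df.iterrows():
        try:
            smiles = canonicalize(row[cmap["smiles"]])
        except StructureError as exc:
            report.issues.append(RowIssue(idx, f"unparseable SMILES: {exc.smiles!r}"))
            continue

        profile = np.zeros(len(panel), dtype=np.uint8)
        flags = np.zeros(len(general_cols), dtype=np.uint8)
        bad_cell = None
        for j, col in enumerate(specific_cols):
            try:
                bit, empty = _parse_activity_cell(row[col])
            except ValueError as exc:
                bad_cell = f"column {col!r}: {exc}"
                break
            profile[j] = bit
            report.n_empty_activity_cells += int(empty)
        if bad_cell is None:
            for j, col in enumerate(general_cols):
                try:
                    bit, empty = _parse_activity_cell(row[col])
                except ValueError as exc:
                    bad_cell = f"column {col!r}: {exc}"
                    break
                flags[j] = bit
                report.n_empty_activity_cells += int(empty)
        if bad_cell is not None:
            report.issues.append(RowIssue(idx, bad_cell))
            continue

        foodb = _optional_text(row.get(cmap["foodb_id"], None))
        if foodb == FOODB_ABSENT_SENTINEL:
            foodb = None

        record = CompoundRecord(
            compound_id=len(records),
            name=str(row[cmap["name"]]).strip(),
            smiles=smiles,
            specific_profile=profile,
            general_flags=flags,
            inchi=_optional_text(row.get(cmap["inchi"], None)),
            inchikey=_optional_text(row.get(cmap["inchikey"], None)),
            food_sources=_split_list_cell(row.get(cmap["food_source"], None)),
            foodb_id=foodb,
            coconut_id=_optional_text(row.get(cmap["coconut_id"], None)),
            doi=_split_list_cell(row.get(cmap["doi"], None)),
        )
        if record.inchikey_well_formed() is False:
            report.issues.append(
                RowIssue(idx, f"malformed InChIKey {record.inchikey!r}", "warning")
            )
        records.append(record)

    report.n_records = len(records)
    panel_for_lib = panel
    if general_cols and tuple(general_cols) != panel.general_families:
        panel_for_lib = TargetPanel(
            targets=panel.targets,
            families=panel.families,
            general_families=tuple(general_cols),
        )
    library = CompoundLibrary(records=records, panel=panel_for_lib, provenance=str(path))
    return library, report


def write_library(library: CompoundLibrary, path, column_map: Optional[Mapping[str, str]] = None) -> Path:
    """Write a library to the CSV dialect :func:`read_database` reads."""
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    general_cols = list(library.panel.general_families)
    rows = []
    for r in library.records:
        row = {
            cmap["name"]: r.name,
            cmap["smiles"]: r.smiles,
            cmap["inchi"]: r.inchi or "",
            cmap["inchikey"]: r.inchikey or "",
            cmap["food_source"]: _LIST_SEPARATOR.join(r.food_sources),
            cmap["foodb_id"]: r.foodb_id if r.foodb_id is not None else FOODB_ABSENT_SENTINEL,
            cmap["coconut_id"]: r.coconut_id or "",
            cmap["doi"]: _LIST_SEPARATOR.join(r.doi),
        }
        for j, t in enumerate(library.panel.names):
            row[t] = int(r.specific_profile[j])
        for j, g in enumerate(general_cols):
            row[g] = int(r.general_flags[j]) if j < len(r.general_flags) else 0
        rows.append(row)
    columns = list(cmap.values()) + list(library.panel.names) + general_cols
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


def read_smiles_list(path) -> pd.DataFrame:
    """Read a plain SMILES file (one per line, optional tab-separated id).

    Returns a DataFrame with columns ``smiles`` and ``id``; lines that fail to
    parse are dropped and counted in ``df.attrs['n_invalid']``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    rows = []
    n_invalid = 0
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            smi = canonicalize(parts[0])
        except StructureError:
            n_invalid += 1
            continue
        rows.append({"smiles": smi, "id": parts[1] if len(parts) > 1 else f"ref{i}"})
    df = pd.DataFrame(rows, columns=["smiles", "id"])
    df.attrs["n_invalid"] = n_invalid
    return df


def write_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    formats: Iterable[str] = ("csv",),
) -> List[Dict[str, object]]:
    """Write named result tables in the requested formats.

    One file per table per format; an empty table still produces a file with
    the header row.  Returns a manifest of ``{table, format, path, rows}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    formats = list(formats)
    unknown = set(formats) - {"csv", "json", "html"}
    if unknown:
        raise ConfigurationError(f"unsupported report formats: {sorted(unknown)}")
    manifest: List[Dict[str, object]] = []
    for name, table in tables.items():
        table = table[sorted(table.columns)] if table.attrs.get("sort_columns") else table
        for fmt in formats:
            out = out_dir / f"{name}.{fmt}"
            if fmt == "csv":
                table.to_csv(out, index=False)
            elif fmt == "json":
                out.write_text(json.dumps(table.to_dict(orient="records"), indent=1, default=str))
            else:
                table.to_html(out, index=False)
            manifest.append(
                {"table": name, "format": fmt, "path": str(out), "rows": int(len(table))}
            )
    return manifest
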