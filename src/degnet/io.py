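"""Readers and writers for every on-disk format.

All tables are UTF-8, tab-delimited TSV with ``#`` comment lines; gene
sets travel as GMT (one pathway per line: ID, description, members).
Readers validate against the in-memory type invariants and reject
malformed input with the offending row or column named; writers emit a
deterministic column order and 6-significant-digit floats so outputs
diff cleanly between runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .deg import DegResult, ExpressionMatrix
from .errors import FormatError, SchemaError
from .synthetic import PathwayAnnotation
from .toxassays import MetaboliteMatrix

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise FormatError(f"{path}: {exc}") from exc


def _write_tsv(frame: pd.DataFrame, path, index: bool) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------- GMT

def read_gmt(path) -> PathwayAnnotation:
    """Parse a GMT file into a pathway annotation.

    Each non-blank line is ID <tab> description <tab> member genes.
    Duplicate members within a line are deduplicated with a warning;
    duplicate pathway IDs or lines with fewer than three fields are
    format errors.
    """
    pathways: dict[str, tuple[str, frozenset]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            if pid in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway ID {pid!r}")
            if len(set(genes)) != len(genes):
                logger.warning(
                    "%s:%d: duplicate gene entries in pathway %s deduplicated",
                    path,
                    lineno,
                    pid,
                )
            pathways[pid] = (desc, frozenset(genes))
    if not pathways:
        raise FormatError(f"{path}: empty GMT file (no pathways)")
    return PathwayAnnotation(pathways=pathways)


def write_gmt(ann: PathwayAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, (desc, members) in ann.pathways.items():
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


# --------------------------------------------------- expression + design

def _read_design(path) -> pd.Series:
    design = _read_tsv(path)
    if list(design.columns[:2]) != ["sample", "condition"]:
        raise FormatError(f"{path}: design needs columns 'sample', 'condition'")
    if design["sample"].duplicated().any():
        dupes = design.loc[design["sample"].duplicated(), "sample"].tolist()
        raise FormatError(f"{path}: duplicate samples in design: {dupes}")
    return design.set_index("sample")["condition"]


def read_expression(matrix_path, design_path) -> ExpressionMatrix:
    """Load a genes x samples log2 matrix and its sample -> condition design."""
    frame = _read_tsv(matrix_path, index_col=0)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise FormatError(f"{matrix_path}: duplicate gene IDs: {dupes}")
    design = _read_design(design_path)
    missing = [s for s in frame.columns if s not in design.index]
    if missing:
        raise FormatError(
            f"{design_path}: samples present in matrix but not design: {missing}"
        )
    try:
        return ExpressionMatrix(values=frame, design=design)
    except SchemaError as exc:
        raise FormatError(f"{matrix_path}: {exc}") from exc


def write_expression(m: ExpressionMatrix, matrix_path, design_path) -> None:
    _write_tsv(m.values, matrix_path, index=True)
    _write_tsv(m.design.rename_axis("sample").reset_index(), design_path, index=False)


# ------------------------------------------------------ endpoint tables

def read_dose_response(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    required = ["dose_mg_per_L", "n_exposed", "n_dead"]
    if list(frame.columns[:3]) != required:
        raise FormatError(f"{path}: dose-response table needs columns {required}")
    if (frame["n_dead"] > frame["n_exposed"]).any():
        bad = frame.index[frame["n_dead"] > frame["n_exposed"]].tolist()
        raise FormatError(f"{path}: n_dead > n_exposed at rows {bad}")
    return frame


def read_reproduction(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    required = ["condition", "worm_id", "offspring"]
    if list(frame.columns[:3]) != required:
        raise FormatError(f"{path}: reproduction table needs columns {required}")
    if (frame["offspring"] < 0).any():
        raise FormatError(f"{path}: negative offspring counts")
    return frame


def read_ct(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    required = ["gene", "condition", "replicate", "ct"]
    if list(frame.columns[:4]) != required:
        raise FormatError(f"{path}: Ct table needs columns {required}")
    return frame


def read_metabolites(matrix_path, design_path) -> MetaboliteMatrix:
    frame = _read_tsv(matrix_path, index_col=0)
    design = _read_design(design_path)
    try:
        return MetaboliteMatrix(values=frame, design=design)
    except SchemaError as exc:
        raise FormatError(f"{matrix_path}: {exc}") from exc


def write_metabolites(m: MetaboliteMatrix, matrix_path, design_path) -> None:
    _write_tsv(m.values, matrix_path, index=True)
    _write_tsv(m.design.rename_axis("sample").reset_index(), design_path, index=False)


# ------------------------------------------------------------- results

def write_deg_table(result: DegResult, path) -> None:
    """Per-contrast DEG table: gene, log2fc, p, is_deg, direction."""
    _write_tsv(result.table.rename_axis("gene"), path, index=True)


def read_deg_list(path) -> frozenset:
    """One gene per line, or the DEG table TSV (then rows with is_deg true)."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if "\t" in first and "is_deg" in first:
        table = _read_tsv(path)
        return frozenset(table.loc[table["is_deg"], table.columns[0]])
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )


def write_venn_summary(common, a_only, b_only, labels: tuple[str, str], path) -> None:
    frame = pd.DataFrame(
        {
            "partition": ["common", f"{labels[0]}_only", f"{labels[1]}_only"],
            "n_genes": [len(common), len(a_only), len(b_only)],
            "genes": [
                ",".join(sorted(common)),
                ",".join(sorted(a_only)),
                ",".join(sorted(b_only)),
            ],
        }
    )
    _write_tsv(frame, path, index=False)


def write_pathway_results(
    results: pd.DataFrame, ann: PathwayAnnotation, path
) -> None:
    """Table-1-style report: pathway_id, description, observed_score, empirical_p, significant."""
    out = results.copy()
    out.insert(1, "description", [ann.pathways[p][0] for p in out["pathway_id"]])
    _write_tsv(out, path, index=False)


# -------------------------------------------------- config and manifest

def read_config(path) -> dict:
    """YAML key-value run configuration."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
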