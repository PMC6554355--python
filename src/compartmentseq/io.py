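"""Readers and writers for the plain-text formats the pipeline consumes.

Count tables follow the featureCounts convention: optional comment lines
starting with ``#``, a header row beginning with ``Geneid`` (optionally
followed by ``Chr``, ``Start``, ``End``, ``Strand``, ``Length``), then one
column per sample. Annotation, metadata and orthologue tables are simple
TSVs; gene sets use the GMT convention (name, description, gene ids).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import CountMatrix, GeneAnnotation

_FEATURECOUNTS_META = ("Chr", "Start", "End", "Strand", "Length")


def read_counts_tsv(path, metadata: pd.DataFrame, counting_mode: str = "all") -> CountMatrix:
    """Read a featureCounts-style TSV into a :class:`CountMatrix`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "Geneid":
        raise ValueError(f"{path}: first column must be 'Geneid', got {df.columns[0]!r}")
    df = df.set_index("Geneid")
    df.index.name = "gene_id"
    drop = [c for c in _FEATURECOUNTS_META if c in df.columns]
    df = df.drop(columns=drop)
    return CountMatrix(df, metadata, counting_mode)


def write_counts_tsv(cm: CountMatrix, path) -> Path:
    path = Path(path)
    out = cm.counts.copy()
    out.insert(0, "Geneid", out.index)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_annotation_tsv(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: annotation needs a 'gene_id' column")
    return GeneAnnotation(df.set_index("gene_id"))


def write_annotation_tsv(annotation: GeneAnnotation, path) -> Path:
    path = Path(path)
    out = annotation.table.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_metadata_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata needs a 'sample_id' column")
    return df.set_index("sample_id")


def write_metadata_tsv(metadata: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = metadata.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)
    return path


def read_gene_sets_gmt(path) -> dict[str, set]:
    """Read GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gene_sets_gmt(sets: dict, path, description: str = "na") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + sorted(genes)) + "\n")
    return path


def read_orthologue_map(path) -> pd.DataFrame:
    """Two-column TSV mapping source (e.g. human) → target (e.g. mouse) ids."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: orthologue map needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["source", "target"]
    return df


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    try:
        import numpy as np

        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
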