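"""Readers and writers for every external format the pipeline touches.

Formats: expression TSV (gene rows, sample columns, log2 intensities),
two-column condition map TSV, GMT gene sets, SIF interactions, flat
``key = value`` config files, and the tab-separated result tables every stage
emits.  Result tables round-trip: writing a list of records and reading the
file back reproduces the records to serialization precision (6 significant
digits for floats).
"""

from __future__ import annotations

import dataclasses
import logging
import typing
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, ParameterError
from .models import (
    CONDITIONS,
    ExpressionMatrix,
    PathwayGraph,
    RunConfig,
)

log = logging.getLogger("pathperturb")

#: SIF relation vocabulary -> edge sign.  Anything else maps to 0 (present
#: but unsigned): topology matters to the search even when sign is unknown.
SIF_RELATION_SIGN = {"activation": 1, "inhibition": -1}
SIGN_RELATION = {1: "activation", -1: "inhibition", 0: "interacts"}


# ---------------------------------------------------------------- expression


def read_expression_tsv(
    path, condition_map: Mapping[str, str], drop_incomplete: bool = True
) -> ExpressionMatrix:
    """Read a genes x samples log2 expression TSV.

    The header row holds sample ids, the first column gene ids.  Rows with a
    non-numeric or empty cell are dropped (with a logged count) when
    ``drop_incomplete`` is on, and raise :class:`FormatError` otherwise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    unlabelled = [s for s in df.columns if s not in condition_map]
    if unlabelled:
        raise ConfigError(f"{path}: samples missing from condition map: {unlabelled}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        if drop_incomplete:
            n_bad = int(bad.any(axis=1).sum())
            log.warning("%s: dropped %d gene row(s) with missing/non-numeric cells", path, n_bad)
            numeric = numeric.loc[~bad.any(axis=1)]
        else:
            r, c = next(zip(*np.nonzero(bad.to_numpy())))
            raise FormatError(
                f"{path}: non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
    return ExpressionMatrix(numeric.astype(float), {s: condition_map[s] for s in df.columns})


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_condition_map(path) -> dict[str, str]:
    """Two-column TSV ``sample<TAB>condition`` (header optional)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sample, cond = parts
        if lineno == 1 and cond not in CONDITIONS:
            continue  # header row
        if cond not in CONDITIONS:
            raise FormatError(f"{path}:{lineno}: unknown condition {cond!r}")
        out[sample] = cond
    return out


def write_condition_map(condition_of: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcondition\n")
        for sample, cond in condition_of.items():
            fh.write(f"{sample}\t{cond}\n")


# ---------------------------------------------------------------- gene sets


def read_gmt(path) -> list[PathwayGraph]:
    """Read a GMT file into edge-less pathway graphs (one per line)."""
    pathways: list[PathwayGraph] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        pid, desc, *genes = fields
        members = frozenset(g for g in genes if g)
        if not members:
            raise FormatError(f"{path}:{lineno}: pathway {pid!r} has no member genes")
        pathways.append(PathwayGraph(pid, desc or pid, members))
    if not pathways:
        log.warning("%s: empty GMT file, no pathways read", path)
    return pathways


def write_gmt(pathways: Sequence[PathwayGraph], path) -> None:
    with open(path, "w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")


def read_sif(path, pathways: Sequence[PathwayGraph]) -> list[PathwayGraph]:
    """Attach SIF interaction edges to every pathway containing both endpoints.

    Lines are ``source<TAB>relation<TAB>target[<TAB>target...]``; relations
    outside the known vocabulary get sign 0.  Edges whose endpoints fall in no
    common pathway are ignored (counted and logged).
    """
    edges: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: SIF line needs >= 3 fields")
        source, relation, *targets = fields
        sign = SIF_RELATION_SIGN.get(relation, 0)
        for target in targets:
            if not target:
                raise FormatError(f"{path}:{lineno}: empty target field")
            edges.append((source, target, sign))

    out: list[PathwayGraph] = []
    used = [False] * len(edges)
    for pw in pathways:
        mine = []
        for i, (u, v, s) in enumerate(edges):
            if u in pw.genes and v in pw.genes and u != v:
                mine.append((u, v, s))
                used[i] = True
        out.append(pw.with_edges(mine))
    n_orphan = sum(1 for i, (u, v, _) in enumerate(edges) if not used[i] and u != v)
    n_loops = sum(1 for u, v, _ in edges if u == v)
    if n_orphan:
        log.warning("%s: %d edge(s) matched no pathway and were ignored", path, n_orphan)
    if n_loops:
        log.warning("%s: %d self-loop(s) dropped", path, n_loops)
    return out


def write_sif(pathways: Sequence[PathwayGraph], path) -> None:
    """Write the union of pathway edges as SIF (each unordered edge once)."""
    seen = set()
    with open(path, "w") as fh:
        for pw in pathways:
            for u, v, sign in pw.edges:
                key = (u, v)
                if key in seen:
                    continue
                seen.add(key)
                fh.write(f"{u}\t{SIGN_RELATION[sign]}\t{v}\n")


# ---------------------------------------------------------------- config


def read_config(path, **overrides) -> RunConfig:
    """Flat ``key = value`` config file mirroring RunConfig field names.

    Blank lines and ``#`` comments are ignored; CLI flags override file values.
    """
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in stripped.split("=", 1))
        mapping[key] = value
    return RunConfig.from_mapping(mapping, **overrides)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        for key, value in config.to_dict().items():
            fh.write(f"{key} = {value}\n")


# ---------------------------------------------------------------- result tables


def _serialize(value) -> str:
    if isinstance(value, (frozenset, set, tuple, list)):
        return ";".join(sorted(map(str, value)))
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_results_tsv(records: Sequence, path, record_type: type | None = None) -> None:
    """Write dataclass records as a TSV with one column per field.

    Floats are serialized with 6 significant digits; sets are semicolon-joined
    in sorted order.  An empty record list still writes the header, for which
    ``record_type`` must then be given.
    """
    if records:
        record_type = type(records[0])
    if record_type is None:
        raise ParameterError("record_type required for an empty record list")
    names = [f.name for f in dataclasses.fields(record_type)]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for rec in records:
            fh.write(
                "\t".join(_serialize(getattr(rec, name)) for name in names) + "\n"
            )


def _parse(raw: str, hint):
    origin = typing.get_origin(hint)
    if origin in (frozenset, set, tuple, list):
        items = [x for x in raw.split(";") if x]
        return origin(items)
    if hint is float:
        return float(raw)
    if hint is int:
        return int(raw)
    return raw


def read_results_tsv(path, record_type: type) -> list:
    """Read back a table written by :func:`write_results_tsv`."""
    hints = typing.get_type_hints(record_type)
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty results file")
    header = lines[0].split("\t")
    expected = [f.name for f in dataclasses.fields(record_type)]
    if header != expected:
        raise FormatError(f"{path}: header {header} != expected {expected}")
    out = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
        kwargs = {name: _parse(cell, hints[name]) for name, cell in zip(header, cells)}
        out.append(record_type(**kwargs))
    return out


# ---------------------------------------------------------------- exon tables


def read_exon_table(path) -> pd.DataFrame:
    """Exon signal TSV: columns ``gene``, ``exon_id`` then one per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "exon_id": str})
    for col in ("gene", "exon_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_gene_table(path) -> pd.DataFrame:
    """Gene signal TSV: column ``gene`` then one per sample; gene-indexed."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if "gene" not in df.columns:
        raise FormatError(f"{path}: missing required column 'gene'")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    return df.set_index("gene")


def write_exon_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")
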