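"""On-disk formats: TSV matrices and tables, GMT gene sets, edge lists.

Conventions: expression/count matrices are TSV with a feature-id first
column and one column per sample; genotype dosages are TSV of {0,1,2};
networks are 3-column edge lists (source, target, region). Writers can
stamp a leading ``#`` comment naming the generating stage and config hash;
readers skip comment lines, so stamped files round-trip.

Identifiers are case-sensitive human-style symbols internally; mouse-case
symbols are harmonized on ingest by case-insensitive match.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .datatypes import DirectedNetwork, Edge, ExpressionMatrix, GeneSet
from .errors import ParseError

log = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_gene_list",
    "write_gene_list",
    "write_table",
    "harmonize_symbols",
]


def _stamp(path: Path, stage: str | None, config_hash: str | None) -> str:
    if stage is None and config_hash is None:
        return ""
    return f"# stage={stage or 'unknown'} config_hash={config_hash or 'none'}\n"


def read_expression_tsv(path: str | Path, meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a features x samples TSV (first column feature ids, header row
    sample ids). Rejects duplicates, ragged rows and non-numeric cells with
    the offending line number."""
    path = Path(path)
    text = path.read_text().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(text) if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty input")
    header = lines[0][1].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ParseError(f"{path}: header has no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    feats: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, ln in lines[1:]:
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        fid = parts[0]
        if fid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate feature id {fid!r}")
        seen.add(fid)
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        feats.append(fid)
    if not feats:
        raise ParseError(f"{path}: no data rows")
    values = pd.DataFrame(rows, index=feats, columns=sample_ids)
    if meta is None:
        meta = pd.DataFrame(index=sample_ids)
    return ExpressionMatrix(values, meta)


def write_expression_tsv(
    matrix: ExpressionMatrix | pd.DataFrame,
    path: str | Path,
    stage: str | None = None,
    config_hash: str | None = None,
) -> None:
    path = Path(path)
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    with open(path, "w") as fh:
        fh.write(_stamp(path, stage, config_hash))
        fh.write("feature_id\t" + "\t".join(map(str, values.columns)) + "\n")
        for fid, row in values.iterrows():
            fh.write(str(fid) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets in GMT format: name, description, members (tab-sep)."""
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        name, desc, *members = parts
        members = [m for m in members if m]
        uniq = list(dict.fromkeys(members))
        if len(uniq) != len(members):
            log.warning("%s:%d: %d duplicate member(s) in set %r deduplicated",
                        path, lineno, len(members) - len(uniq), name)
        sets.append(GeneSet(name=name, members=frozenset(uniq), description=desc))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *sorted(s.members)]) + "\n")


def read_edge_list(path: str | Path) -> DirectedNetwork:
    """Read a network as TSV: source, target, provenance (header optional)."""
    path = Path(path)
    edges: list[Edge] = []
    nodes: set[str] = set()
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if parts[0] == "source":
            continue
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: edge line needs >= 2 fields")
        src, tgt = parts[0], parts[1]
        prov = parts[2] if len(parts) > 2 else ""
        edges.append(Edge(src, tgt, prov))
        nodes.update((src, tgt))
    return DirectedNetwork(nodes=frozenset(nodes), edges=edges)


def write_edge_list(
    network: DirectedNetwork,
    path: str | Path,
    stage: str | None = None,
    config_hash: str | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(Path(path), stage, config_hash))
        fh.write("source\ttarget\tregion\n")
        for e in sorted(network.edges, key=lambda e: (e.source, e.target, e.provenance)):
            fh.write(f"{e.source}\t{e.target}\t{e.provenance}\n")


def read_gene_list(path: str | Path) -> list[str]:
    out = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    stage: str | None = None,
    config_hash: str | None = None,
    index: bool = False,
) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(Path(path), stage, config_hash))
        table.to_csv(fh, sep="\t", index=index)


def harmonize_symbols(symbols: Iterable[str], reference: Iterable[str]) -> dict[str, str]:
    """Map symbols onto a reference symbol set by case-insensitive match.

    Returns a mapping only for symbols that matched; unmatched symbols are
    logged with a count (cross-species homology mapping is out of scope).
    """
    ref = {r.upper(): r for r in reference}
    mapping: dict[str, str] = {}
    misses = 0
    for s in symbols:
        hit = ref.get(s.upper())
        if hit is not None:
            mapping[s] = hit
        else:
            misses += 1
    if misses:
        log.info("harmonize_symbols: %d symbol(s) had no case-insensitive match", misses)
    return mapping
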