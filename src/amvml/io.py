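"""Readers and writers for the on-disk formats.

The format surface is deliberately small and text-based:

* association matrices as two-column edge lists (``disease_id, mirna_id``,
  CSV or TSV, optional header) or dense headered CSV;
* similarity matrices and predictions as dense CSV with an identifier header
  row and index column, at full double precision;
* DAG edges as two-column TSV ``parent<TAB>child`` with a separate roots file;
* mature sequences as FASTA;
* solver configuration as a flat YAML mapping.

miRNA identifiers are lower-cased on input (hsa-mir-... convention); disease
identifiers are taken verbatim.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .containers import AssociationMatrix, SimilarityView
from .errors import ReconciliationError
from .similarity import DiseaseDAG
from .solver import AMVMLConfig

__all__ = [
    "read_association_list",
    "write_association",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "write_matrix",
    "read_fasta_sequences",
    "read_dag_edges",
    "build_disease_dag",
    "read_config",
    "align_axes",
]

logger = logging.getLogger("amvml")

_HEADER_TOKENS = {"disease", "disease_id", "mirna", "mirna_id", "mir", "mirna_name",
                  "disease_name"}


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_association_list(path: str | Path, format: str = "edge_list") -> AssociationMatrix:
    """Read a binary association matrix from an edge list or dense CSV.

    Edge lists have two columns (disease id, miRNA id); duplicates are
    collapsed to a single association and logged.  Axis orders are the sorted
    canonical identifiers.  Dense files carry disease ids as the index column
    and miRNA ids as the header.
    """
    path = Path(path)
    if format == "dense":
        df = pd.read_csv(path, index_col=0)
        mat = df.to_numpy()
        if not np.isin(mat, (0, 1)).all():
            raise ValueError(f"{path}: dense association matrix must be binary")
        return AssociationMatrix(
            matrix=mat,
            disease_ids=tuple(str(i) for i in df.index),
            mirna_ids=tuple(str(c).lower() for c in df.columns),
        )
    if format != "edge_list":
        raise ValueError(f"unknown format {format!r}")
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip().strip('"') for p in line.replace("\t", ",").split(",")]
            parts = [p for p in parts if p]
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            if lineno == 1 and parts[0].lower() in _HEADER_TOKENS:
                continue
            pairs.append((parts[0], parts[1].lower()))
    if not pairs:
        raise ValueError(f"{path}: no association records found")
    if len(set(pairs)) != len(pairs):
        logger.warning("%s: %d duplicate association records collapsed",
                       path, len(pairs) - len(set(pairs)))
        pairs = list(dict.fromkeys(pairs))
    diseases = tuple(sorted({d for d, _ in pairs}))
    mirnas = tuple(sorted({m for _, m in pairs}))
    drow = {d: i for i, d in enumerate(diseases)}
    mcol = {m: j for j, m in enumerate(mirnas)}
    Y = np.zeros((len(diseases), len(mirnas)), dtype=np.int8)
    for d, m in pairs:
        Y[drow[d], mcol[m]] = 1
    return AssociationMatrix(matrix=Y, disease_ids=diseases, mirna_ids=mirnas)


def write_association(
    assoc: AssociationMatrix, path: str | Path, format: str = "dense"
) -> None:
    path = Path(path)
    if format == "dense":
        pd.DataFrame(
            assoc.matrix, index=list(assoc.disease_ids), columns=list(assoc.mirna_ids)
        ).to_csv(path)
    elif format == "edge_list":
        sep = _sep_for(path)
        with open(path, "w") as fh:
            fh.write(f"disease_id{sep}mirna_id\n")
            for i, j in assoc.positives():
                fh.write(f"{assoc.disease_ids[i]}{sep}{assoc.mirna_ids[j]}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_similarity_matrix(
    path: str | Path, space: str = "disease", name: str | None = None
) -> SimilarityView:
    """Read a dense headered CSV similarity matrix.

    Row and column identifiers must agree; asymmetries up to 1e-8 are
    accepted silently, larger ones are symmetrized as ``(A + A') / 2`` with a
    warning.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix must be square, got {df.shape}")
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: header row and index column disagree")
    try:
        A = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.isfinite(A).all():
        i, j = np.argwhere(~np.isfinite(A))[0]
        raise ValueError(f"{path}: non-finite value at row {rows[i]!r}, column {cols[j]!r}")
    asym = np.abs(A - A.T).max()
    if asym > 1e-8:
        warnings.warn(
            f"{path}: matrix asymmetric by {asym:.3g}; symmetrizing as (A + A')/2",
            stacklevel=2,
        )
        A = 0.5 * (A + A.T)
    ids = tuple(r.lower() for r in rows) if space == "mirna" else tuple(rows)
    return SimilarityView(name=name or path.stem, space=space, matrix=A, ids=ids)


def write_matrix(
    matrix: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Write a dense matrix as headered CSV at full double precision."""
    pd.DataFrame(np.asarray(matrix), index=list(row_ids), columns=list(col_ids)).to_csv(
        path
    )


def write_similarity_matrix(view: SimilarityView, path: str | Path) -> None:
    write_matrix(view.matrix, view.ids, view.ids, path)


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read mature sequences from FASTA; record ids are lower-cased."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id.lower()] = str(rec.seq)
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    return seqs


def read_dag_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV ``parent<TAB>child`` edge list."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'parent<TAB>child'")
            if lineno == 1 and parts[0].strip().lower() in {"parent", "parent_id"}:
                continue
            edges.append((parts[0].strip(), parts[1].strip()))
    return edges


def build_disease_dag(disease: str, edges: Iterable[tuple[str, str]]) -> DiseaseDAG:
    """Ancestor closure of one disease from a global parent->child edge list."""
    parents_of: dict[str, set[str]] = {}
    for p, c in edges:
        parents_of.setdefault(c, set()).add(p)
    nodes = {disease}
    frontier = [disease]
    while frontier:
        node = frontier.pop()
        for parent in parents_of.get(node, ()):
            if parent not in nodes:
                nodes.add(parent)
                frontier.append(parent)
    induced = {(p, c) for p, c in edges if p in nodes and c in nodes}
    return DiseaseDAG(root=disease, nodes=frozenset(nodes), edges=frozenset(induced))


def read_config(path: str | Path) -> tuple[AMVMLConfig, dict]:
    """Read a flat YAML config; unknown keys are returned as extras."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f for f in AMVMLConfig.__dataclass_fields__}
    cfg = AMVMLConfig(**{k: v for k, v in raw.items() if k in known})
    extras = {k: v for k, v in raw.items() if k not in known}
    return cfg, extras


def align_axes(
    assoc: AssociationMatrix,
    views_D: Sequence[SimilarityView] = (),
    views_M: Sequence[SimilarityView] = (),
) -> tuple[AssociationMatrix, list[SimilarityView], list[SimilarityView]]:
    """Reindex all objects onto the association matrix's identifier order.

    Every view must cover the association matrix's identifiers in its space;
    missing identifiers raise a :class:`ReconciliationError` naming them (no
    silent imputation).  Idempotent: aligning aligned objects is a no-op.
    """
    out_D = []
    for v in views_D:
        if v.space != "disease":
            raise ValueError(f"view {v.name!r} is not a disease view")
        out_D.append(v.reindexed(assoc.disease_ids))
    out_M = []
    for v in views_M:
        if v.space != "mirna":
            raise ValueError(f"view {v.name!r} is not a miRNA view")
        out_M.append(v.reindexed(assoc.mirna_ids))
    return assoc, out_D, out_M
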