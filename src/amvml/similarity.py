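"""Similarity views for diseases and miRNAs.

Four constructions are provided, each yielding a :class:`SimilarityView`:

* **Disease semantic similarity** from MeSH-style directed acyclic graphs.
  Each disease contributes to its own semantics with weight 1 and each
  ancestor with a weight that decays by a factor of 0.5 per level (taking the
  best path when several exist).  Two diseases are similar in proportion to
  the total contribution of their shared ancestors.
* **miRNA sequence similarity** from global (end-to-end) pairwise alignment
  of mature sequences with an affine gap penalty, min-max normalized to [0, 1].
* **miRNA functional similarity** from the disease sets the miRNAs are known
  to be associated with, using best-match averaging of disease semantic
  similarities across the two sets.
* **Gaussian interaction profile (GIP) kernel similarity** in either space:
  an RBF kernel on the rows (diseases) or columns (miRNAs) of the binary
  association matrix, with the bandwidth scaled by the mean squared profile
  norm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from scipy.spatial.distance import cdist

from .containers import AssociationMatrix, SimilarityView
from .errors import DegenerateInputError, StructuralError

__all__ = [
    "DiseaseDAG",
    "AlignmentParams",
    "dag_contribution",
    "disease_semantic_similarity",
    "disease_group_similarity",
    "semantic_similarity_matrix",
    "mirna_functional_similarity",
    "align_score",
    "normalize_scores",
    "sequence_similarity",
    "gip_kernel",
]

DECAY = 0.5  # per-level decay of ancestor contributions


@dataclass(frozen=True)
class DiseaseDAG:
    """The ancestor closure of one disease in the MeSH hierarchy.

    ``root`` is the disease itself; ``nodes`` contains the disease together
    with all of its ancestors, and ``edges`` the directed parent->child links
    among them.  In MeSH orientation the disease sits at the bottom: every
    non-root node must reach the root by following child links.
    """

    root: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        if self.root not in self.nodes:
            raise StructuralError(f"root {self.root!r} not among DAG nodes")
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise StructuralError(f"edge ({p!r}, {c!r}) leaves the node set")

    def children(self, node: str) -> set[str]:
        return {c for p, c in self.edges if p == node}


def dag_contribution(dag: DiseaseDAG) -> dict[str, float]:
    """Semantic contribution of every node of ``dag`` to its root disease.

    The root contributes 1; any other node t contributes
    ``max(DECAY * contribution(child) for child of t within the DAG)``,
    i.e. contributions decay by 0.5 per hierarchy level along the best
    downward path to the disease.

    Raises
    ------
    StructuralError
        If the edge set contains a cycle, or a non-root node has no child
        inside the DAG (it could never reach the disease).
    """
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    if not nx.is_directed_acyclic_graph(g):
        raise StructuralError(f"DAG of {dag.root!r} contains a cycle")
    contrib: dict[str, float] = {}
    # children before parents: reversed topological order of parent->child edges
    for node in reversed(list(nx.topological_sort(g))):
        if node == dag.root:
            contrib[node] = 1.0
            continue
        kids = list(g.successors(node))
        if not kids:
            raise StructuralError(
                f"node {node!r} in DAG of {dag.root!r} has no child; "
                "every ancestor must reach the disease"
            )
        contrib[node] = max(DECAY * contrib[c] for c in kids)
    return contrib


def disease_semantic_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG) -> float:
    """Semantic similarity of two diseases from their shared ancestors.

    The value is the summed contribution of nodes common to both DAGs
    (counted from each side) over the total contribution in both DAGs;
    it is symmetric, 1 for identical DAGs and 0 for disjoint node sets.
    """
    ci = dag_contribution(dag_i)
    cj = dag_contribution(dag_j)
    shared = set(ci) & set(cj)
    num = sum(ci[t] + cj[t] for t in shared)
    den = sum(ci.values()) + sum(cj.values())
    return num / den


def disease_group_similarity(
    d: str, group: Iterable[str], S: Callable[[str, str], float]
) -> float:
    """Best-match similarity of disease ``d`` to a non-empty disease group."""
    group = list(group)
    if not group:
        raise ValueError("disease group must be non-empty")
    return max(S(d, g) for g in group)


def semantic_similarity_matrix(
    dags: Mapping[str, DiseaseDAG],
    disease_ids: Sequence[str],
    *,
    missing: str = "zero",
    name: str = "semantic",
) -> SimilarityView:
    """Pairwise disease semantic similarity matrix over ``disease_ids``.

    Diseases without a DAG get similarity 0 to every other disease and 1 to
    themselves when ``missing="zero"`` (the default), or raise a ``KeyError``
    when ``missing="error"``.
    """
    if missing not in ("zero", "error"):
        raise ValueError("missing must be 'zero' or 'error'")
    ids = list(disease_ids)
    absent = [d for d in ids if d not in dags]
    if absent and missing == "error":
        raise KeyError(f"no DAG for diseases: {absent[:10]}")
    contribs = {d: dag_contribution(dags[d]) for d in ids if d in dags}
    n = len(ids)
    M = np.eye(n)
    for a in range(n):
        ca = contribs.get(ids[a])
        if ca is None:
            continue
        total_a = sum(ca.values())
        for b in range(a):
            cb = contribs.get(ids[b])
            if cb is None:
                continue
            shared = set(ca) & set(cb)
            if shared:
                num = sum(ca[t] + cb[t] for t in shared)
                M[a, b] = M[b, a] = num / (total_a + sum(cb.values()))
    return SimilarityView(name=name, space="disease", matrix=M, ids=tuple(ids))


def mirna_functional_similarity(
    assoc: AssociationMatrix,
    disease_sim: SimilarityView,
    *,
    name: str = "functional",
) -> SimilarityView:
    """miRNA functional similarity from shared associated-disease semantics.

    For miRNAs i and j with known disease sets DT_i and DT_j, the similarity
    is the best-match average: each disease of one set is matched to its most
    similar disease in the other set, and the matched similarities from both
    directions are summed and divided by ``|DT_i| + |DT_j|``.  A miRNA with no
    known disease gets a zero row/column with a unit diagonal (the measure is
    undefined for it).
    """
    if disease_sim.space != "disease":
        raise ValueError("disease_sim must be a disease-space view")
    sim = disease_sim.reindexed(assoc.disease_ids)
    S = sim.matrix
    Y = assoc.matrix
    p = assoc.n_mirnas
    disease_sets = [np.flatnonzero(Y[:, j]) for j in range(p)]
    M = np.eye(p)
    for i in range(p):
        di = disease_sets[i]
        if di.size == 0:
            continue
        for j in range(i):
            dj = disease_sets[j]
            if dj.size == 0:
                continue
            sub = S[np.ix_(di, dj)]
            val = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (di.size + dj.size)
            M[i, j] = M[j, i] = val
    return SimilarityView(name=name, space="mirna", matrix=M, ids=assoc.mirna_ids)


# ---------------------------------------------------------------------------
# sequence similarity
# ---------------------------------------------------------------------------

_ALPHABET = set("ACGU")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for global nucleotide alignment.

    ``gap_open`` and ``gap_extend`` are penalties (non-negative); a gap of
    length L costs ``gap_open + gap_extend * L`` when
    ``first_gap_includes_extend`` is True (the convention of the Biostrings
    ``pairwiseAlignment`` function: the first gap position pays both the
    opening and an extension), or ``gap_open + gap_extend * (L - 1)``
    otherwise.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    first_gap_includes_extend: bool = True

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


def _normalize_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("sequence must be non-empty")
    s = seq.upper().replace("T", "U")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGU/T characters: {sorted(bad)}")
    return s


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    first = params.gap_open + (params.gap_extend if params.first_gap_includes_extend else 0.0)
    aligner.open_gap_score = -first
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_score(
    seq_i: str, seq_j: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Optimal global alignment score of two RNA sequences.

    Sequences are upper-cased and T is mapped to U before alignment; end gaps
    are penalized like internal gaps (true end-to-end alignment).
    """
    a = _normalize_sequence(seq_i)
    b = _normalize_sequence(seq_j)
    return float(_make_aligner(params).score(a, b))


def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Affinely map a score matrix onto [0, 1] by its global min and max.

    The extremes are taken over *all* entries, including self-alignments on
    the diagonal, so the best self-alignment maps to 1.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("score matrix contains non-finite entries")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise DegenerateInputError("all alignment scores identical; cannot min-max normalize")
    return (raw - lo) / (hi - lo)


def sequence_similarity(
    sequences: Mapping[str, str],
    mirna_ids: Sequence[str],
    params: AlignmentParams = AlignmentParams(),
    *,
    name: str = "sequence",
) -> SimilarityView:
    """Min-max-normalized global-alignment similarity over ``mirna_ids``."""
    ids = list(mirna_ids)
    missing = [m for m in ids if m not in sequences]
    if missing:
        raise KeyError(f"no sequence for miRNAs: {missing[:10]}")
    seqs = [_normalize_sequence(sequences[m]) for m in ids]
    aligner = _make_aligner(params)
    n = len(ids)
    raw = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            raw[i, j] = raw[j, i] = aligner.score(seqs[i], seqs[j])
    return SimilarityView(
        name=name, space="mirna", matrix=normalize_scores(raw), ids=tuple(ids)
    )


def gip_kernel(
    assoc: AssociationMatrix,
    space: str,
    bandwidth_prior: float = 1.0,
    *,
    name: str | None = None,
) -> SimilarityView:
    """Gaussian interaction profile kernel similarity in one entity space.

    The profile of a disease is its row of Y, the profile of a miRNA its
    column.  The kernel is ``exp(-beta * ||IP_i - IP_j||^2)`` with
    ``beta = bandwidth_prior / mean(||IP||^2)``, so the bandwidth adapts to
    the overall density of the association matrix.
    """
    if space not in ("disease", "mirna"):
        raise ValueError(f"space must be 'disease' or 'mirna', got {space!r}")
    if bandwidth_prior <= 0:
        raise ValueError("bandwidth_prior must be positive")
    Y = assoc.matrix.astype(float)
    profiles = Y if space == "disease" else Y.T
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise DegenerateInputError("association matrix is all-zero; GIP bandwidth undefined")
    beta = bandwidth_prior / mean_sq
    K = np.exp(-beta * cdist(profiles, profiles, "sqeuclidean"))
    ids = assoc.disease_ids if space == "disease" else assoc.mirna_ids
    return SimilarityView(
        name=name or f"gip_{space}", space=space, matrix=K, ids=ids
    )
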