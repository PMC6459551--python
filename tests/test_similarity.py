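"""Unit and oracle tests for the similarity constructions."""

import itertools

import numpy as np
import pytest

from amvml import AssociationMatrix, SimilarityView
from amvml.errors import DegenerateInputError, StructuralError
from amvml.similarity import (
    AlignmentParams,
    DiseaseDAG,
    align_score,
    dag_contribution,
    disease_group_similarity,
    disease_semantic_similarity,
    gip_kernel,
    mirna_functional_similarity,
    normalize_scores,
    semantic_similarity_matrix,
)

# ---------------------------------------------------------------------------
# disease DAG semantics
# ---------------------------------------------------------------------------

def dag(root, nodes, edges):
    return DiseaseDAG(root=root, nodes=frozenset(nodes), edges=frozenset(edges))


CHAIN = dag("r", {"r", "a", "b"}, {("a", "r"), ("b", "a")})
DIAMOND = dag("r", {"r", "a", "b", "c"},
              {("a", "r"), ("b", "r"), ("c", "a"), ("c", "b")})


@pytest.mark.parametrize(
    "d, expected",
    [
        (dag("r", {"r"}, set()), {"r": 1.0}),
        (CHAIN, {"r": 1.0, "a": 0.5, "b": 0.25}),
        (DIAMOND, {"r": 1.0, "a": 0.5, "b": 0.5, "c": 0.25}),
    ],
)
def test_dag_contribution_decays_along_best_path(d, expected):
    assert dag_contribution(d) == pytest.approx(expected)


def test_dag_contribution_rejects_cycles_and_dangling_nodes():
    with pytest.raises(StructuralError):
        dag_contribution(dag("r", {"r", "a"}, {("a", "r"), ("r", "a")}))
    # "x" has no child in the DAG: it can never reach the disease
    with pytest.raises(StructuralError):
        dag_contribution(dag("r", {"r", "x"}, set()))


def test_semantic_similarity_identical_disjoint_and_toy():
    assert disease_semantic_similarity(CHAIN, CHAIN) == pytest.approx(1.0)
    other = dag("s", {"s", "x"}, {("x", "s")})
    assert disease_semantic_similarity(CHAIN, other) == 0.0
    d1 = dag("d1", {"d1", "a"}, {("a", "d1")})
    d2 = dag("d2", {"d2", "a"}, {("a", "d2")})
    # shared ancestor contributes 0.5 from each side over totals 1.5 + 1.5
    assert disease_semantic_similarity(d1, d2) == pytest.approx(1.0 / 3.0)
    assert disease_semantic_similarity(d2, d1) == pytest.approx(1.0 / 3.0)


def test_semantic_similarity_monotone_in_shared_ancestry():
    # same pair, but a second shared ancestor is added to both DAGs
    d1 = dag("d1", {"d1", "a"}, {("a", "d1")})
    d2 = dag("d2", {"d2", "a"}, {("a", "d2")})
    base = disease_semantic_similarity(d1, d2)
    e1 = dag("d1", {"d1", "a", "t"}, {("a", "d1"), ("t", "a")})
    e2 = dag("d2", {"d2", "a", "t"}, {("a", "d2"), ("t", "a")})
    assert disease_semantic_similarity(e1, e2) >= base


def test_group_similarity_is_a_max():
    S = lambda x, y: {("d", "x"): 0.2, ("d", "y"): 0.7, ("d", "d"): 1.0}[(x, y)]
    assert disease_group_similarity("d", ["x", "y"], S) == 0.7
    assert disease_group_similarity("d", ["x"], S) == 0.2
    assert disease_group_similarity("d", ["d", "x"], S) == 1.0
    with pytest.raises(ValueError):
        disease_group_similarity("d", [], S)


def test_semantic_matrix_matches_pairwise_calls_and_handles_missing():
    dags = {
        "d1": dag("d1", {"d1", "a"}, {("a", "d1")}),
        "d2": dag("d2", {"d2", "a"}, {("a", "d2")}),
        "d3": dag("d3", {"d3"}, set()),
    }
    view = semantic_similarity_matrix(dags, ["d1", "d2", "d3"])
    assert np.allclose(view.matrix, view.matrix.T)
    assert np.allclose(np.diag(view.matrix), 1.0)
    for i, j in itertools.combinations(range(3), 2):
        ids = ["d1", "d2", "d3"]
        assert view.matrix[i, j] == pytest.approx(
            disease_semantic_similarity(dags[ids[i]], dags[ids[j]])
        )
    # a disease with no DAG: zero to all others, one to itself
    partial = semantic_similarity_matrix({"d1": dags["d1"]}, ["d1", "d2"])
    assert partial.matrix[0, 1] == 0.0 and partial.matrix[1, 1] == 1.0
    with pytest.raises(KeyError):
        semantic_similarity_matrix({"d1": dags["d1"]}, ["d1", "d2"], missing="error")


# ---------------------------------------------------------------------------
# miRNA functional similarity
# ---------------------------------------------------------------------------

from tests_oracles import functional_oracle as _functional_oracle  # noqa: E402
from tests_oracles import gip_oracle as _gip_oracle  # noqa: E402


def test_functional_similarity_hand_values():
    S = np.array([[1.0, 0.4, 0.5], [0.4, 1.0, 0.3], [0.5, 0.3, 1.0]])
    dsim = SimilarityView(name="s", space="disease", matrix=S, ids=("a", "b", "c"))
    # m0: {a}, m1: {b}, m2: {a,b}, m3: {}
    Y = np.array([[1, 0, 1, 0], [0, 1, 1, 0], [0, 0, 0, 0]])
    assoc = AssociationMatrix(matrix=Y, disease_ids=("a", "b", "c"),
                              mirna_ids=("m0", "m1", "m2", "m3"))
    view = mirna_functional_similarity(assoc, dsim)
    assert view.matrix[0, 1] == pytest.approx(0.4)  # singleton sets: S(a,b)
    # DT_i={a,b}, DT_j={b}: (S(a,{b}) + S(b,{b}) + S(b,{a,b})) / 3
    assert view.matrix[2, 1] == pytest.approx((0.4 + 1.0 + 1.0) / 3.0)
    assert np.allclose(np.diag(view.matrix), 1.0)
    # empty disease set: zero row/column except the diagonal
    assert view.matrix[3, :3].max() == 0.0 and view.matrix[3, 3] == 1.0


def test_functional_similarity_equals_naive_loop(rng):
    Y = rng.binomial(1, 0.4, size=(6, 8))
    R = rng.uniform(0.0, 1.0, size=(6, 6))
    S = 0.5 * (R + R.T)
    np.fill_diagonal(S, 1.0)
    dsim = SimilarityView(name="s", space="disease", matrix=S,
                          ids=tuple(f"d{k}" for k in range(6)))
    assoc = AssociationMatrix(matrix=Y, disease_ids=dsim.ids,
                              mirna_ids=tuple(f"m{k}" for k in range(8)))
    view = mirna_functional_similarity(assoc, dsim)
    assert np.allclose(view.matrix, _functional_oracle(Y, S), atol=1e-12)
    assert np.allclose(view.matrix, view.matrix.T)


# ---------------------------------------------------------------------------
# sequence alignment
# ---------------------------------------------------------------------------

def _gap_cost(length, params):
    extra = params.gap_extend if params.first_gap_includes_extend else 0.0
    return params.gap_open + extra + params.gap_extend * (length - 1)


def _align_oracle(a, b, params):
    """Exhaustive enumeration of all global alignments with affine gap runs."""
    best = -np.inf

    def rec(i, j, score, gap_state):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = params.match if a[i] == b[j] else params.mismatch
            rec(i + 1, j + 1, score + s, None)
        if i < len(a):  # gap in b
            cost = _gap_cost(1, params) if gap_state != "del" else params.gap_extend
            rec(i + 1, j, score - cost, "del")
        if j < len(b):  # gap in a
            cost = _gap_cost(1, params) if gap_state != "ins" else params.gap_extend
            rec(i, j + 1, score - cost, "ins")

    rec(0, 0, 0.0, None)
    return best


@pytest.mark.parametrize("first_gap_includes_extend", [True, False])
def test_align_score_matches_exhaustive_enumeration(first_gap_includes_extend, rng):
    params = AlignmentParams(first_gap_includes_extend=first_gap_includes_extend)
    alphabet = "AC"
    seqs = ["".join(s) for L in (1, 2, 3)
            for s in itertools.product(alphabet, repeat=L)]
    for a, b in itertools.product(seqs, repeat=2):
        assert align_score(a, b, params) == pytest.approx(_align_oracle(a, b, params))
    # sampled longer pairs over the two-letter alphabet
    for _ in range(120):
        a = "".join(rng.choice(list(alphabet), size=rng.integers(4, 6)))
        b = "".join(rng.choice(list(alphabet), size=rng.integers(4, 6)))
        assert align_score(a, b, params) == pytest.approx(_align_oracle(a, b, params))


def test_align_score_basics():
    assert align_score("ACGUA", "ACGUA") == 5.0
    assert align_score("ACGU", "ACGA") == 2.0  # three matches, one mismatch
    assert align_score("A", "AG") == pytest.approx(1.0 - 7.0)  # match + length-1 gap
    assert align_score("acgt", "ACGU") == 4.0  # case folding and T->U
    assert align_score("AG", "A") == align_score("A", "AG")  # symmetry
    with pytest.raises(ValueError):
        align_score("", "ACGU")
    with pytest.raises(ValueError):
        align_score("ACGN", "ACGU")


def test_normalize_scores_examples_and_affine_invariance(rng):
    assert np.allclose(normalize_scores(np.array([[4.0, 2.0], [2.0, 4.0]])),
                       [[1, 0], [0, 1]])
    assert np.allclose(normalize_scores(np.array([[4.0, 2.0], [2.0, 3.0]])),
                       [[1, 0], [0, 0.5]])
    with pytest.raises(DegenerateInputError):
        normalize_scores(np.full((3, 3), 2.0))
    X = rng.normal(size=(5, 5))
    assert np.allclose(normalize_scores(3.2 * X + 7.0), normalize_scores(X))


# ---------------------------------------------------------------------------
# interaction-profile kernel
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("space", ["disease", "mirna"])
def test_gip_kernel_equals_naive_double_loop(space, rng):
    for _ in range(5):
        Y = rng.binomial(1, 0.4, size=(6, 8))
        if Y.sum() == 0:
            continue
        assoc = AssociationMatrix(matrix=Y,
                                  disease_ids=tuple(f"d{k}" for k in range(6)),
                                  mirna_ids=tuple(f"m{k}" for k in range(8)))
        K = gip_kernel(assoc, space, 1.0).matrix
        assert np.allclose(K, _gip_oracle(Y.astype(float), space, 1.0), atol=1e-12)
        assert np.allclose(np.diag(K), 1.0)
        assert (K > 0).all() and (K <= 1).all()


def test_gip_kernel_identity_example_and_bandwidth_scaling():
    assoc = AssociationMatrix(matrix=np.eye(2, dtype=int),
                              disease_ids=("d0", "d1"), mirna_ids=("m0", "m1"))
    K1 = gip_kernel(assoc, "mirna", 1.0).matrix
    # profiles are unit columns: mean squared norm 1, squared distance 2
    assert K1[0, 1] == pytest.approx(np.exp(-2.0))
    K2 = gip_kernel(assoc, "mirna", 2.0).matrix
    assert K2[0, 1] == pytest.approx(K1[0, 1] ** 2)
    empty = AssociationMatrix(matrix=np.zeros((2, 2), dtype=int),
                              disease_ids=("d0", "d1"), mirna_ids=("m0", "m1"))
    with pytest.raises(DegenerateInputError):
        gip_kernel(empty, "disease")


def test_all_views_are_symmetric_and_finite(default_instance):
    for view in default_instance.views_D + default_instance.views_M:
        assert np.abs(view.matrix - view.matrix.T).max() < 1e-10
        assert np.isfinite(view.matrix).all()
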