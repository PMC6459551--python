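"""Cross-validation protocols for association predictors.

Four validation frameworks are provided, all leakage-safe: any similarity
view that is *derived from the association matrix* (interaction-profile
kernels, functional similarity) is rebuilt from the masked training matrix in
every fold, while label-independent views (sequence, semantic) are passed
through unchanged.  Views are therefore specified either as a ready
:class:`SimilarityView` or as a *builder* — a callable mapping the training
:class:`AssociationMatrix` to a view.

* ``global_loocv`` — leave out one known association at a time and rank it
  against every pair unobserved in the full matrix.
* ``kfold_cv`` — repeated k-fold partition of the positives (default 5 folds,
  10 repeats), one ROC per fold.
* ``lodocv`` — leave-one-disease-out: blank a disease's whole row and recover
  it from the other diseases; one AUC per disease.
* ``topn_validation`` — train on an older snapshot and count per-disease
  top-N predictions confirmed by a newer snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
from scipy.stats import wilcoxon
from sklearn.metrics import roc_auc_score, roc_curve

from .containers import AssociationMatrix, SimilarityView
from .errors import ReconciliationError, UndefinedMetricError
from .similarity import gip_kernel, mirna_functional_similarity
from .solver import AMVMLConfig, fit_amvml

__all__ = [
    "CVReport",
    "ViewLike",
    "Predictor",
    "gip_view_builder",
    "functional_view_builder",
    "realize_views",
    "amvml_predictor",
    "similarity_profile_baseline",
    "roc_auc",
    "roc_points",
    "global_loocv",
    "kfold_cv",
    "lodocv",
    "topn_validation",
    "compare_auc_vectors",
    "snapshot_counts",
]

ViewBuilder = Callable[[AssociationMatrix], SimilarityView]
ViewLike = Union[SimilarityView, ViewBuilder]
Predictor = Callable[
    [Sequence[SimilarityView], Sequence[SimilarityView], AssociationMatrix, AMVMLConfig],
    np.ndarray,
]


@dataclass
class CVReport:
    """Outcome of one validation run."""

    scheme: str
    auc: float | np.ndarray
    auc_sd: float | None = None
    roc_points: np.ndarray | None = None
    per_fold_auc: list[float] | None = None
    folds: list | None = None
    seed: int | None = None
    n_repeats: int | None = None
    excluded: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        return {
            "scheme": self.scheme,
            "auc": conv(self.auc),
            "auc_sd": conv(self.auc_sd),
            "roc_points": conv(self.roc_points),
            "per_fold_auc": conv(self.per_fold_auc),
            "folds": conv(self.folds),
            "seed": self.seed,
            "n_repeats": self.n_repeats,
            "excluded": list(self.excluded),
            "extra": conv(self.extra),
        }


# ---------------------------------------------------------------------------
# view specification
# ---------------------------------------------------------------------------

def gip_view_builder(space: str, bandwidth_prior: float = 1.0) -> ViewBuilder:
    """Builder for an interaction-profile kernel view, recomputed per fold."""
    return lambda assoc: gip_kernel(assoc, space, bandwidth_prior)


def functional_view_builder(disease_sim: SimilarityView) -> ViewBuilder:
    """Builder for the miRNA functional-similarity view, recomputed per fold."""
    return lambda assoc: mirna_functional_similarity(assoc, disease_sim)


def realize_views(
    views: Sequence[ViewLike], assoc_train: AssociationMatrix
) -> list[SimilarityView]:
    """Materialize static views and builders against a training matrix."""
    return [v(assoc_train) if callable(v) else v for v in views]


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------

def amvml_predictor(
    views_D: Sequence[SimilarityView],
    views_M: Sequence[SimilarityView],
    assoc_train: AssociationMatrix,
    config: AMVMLConfig,
) -> np.ndarray:
    """The AMVML model as a predictor: returns the fitted score matrix F."""
    return fit_amvml(views_D, views_M, assoc_train, config).F


def similarity_profile_baseline(
    views_D: Sequence[SimilarityView],
    views_M: Sequence[SimilarityView],
    assoc_train: AssociationMatrix,
    config: AMVMLConfig,
) -> np.ndarray:
    """Label-free baseline: mean miRNA similarity to a disease's known miRNAs.

    ``score(d, m) = sum_{m'} Y[d, m'] * A[m', m] / max(1, #positives of d)``
    with A the element-wise mean of the supplied miRNA views.  No graph
    learning, no disease-space propagation.
    """
    A = np.mean([v.matrix for v in views_M], axis=0)
    Y = assoc_train.matrix.astype(float)
    counts = Y.sum(axis=1, keepdims=True)
    return (Y @ A) / np.maximum(counts, 1.0)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney normalization, ties credited 0.5)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC curve as an array of (FPR, TPR) pairs, both monotone."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# validation schemes
# ---------------------------------------------------------------------------

def global_loocv(
    views_D: Sequence[ViewLike],
    views_M: Sequence[ViewLike],
    assoc: AssociationMatrix,
    config: AMVMLConfig = AMVMLConfig(),
    predictor: Predictor = amvml_predictor,
) -> CVReport:
    """Global leave-one-out cross-validation.

    Each known association is masked in turn, Y-derived views are rebuilt
    from the masked matrix, the model is refitted, and the held-out pair is
    ranked against every pair that is unobserved in the *full* matrix.  The
    global AUC is the mean, over held-out positives, of the fraction of
    candidate pairs scored below the positive (ties counted half); the ROC
    curve is the corresponding exceedance curve.
    """
    Y = assoc.matrix
    positives = np.argwhere(Y == 1)
    if len(positives) < 2:
        raise ValueError("global LOOCV needs at least two known associations")
    candidate_mask = Y == 0
    fracs = np.empty(len(positives))
    for k, (i, j) in enumerate(positives):
        Yt = Y.copy()
        Yt[i, j] = 0
        train = assoc.with_matrix(Yt)
        F = predictor(
            realize_views(views_D, train), realize_views(views_M, train), train, config
        )
        s = F[i, j]
        cand = F[candidate_mask]
        fracs[k] = ((cand < s).sum() + 0.5 * (cand == s).sum()) / cand.size
    # exceedance curve: at false-positive rate x, the true-positive rate is
    # the fraction of held-out positives outranking all but an x-fraction of
    # the candidates
    grid = np.linspace(0.0, 1.0, 201)
    tpr = np.array([np.mean(fracs >= 1.0 - x) for x in grid])
    return CVReport(
        scheme="global_loocv",
        auc=float(fracs.mean()),
        roc_points=np.column_stack([grid, tpr]),
        extra={"per_positive_quantile": fracs},
    )


def _derived_seed(seed: int, offset: int) -> int:
    return int((seed + offset) % (2**31 - 1))


def kfold_cv(
    views_D: Sequence[ViewLike],
    views_M: Sequence[ViewLike],
    assoc: AssociationMatrix,
    config: AMVMLConfig = AMVMLConfig(),
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    predictor: Predictor = amvml_predictor,
) -> CVReport:
    """Repeated k-fold cross-validation over the known associations.

    Per repeat, positives are randomly partitioned into k folds; each fold is
    masked in turn, Y-derived views are rebuilt, the model is refitted, and a
    ROC is computed over the masked positives versus all pairs unobserved in
    the full matrix.  Reports the mean and standard deviation of the
    ``k * repeats`` fold AUCs.
    """
    Y = assoc.matrix
    positives = np.argwhere(Y == 1)
    if len(positives) < k:
        raise ValueError(f"need at least {k} positives for {k}-fold CV")
    neg_mask = Y == 0
    fold_aucs: list[float] = []
    fold_record: list[list[list[int]]] = []
    for r in range(repeats):
        rng = np.random.default_rng(_derived_seed(seed, r))
        perm = rng.permutation(len(positives))
        folds = np.array_split(perm, k)
        fold_record.append([f.tolist() for f in folds])
        for fold in folds:
            held = positives[fold]
            Yt = Y.copy()
            Yt[held[:, 0], held[:, 1]] = 0
            train = assoc.with_matrix(Yt)
            F = predictor(
                realize_views(views_D, train), realize_views(views_M, train), train, config
            )
            scores = np.concatenate([F[held[:, 0], held[:, 1]], F[neg_mask]])
            labels = np.concatenate(
                [np.ones(len(held), dtype=int), np.zeros(int(neg_mask.sum()), dtype=int)]
            )
            fold_aucs.append(roc_auc(scores, labels))
    aucs = np.array(fold_aucs)
    return CVReport(
        scheme="kfold",
        auc=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        per_fold_auc=[float(a) for a in aucs],
        folds=fold_record,
        seed=seed,
        n_repeats=repeats,
    )


def lodocv(
    views_D: Sequence[ViewLike],
    views_M: Sequence[ViewLike],
    assoc: AssociationMatrix,
    config: AMVMLConfig = AMVMLConfig(),
    predictor: Predictor = amvml_predictor,
) -> CVReport:
    """Leave-one-disease-out cross-validation: one AUC per evaluated disease.

    For each disease with at least one known association, its whole row is
    blanked, Y-derived views are rebuilt, the model is refitted, and the AUC
    of the blanked row's scores against the original row labels is recorded.
    Diseases with no positives are excluded and listed in the report.
    """
    Y = assoc.matrix
    aucs: list[float] = []
    evaluated: list[str] = []
    excluded: list[str] = []
    for i, did in enumerate(assoc.disease_ids):
        if Y[i].sum() == 0:
            excluded.append(did)
            continue
        Yt = Y.copy()
        Yt[i, :] = 0
        train = assoc.with_matrix(Yt)
        F = predictor(
            realize_views(views_D, train), realize_views(views_M, train), train, config
        )
        aucs.append(roc_auc(F[i], Y[i]))
        evaluated.append(did)
    return CVReport(
        scheme="lodocv",
        auc=np.array(aucs),
        excluded=excluded,
        extra={"diseases": evaluated},
    )


def topn_validation(
    Y_old: AssociationMatrix,
    Y_new: AssociationMatrix,
    views_D: Sequence[ViewLike],
    views_M: Sequence[ViewLike],
    config: AMVMLConfig = AMVMLConfig(),
    N_list: Sequence[int] = (10, 20, 30, 40, 50),
    predictor: Predictor = amvml_predictor,
    mode: str = "per_disease",
) -> CVReport:
    """Temporal validation: train on an old snapshot, confirm with a new one.

    The model is fitted on the old snapshot (expanded onto the new snapshot's
    identifier universe); for every disease, candidate miRNAs unobserved in
    the old snapshot are ranked and hits among the associations newly present
    in ``Y_new`` are counted in the top-N list.  With ``mode="per_disease"``
    (default) counts are per-disease top-N lists summed over diseases; with
    ``mode="global"`` a single ranking of all candidate pairs is used.
    """
    if mode not in ("per_disease", "global"):
        raise ValueError("mode must be 'per_disease' or 'global'")
    missing_d = set(Y_old.disease_ids) - set(Y_new.disease_ids)
    missing_m = set(Y_old.mirna_ids) - set(Y_new.mirna_ids)
    if missing_d or missing_m:
        raise ReconciliationError(
            "old snapshot identifiers absent from new snapshot: "
            f"diseases {sorted(missing_d)[:5]}, miRNAs {sorted(missing_m)[:5]}"
        )
    # expand the old snapshot onto the new snapshot's axes
    drow = {d: i for i, d in enumerate(Y_new.disease_ids)}
    mcol = {m: j for j, m in enumerate(Y_new.mirna_ids)}
    old_expanded = np.zeros_like(Y_new.matrix)
    oi = [drow[d] for d in Y_old.disease_ids]
    oj = [mcol[m] for m in Y_old.mirna_ids]
    old_expanded[np.ix_(oi, oj)] = Y_old.matrix
    train = Y_new.with_matrix(old_expanded)

    F = predictor(
        realize_views(views_D, train), realize_views(views_M, train), train, config
    )
    new_only = (Y_new.matrix == 1) & (old_expanded == 0)
    candidates = old_expanded == 0
    counts: dict[int, int] = {}
    if mode == "per_disease":
        for N in N_list:
            total = 0
            for i in range(train.n_diseases):
                cand = np.flatnonzero(candidates[i])
                top = cand[np.argsort(-F[i, cand], kind="stable")[:N]]
                total += int(new_only[i, top].sum())
            counts[int(N)] = total
    else:
        cand = np.argwhere(candidates)
        order = np.argsort(-F[candidates], kind="stable")
        hits = new_only[candidates][order]
        for N in N_list:
            counts[int(N)] = int(hits[:N].sum())
    return CVReport(
        scheme="topn",
        auc=float("nan"),
        extra={"counts": counts, "mode": mode, "n_new_associations": int(new_only.sum())},
    )


def compare_auc_vectors(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired AUC vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 5:
        raise ValueError("AUC vectors must be 1-d, equal length >= 5")
    if np.all(a == b):
        raise UndefinedMetricError("Wilcoxon test undefined: all paired differences are zero")
    return float(wilcoxon(a, b, alternative="two-sided").pvalue)


def snapshot_counts(Y_old: AssociationMatrix, Y_new: AssociationMatrix) -> dict[str, int]:
    """Bookkeeping of a database-version pair (old/new snapshots).

    Returns association counts per snapshot, the active disease/miRNA counts
    (entities with at least one association), and the partition of the new
    snapshot's novel associations into those whose disease *and* miRNA were
    already active in the old snapshot versus the rest.
    """
    missing_d = set(Y_old.disease_ids) - set(Y_new.disease_ids)
    missing_m = set(Y_old.mirna_ids) - set(Y_new.mirna_ids)
    if missing_d or missing_m:
        raise ReconciliationError("old snapshot identifiers absent from new snapshot")
    drow = {d: i for i, d in enumerate(Y_new.disease_ids)}
    mcol = {m: j for j, m in enumerate(Y_new.mirna_ids)}
    old = np.zeros_like(Y_new.matrix)
    old[np.ix_([drow[d] for d in Y_old.disease_ids], [mcol[m] for m in Y_old.mirna_ids])] = (
        Y_old.matrix
    )
    new = Y_new.matrix
    old_active_d = old.sum(axis=1) > 0
    old_active_m = old.sum(axis=0) > 0
    novel = (new == 1) & (old == 0)
    in_old_universe = novel & old_active_d[:, None] & old_active_m[None, :]
    return {
        "n_assoc_old": int(old.sum()),
        "n_diseases_old": int(old_active_d.sum()),
        "n_mirnas_old": int(old_active_m.sum()),
        "n_assoc_new": int(new.sum()),
        "n_diseases_new": int((new.sum(axis=1) > 0).sum()),
        "n_mirnas_new": int((new.sum(axis=0) > 0).sum()),
        "n_novel": int(novel.sum()),
        "n_novel_within_old_entities": int(in_old_universe.sum()),
        "n_novel_with_new_entities": int(novel.sum() - in_old_universe.sum()),
    }
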