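"""Seeded synthetic benchmark instances.

The generator emulates the structure of a curated miRNA-disease catalogue:
diseases and miRNAs fall into latent groups, matched group pairs have a high
association propensity and unmatched pairs a low one, and the observed binary
matrix is a Bernoulli sample of those propensities.  Similarity views of
controllable fidelity are produced by convexly mixing the ground-truth block
affinity with symmetric uniform noise, so the self-weighted view fusion can
be tested against a known ranking of view quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AssociationMatrix, SimilarityView

__all__ = [
    "SyntheticInstance",
    "make_block_instance",
    "corrupt_view",
    "sparsify_snapshot",
]

# Default noise levels of the two views generated per space: one faithful
# view and one pure-noise view, the setting under which self-weighting is
# expected to separate view quality.
DEFAULT_NOISE_LEVELS = (0.2, 1.0)


@dataclass(frozen=True)
class SyntheticInstance:
    """A complete seeded instance: truth, sample, and similarity views."""

    propensity: np.ndarray
    Y: AssociationMatrix
    true_SD: np.ndarray
    true_SM: np.ndarray
    views_D: tuple[SimilarityView, ...]
    views_M: tuple[SimilarityView, ...]
    seed: int
    disease_groups: np.ndarray = field(default=None, compare=False)
    mirna_groups: np.ndarray = field(default=None, compare=False)


def _group_assignment(n: int, n_groups: int) -> np.ndarray:
    """Contiguous, nearly equal-sized group labels for n items."""
    labels = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(np.arange(n), n_groups)):
        labels[chunk] = g
    return labels


def corrupt_view(
    true_affinity: np.ndarray,
    noise_level: float,
    seed: int,
    *,
    space: str = "disease",
    ids: tuple[str, ...] | None = None,
    name: str | None = None,
) -> SimilarityView:
    """Convex mixture ``(1 - lam) * A + lam * E`` of an affinity with noise.

    ``E`` is a seeded symmetric matrix with entries in [0, 1] (the average of
    a uniform draw and its transpose).  ``noise_level`` 0 returns the truth
    unchanged; 1 returns pure noise with no correlation to the truth.
    """
    if not 0.0 <= noise_level <= 1.0:
        raise ValueError(f"noise_level must be in [0, 1], got {noise_level}")
    A = np.asarray(true_affinity, dtype=float)
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    R = rng.uniform(0.0, 1.0, size=(n, n))
    E = 0.5 * (R + R.T)
    M = (1.0 - noise_level) * A + noise_level * E
    M = 0.5 * (M + M.T)
    if ids is None:
        prefix = "d" if space == "disease" else "m"
        ids = tuple(f"{prefix}{k}" for k in range(n))
    return SimilarityView(
        name=name or f"{space}_noise{noise_level:g}",
        space=space,
        matrix=M,
        ids=ids,
        noise_level=noise_level,
    )


def make_block_instance(
    q: int = 60,
    p: int = 80,
    n_disease_groups: int = 3,
    n_mirna_groups: int = 4,
    within_prob: float = 0.9,
    between_prob: float = 0.05,
    density_scale: float = 0.5,
    seed: int = 0,
    noise_levels: tuple[float, ...] = DEFAULT_NOISE_LEVELS,
) -> SyntheticInstance:
    """Block-structured bipartite instance with similarity views.

    Diseases are split into ``n_disease_groups`` contiguous groups and miRNAs
    into ``n_mirna_groups``; a miRNA group g is matched to disease group
    ``g mod n_disease_groups``.  Matched pairs have propensity
    ``density_scale * within_prob``, unmatched ``density_scale *
    between_prob``, and Y is an independent Bernoulli sample.  Ground-truth
    affinities are row-normalized same-group indicators; per space, one view
    is generated for each entry of ``noise_levels`` by corrupting the block
    indicator affinity.
    """
    for name, prob in (("within_prob", within_prob), ("between_prob", between_prob),
                       ("density_scale", density_scale)):
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {prob}")
    if n_disease_groups > q or n_mirna_groups > p:
        raise ValueError("cannot have more groups than items")

    rng = np.random.default_rng(seed)
    gd = _group_assignment(q, n_disease_groups)
    gm = _group_assignment(p, n_mirna_groups)
    matched = gd[:, None] == (gm[None, :] % n_disease_groups)
    propensity = density_scale * np.where(matched, within_prob, between_prob)
    Ymat = rng.binomial(1, propensity)

    disease_ids = tuple(f"d{k}" for k in range(q))
    mirna_ids = tuple(f"m{k}" for k in range(p))
    Y = AssociationMatrix(matrix=Ymat, disease_ids=disease_ids, mirna_ids=mirna_ids)

    BD = (gd[:, None] == gd[None, :]).astype(float)
    BM = (gm[:, None] == gm[None, :]).astype(float)
    true_SD = BD / BD.sum(axis=1, keepdims=True)
    true_SM = BM / BM.sum(axis=1, keepdims=True)

    views_D = tuple(
        corrupt_view(BD, lam, seed=seed + 1000 + 7 * k, space="disease",
                     ids=disease_ids, name=f"disease_view{k}_noise{lam:g}")
        for k, lam in enumerate(noise_levels)
    )
    views_M = tuple(
        corrupt_view(BM, lam, seed=seed + 2000 + 7 * k, space="mirna",
                     ids=mirna_ids, name=f"mirna_view{k}_noise{lam:g}")
        for k, lam in enumerate(noise_levels)
    )
    return SyntheticInstance(
        propensity=propensity,
        Y=Y,
        true_SD=true_SD,
        true_SM=true_SM,
        views_D=views_D,
        views_M=views_M,
        seed=seed,
        disease_groups=gd,
        mirna_groups=gm,
    )


def sparsify_snapshot(
    Y_full: AssociationMatrix, keep_fraction: float, seed: int
) -> AssociationMatrix:
    """Thin the positives of a matrix, emulating an older database snapshot.

    Each positive is retained independently with probability
    ``keep_fraction``; negatives are unchanged.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    rng = np.random.default_rng(seed)
    mat = Y_full.matrix.copy()
    pos = np.argwhere(mat == 1)
    drop = rng.random(len(pos)) >= keep_fraction
    mat[pos[drop, 0], pos[drop, 1]] = 0
    return Y_full.with_matrix(mat)
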