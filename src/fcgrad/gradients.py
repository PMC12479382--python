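"""Cortical gradients: diffusion-map embedding of FC similarity.

Pipeline per scan: row-wise thresholding of the Fisher-z FC matrix
(keep the top 10% of edges per row), cosine similarity between the
thresholded rows, diffusion-map embedding of the resulting affinity
with density normalization alpha = 0.5, then Procrustes rotation of
every scan's embedding onto a group template built from baseline scans
(10 iterations). Dispersion summarizes each network's spread in the
first-3-gradient space.

The embedding follows the standard construction: with affinity W and
degrees D, the density-normalized kernel is W' = D^-alpha W D^-alpha,
the transition operator M = D'^-1 W'; the nontrivial right eigenvectors
of M, scaled by lambda/(1-lambda) (diffusion time 0), are the gradient
scores. The trivial constant eigenvector (lambda = 1) is dropped.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .types import DispersionSummary, FCMatrix, GradientSet, NetworkAtlas

DENSITY = 0.10
ALPHA = 0.5
N_COMPONENTS = 10
N_ANALYZED = 3
PROCRUSTES_ITER = 10


def threshold_rows(fc: FCMatrix, density: float = DENSITY) -> np.ndarray:
    """Keep the ceil(density * (P-1)) largest off-diagonal entries per row.

    Ties are broken in favor of the lower parcel index. The result is
    generally asymmetric and is consumed as-is by :func:`cosine_affinity`.
    """
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    v = fc.values
    p = v.shape[0]
    keep = math.ceil(density * (p - 1))
    out = np.zeros_like(v)
    for i in range(p):
        row = v[i].copy()
        row[i] = -np.inf  # diagonal never competes
        # stable sort on descending value -> ties keep ascending index order
        order = np.argsort(-row, kind="stable")[:keep]
        out[i, order] = v[i, order]
    return out


def cosine_affinity(thresholded: np.ndarray) -> tuple[np.ndarray, int]:
    """Cosine similarity between rows, negatives clipped to zero.

    Returns the symmetric nonnegative affinity and the count of clipped
    negative entries (off-diagonal, each unordered pair counted once).
    """
    x = np.asarray(thresholded, dtype=float)
    norms = np.linalg.norm(x, axis=1)
    zero_rows = np.flatnonzero(norms == 0)
    if zero_rows.size:
        raise ValueError(f"all-zero rows after thresholding: {zero_rows.tolist()}")
    sim = (x @ x.T) / np.outer(norms, norms)
    sim = (sim + sim.T) / 2.0
    np.clip(sim, None, 1.0, out=sim)
    off = ~np.eye(len(sim), dtype=bool)
    n_clipped = int(np.count_nonzero(sim[off] < 0)) // 2
    np.clip(sim, 0.0, None, out=sim)
    return sim, n_clipped


def diffusion_embedding(
    affinity: np.ndarray,
    parcel_ids,
    n_components: int = N_COMPONENTS,
    alpha: float = ALPHA,
) -> GradientSet:
    """Diffusion-map embedding of a nonnegative symmetric affinity.

    Solved through the symmetric conjugate S = D'^-1/2 W' D'^-1/2 of the
    transition operator, whose eigenvectors map back to the right
    eigenvectors of M; components are normalized so the trivial
    eigenvector is constant 1, then dropped.
    """
    w = np.asarray(affinity, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("affinity must be square")
    if np.any(w < 0):
        raise ValueError("affinity must be nonnegative")
    if np.max(np.abs(w - w.T)) > 1e-10:
        raise ValueError("affinity must be symmetric")
    n_comp_graph, _ = connected_components(csr_matrix(w > 0), directed=False)
    if n_comp_graph > 1:
        raise ValueError(
            f"affinity graph has {n_comp_graph} components; "
            "increase threshold density or coupling so the graph is connected"
        )
    p = w.shape[0]
    n_components = min(n_components, p - 1)

    d = w.sum(axis=1)
    w1 = w / np.outer(d**alpha, d**alpha)
    d1 = w1.sum(axis=1)
    inv_sqrt_d1 = 1.0 / np.sqrt(d1)
    s = w1 * np.outer(inv_sqrt_d1, inv_sqrt_d1)
    s = (s + s.T) / 2.0

    evals, evecs = eigh(s, subset_by_index=(p - n_components - 1, p - 1))
    evals = evals[::-1]
    evecs = evecs[:, ::-1]

    # right eigenvectors of M; divide by the trivial one so it is all-ones
    psi = evecs * inv_sqrt_d1[:, None]
    psi = psi / psi[:, [0]]

    lam = np.clip(evals[1:], 0.0, 1.0 - 1e-12)
    scores = psi[:, 1:] * (lam / (1.0 - lam))
    total = lam.sum()
    var_exp = lam / total if total > 0 else np.zeros_like(lam)
    return GradientSet(
        scores=scores,
        eigenvalues=lam,
        parcel_ids=list(parcel_ids),
        alpha=alpha,
        variance_explained=var_exp,
    )


def gradients_from_fc(
    fc: FCMatrix,
    density: float = DENSITY,
    n_components: int = N_COMPONENTS,
    alpha: float = ALPHA,
) -> GradientSet:
    """threshold_rows -> cosine_affinity -> diffusion_embedding."""
    thresholded = threshold_rows(fc, density)
    affinity, _ = cosine_affinity(thresholded)
    return diffusion_embedding(affinity, fc.parcel_ids, n_components, alpha)


def variance_explained(eigenvalues: np.ndarray, k: int = N_ANALYZED) -> float:
    """Fraction of spectrum mass carried by the first k components."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(lam) > 1e-12) or np.any(lam < 0):
        raise ValueError("eigenvalues must be descending and nonnegative")
    total = lam.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum has no variance to attribute")
    return float(lam[:k].sum() / total)


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def procrustes_align(
    gradients: list[GradientSet],
    template: GradientSet | np.ndarray | None = None,
    n_iter: int = PROCRUSTES_ITER,
    template_indices: list[int] | None = None,
) -> tuple[list[GradientSet], np.ndarray, list[float]]:
    """Orthogonal (rotation/reflection, no scaling) alignment to a template.

    With an explicit ``template``, every embedding is aligned to it in a
    single pass. Without one, a group template is built iteratively:
    start from the mean of the ``template_indices`` scans (the baseline
    scans; all scans if None), align everything to it, replace the
    template by the mean of the aligned embeddings, repeat ``n_iter``
    times. All embeddings are column-mean-centered first.

    Returns (aligned gradient sets, final template scores, per-iteration
    mean squared disparity). The disparity sequence is non-increasing —
    the generalized-Procrustes objective decreases at both the rotation
    and the mean-update step.
    """
    if not gradients:
        raise ValueError("nothing to align")
    shapes = {g.scores.shape for g in gradients}
    if len(shapes) > 1:
        raise ValueError(f"embeddings disagree in shape: {sorted(shapes)}")
    xs = [_center(g.scores) for g in gradients]

    disparities: list[float] = []
    if template is not None:
        t = template.scores if isinstance(template, GradientSet) else template
        t = _center(np.asarray(t, dtype=float))
        if t.shape != xs[0].shape:
            raise ValueError("template shape must match the embeddings")
        aligned = [_rotate_onto(x, t) for x in xs]
        disparities = [float(np.mean([_sqdist(a, t) for a in aligned]))]
        final_t = t
    else:
        idx = template_indices if template_indices is not None else range(len(xs))
        t = np.mean([xs[i] for i in idx], axis=0)
        aligned = xs
        for _ in range(n_iter):
            aligned = [_rotate_onto(x, t) for x in xs]
            t = np.mean(aligned, axis=0)
            disparities.append(float(np.mean([_sqdist(a, t) for a in aligned])))
        final_t = t

    out = []
    for g, a in zip(gradients, aligned):
        out.append(
            GradientSet(
                scores=a,
                eigenvalues=g.eigenvalues,
                parcel_ids=list(g.parcel_ids),
                alpha=g.alpha,
                aligned_to="group-template" if template is None else "given-template",
                variance_explained=g.variance_explained,
            )
        )
    return out, final_t, disparities


def _rotate_onto(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    r, _ = orthogonal_procrustes(x, t)
    return x @ r


def _sqdist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b) ** 2)


def dispersion(
    gradients: GradientSet, atlas: NetworkAtlas, k: int = N_ANALYZED
) -> DispersionSummary:
    """Within/between-network dispersion in the first-k gradient space.

    Within-network dispersion is the sum of squared Euclidean distances
    of the network's parcels to the network centroid; between-network
    dispersion is the Euclidean distance between network centroids.
    """
    if k > gradients.n_components:
        raise ValueError(f"k={k} exceeds the {gradients.n_components} computed components")
    pts = gradients.scores[:, :k]
    centroids: dict[str, np.ndarray] = {}
    within: dict[str, float] = {}
    for net in atlas.networks:
        idx = atlas.indices_of(net, gradients.parcel_ids)
        if len(idx) == 0:
            raise ValueError(f"network {net} has no parcels in this embedding")
        sub = pts[idx]
        c = sub.mean(axis=0)
        centroids[net] = c
        within[net] = float(((sub - c) ** 2).sum())
    between: dict[tuple[str, str], float] = {}
    nets = atlas.networks
    for i, a in enumerate(nets):
        for b in nets[i + 1 :]:
            between[(a, b)] = float(np.linalg.norm(centroids[a] - centroids[b]))
    return DispersionSummary(within=within, between=between, centroids=centroids)
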