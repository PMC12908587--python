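"""Alpha/beta diversity, ordination, and group-structure tests.

Shannon entropy and Faith's phylogenetic diversity per sample; Bray-Curtis
and (normalised) weighted UniFrac dissimilarity between samples; principal
coordinates analysis via Gower double centering; PERMANOVA (Anderson
pseudo-F on squared distances, whole-label permutations, add-one p);
beta-dispersion homogeneity (distances to own-group centroid in the
retained positive-eigenvalue PCoA space) and the rank-sum comparison of
those centroid distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alpha diversity


def shannon(p: Sequence[float]) -> float:
    """Shannon entropy -sum p ln p in nats (zero entries contribute 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("composition entries must be non-negative")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def branch_structure(
    tree: TreeNode, species_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and leaf-descendancy incidence for a rooted tree.

    Returns ``(lengths, incidence)`` where row b of ``incidence`` marks the
    species (ordered as ``species_ids``) descending from branch b.  The
    root itself carries no branch; edges with ``None`` length are treated
    as zero-length and excluded.
    """
    ids = list(species_ids)
    col = {s: j for j, s in enumerate(ids)}
    tip_names = {t.name for t in tree.tips()}
    missing = [s for s in ids if s not in tip_names]
    if missing:
        raise ValueError(f"species absent from tree: {missing}")
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    masks: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip():
            mask = np.zeros(len(ids), dtype=bool)
            if node.name in col:
                mask[col[node.name]] = True
        else:
            mask = np.zeros(len(ids), dtype=bool)
            for child in node.children:
                mask |= masks[id(child)]
        masks[id(node)] = mask
        if node.parent is not None and node.length is not None:
            lengths.append(float(node.length))
            rows.append(mask)
    if not rows:
        raise ValueError("tree has no branches with lengths")
    return np.asarray(lengths), np.asarray(rows)


def faith_pd(present: Sequence[str], tree: TreeNode) -> float:
    """Faith's PD: total branch length connecting the root to each present
    species (stem path to the root included)."""
    present = list(present)
    if not present:
        return 0.0
    lengths, incidence = branch_structure(tree, present)
    covered = incidence.any(axis=1)
    return float(lengths[covered].sum())


# ---------------------------------------------------------------------------
# Beta diversity


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("compositions must share the species universe")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValueError("both compositions are all-zero")
    return float(np.sum(np.abs(x - y)) / denom)


def weighted_unifrac(
    x: Sequence[float],
    y: Sequence[float],
    species_ids: Sequence[str],
    tree: TreeNode,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac between two compositions over ``species_ids``.

    For each branch b with length l_b let A_b, B_b be the fractions of
    community x resp. y descending from b; returns
    sum l_b |A_b - B_b| / sum l_b (A_b + B_b) when normalised, the raw
    numerator otherwise.
    """
    lengths, incidence = branch_structure(tree, species_ids)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = incidence @ x
    b = incidence @ y
    num = float(np.sum(lengths * np.abs(a - b)))
    if not normalized:
        return num
    den = float(np.sum(lengths * (a + b)))
    if den == 0:
        raise ValueError("both communities are empty on the tree")
    return num / den


def beta_diversity(
    table: pd.DataFrame,
    metric: str,
    tree: TreeNode | None = None,
    normalized: bool = True,
) -> pd.DataFrame:
    """Pairwise dissimilarity matrix over the rows (samples) of ``table``."""
    samples = list(table.index)
    mat = table.to_numpy(dtype=float)
    n = len(samples)
    d = np.zeros((n, n))
    if metric == "bray_curtis":
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = bray_curtis(mat[i], mat[j])
    elif metric == "weighted_unifrac":
        if tree is None:
            raise ValueError("weighted_unifrac requires a tree")
        lengths, incidence = branch_structure(tree, list(table.columns))
        frac = mat @ incidence.T  # sample x branch fractions
        for i in range(n):
            for j in range(i + 1, n):
                num = np.sum(lengths * np.abs(frac[i] - frac[j]))
                if normalized:
                    den = np.sum(lengths * (frac[i] + frac[j]))
                    d[i, j] = d[j, i] = num / den
                else:
                    d[i, j] = d[j, i] = num
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=samples, columns=samples)


# ---------------------------------------------------------------------------
# Ordination


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # n x k, axes sorted by decreasing eigenvalue
    eigenvalues: np.ndarray  # k retained positive eigenvalues
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float
    sample_ids: list | None = None


def pcoa(d: np.ndarray | pd.DataFrame) -> PCoAResult:
    """Principal coordinates analysis via Gower double centering.

    Axes with non-positive eigenvalues are dropped; the absolute mass of
    negative eigenvalues is reported (no Cailliez/Lingoes correction).
    """
    sample_ids = None
    if isinstance(d, pd.DataFrame):
        sample_ids = list(d.index)
        d = d.to_numpy(dtype=float)
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1])) * 1e-9 if n > 1 else 0.0
    keep = eigvals > tol
    neg_mass = float(np.abs(eigvals[eigvals < -tol]).sum())
    if neg_mass > 0:
        logger.warning(
            "PCoA dropped negative eigenvalues (total mass %.4g)", neg_mass
        )
    ev = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(ev)
    return PCoAResult(
        coordinates=coords,
        eigenvalues=ev,
        proportion_explained=ev / ev.sum() if ev.size else ev,
        negative_eigenvalue_mass=neg_mass,
        sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# Group-structure tests


def _check_groups(labels: np.ndarray) -> list[np.ndarray]:
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    masks = [labels == g for g in uniq]
    for g, m in zip(uniq, masks):
        if m.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    return masks


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, n: int, n_groups: int) -> float:
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d: np.ndarray | pd.DataFrame,
    labels: Sequence,
    n_perm: int = 9999,
    seed: int | None = None,
    strata: Sequence | None = None,
) -> tuple[float, float]:
    """Anderson-style PERMANOVA on a distance matrix.

    Permutes whole-sample labels; the p-value uses the add-one estimator
    (1 + #{F_perm >= F_obs}) / (1 + n_perm).  When ``strata`` is given
    (e.g. the subject of each sample), all samples of a stratum keep a
    common label and label assignments are permuted across strata —
    the appropriate exchangeability for repeated-measures designs.
    """
    if isinstance(d, pd.DataFrame):
        d = d.to_numpy(dtype=float)
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels must align with the distance matrix")
    _check_groups(labels)
    n_groups = len(pd.unique(labels))
    d2 = d**2
    f_obs = _pseudo_f(d2, labels, n, n_groups)
    rng = np.random.default_rng(seed)
    count = 0
    permuter = _label_permuter(labels, strata, rng)
    for _ in range(n_perm):
        f_perm = _pseudo_f(d2, permuter(), n, n_groups)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


def _label_permuter(labels, strata, rng):
    """Callable yielding permuted label vectors (block-wise under strata)."""
    n = labels.shape[0]
    if strata is None:
        return lambda: labels[rng.permutation(n)]
    strata = np.asarray(strata)
    if strata.shape != (n,):
        raise ValueError("strata must align with labels")
    uniq = pd.unique(strata)
    block_idx = [np.flatnonzero(strata == s) for s in uniq]
    block_labels = []
    for s, idx in zip(uniq, block_idx):
        if len(pd.unique(labels[idx])) != 1:
            raise ValueError(f"stratum {s!r} carries more than one label")
        block_labels.append(labels[idx[0]])
    block_labels = np.asarray(block_labels)

    def _next() -> np.ndarray:
        permuted = block_labels[rng.permutation(block_labels.size)]
        out = np.empty(n, dtype=labels.dtype)
        for lab, idx in zip(permuted, block_idx):
            out[idx] = lab
        return out

    return _next


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    groups = pd.unique(labels)
    for g in groups:
        v = values[labels == g]
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += np.sum((v - v.mean()) ** 2)
    df_b = len(groups) - 1
    df_w = values.size - len(groups)
    if ss_within == 0:
        return 0.0 if ss_between == 0 else np.inf
    return (ss_between / df_b) / (ss_within / df_w)


@dataclass
class DispersionResult:
    f: float
    p: float
    centroid_distances: np.ndarray
    labels: np.ndarray
    n_axes: int


def dispersion_test(
    d: np.ndarray | pd.DataFrame,
    labels: Sequence,
    n_perm: int = 9999,
    seed: int | None = None,
    strata: Sequence | None = None,
) -> DispersionResult:
    """Homogeneity of multivariate group dispersions.

    Samples are embedded by PCoA on all retained positive axes; each
    sample's Euclidean distance to its own group centroid is tested for
    group differences with a one-way F statistic.  The null recomputes the
    centroid distances under each permuted labelling (add-one p), which
    stays calibrated when samples are clustered; ``strata`` permutes
    labels block-wise (see :func:`permanova`) for repeated-measures
    designs.
    """
    labels = np.asarray(labels)
    _check_groups(labels)
    res = pcoa(d)
    coords = res.coordinates

    def _centroid_distances(lab: np.ndarray) -> np.ndarray:
        z = np.empty(len(lab))
        for g in pd.unique(lab):
            idx = lab == g
            centroid = coords[idx].mean(axis=0)
            z[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
        return z

    z = _centroid_distances(labels)
    f_obs = _anova_f(z, labels)
    rng = np.random.default_rng(seed)
    count = 0
    permuter = _label_permuter(labels, strata, rng)
    for _ in range(n_perm):
        lab_perm = permuter()
        f_perm = _anova_f(_centroid_distances(lab_perm), lab_perm)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return DispersionResult(
        f=float(f_obs), p=float(p), centroid_distances=z,
        labels=labels, n_axes=coords.shape[1],
    )


def centroid_distance_comparison(
    distances: Sequence[float], labels: Sequence
) -> float:
    """Exact two-sided rank-sum test of centroid distances between two groups."""
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    a = distances[labels == uniq[0]]
    b = distances[labels == uniq[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return stats.wilcoxon_rank_sum(a, b)
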