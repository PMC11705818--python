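"""Community-level diversity and ordination statistics.

Alpha diversity (richness, Shannon with natural log), Bray–Curtis
dissimilarity on square-root transformed fraction-scale profiles, classical
PCoA via Gower double-centering, and permutation PERMANOVA computed
directly from the distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable


@dataclass
class DistanceMatrix:
    """Symmetric sample × sample dissimilarity matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray
    explained: np.ndarray  # fraction per axis, denominator = Σ positive λ


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p: float
    n_perm: int


def alpha_diversity(profile) -> tuple[int, float]:
    """(richness, Shannon index) for one sample's abundance vector.

    Richness counts taxa with abundance strictly greater than zero;
    Shannon is −Σ p·ln p over the positive fractions. An all-zero
    profile returns (0, 0.0).
    """
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    pos = x[x > 0]
    if pos.size == 0:
        return 0, 0.0
    p = pos / pos.sum()
    return int(pos.size), float(-(p * np.log(p)).sum())


def bray_curtis(table: AbundanceTable, transform: str = "sqrt") -> DistanceMatrix:
    """Bray–Curtis distance matrix of the (optionally square-root
    transformed) fraction-scale profiles.

    A pair of all-zero samples gets distance 0 with a warning (scipy
    would return NaN there).
    """
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    x = table.to_fraction().to_numpy()
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform != "none":
        raise ValueError("transform must be 'sqrt' or 'none'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair(s); distance set to 0", stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(ids=table.samples, values=d)


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical principal coordinate analysis.

    B = −½·J·D²·J with J = I − 11ᵀ/n; positive eigenpairs give the
    coordinates (eigenvector · √λ); negative eigenvalues are dropped from
    both the coordinates and the explained-variance denominator.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d2 = d.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(1.0, abs(evals[0]))
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    explained = lam / lam.sum() if lam.size else lam
    cols = [f"PCo{i + 1}" for i in range(lam.size)]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=d.ids, columns=cols),
        eigenvalues=lam,
        explained=explained,
    )


def _permanova_f_r2(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R² from a squared-distance matrix and group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 2:
            raise ValueError("every group needs at least 2 samples")
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    g = np.unique(groups).size
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    d: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutation multivariate ANOVA on a distance matrix.

    Variance is partitioned on squared distances; significance comes from
    ``n_perm`` label permutations with the +1 correction, so p is never
    zero and never below 1/(n_perm+1).
    """
    labels = pd.Series(labels, index=d.ids) if not isinstance(labels, pd.Series) else labels
    groups = labels.reindex(d.ids).to_numpy()
    if pd.isna(groups).any():
        raise ValueError("labels missing for some samples")
    if np.unique(groups).size < 2:
        raise ValueError("need at least 2 groups")
    d2 = d.values ** 2
    f_obs, r2 = _permanova_f_r2(d2, groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        f_perm, _ = _permanova_f_r2(d2, perm)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(r2=float(r2), pseudo_f=float(f_obs), p=float(p), n_perm=n_perm)
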