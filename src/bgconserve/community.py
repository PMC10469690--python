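"""Community-level structure of biosynthetic space.

Bray-Curtis dissimilarity between genome BGC profiles, Mantel correlation
against phylogenetic (cophenetic) distance, principal-coordinate
ordination, PERMANOVA over taxonomic groups, and the numeric parameters of
per-group probability-mass ellipses for ordination plots.

Mantel, PCoA and PERMANOVA are implemented directly on numpy arrays so
that the null vectors and sum-of-squares decomposition are part of the
result objects; the scikit-bio equivalents serve as independent
cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .core import TraitTable


@dataclass
class MantelResult:
    r_obs: float
    p_value: float
    n_perm: int
    null_rs: np.ndarray
    method: str = "pearson"


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # n x k, positive-eigenvalue axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per positive axis


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    df_between: int
    df_within: int
    n_perm: int
    ss_between: float
    ss_within: float
    ss_total: float
    null_fs: np.ndarray


def bray_curtis(table: TraitTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between genome count profiles.

    ``BC(i,j) = sum|x_i - x_j| / sum(x_i + x_j)`` in [0, 1].  Pairs of
    all-zero profiles are undefined (0/0) and are set to 0 with a warning.
    """
    x = table.counts.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("negative entries")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} all-zero profile(s); their mutual "
            "dissimilarity is set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        mat = squareform(pdist(x, metric="braycurtis"))
    mat = np.nan_to_num(mat, nan=0.0)
    return DistanceMatrix(mat, ids=table.genome_ids)


def _lower_triangle(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> MantelResult:
    """Mantel test between two distance matrices over the same labels.

    ``r_obs`` is the Pearson (or Spearman) correlation of the
    lower-triangle entries; the null permutes the rows/columns of the
    second matrix jointly; one-sided upper-tail p.
    """
    if list(dm1.ids) != list(dm2.ids):
        if set(dm1.ids) != set(dm2.ids):
            raise ValueError("distance matrices have different labels")
        dm2 = dm2.filter(dm1.ids)
    n = dm1.shape[0]
    if n < 3:
        raise ValueError("need >= 3 labels")
    a = np.asarray(dm1.data, dtype=float)
    b = np.asarray(dm2.data, dtype=float)
    if method == "spearman":
        a = _rank_offdiag(a)
        b = _rank_offdiag(b)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    va = _lower_triangle(a)
    vb = _lower_triangle(b)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in distance triangle; Mantel r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    il, jl = np.tril_indices(n, k=-1)
    za = (va - va.mean()) / va.std()
    for k in range(n_perm):
        perm = rng.permutation(n)
        vbp = b[perm[:, None], perm[None, :]][il, jl]
        null[k] = float(np.mean(za * (vbp - vbp.mean()) / vbp.std()))
    p = (1 + int((null >= r_obs).sum())) / (n_perm + 1)
    return MantelResult(r_obs=r_obs, p_value=p, n_perm=n_perm, null_rs=null, method=method)


def _rank_offdiag(mat: np.ndarray) -> np.ndarray:
    """Rank-transform the off-diagonal entries (for Spearman Mantel)."""
    n = mat.shape[0]
    i, j = np.tril_indices(n, k=-1)
    ranks = stats.rankdata(mat[i, j])
    out = np.zeros_like(mat)
    out[i, j] = ranks
    out[j, i] = ranks
    return out


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis by Gower double-centering.

    ``B = -1/2 J D^2 J`` with ``J = I - 11'/n``; coordinates are the
    eigenvectors of B scaled by the square root of their (positive)
    eigenvalues.  Negative eigenvalues are reported, not corrected.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need >= 3 points")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    prop = evals[pos] / evals[pos].sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=evals,
        proportion_explained=prop,
    )


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Sums of squares follow the standard distance decomposition:
    ``SS_total = sum_{i<j} d_ij^2 / n``, ``SS_within`` summed per group,
    ``SS_between`` their difference.  The null permutes group labels.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != dm.shape[0]:
        raise ValueError("group vector length mismatch")
    labels, codes = np.unique(groups, return_inverse=True)
    k = len(labels)
    n = dm.shape[0]
    if k < 2:
        raise ValueError("need >= 2 groups")
    if n < k + 1:
        raise ValueError("need more observations than groups")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    ss_total = d2.sum() / (2 * n)
    sizes = np.bincount(codes, minlength=k).astype(float)

    def ss_within_of(code_matrix: np.ndarray) -> np.ndarray:
        # code_matrix: (m, n) permuted codes; returns (m,) SS_within
        m = code_matrix.shape[0]
        out = np.zeros(m)
        for g in range(k):
            mask = (code_matrix == g).astype(float)
            out += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2 * sizes[g])
        return out

    ss_within = float(ss_within_of(codes[None, :])[0])
    ss_between = ss_total - ss_within
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore"):
        f_obs = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.int64)
    for m in range(n_perm):
        perms[m] = codes[rng.permutation(n)]
    ss_w_null = ss_within_of(perms)
    ss_b_null = ss_total - ss_w_null
    with np.errstate(divide="ignore"):
        null_fs = (ss_b_null / df_b) / (ss_w_null / df_w)
    p = (1 + int((null_fs >= f_obs).sum())) / (n_perm + 1)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        n_perm=n_perm,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
        null_fs=null_fs,
    )


def group_ellipses(
    coordinates: pd.DataFrame,
    groups,
    mass: float = 0.8,
    axes: tuple[str, str] = ("PC1", "PC2"),
) -> pd.DataFrame:
    """Per-group Gaussian probability-mass ellipse parameters.

    For each group the 2-D mean and covariance of the chosen ordination
    axes define the smallest ellipse containing ``mass`` of a fitted
    normal: half-axes ``sqrt(chi2_2(mass) * eigenvalue)`` along the
    covariance eigenvectors.  Output is numbers only (TSV-friendly).
    """
    q = stats.chi2.ppf(mass, df=2)
    rows = []
    xy = coordinates[list(axes)]
    for g, sub in xy.groupby(np.asarray(groups)):
        mean = sub.mean(axis=0).to_numpy()
        if len(sub) < 3:
            rows.append([g, len(sub), *mean, np.nan, np.nan, np.nan])
            continue
        cov = np.cov(sub.to_numpy().T)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
        rows.append(
            [g, len(sub), *mean, float(np.sqrt(q * evals[0])), float(np.sqrt(q * evals[1])), angle]
        )
    return pd.DataFrame(
        rows,
        columns=["group", "n", "mean_x", "mean_y", "semi_major", "semi_minor", "angle_deg"],
    )
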