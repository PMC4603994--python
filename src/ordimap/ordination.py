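"""Nonmetric distance transform and multidimensional scaling.

Associations are turned into nonmetric distances by d = (−1) × tau — kept
zero-centered on purpose, rather than the usual 1 − tau — and embedded by
classical scaling computed through the singular value decomposition:
recover the similarity S = −d, double-center B = J·S·J with
J = I − (1/n)·11ᵀ, factor B = U·Σ·Vᵀ, and take coordinates U·Σ^{1/2}
truncated to the leading k axes.  SVD keeps the factorization numerically
stable under the heavy multicollinearity typical of co-expression
matrices.  Because −tau is nonmetric, B may have negative eigendirections;
SVD orders axes by eigenvalue magnitude and the sign of each retained
eigenvalue is reported so heavily non-Euclidean structure is visible.

Two iterative nonmetric comparators (Sammon's mapping and Kruskal's
stress-1 scaling) act as robustness checks, plus a Procrustes statistic to
quantify how similar two configurations are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pathlib import Path
from scipy.spatial import procrustes as _procrustes
from scipy.spatial.distance import pdist, squareform

from .correlation import AssociationMatrix


class OrdinationError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Nonmetric distances d = −tau with provenance."""

    d: pd.DataFrame
    species: pd.Series
    provenance: str = ""

    def __post_init__(self) -> None:
        a = self.d.to_numpy()
        if not self.d.index.equals(self.d.columns):
            raise OrdinationError("distance matrix index and columns differ")
        if not np.allclose(a, a.T, atol=1e-10):
            raise OrdinationError("distance matrix is not symmetric")
        if np.abs(a).max() > 1 + 1e-9:
            raise OrdinationError("distances outside [-1, 1]")
        self.species = self.species.reindex(self.d.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.d.index)


@dataclass
class OrdinationResult:
    """Gene coordinates across k retained dimensions.

    ``axis_eigen_signs`` carries the sign of the eigenvalue behind each
    retained axis (+1 Euclidean-like, −1 non-Euclidean).  The per-axis
    orientation convention: each axis is flipped so that its
    largest-magnitude loading is positive, making runs reproducible.
    """

    coordinates: pd.DataFrame        # genes × dim1..dimk
    species: pd.Series
    singular_values: np.ndarray      # all n, nonincreasing
    k_retained: int
    method: str                      # classical_svd | sammon | kruskal
    stress: float | None = None
    axis_eigen_signs: np.ndarray | None = None
    converged: bool = True

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coordinates.index)

    def coords_array(self, n_dims: int | None = None) -> np.ndarray:
        a = self.coordinates.to_numpy(dtype=float)
        return a if n_dims is None else a[:, :n_dims]

    def to_tsv(self, path: str | Path) -> None:
        out = self.coordinates.copy()
        out.insert(0, "species", self.species)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path, method: str = "classical_svd") -> "OrdinationResult":
        t = pd.read_csv(path, sep="\t", index_col="gene_id")
        species = t.pop("species")
        return cls(
            coordinates=t.astype(float),
            species=species,
            singular_values=np.array([]),
            k_retained=t.shape[1],
            method=method,
        )


def to_distance(assoc: AssociationMatrix) -> DistanceMatrix:
    """Elementwise negation: d = (−1) × tau (zero-centered nonmetric distance)."""
    prov = f"{assoc.mode} Kendall"
    if assoc.covariate_name:
        prov += f" | covariate={assoc.covariate_name}"
    return DistanceMatrix(d=-assoc.tau, species=assoc.species, provenance=prov)


def _fix_axis_signs(coords: np.ndarray) -> np.ndarray:
    """Flip each axis so its largest-magnitude loading is positive."""
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def classical_scaling_svd(dist: DistanceMatrix, k: int) -> OrdinationResult:
    """Classical (principal-coordinates) scaling via SVD of the
    double-centered similarity matrix.  Deterministic up to the documented
    axis-sign convention."""
    n = len(dist.gene_ids)
    if not (1 <= k < n):
        raise OrdinationError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    S = -dist.d.to_numpy(dtype=float)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ S @ J
    B = (B + B.T) / 2.0
    U, s, Vt = np.linalg.svd(B, hermitian=True)
    coords = U[:, :k] * np.sqrt(s[:k])
    # eigenvalue sign of each retained axis: u_j' B u_j = lambda_j
    signs = np.sign(np.einsum("ij,ij->j", U[:, :k], B @ U[:, :k]))
    coords = _fix_axis_signs(coords)
    cols = [f"dim{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.d.index, columns=cols),
        species=dist.species,
        singular_values=s,
        k_retained=k,
        method="classical_svd",
        stress=None,
        axis_eigen_signs=signs,
    )


def _shifted_dissimilarity(dist: DistanceMatrix) -> np.ndarray:
    """Uniformly shift d to strictly positive for the iterative nonmetric
    methods.

    Zero-centered −tau distances are shifted so the smallest off-diagonal
    value becomes a small positive floor (guarding the 1/d weights);
    already-positive inputs pass through untouched.  The uniform shift
    preserves rank order, which is all the nonmetric methods use.
    """
    D = dist.d.to_numpy(dtype=float).copy()
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    dmin, dmax = D[off].min(), D[off].max()
    span = dmax - dmin
    if span <= 0:
        raise OrdinationError("all off-diagonal distances identical")
    floor = 1e-3 * span
    if dmin < floor:
        D = D + (floor - dmin)
    np.fill_diagonal(D, 0.0)
    return D


def sammon_mapping(
    dist: DistanceMatrix,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-9,
    rng_seed: int | None = None,
) -> OrdinationResult:
    """Sammon's nonlinear mapping, initialized from classical scaling.

    Minimizes E = (1/Σd) Σ (d_ij − δ_ij)²/d_ij by the classic
    diagonal-Newton update with step halving, so the stress is
    non-increasing across iterations.  Deterministic: the initialization
    is the classical-scaling configuration (``rng_seed`` is accepted for
    interface symmetry but unused).
    """
    n = len(dist.gene_ids)
    D = _shifted_dissimilarity(dist)
    Y = classical_scaling_svd(dist, k).coords_array().copy()
    off = ~np.eye(n, dtype=bool)
    c = D[off].sum() / 2.0
    alpha = 0.3  # Sammon's "magic factor"

    def stress_of(Yc: np.ndarray) -> float:
        delta = squareform(pdist(Yc))
        err = (D - delta) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(off, err / np.where(D > 0, D, 1.0), 0.0)
        return term.sum() / (2.0 * c)

    E = stress_of(Y)
    converged = False
    for _ in range(max_iter):
        delta = squareform(pdist(Y))
        np.fill_diagonal(delta, 1.0)                  # excluded by `off` anyway
        delta = np.maximum(delta, 1e-12)              # coincident points
        Dm = np.where(D > 0, D, 1.0)
        w = np.where(off, 1.0 / (Dm * delta), 0.0)    # 1/(D_ij d_ij)
        diff = D - delta
        diffs = Y[:, None, :] - Y[None, :, :]          # n × n × k
        # Sammon (1969) diagonal pseudo-Newton step
        grad = (-2.0 / c) * np.einsum("ij,ijq->iq", w * diff, diffs)
        curv = w[..., None] * (
            diff[..., None]
            - (diffs**2 / delta[..., None]) * (1.0 + diff / delta)[..., None]
        )
        denom = np.abs((-2.0 / c) * curv.sum(axis=1))
        denom[denom < 1e-12] = 1e-12
        step = alpha * grad / denom
        # backtracking: guarantee non-increasing stress
        factor = 1.0
        for _half in range(30):
            Y_new = Y - factor * step
            E_new = stress_of(Y_new)
            if E_new <= E:
                break
            factor *= 0.5
        else:
            converged = True
            break
        if E - E_new < tol:
            Y = Y_new
            E = E_new
            converged = True
            break
        Y = Y_new
        E = E_new
    if not converged:
        warnings.warn("Sammon mapping did not converge within max_iter", stacklevel=2)
    Y = _fix_axis_signs(Y)
    cols = [f"dim{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(Y, index=dist.d.index, columns=cols),
        species=dist.species,
        singular_values=np.array([]),
        k_retained=k,
        method="sammon",
        stress=float(E),
        converged=converged,
    )


def kruskal_nmds(
    dist: DistanceMatrix,
    k: int,
    max_iter: int = 300,
    tol: float = 1e-6,
    rng_seed: int | None = 0,
) -> OrdinationResult:
    """Kruskal's nonmetric MDS (stress-1 with monotone regression),
    initialized from the classical-scaling configuration."""
    from sklearn.manifold import MDS

    D = _shifted_dissimilarity(dist)
    init = classical_scaling_svd(dist, k).coords_array().copy()
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",  # overridden by the explicit classical-scaling init below
        n_init=1,
        max_iter=max_iter,
        eps=tol,
        normalized_stress=True,
        random_state=rng_seed,
    )
    Y = model.fit_transform(D, init=init)
    Y = _fix_axis_signs(np.asarray(Y, dtype=float))
    converged = model.n_iter_ < max_iter
    if not converged:
        warnings.warn("Kruskal NMDS did not converge within max_iter", stacklevel=2)
    cols = [f"dim{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(Y, index=dist.d.index, columns=cols),
        species=dist.species,
        singular_values=np.array([]),
        k_retained=k,
        method="kruskal",
        stress=float(model.stress_),
        converged=converged,
    )


def configuration_agreement(a: OrdinationResult, b: OrdinationResult) -> float:
    """Procrustes correlation in [0, 1] between two configurations.

    After optimal translation/rotation/reflection/scaling, returns
    sqrt(1 − residual/total); 1 means identical shapes, values near 0 mean
    unrelated configurations.
    """
    if set(a.gene_ids) != set(b.gene_ids):
        raise OrdinationError("gene sets differ between configurations")
    if a.k_retained != b.k_retained:
        raise OrdinationError("configurations have different dimensionality")
    cb = b.coordinates.loc[a.gene_ids].to_numpy(dtype=float)
    ca = a.coords_array()
    _, _, disparity = _procrustes(ca, cb)
    return float(np.sqrt(max(0.0, 1.0 - disparity)))
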