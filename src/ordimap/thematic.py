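"""Map-level statistics over ordination results.

Everything the downstream biology reads off the maps lives here:
dispersion ellipses around labeled gene groups (1.6-SD covariance
ellipses), kernel density fields and a complementarity score between the
miRNA and mRNA fields, per-miRNA median-correlation shifts between
conditions, the target-pair distance analysis with its sign-flip control
ordination, the mirSVR-score vs per-dimension-distance regression, and
seed-sequence grouping of miRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import AssociationMatrix
from .matrix_io import MIRNA, MRNA, SeedTable, TargetTable
from .ordination import OrdinationResult, classical_scaling_svd, to_distance


class ThematicError(ValueError):
    pass


# ---------------------------------------------------------------- ellipses


@dataclass
class EllipseSpec:
    """Covariance dispersion ellipse of a labeled point group.

    The boundary lies at ``scale`` standard deviations along each
    principal axis of the sample covariance (the ordination-plot 'sd'
    convention), not at a chi-square quantile.
    """

    class_label: str | None
    center: np.ndarray
    covariance: np.ndarray
    scale: float = 1.6

    def semi_axes(self) -> np.ndarray:
        """Ellipse semi-axis lengths (scale · sqrt of covariance eigenvalues)."""
        vals = np.linalg.eigvalsh(self.covariance)
        return self.scale * np.sqrt(np.maximum(vals, 0.0))[::-1]

    def mahalanobis(self, points: np.ndarray) -> np.ndarray:
        """Mahalanobis distance of points from the center; points with
        distance ≤ scale lie inside the ellipse."""
        pts = np.atleast_2d(points) - self.center
        inv = np.linalg.pinv(self.covariance)
        return np.sqrt(np.einsum("ij,jk,ik->i", pts, inv, pts))

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.mahalanobis(points) <= self.scale

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """2-D boundary polyline (first two dimensions) for plotting."""
        if self.center.shape[0] < 2:
            raise ThematicError("boundary requires at least 2 dimensions")
        cov2 = self.covariance[:2, :2]
        vals, vecs = np.linalg.eigh(cov2)
        t = np.linspace(0, 2 * np.pi, n_points)
        circle = np.stack([np.cos(t), np.sin(t)])
        pts = vecs @ (np.sqrt(np.maximum(vals, 0))[:, None] * circle) * self.scale
        return (pts.T + self.center[:2])


def dispersion_ellipse(points, scale: float = 1.6, class_label: str | None = None) -> EllipseSpec:
    """Covariance ellipse (center = mean, boundary at ``scale`` SDs)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, k = pts.shape
    if n < k + 1:
        raise ThematicError(f"need at least {k + 1} points in {k} dimensions (got {n})")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    cov = np.atleast_2d(cov)
    if np.allclose(cov, 0):
        raise ThematicError("all points identical: degenerate ellipse")
    return EllipseSpec(class_label=class_label, center=center, covariance=cov, scale=scale)


def class_ellipses(
    ord_result: OrdinationResult,
    annotations: pd.Series,
    n_dims: int = 3,
    scale: float = 1.6,
) -> dict[str, EllipseSpec]:
    """One dispersion ellipse per functional class with enough members."""
    coords = ord_result.coords_array(n_dims)
    ids = np.array(ord_result.gene_ids)
    out: dict[str, EllipseSpec] = {}
    for label in annotations.dropna().unique():
        members = np.isin(ids, annotations.index[annotations == label])
        if members.sum() >= n_dims + 1:
            out[label] = dispersion_ellipse(coords[members], scale=scale, class_label=label)
    return out


# ---------------------------------------------------------------- density


@dataclass
class DensityField:
    """Gaussian-kernel density on a regular 2-D grid, normalized to 1."""

    x_grid: np.ndarray
    y_grid: np.ndarray
    density: np.ndarray          # shape (len(y_grid), len(x_grid))
    bandwidth: float

    @property
    def cell_area(self) -> float:
        return float((self.x_grid[1] - self.x_grid[0]) * (self.y_grid[1] - self.y_grid[0]))

    def mode_location(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.x_grid[ix]), float(self.y_grid[iy])

    def same_grid(self, other: "DensityField") -> bool:
        return (
            self.x_grid.shape == other.x_grid.shape
            and self.y_grid.shape == other.y_grid.shape
            and np.allclose(self.x_grid, other.x_grid)
            and np.allclose(self.y_grid, other.y_grid)
        )


def kernel_density_field(
    points,
    grid_size: int = 64,
    bandwidth: float = 0.1,
    extent: tuple[float, float, float, float] | None = None,
) -> DensityField:
    """Gaussian KDE of 2-D points on a regular grid.

    The grid covers the bounding box plus a 3-bandwidth margin unless an
    explicit ``extent`` (xmin, xmax, ymin, ymax) is given — pass a shared
    extent when two fields will be compared cell by cell.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))[:, :2]
    if len(pts) < 2:
        raise ThematicError("need at least 2 points for a density field")
    if bandwidth <= 0:
        raise ThematicError("bandwidth must be > 0")
    if extent is None:
        m = 3.0 * bandwidth
        extent = (pts[:, 0].min() - m, pts[:, 0].max() + m, pts[:, 1].min() - m, pts[:, 1].max() + m)
    xg = np.linspace(extent[0], extent[1], grid_size)
    yg = np.linspace(extent[2], extent[3], grid_size)
    XX, YY = np.meshgrid(xg, yg)
    grid_pts = np.stack([XX.ravel(), YY.ravel()], axis=1)
    # explicit isotropic Gaussian kernel with absolute bandwidth
    d2 = ((grid_pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    dens = np.exp(-d2 / (2.0 * bandwidth**2)).sum(axis=1)
    dens = dens.reshape(grid_size, grid_size)
    cell = (xg[1] - xg[0]) * (yg[1] - yg[0])
    total = dens.sum() * cell
    if total > 0:
        dens = dens / total
    return DensityField(x_grid=xg, y_grid=yg, density=dens, bandwidth=bandwidth)


def complementarity_score(field_a: DensityField, field_b: DensityField) -> float:
    """Spearman correlation of two density fields across grid cells.

    Negative values mean the two point sets occupy complementary regions
    of the map.  NaN (flagged undefined) when either field has no rank
    variation.
    """
    if not field_a.same_grid(field_b):
        raise ThematicError("density fields are on different grids")
    a = field_a.density.ravel()
    b = field_b.density.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("uniform density field: complementarity undefined", stacklevel=2)
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


# ------------------------------------------------------- median-shift


@dataclass
class MedianShiftReport:
    """Per-miRNA median correlation with all mRNAs, by condition."""

    table: pd.DataFrame          # index miRNA; columns median_a, median_b, delta
    threshold: float
    decreased_ids: list[str]     # delta < −threshold
    increased_ids: list[str]     # delta > +threshold


def median_correlation_shift(
    assoc_a: AssociationMatrix,
    assoc_b: AssociationMatrix,
    threshold: float = 0.15,
) -> MedianShiftReport:
    """Shift of each miRNA's median correlation with all mRNAs, A − B.

    Strict thresholding: a miRNA is 'decreased' when delta < −threshold
    and 'increased' when delta > +threshold.
    """
    mirnas = assoc_a.species_ids(MIRNA)
    mrnas = assoc_a.species_ids(MRNA)
    if set(mirnas) != set(assoc_b.species_ids(MIRNA)) or set(mrnas) != set(
        assoc_b.species_ids(MRNA)
    ):
        raise ThematicError("the two association matrices cover different gene sets")
    if not mrnas:
        raise ThematicError("no mRNAs present")
    if not mirnas:
        raise ThematicError("no miRNAs present")
    med_a = assoc_a.tau.loc[mirnas, mrnas].median(axis=1)
    med_b = assoc_b.tau.loc[mirnas, mrnas].median(axis=1)
    delta = med_a - med_b
    table = pd.DataFrame({"median_a": med_a, "median_b": med_b, "delta": delta})
    return MedianShiftReport(
        table=table,
        threshold=threshold,
        decreased_ids=list(table.index[delta < -threshold]),
        increased_ids=list(table.index[delta > threshold]),
    )


# -------------------------------------------------------- target pairs


@dataclass
class TargetDistanceReport:
    """Mean map distances of target pairs vs background, plus the
    sign-flip control (miRNA–mRNA correlation blocks negated, ordination
    recomputed)."""

    observed_mean: float
    background_mean: float
    background_sd: float
    signflip_mean: float
    n_dims: int
    n_pairs: int


def _pair_distances(coords: pd.DataFrame, pairs: list[tuple[str, str]], n_dims: int) -> np.ndarray:
    a = coords.loc[[p[0] for p in pairs]].to_numpy(dtype=float)[:, :n_dims]
    b = coords.loc[[p[1] for p in pairs]].to_numpy(dtype=float)[:, :n_dims]
    return np.sqrt(((a - b) ** 2).sum(axis=1))


def sign_flip_association(assoc: AssociationMatrix) -> AssociationMatrix:
    """Negate the miRNA-vs-mRNA off-diagonal blocks, preserving symmetry."""
    tau = assoc.tau.copy()
    mirnas = assoc.species_ids(MIRNA)
    mrnas = assoc.species_ids(MRNA)
    tau.loc[mirnas, mrnas] = -tau.loc[mirnas, mrnas]
    tau.loc[mrnas, mirnas] = -tau.loc[mrnas, mirnas]
    return AssociationMatrix(
        tau, species=assoc.species, mode=assoc.mode, covariate_name=assoc.covariate_name
    )


def target_pair_analysis(
    ord_result: OrdinationResult,
    assoc: AssociationMatrix,
    targets: TargetTable,
    n_dims: int = 3,
) -> TargetDistanceReport:
    """Distances of miRNA–target pairs on the map vs the background of all
    miRNA–mRNA pairs, with a sign-flip control.

    The sign-flip arm simulates the alternative map: the miRNA-vs-mRNA
    correlation blocks are negated and the full classical-SVD ordination
    is recomputed with identical settings before re-measuring the mean
    pair distance.
    """
    if len(targets) == 0:
        raise ThematicError("empty target table")
    if n_dims > ord_result.k_retained:
        raise ThematicError(
            f"n_dims={n_dims} exceeds retained dimensions ({ord_result.k_retained})"
        )
    coords = ord_result.coordinates
    missing = [
        g
        for pair in targets.pairs()
        for g in pair
        if g not in coords.index
    ]
    if missing:
        raise ThematicError(f"target genes absent from the ordination: {sorted(set(missing))}")

    observed = _pair_distances(coords, targets.pairs(), n_dims)

    mirnas = ord_result.species.index[ord_result.species == MIRNA]
    mrnas = ord_result.species.index[ord_result.species == MRNA]
    cm = coords.loc[mirnas].to_numpy(dtype=float)[:, :n_dims]
    cr = coords.loc[mrnas].to_numpy(dtype=float)[:, :n_dims]
    bg = np.sqrt(((cm[:, None, :] - cr[None, :, :]) ** 2).sum(axis=2)).ravel()

    flipped = sign_flip_association(assoc)
    ord_flip = classical_scaling_svd(to_distance(flipped), k=ord_result.k_retained)
    flip_d = _pair_distances(ord_flip.coordinates, targets.pairs(), n_dims)

    return TargetDistanceReport(
        observed_mean=float(observed.mean()),
        background_mean=float(bg.mean()),
        background_sd=float(bg.std()),
        signflip_mean=float(flip_d.mean()),
        n_dims=n_dims,
        n_pairs=len(targets),
    )


# ----------------------------------------------------- mirSVR regression


@dataclass
class MirsvrRegression:
    """OLS of mirSVR scores on per-dimension coordinate distances."""

    r_squared: float
    f_pvalue: float
    coefficients: pd.Series
    n_pairs: int
    n_dims: int


def mirsvr_distance_regression(
    ord_result: OrdinationResult,
    targets: TargetTable,
    n_dims: int = 50,
) -> MirsvrRegression:
    """Multiple regression of the mirSVR score of each target pair on the
    pair's distance |x_d(miRNA) − x_d(mRNA)| in each of the first
    ``n_dims`` ordination dimensions.
    """
    import statsmodels.api as sm

    if n_dims > ord_result.k_retained:
        raise ThematicError(
            f"n_dims={n_dims} exceeds retained dimensions ({ord_result.k_retained})"
        )
    n_pairs = len(targets)
    if n_pairs <= n_dims + 1:
        raise ThematicError(
            f"need more than n_dims + 1 = {n_dims + 1} pairs (got {n_pairs})"
        )
    coords = ord_result.coordinates
    a = coords.loc[targets.table["mirna_id"]].to_numpy(dtype=float)[:, :n_dims]
    b = coords.loc[targets.table["mrna_id"]].to_numpy(dtype=float)[:, :n_dims]
    X = np.abs(a - b)
    y = targets.table["mirsvr_score"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("constant mirSVR scores: regression undefined", stacklevel=2)
        return MirsvrRegression(
            r_squared=float("nan"),
            f_pvalue=float("nan"),
            coefficients=pd.Series(dtype=float),
            n_pairs=n_pairs,
            n_dims=n_dims,
        )
    model = sm.OLS(y, sm.add_constant(X)).fit()
    names = ["const"] + [f"dim{i + 1}" for i in range(n_dims)]
    return MirsvrRegression(
        r_squared=float(model.rsquared),
        f_pvalue=float(model.f_pvalue),
        coefficients=pd.Series(model.params, index=names),
        n_pairs=n_pairs,
        n_dims=n_dims,
    )


# ------------------------------------------------------------ seed groups


@dataclass
class SeedGroups:
    """miRNAs grouped by identical (normalized) seed sequence."""

    groups: dict[str, list[str]]     # seed -> miRNA ids (size >= 2)
    n_singletons: int

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def normalize_seed(seed: str) -> str:
    """Uppercase and T→U before exact matching."""
    return seed.upper().replace("T", "U")


def seed_group_partition(seeds: SeedTable) -> SeedGroups:
    """Group miRNAs sharing an identical seed; singletons are excluded
    from the groups but counted."""
    if len(seeds) == 0:
        raise ThematicError("empty seed table")
    by_seed: dict[str, list[str]] = {}
    for _, row in seeds.table.iterrows():
        by_seed.setdefault(normalize_seed(row["seed_sequence"]), []).append(row["mirna_id"])
    groups = {s: ids for s, ids in by_seed.items() if len(ids) >= 2}
    n_singletons = sum(1 for ids in by_seed.values() if len(ids) == 1)
    return SeedGroups(groups=groups, n_singletons=n_singletons)


# ------------------------------------------------------------ plotting


def plot_ordination_map(
    ord_result: OrdinationResult,
    annotations: pd.Series | None = None,
    ellipse_scale: float = 1.6,
    ax=None,
):
    """Scatter of the first two dimensions, miRNA vs mRNA markers, with
    per-class dispersion ellipses when annotations are given."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    coords = ord_result.coords_array(2)
    is_mir = (ord_result.species == MIRNA).to_numpy()
    ax.scatter(coords[~is_mir, 0], coords[~is_mir, 1], s=8, c="0.6", label="mRNA")
    ax.scatter(coords[is_mir, 0], coords[is_mir, 1], s=14, c="tab:blue", label="miRNA")
    if annotations is not None:
        for label, ell in class_ellipses(ord_result, annotations, n_dims=2, scale=ellipse_scale).items():
            bd = ell.boundary()
            ax.plot(bd[:, 0], bd[:, 1], lw=1.2, label=label)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend(fontsize=7, loc="best")
    return ax


def plot_density_field(field: DensityField, ax=None, **imshow_kwargs):
    """Heat map of a density field."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    extent = (field.x_grid[0], field.x_grid[-1], field.y_grid[0], field.y_grid[-1])
    ax.imshow(field.density, origin="lower", extent=extent, aspect="auto", **imshow_kwargs)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    return ax
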