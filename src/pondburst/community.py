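"""Community tables, crossed-DPCoA ordination and alpha-diversity indices.

The ordination follows double principal coordinate analysis (DPCoA):
species are embedded in a Euclidean space reproducing their pairwise
dissimilarities (principal coordinates, with a Lingoes correction when the
dissimilarity is not Euclidean), communities sit at the proportion-weighted
centroids of their species, and factor levels at the centroids of their
communities.  The *crossed* variant studies one factor (A) in the presence
of a crossed nuisance factor (B) by first moving every level of B to the
centre of the space, then extracting the principal axes of the A-level
centroids.

Alpha diversity is summarised per community by species richness, the
Gini-Simpson index 1 - sum(p_i^2), and Rao's quadratic entropy
sum_ij p_i p_j d_ij, which weighs species pairs by their (acoustic)
dissimilarity; with unit distances Rao reduces to Gini-Simpson.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventWindow, PERIODS
from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Community table
# ---------------------------------------------------------------------------


@dataclass
class CommunityTable:
    """Communities x species proportion matrix with two crossed factors.

    Rows are keyed by (site, event, period); ``proportions`` rows sum to 1
    (presence/absence converted to uniform proportions).  ``factor_event``
    and ``factor_period`` give the two crossed factor levels per row.
    """

    proportions: pd.DataFrame
    factor_event: pd.Series
    factor_period: pd.Series

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy(dtype=float)
        if p.size == 0:
            raise InvalidInputError("community table is empty")
        if np.any(p < 0):
            raise InvalidInputError("proportions must be nonnegative")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-9:
            raise InvalidInputError("community rows must sum to 1")
        for f in (self.factor_event, self.factor_period):
            if not f.index.equals(self.proportions.index):
                raise InvalidInputError("factors must cover all community rows")

    @property
    def species(self) -> list[str]:
        return list(self.proportions.columns)

    def __len__(self) -> int:
        return len(self.proportions)


def vote_majority(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-cell majority vote over an odd number of 0/1 annotator tables."""
    if not tables:
        raise InvalidInputError("need at least one annotator table")
    if len(tables) % 2 == 0:
        logger.warning("even number of annotators: ties resolved as absence")
    stack = sum(t.to_numpy(dtype=int) for t in tables)
    out = (stack * 2 > len(tables)).astype(int)
    return pd.DataFrame(out, index=tables[0].index, columns=tables[0].columns)


def vote_and_tabulate(
    annotator_tables: list[pd.DataFrame],
    windows: list[EventWindow],
    subsample: str | pd.Timedelta = "2h",
) -> CommunityTable:
    """Majority-voted community table per (site, event, period).

    ``annotator_tables`` are 0/1 presence tables indexed by
    (site, timestamp).  Within each event window, recordings on the
    ``subsample`` grid are selected (6 per 12-h period at the 2-h default);
    a species is present in a period if present in any of its subsampled
    recordings (union), and presences become uniform proportions.  Periods
    with no species are dropped with a warning.
    """
    voted = vote_majority(annotator_tables)
    rows, keys, f_event, f_period = [], [], [], []
    for w in windows:
        site = w.event.site_id
        label = w.event_label or site
        for period, (lo, hi) in w.period_bounds().items():
            times = [t for t in w.subsample(subsample) if lo <= t < hi]
            present = None
            for t in times:
                key = (site, t)
                if key not in voted.index:
                    logger.warning("no annotated recording at %s %s", site, t)
                    continue
                row = voted.loc[key]
                present = row if present is None else (present | row)
            if present is None or int(present.sum()) == 0:
                logger.warning("empty community for %s %s; row dropped", label, period)
                continue
            rows.append(present / present.sum())
            keys.append((site, label, period))
            f_event.append(label)
            f_period.append(period)
    if not rows:
        raise InvalidInputError("no non-empty communities")
    index = pd.MultiIndex.from_tuples(keys, names=["site", "event", "period"])
    return CommunityTable(
        proportions=pd.DataFrame(rows, index=index),
        factor_event=pd.Series(f_event, index=index),
        factor_period=pd.Series(f_period, index=index),
    )


# ---------------------------------------------------------------------------
# Species space (principal coordinates)
# ---------------------------------------------------------------------------


def species_space(
    d: pd.DataFrame | np.ndarray | str,
    species: list[str] | None = None,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Euclidean embedding of a species dissimilarity matrix.

    Principal-coordinate embedding of ``d``: the Gram matrix
    ``-0.5 * J d^2 J`` (J the centring operator) is eigen-decomposed and
    coordinates are eigenvectors scaled by sqrt(eigenvalue).  If any
    eigenvalue is below ``-tol`` the matrix is not Euclidean and the Lingoes
    additive correction (d^2 + 2c off-diagonal, c = -lambda_min) is applied
    and logged.  ``d = "equidistant"`` places all species at unit mutual
    distance.
    """
    if isinstance(d, str):
        if d != "equidistant":
            raise InvalidInputError(f"unknown species space {d!r}")
        if not species:
            raise InvalidInputError("species list required for equidistant space")
        n = len(species)
        d = pd.DataFrame(1.0 - np.eye(n), index=species, columns=species)
    if isinstance(d, pd.DataFrame):
        species = list(d.index)
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        species = species or [f"sp{i + 1}" for i in range(dm.shape[0])]
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-12):
        raise InvalidInputError("dissimilarity matrix must be symmetric")
    if np.any(np.abs(np.diag(dm)) > 1e-12):
        raise InvalidInputError("dissimilarity matrix must have zero diagonal")

    n = dm.shape[0]
    d2 = dm**2
    jj = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * jj @ d2 @ jj
    vals = np.linalg.eigvalsh(gram)
    if vals[0] < -tol:
        c = -vals[0]
        logger.info("non-Euclidean dissimilarity: Lingoes constant %.3g applied", c)
        d2 = d2 + 2.0 * c * (1.0 - np.eye(n))
        gram = -0.5 * jj @ d2 @ jj
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > tol * max(vals[0], 1.0)
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return pd.DataFrame(
        coords,
        index=species,
        columns=[f"pc{i + 1}" for i in range(int(keep.sum()))],
    )


# ---------------------------------------------------------------------------
# Crossed DPCoA
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Eigenvalues and coordinates of a (crossed-)DPCoA fit.

    ``community_coords`` are the raw proportion-weighted species centroids
    projected on the principal axes (so each community lies at the centroid
    of its species); ``centered_community_coords`` have each factor-B level
    moved to the origin — the plotted configuration; ``level_coords`` are
    the factor-A level centroids of the centred communities.
    """

    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    species_coords: pd.DataFrame
    community_coords: pd.DataFrame
    centered_community_coords: pd.DataFrame
    level_coords: pd.DataFrame
    axes: np.ndarray = field(repr=False)
    total_inertia: float = 0.0

    def summary(self) -> str:
        lines = [
            "Crossed-DPCoA ordination",
            "=" * 50,
            f"communities: {len(self.community_coords)}   "
            f"species: {len(self.species_coords)}   "
            f"factor-A levels: {len(self.level_coords)}",
            f"total inertia (between A-levels): {self.total_inertia:.6f}",
            "axis  eigenvalue  %variance",
        ]
        for k, (ev, vf) in enumerate(zip(self.eigenvalues, self.variance_fraction)):
            lines.append(f"  {k + 1:<4d}{ev:>10.5f}{100 * vf:>10.1f}%")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Communities coloured by factor-A level, species as crosses."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cc = self.centered_community_coords
        for level, lv in self.level_coords.iterrows():
            ax.scatter([], [], label=str(level))
        if cc.shape[1] >= 2:
            ax.scatter(cc.iloc[:, 0], cc.iloc[:, 1], s=12, alpha=0.6)
            sp = self.species_coords
            ax.scatter(sp.iloc[:, 0], sp.iloc[:, 1], marker="x", color="k")
            ax.set_xlabel(f"axis 1 ({100 * self.variance_fraction[0]:.1f}%)")
            ax.set_ylabel(f"axis 2 ({100 * self.variance_fraction[1]:.1f}%)")
        return ax


class CrossedDPCoA:
    """Crossed-DPCoA model: effect of factor A with crossed factor B removed.

    Parameters
    ----------
    table : CommunityTable
        Proportion matrix with row factors.
    species_distances : DataFrame, "equidistant", or precomputed coordinates
        Species dissimilarity matrix (embedded by :func:`species_space`),
        the string "equidistant", or a coordinates DataFrame indexed by
        species.
    factor_a, factor_b : str or pandas.Series
        "event" / "period" to use the table's factors, or explicit series.
    weights : array-like, optional
        Community weights (default uniform).
    """

    def __init__(
        self,
        table: CommunityTable,
        species_distances="equidistant",
        factor_a="period",
        factor_b="event",
        weights=None,
    ) -> None:
        self.table = table
        if isinstance(species_distances, pd.DataFrame) and list(
            species_distances.index
        ) != list(species_distances.columns):
            # coordinates, not a square dissimilarity matrix
            self.species_coords = species_distances
        elif isinstance(species_distances, pd.DataFrame):
            self.species_coords = species_space(
                species_distances.loc[table.species, table.species]
            )
        else:
            self.species_coords = species_space(
                species_distances, species=table.species
            )
        self.factor_a = self._factor(table, factor_a)
        self.factor_b = self._factor(table, factor_b)
        n = len(table)
        self.weights = (
            np.full(n, 1.0 / n)
            if weights is None
            else np.asarray(weights, dtype=float) / np.sum(weights)
        )

    @staticmethod
    def _factor(table: CommunityTable, f) -> pd.Series:
        if isinstance(f, str):
            if f == "event":
                return table.factor_event
            if f == "period":
                return table.factor_period
            raise InvalidInputError(f"unknown factor {f!r}")
        f = pd.Series(f)
        if not f.index.equals(table.proportions.index):
            raise InvalidInputError("factor index must match the community table")
        return f

    def fit(self, n_axes: int | None = None, tol: float = 1e-12) -> OrdinationResult:
        table = self.table
        P = table.proportions[self.species_coords.index.tolist()].to_numpy(dtype=float)
        Z = self.species_coords.to_numpy(dtype=float)
        w = self.weights
        Y = P @ Z  # communities at species centroids

        # centre factor B: subtract each B level's weighted community centroid
        Yc = Y.copy()
        for level in self.factor_b.unique():
            m = (self.factor_b == level).to_numpy()
            centroid = np.average(Y[m], axis=0, weights=w[m])
            Yc[m] -= centroid

        # factor-A level centroids of the centred communities
        levels = list(dict.fromkeys(self.factor_a))
        if len(levels) < 1 or any(
            not (self.factor_a == lv).any() for lv in levels
        ):
            raise InvalidInputError("every factor-A level needs at least one row")
        M = np.empty((len(levels), Z.shape[1]))
        Wl = np.empty(len(levels))
        for i, lv in enumerate(levels):
            m = (self.factor_a == lv).to_numpy()
            Wl[i] = w[m].sum()
            M[i] = np.average(Yc[m], axis=0, weights=w[m])

        # weighted principal axes of the A-level centroids
        C = (M * Wl[:, None]).T @ M
        vals, vecs = np.linalg.eigh(C)
        order = np.argsort(vals)[::-1]
        vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
        keep = vals > tol * max(vals[0], 1.0) if vals[0] > 0 else np.zeros_like(vals, bool)
        k = int(keep.sum())
        if n_axes is not None:
            k = min(k, n_axes)
        U = vecs[:, :k] if k else vecs[:, :0]

        # reproducible axis orientation: largest-|loading| species positive
        sp = Z @ U
        for j in range(k):
            imax = int(np.argmax(np.abs(sp[:, j])))
            if sp[imax, j] < 0:
                U[:, j] = -U[:, j]
                sp[:, j] = -sp[:, j]

        total = float(vals.sum())
        axis_names = [f"axis{i + 1}" for i in range(k)]
        idx = table.proportions.index
        return OrdinationResult(
            eigenvalues=vals[:k],
            variance_fraction=(vals[:k] / total) if total > 0 else vals[:k],
            species_coords=pd.DataFrame(sp[:, :k], index=self.species_coords.index, columns=axis_names),
            community_coords=pd.DataFrame(Y @ U, index=idx, columns=axis_names),
            centered_community_coords=pd.DataFrame(Yc @ U, index=idx, columns=axis_names),
            level_coords=pd.DataFrame(M @ U, index=pd.Index(levels, name="level"), columns=axis_names),
            axes=U,
            total_inertia=total,
        )


def crossed_dpcoa(
    table: CommunityTable,
    species_distances="equidistant",
    factor_a="period",
    factor_b="event",
    weights=None,
) -> OrdinationResult:
    """Functional wrapper around :class:`CrossedDPCoA`."""
    return CrossedDPCoA(
        table, species_distances, factor_a=factor_a, factor_b=factor_b, weights=weights
    ).fit()


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def _check_proportions(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise InvalidInputError("p must be a proportion vector summing to 1")
    return p


def richness(p) -> int:
    """Number of species with nonzero proportion."""
    return int(np.count_nonzero(_check_proportions(p) > 0))


def gini_simpson(p) -> float:
    """Gini-Simpson index 1 - sum(p_i^2)."""
    p = _check_proportions(p)
    return float(1.0 - np.sum(p**2))


def rao(p, d) -> float:
    """Rao quadratic entropy sum_ij p_i p_j d_ij."""
    p = _check_proportions(p)
    d = np.asarray(d, dtype=float)
    if d.shape != (p.size, p.size):
        raise InvalidInputError("distance matrix shape must match p")
    return float(p @ d @ p)


def diversity_by_period(
    table: CommunityTable, d: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Richness, Gini-Simpson and Rao per community row, plus period summaries.

    ``d`` is the species dissimilarity matrix (unit distances if None, in
    which case Rao equals Gini-Simpson).  Returns ``(per_row, by_period)``
    where ``by_period`` holds mean and s.d. of each index across events.
    """
    species = table.species
    if d is None:
        dm = 1.0 - np.eye(len(species))
    else:
        dm = d.loc[species, species].to_numpy(dtype=float)
    rows = []
    for key, row in table.proportions.iterrows():
        p = row.to_numpy(dtype=float)
        rows.append(
            {
                "richness": richness(p),
                "gini_simpson": gini_simpson(p),
                "rao": rao(p, dm),
            }
        )
    per_row = pd.DataFrame(rows, index=table.proportions.index)
    by_period = per_row.groupby(table.factor_period.to_numpy()).agg(["mean", "std"])
    by_period.index.name = "period"
    by_period = by_period.reindex([p for p in PERIODS if p in by_period.index])
    return per_row, by_period
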