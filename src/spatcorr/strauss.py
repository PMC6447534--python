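"""Multitype Strauss point-process model of gene-gene spatial interaction.

The positions of transcripts of several genes ("types") inside an analysis
window are modelled as a multitype Strauss process with unnormalized
density

    l(Z) proportional to  prod_i beta_i^{n_i} * prod_{i<=j} gamma_ij^{s_ij}

where n_i is the number of type-i points, s_ij the number of unordered
pairs of points of types i and j lying within the interaction radius r of
each other, beta_i the first-order intensity of type i, and gamma_ij the
pairwise interaction: gamma < 1 inhibition, gamma > 1 clustering,
gamma = 1 independence (the process degenerates to independent Poisson
processes).  The normalizing constant is intractable and never computed:
estimation uses maximum pseudolikelihood through the Berman-Turner
quadrature device, and simulation uses a fixed-count Metropolis-Hastings
sampler, both of which depend only on the Papangelou conditional
intensity

    lambda((u, i) | Z) = beta_i * prod_j gamma_ij^{t_j(u, r)}

with t_j(u, r) the number of type-j points of Z within r of u.  The
conditional intensity is log-linear in (log beta_i, log gamma_ij), so the
pseudolikelihood maximization is a weighted Poisson regression.

The density is integrable as an unconditional process only for
gamma <= 1; pseudolikelihood estimates of gamma > 1 remain well defined,
and the fixed-count (conditional) sampler is proper for any gamma > 0,
which permits the clustering regime observed in tissue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from shapely.geometry import Point, box

from .data import TranscriptTable, abundance_filter
from .islets import IsletSet, assign_islet_membership

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Pseudolikelihood optimization failed to converge."""


class FeasibilityError(RuntimeError):
    """No point configuration satisfying a hard-core constraint was found."""


# --------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class Window:
    """Planar analysis window: a circle (size = radius) or square (size = side)."""

    shape: str
    cx: float
    cy: float
    size: float

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "square"):
            raise ValueError(f"unknown window shape {self.shape!r}")
        if self.size <= 0:
            raise ValueError("window size must be > 0")

    @classmethod
    def circle(cls, cx: float, cy: float, radius: float) -> "Window":
        return cls("circle", cx, cy, radius)

    @classmethod
    def square(cls, cx: float, cy: float, side: float) -> "Window":
        return cls("square", cx, cy, side)

    @property
    def area(self) -> float:
        if self.shape == "circle":
            return float(np.pi * self.size**2)
        return float(self.size**2)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        h = self.size if self.shape == "circle" else self.size / 2.0
        return (self.cx - h, self.cy - h, self.cx + h, self.cy + h)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 2)
        dx, dy = pts[:, 0] - self.cx, pts[:, 1] - self.cy
        if self.shape == "circle":
            return dx**2 + dy**2 <= self.size**2 * (1 + 1e-12)
        h = self.size / 2.0
        return (np.abs(dx) <= h * (1 + 1e-12)) & (np.abs(dy) <= h * (1 + 1e-12))

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.shape == "circle":
            r = self.size * np.sqrt(rng.uniform(size=n))
            th = rng.uniform(0.0, 2 * np.pi, size=n)
            return np.column_stack(
                [self.cx + r * np.cos(th), self.cy + r * np.sin(th)]
            )
        h = self.size / 2.0
        return np.column_stack(
            [
                rng.uniform(self.cx - h, self.cx + h, size=n),
                rng.uniform(self.cy - h, self.cy + h, size=n),
            ]
        )

    def to_shapely(self):
        if self.shape == "circle":
            return Point(self.cx, self.cy).buffer(self.size, quad_segs=256)
        h = self.size / 2.0
        return box(self.cx - h, self.cy - h, self.cx + h, self.cy + h)


@dataclass(frozen=True)
class PointPattern:
    """Typed planar point pattern inside a window."""

    xy: np.ndarray
    types: np.ndarray  # string labels, one per point
    window: Window
    type_set: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, float).reshape(-1, 2)
        types = np.asarray(self.types, dtype=object)
        if len(types) != len(xy):
            raise ValueError("xy and types must have equal length")
        if len(xy) and not self.window.contains(xy).all():
            raise ValueError("all points must lie inside the window")
        tset = self.type_set or tuple(sorted(set(types.tolist())))
        extra = set(types.tolist()) - set(tset)
        if extra:
            raise ValueError(f"point types outside declared type set: {extra}")
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "types", types)
        object.__setattr__(self, "type_set", tuple(tset))

    def __len__(self) -> int:
        return len(self.xy)

    def counts(self) -> pd.Series:
        c = pd.Series(self.types.tolist()).value_counts()
        return pd.Series(
            [int(c.get(t, 0)) for t in self.type_set],
            index=list(self.type_set), name="n",
        )


@dataclass(frozen=True)
class StraussParams:
    """Parameters of the multitype Strauss process.

    beta: intensity per type (points per square micrometre); gamma:
    symmetric interaction matrix; radius: interaction distance r in
    micrometres.  The normalizing constant is intentionally absent.
    """

    types: tuple[str, ...]
    beta: np.ndarray
    gamma: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, float)
        gamma = np.asarray(self.gamma, float)
        t = len(self.types)
        if beta.shape != (t,) or (beta <= 0).any():
            raise ValueError("beta must be positive, one entry per type")
        if gamma.shape != (t, t) or not np.allclose(gamma, gamma.T, equal_nan=True):
            raise ValueError("gamma must be a symmetric types x types matrix")
        if (gamma < 0).any():
            raise ValueError("gamma entries must be >= 0")
        if self.radius <= 0:
            raise ValueError("interaction radius must be > 0")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma", gamma)

    def gamma_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.gamma, index=list(self.types), columns=list(self.types)
        )


@dataclass(frozen=True)
class PairCounts:
    """Per-type counts n_i and unordered within-radius pair counts s_ij."""

    types: tuple[str, ...]
    n: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n, int)
        s = np.asarray(self.s, int)
        t = len(self.types)
        if n.shape != (t,) or (n < 0).any():
            raise ValueError("n must be non-negative, one entry per type")
        if s.shape != (t, t) or (s != s.T).any() or (s < 0).any():
            raise ValueError("s must be a symmetric non-negative matrix")
        for i in range(t):
            if s[i, i] > n[i] * (n[i] - 1) // 2:
                raise ValueError("same-type pair count exceeds maximum")
            for j in range(t):
                if i != j and s[i, j] > n[i] * n[j]:
                    raise ValueError("cross-type pair count exceeds maximum")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "s", s)


def count_pairs(pattern: PointPattern, r: float) -> PairCounts:
    """Unordered within-radius pair counts s_ij and type counts n_i.

    Each unordered pair of points at distance <= r contributes once to the
    entry for its (unordered) type pair; the distance boundary is
    inclusive.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    types = pattern.type_set
    idx = {t: k for k, t in enumerate(types)}
    n = pattern.counts().to_numpy()
    s = np.zeros((len(types), len(types)), dtype=int)
    if len(pattern) >= 2:
        tree = cKDTree(pattern.xy)
        tcodes = np.array([idx[t] for t in pattern.types])
        for a, b in tree.query_pairs(r):
            i, j = tcodes[a], tcodes[b]
            s[i, j] += 1
            if i != j:
                s[j, i] += 1
    return PairCounts(types, n, s)


def log_density_unnormalized(
    pattern: PointPattern, params: StraussParams
) -> float:
    """Log of the Strauss density up to the normalizing constant.

    sum_i n_i log beta_i + sum_{i<=j} s_ij log gamma_ij; -inf when a
    hard-core pair (gamma = 0) is present in the pattern.
    """
    missing = set(pattern.type_set) - set(params.types)
    if missing:
        raise ValueError(f"pattern types absent from params: {sorted(missing)}")
    # re-index pattern under the params type order
    pat = PointPattern(pattern.xy, pattern.types, pattern.window, params.types)
    pc = count_pairs(pat, params.radius)
    total = float(np.dot(pc.n, np.log(params.beta)))
    t = len(params.types)
    for i in range(t):
        for j in range(i, t):
            sij = pc.s[i, j]
            if sij == 0:
                continue
            g = params.gamma[i, j]
            if g == 0.0:
                return float("-inf")
            total += sij * np.log(g)
    return total


# --------------------------------------------------------------------------
# pseudolikelihood fitting (Berman-Turner device)


def _pair_index(types: Sequence[str]) -> list[tuple[int, int]]:
    t = len(types)
    return [(i, j) for i in range(t) for j in range(i, t)]


def _quadrature(
    pattern: PointPattern, dummy_intensity: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified dummy points and counting-rule quadrature weights.

    The window's bounding box is tiled by a k x k grid (one stratified
    dummy proposal per tile); each quadrature location's weight is the area
    of its tile clipped to the window divided by the number of quadrature
    locations falling in that tile.
    """
    win = pattern.window
    x0, y0, x1, y1 = win.bbox
    n_dummy = max(int(np.ceil(dummy_intensity * win.area)), 16)
    k = int(np.ceil(np.sqrt(n_dummy)))
    ex = np.linspace(x0, x1, k + 1)
    ey = np.linspace(y0, y1, k + 1)
    # one uniform proposal per tile, kept if inside the window
    gx = ex[:-1][:, None] + rng.uniform(size=(k, k)) * (ex[1] - ex[0])
    gy = ey[:-1][None, :] + rng.uniform(size=(k, k)) * (ey[1] - ey[0])
    dummies = np.column_stack([gx.ravel(), gy.ravel()])
    dummies = dummies[win.contains(dummies)]
    locs = np.vstack([pattern.xy, dummies]) if len(pattern) else dummies

    poly = win.to_shapely()
    ix = np.clip(np.searchsorted(ex, locs[:, 0], side="right") - 1, 0, k - 1)
    iy = np.clip(np.searchsorted(ey, locs[:, 1], side="right") - 1, 0, k - 1)
    tile_id = ix * k + iy
    counts = np.bincount(tile_id, minlength=k * k)
    tile_area = np.zeros(k * k)
    for tid in np.unique(tile_id):
        i, j = divmod(tid, k)
        cell = box(ex[i], ey[j], ex[i + 1], ey[j + 1])
        tile_area[tid] = cell.intersection(poly).area
    w = tile_area[tile_id] / counts[tile_id]
    # guard against degenerate zero-area tiles from polygonal clipping
    w = np.maximum(w, 1e-12)
    return locs, w


def _neighbor_counts(
    pattern: PointPattern, locs: np.ndarray, r: float
) -> np.ndarray:
    """t[k, j]: number of type-j data points within r of location k.

    Locations coinciding with a data point of type j (the leading len(pattern)
    rows) exclude the point itself.
    """
    types = pattern.type_set
    t = np.zeros((len(locs), len(types)), dtype=float)
    for j, lab in enumerate(types):
        sub = pattern.xy[pattern.types == lab]
        if len(sub) == 0:
            continue
        tree = cKDTree(sub)
        t[:, j] = tree.query_ball_point(locs, r, return_length=True)
    for k_, lab in enumerate(pattern.types):
        t[k_, types.index(lab)] -= 1.0  # remove self-count
    return t


@dataclass
class StraussResults:
    """Maximum-pseudolikelihood fit of a multitype Strauss model.

    Estimates are on the natural scale; standard errors derive from the
    observed information of the composite likelihood (delta method for the
    natural scale).  Interaction entries that were unidentifiable in the
    window (a type with < 2 points, or no exposure for a pair) are NaN.
    """

    params: StraussParams
    se_log_beta: np.ndarray
    se_log_gamma: np.ndarray
    n_points: pd.Series
    pair_counts: PairCounts
    converged: bool
    model: "MultitypeStraussModel | None" = field(default=None, repr=False)

    @property
    def beta(self) -> pd.Series:
        return pd.Series(
            self.params.beta, index=list(self.params.types), name="beta"
        )

    @property
    def gamma(self) -> pd.DataFrame:
        return self.params.gamma_frame()

    @property
    def gamma_se(self) -> pd.DataFrame:
        se = self.params.gamma * self.se_log_gamma
        return pd.DataFrame(
            se, index=list(self.params.types), columns=list(self.params.types)
        )

    def summary(self) -> str:
        types = self.params.types
        lines = [
            "Multitype Strauss process: maximum pseudolikelihood fit",
            f"  interaction radius r = {self.params.radius:g} um, "
            f"window area = {self.pattern_area():.1f} um^2",
            f"  points: " + ", ".join(
                f"{t}={int(self.n_points[t])}" for t in types
            ),
            "",
            f"  {'pair':<16}{'gamma':>8}{'se':>8}{'s_ij':>8}",
        ]
        for i, ti in enumerate(types):
            for j in range(i, len(types)):
                tj = types[j]
                g = self.params.gamma[i, j]
                se = g * self.se_log_gamma[i, j]
                lines.append(
                    f"  {ti + ' ~ ' + tj:<16}{g:>8.3f}{se:>8.3f}"
                    f"{self.pair_counts.s[i, j]:>8d}"
                )
        lines.append("")
        lines.append(
            f"  {'type':<10}{'beta':>12}{'se(log)':>10}"
        )
        for i, t in enumerate(types):
            lines.append(
                f"  {t:<10}{self.params.beta[i]:>12.6f}"
                f"{self.se_log_beta[i]:>10.3f}"
            )
        return "\n".join(lines)

    def pattern_area(self) -> float:
        if self.model is not None:
            return self.model.pattern.window.area
        return float("nan")

    def simulate(
        self, n_per_type: Mapping[str, int] | None = None,
        steps: int | None = None, seed: int = 0,
    ) -> PointPattern:
        """Simulate a pattern from the fitted parameters (fixed counts)."""
        if self.model is None:
            raise ValueError("results not attached to a model")
        window = self.model.pattern.window
        if n_per_type is None:
            n_per_type = {t: int(self.n_points[t]) for t in self.params.types}
        return simulate_multitype_strauss(
            self.params, window, n_per_type, steps=steps, seed=seed
        )


class MultitypeStraussModel:
    """Multitype Strauss process model for a typed point pattern.

    The likelihood has an intractable normalizing constant, so ``fit``
    maximizes the log pseudolikelihood

        sum_x log lambda((x, m_x) | Z)  -  sum_m integral_W lambda((u, m) | Z) du

    with the integral approximated on a quadrature of data plus stratified
    dummy points (Berman-Turner device).  Because the conditional
    intensity is log-linear in the parameters, the maximization is a
    Poisson regression with an offset for the quadrature weights, solved
    by iteratively reweighted least squares.

    Parameters
    ----------
    pattern : PointPattern
        The observed typed pattern and its window.
    radius : float
        Interaction radius r in micrometres (default 20, twice the typical
        nuclei spacing, targeting interactions between neighboring cells).
    dummy_intensity : float, optional
        Intensity of dummy quadrature points; defaults to 5x the pooled
        intensity of the pattern (all types combined), which keeps the
        quadrature discretization error in the interaction estimates well
        below their sampling noise.
    """

    def __init__(
        self,
        pattern: PointPattern,
        radius: float = 20.0,
        dummy_intensity: float | None = None,
    ) -> None:
        if radius <= 0:
            raise ValueError("radius must be > 0")
        if len(pattern) == 0:
            raise ValueError("cannot fit an empty pattern")
        self.pattern = pattern
        self.radius = float(radius)
        if dummy_intensity is None:
            dummy_intensity = 5.0 * len(pattern) / pattern.window.area
        self.dummy_intensity = float(dummy_intensity)

    @classmethod
    def from_transcripts(
        cls,
        table: TranscriptTable,
        window: Window,
        genes: Sequence[str] | None = None,
        radius: float = 20.0,
        dummy_intensity: float | None = None,
    ) -> "MultitypeStraussModel":
        """Build a model from the transcripts of ``genes`` inside ``window``."""
        recs = table.records
        if genes is not None:
            recs = recs[recs["gene"].isin(set(genes))]
        xy = recs[["x", "y"]].to_numpy(float)
        inside = window.contains(xy)
        pattern = PointPattern(
            xy[inside],
            recs["gene"].to_numpy(object)[inside],
            window,
            tuple(genes) if genes is not None else (),
        )
        return cls(pattern, radius=radius, dummy_intensity=dummy_intensity)

    def fit(self, seed: int = 0, maxiter: int = 200) -> StraussResults:
        """Maximum pseudolikelihood estimate with asymptotic standard errors.

        Types with fewer than one point are excluded from the design and
        their parameters reported as NaN; same-type interactions need at
        least two points to be identifiable.
        """
        pattern = self.pattern
        all_types = pattern.type_set
        n_all = pattern.counts()
        fit_types = tuple(t for t in all_types if n_all[t] >= 1)
        if not fit_types:
            raise ValueError("no type has any points; nothing to fit")
        sub = PointPattern(
            pattern.xy, pattern.types, pattern.window, pattern.type_set
        )
        rng = np.random.default_rng(seed)
        locs, w = _quadrature(sub, self.dummy_intensity, rng)
        tcounts = _neighbor_counts(sub, locs, self.radius)  # (L, T_all)

        # identifiable pairs: both member types present (>=2 points for i==i)
        tidx = {t: k for k, t in enumerate(all_types)}
        pairs = []
        for i, ti in enumerate(fit_types):
            for tj in fit_types[i:]:
                if ti == tj and n_all[ti] < 2:
                    continue
                pairs.append((ti, tj))

        n_loc = len(locs)
        n_types = len(fit_types)
        rows = n_loc * n_types
        ncov = n_types + len(pairs)
        X = np.zeros((rows, ncov))
        z = np.zeros(rows)
        offs = np.tile(np.log(w), n_types)
        for m, tm in enumerate(fit_types):
            blk = slice(m * n_loc, (m + 1) * n_loc)
            X[blk, m] = 1.0  # log beta_m
            for p, (ti, tj) in enumerate(pairs):
                col = np.zeros(n_loc)
                if tm == ti:
                    col += tcounts[:, tidx[tj]]
                if tm == tj and ti != tj:
                    col += tcounts[:, tidx[ti]]
                X[blk, n_types + p] = col
            is_data = np.zeros(n_loc, bool)
            is_data[: len(sub)] = sub.types == tm
            z[blk] = np.where(is_data, 1.0, 0.0)

        # drop unexposed pair covariates (identically zero columns)
        keep = [True] * n_types + [
            bool(np.abs(X[:, n_types + p]).max() > 0) for p in range(len(pairs))
        ]
        keep = np.array(keep)
        Xk = X[:, keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(z, Xk, family=sm.families.Poisson(), offset=offs)
            res = glm.fit(maxiter=maxiter, tol=1e-8)
        if not res.converged:
            raise ConvergenceError(
                "pseudolikelihood IRLS did not converge: "
                f"{res.fit_history['iteration']} iterations, "
                f"deviance trace {res.fit_history.get('deviance', [])[-5:]}"
            )

        coef = np.full(ncov, np.nan)
        se = np.full(ncov, np.nan)
        coef[keep] = res.params
        se[keep] = res.bse

        t_all = len(all_types)
        beta = np.full(t_all, np.nan)
        se_log_beta = np.full(t_all, np.nan)
        gamma = np.full((t_all, t_all), np.nan)
        se_log_gamma = np.full((t_all, t_all), np.nan)
        for m, tm in enumerate(fit_types):
            beta[tidx[tm]] = np.exp(coef[m])
            se_log_beta[tidx[tm]] = se[m]
        for p, (ti, tj) in enumerate(pairs):
            i, j = tidx[ti], tidx[tj]
            gamma[i, j] = gamma[j, i] = np.exp(coef[n_types + p])
            se_log_gamma[i, j] = se_log_gamma[j, i] = se[n_types + p]

        # params object requires positive beta; fill unfitted with tiny value
        params = StraussParams(
            all_types,
            np.where(np.isnan(beta), np.nan, beta),
            gamma,
            self.radius,
        )
        return StraussResults(
            params=params,
            se_log_beta=se_log_beta,
            se_log_gamma=se_log_gamma,
            n_points=n_all,
            pair_counts=count_pairs(sub, self.radius),
            converged=bool(res.converged),
            model=self,
        )


def fit_pseudolikelihood(
    pattern: PointPattern,
    r: float = 20.0,
    dummy_intensity: float | None = None,
    seed: int = 0,
) -> StraussResults:
    """Fit a multitype Strauss model to one pattern (functional surface)."""
    return MultitypeStraussModel(
        pattern, radius=r, dummy_intensity=dummy_intensity
    ).fit(seed=seed)


# --------------------------------------------------------------------------
# per-islet fitting and aggregation


@dataclass
class IsletStraussResults:
    """Per-islet Strauss fits aggregated to mean +/- std per type pair.

    ``per_window`` holds one gamma DataFrame per fitted islet; pairs a
    given islet could not identify are NaN there and excluded from the
    aggregation.  ``windows_used`` counts the islets contributing to each
    pair.  The std is the sample standard deviation across islets (0, with
    a warning, when only one islet contributes).
    """

    types: tuple[str, ...]
    gamma_mean: pd.DataFrame
    gamma_std: pd.DataFrame
    windows_used: pd.DataFrame
    per_window: list[pd.DataFrame]
    radius: float
    min_count: int

    def pair_table(self) -> pd.DataFrame:
        """Long-form table: one row per unordered pair."""
        rows = []
        for i, ti in enumerate(self.types):
            for tj in self.types[i:]:
                if ti == tj:
                    continue
                rows.append(
                    {
                        "pair": f"{ti}~{tj}",
                        "mean": self.gamma_mean.loc[ti, tj],
                        "std": self.gamma_std.loc[ti, tj],
                        "n_windows": int(self.windows_used.loc[ti, tj]),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Per-islet multitype Strauss fits "
            f"(r = {self.radius:g} um, gene gate >= {self.min_count} "
            "transcripts in islets)",
            f"  islets fitted: {len(self.per_window)}",
            f"  {'pair':<16}{'mean':>8}{'std':>8}{'windows':>9}",
        ]
        for _, row in self.pair_table().iterrows():
            lines.append(
                f"  {row['pair']:<16}{row['mean']:>8.2f}{row['std']:>8.2f}"
                f"{row['n_windows']:>9d}"
            )
        return "\n".join(lines)


def fit_per_islet(
    table: TranscriptTable,
    islets: IsletSet,
    r: float = 20.0,
    min_count: int = 500,
    seed: int = 0,
    windows: Sequence[Window] | None = None,
) -> IsletStraussResults:
    """Fit the Strauss model within each islet and aggregate across islets.

    Genes are gated by their tissue-wide transcript count inside islets
    (>= min_count); each qualifying islet is an analysis window (its
    circle, unless ``windows`` overrides the geometry) and receives an
    independent fit.  Per-pair interaction estimates are averaged across
    the islets in which the pair was identifiable.
    """
    if len(islets) == 0:
        raise ValueError("no islets to fit in")
    inside = assign_islet_membership(table.xy, islets)
    genes = abundance_filter(table, min_count, region_mask=inside)
    if len(genes) < 2:
        raise ValueError(
            f"fewer than 2 genes pass the {min_count}-count islet gate"
        )
    if windows is None:
        windows = [Window.circle(c.cx, c.cy, c.radius) for c in islets]

    recs = table.records[table.records["gene"].isin(set(genes))]
    xy = recs[["x", "y"]].to_numpy(float)
    labels = recs["gene"].to_numpy(object)
    types = tuple(genes)
    per_window: list[pd.DataFrame] = []
    rng = np.random.default_rng(seed)
    for win in windows:
        m = win.contains(xy)
        if m.sum() < 4:
            continue
        sub_types = labels[m]
        cts = pd.Series(sub_types.tolist()).value_counts()
        present = [t for t in types if cts.get(t, 0) >= 2]
        if len(present) < 2:
            continue
        keep = np.isin(sub_types, present)
        pattern = PointPattern(
            xy[m][keep], sub_types[keep], win, tuple(present)
        )
        try:
            res = MultitypeStraussModel(pattern, radius=r).fit(
                seed=int(rng.integers(2**31 - 1))
            )
        except ConvergenceError:
            logger.warning("islet window %s: fit did not converge; skipped", win)
            continue
        g = pd.DataFrame(np.nan, index=list(types), columns=list(types))
        gf = res.gamma
        for ti in present:
            for tj in present:
                g.loc[ti, tj] = gf.loc[ti, tj]
        per_window.append(g)

    if not per_window:
        raise ValueError("no islet window produced a fit")
    stack = np.stack([g.to_numpy() for g in per_window])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        nwin = np.sum(~np.isnan(stack), axis=0)
        std = np.where(
            nwin > 1,
            np.nanstd(stack, axis=0, ddof=1),
            np.where(nwin == 1, 0.0, np.nan),
        )
    if (nwin == 1).any():
        logger.warning(
            "some pairs were fitted in a single islet; std reported as 0"
        )
    idx = list(types)
    return IsletStraussResults(
        types=types,
        gamma_mean=pd.DataFrame(mean, index=idx, columns=idx),
        gamma_std=pd.DataFrame(std, index=idx, columns=idx),
        windows_used=pd.DataFrame(nwin, index=idx, columns=idx),
        per_window=per_window,
        radius=r,
        min_count=min_count,
    )


def geometry_robustness(
    table: TranscriptTable,
    islets: IsletSet,
    r: float = 20.0,
    min_count: int = 500,
    seed: int = 0,
) -> dict:
    """Refit with circle vs equal-area square windows at the islet centers.

    The square's side is radius * sqrt(pi), so both windows have the same
    area; a model capturing genuine interaction rather than window
    artefacts should report nearly identical gamma under both geometries.
    """
    circles = [Window.circle(c.cx, c.cy, c.radius) for c in islets]
    squares = [
        Window.square(c.cx, c.cy, c.radius * np.sqrt(np.pi)) for c in islets
    ]
    res_c = fit_per_islet(table, islets, r, min_count, seed, windows=circles)
    res_s = fit_per_islet(table, islets, r, min_count, seed, windows=squares)
    common = [t for t in res_c.types if t in res_s.types]
    diff = (
        res_c.gamma_mean.loc[common, common]
        - res_s.gamma_mean.loc[common, common]
    ).abs()
    return {"circle": res_c, "square": res_s, "abs_difference": diff}


# --------------------------------------------------------------------------
# simulation


def simulate_multitype_strauss(
    params: StraussParams,
    window: Window,
    n_per_type: Mapping[str, int],
    steps: int | None = None,
    seed: int = 0,
    max_init_retries: int = 1000,
    return_acceptance: bool = False,
):
    """Fixed-count Metropolis-Hastings simulation of the Strauss process.

    Holding the per-type counts fixed, single points are relocated to
    uniform proposals and accepted with probability
    min(1, prod_j gamma_{ij}^{delta s}); this targets the conditional
    Strauss distribution given the counts, which is proper for any
    gamma > 0 (including the clustering regime gamma > 1).  With all
    gamma = 1 every proposal is accepted and the result is a binomial
    (uniform) pattern.

    ``steps`` defaults to 100 relocations per point (10,000 per 100
    points).  Identical seed and inputs give identical output.
    """
    rng = np.random.default_rng(seed)
    types = params.types
    counts = np.array([int(n_per_type.get(t, 0)) for t in types])
    if (counts < 0).any():
        raise ValueError("n_per_type must be non-negative")
    n_total = int(counts.sum())
    hard = params.gamma == 0.0
    with np.errstate(divide="ignore"):
        log_gamma = np.where(hard, -np.inf, np.log(np.maximum(params.gamma, 1e-300)))
    r2 = params.radius**2

    tcodes = np.repeat(np.arange(len(types)), counts)
    labels = np.array(list(types), dtype=object)[tcodes]

    pts = window.sample_uniform(n_total, rng)
    if hard.any():
        # sequential dart-throwing: place each point avoiding hard-core
        # conflicts with the points already placed
        for i in range(n_total):
            for attempt in range(max_init_retries + 1):
                if attempt == max_init_retries:
                    raise FeasibilityError(
                        "could not place initial points without violating "
                        f"a hard-core constraint ({max_init_retries} "
                        "attempts per point)"
                    )
                prev = pts[:i]
                d2 = (prev[:, 0] - pts[i, 0]) ** 2 + (prev[:, 1] - pts[i, 1]) ** 2
                conflict = (d2 <= r2) & hard[tcodes[i], tcodes[:i]]
                if not conflict.any():
                    break
                pts[i] = window.sample_uniform(1, rng)[0]

    if steps is None:
        steps = max(100 * n_total, 1)
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if n_total == 0:
        pat = PointPattern(np.empty((0, 2)), np.empty(0, object), window, types)
        return (pat, 1.0) if return_acceptance else pat

    idx_choices = rng.integers(0, n_total, size=steps)
    proposals = window.sample_uniform(steps, rng)
    unif = rng.uniform(size=steps)
    type_masks = [tcodes == k for k in range(len(types))]
    accepted = 0
    for step in range(steps):
        i = idx_choices[step]
        ti = tcodes[i]
        old = pts[i]
        new = proposals[step]
        d2_old = (pts[:, 0] - old[0]) ** 2 + (pts[:, 1] - old[1]) ** 2
        d2_new = (pts[:, 0] - new[0]) ** 2 + (pts[:, 1] - new[1]) ** 2
        d2_old[i] = d2_new[i] = np.inf  # the moving point never pairs with itself
        near_old = d2_old <= r2
        near_new = d2_new <= r2
        delta = 0.0
        for k in range(len(types)):
            lg = log_gamma[ti, k]
            if lg == 0.0:
                continue
            ds = int(np.count_nonzero(near_new & type_masks[k])) - int(
                np.count_nonzero(near_old & type_masks[k])
            )
            if ds:
                delta += ds * lg
        if delta >= 0 or unif[step] < np.exp(delta):
            pts[i] = new
            accepted += 1
    pat = PointPattern(pts, labels, window, types)
    if return_acceptance:
        return pat, accepted / steps
    return pat
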