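"""Per-pH titration statistics from occupancy trajectories.

The central objects are the per-pH moments of the proton-count vector:
mean protonations, the variance of the total bound-proton count, and the
covariance of each site's occupancy with the total. These moments are not
merely descriptive — by the fluctuation relations of linkage theory they
*are* the slopes of the titration curves,

    d n̄ / dpH   = −ln10 · var(n)
    d n̄_i / dpH = −ln10 · cov(n_i, n)

so a titration curve sampled at a handful of pH values comes with exact
derivative information at every sample. That is what lets the linkage
module build thermodynamically anchored Hermite splines instead of fitted
Hill curves.

Moments use population (1/N) normalisation: the fluctuation relations are
ensemble identities, and 1/(N−1) would break the exact additivity
Σ_i cov(n_i, n) = var(n) against the enumeration oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .constants import LN10
from .occupancy import ACID, OccupancyTrajectory, SiteDefinition

__all__ = [
    "TitrationPoint",
    "TitrationCurve",
    "HillFit",
    "compute_titration_point",
    "build_titration_curve",
    "titration_slope_total",
    "titration_slope_site",
    "fit_hill",
    "hill_curve",
    "protein_charge_curve",
    "isoionic_point",
    "bootstrap_errors",
    "block_bootstrap_indices",
]


@dataclass
class TitrationPoint:
    """Pooled moments of the bound-proton counts at one (form, pH)."""

    pH: float
    site_labels: tuple[str, ...]
    n_mean: float
    n_var: float
    site_means: np.ndarray  # (M,)
    site_cov_total: np.ndarray  # (M,) cov(n_i, n)
    n_frames_used: int
    se_n_mean: float | None = None
    se_site_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.site_means = np.asarray(self.site_means, dtype=float)
        self.site_cov_total = np.asarray(self.site_cov_total, dtype=float)

    def site_index(self, label: str) -> int:
        try:
            return self.site_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown site {label!r}") from None


@dataclass
class TitrationCurve:
    """Titration points of one form at strictly increasing pH."""

    form: str
    points: list[TitrationPoint]

    def __post_init__(self) -> None:
        phs = [p.pH for p in self.points]
        if any(b <= a for a, b in zip(phs, phs[1:])):
            raise ValueError("points must be at strictly increasing pH")
        labels = {p.site_labels for p in self.points}
        if len(labels) > 1:
            raise ValueError("inconsistent site lists across points")

    @property
    def pH_values(self) -> np.ndarray:
        return np.array([p.pH for p in self.points])

    @property
    def site_labels(self) -> tuple[str, ...]:
        return self.points[0].site_labels

    @property
    def n_means(self) -> np.ndarray:
        return np.array([p.n_mean for p in self.points])

    def site_mean_series(self, label: str) -> np.ndarray:
        i = self.points[0].site_index(label)
        return np.array([p.site_means[i] for p in self.points])

    def site_slope_series(self, label: str) -> np.ndarray:
        i = self.points[0].site_index(label)
        return np.array([-LN10 * p.site_cov_total[i] for p in self.points])

    @property
    def total_slopes(self) -> np.ndarray:
        return np.array([-LN10 * p.n_var for p in self.points])


def _pooled_occupancies(trajs: Sequence[OccupancyTrajectory]) -> np.ndarray:
    if not trajs:
        raise ValueError("at least one replicate required")
    labels = trajs[0].site_labels
    ph = trajs[0].pH
    form = trajs[0].form
    for t in trajs[1:]:
        if t.site_labels != labels:
            raise ValueError("replicates disagree on site lists")
        if abs(t.pH - ph) > 1e-9 or t.form != form:
            raise ValueError("replicates must share (form, pH)")
    pooled = np.vstack([t.retained() for t in trajs])
    if pooled.shape[0] == 0:
        raise ValueError("zero retained frames across all replicates")
    return pooled


def _moments(pooled: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(n_mean, n_var, site_means, cov(n_i, n)) with 1/N normalisation."""
    site_means = pooled.mean(axis=0)
    n_per_frame = pooled.sum(axis=1)
    n_mean = float(site_means.sum())  # equals n_per_frame.mean() exactly
    centered_total = n_per_frame - n_mean
    n_var = float(np.mean(centered_total**2))
    cov = (pooled - site_means).T @ centered_total / pooled.shape[0]
    return n_mean, n_var, site_means, cov


def compute_titration_point(
    trajs: Sequence[OccupancyTrajectory] | OccupancyTrajectory,
) -> TitrationPoint:
    """Pool the retained frames of all replicates and compute the moments.

    The additivity identities n̄ = Σ n̄_i and var(n) = Σ cov(n_i, n) hold
    exactly (bilinearity of covariance), which downstream code relies on.
    """
    if isinstance(trajs, OccupancyTrajectory):
        trajs = [trajs]
    pooled = _pooled_occupancies(trajs)
    n_mean, n_var, site_means, cov = _moments(pooled)
    return TitrationPoint(
        pH=trajs[0].pH,
        site_labels=trajs[0].site_labels,
        n_mean=n_mean,
        n_var=n_var,
        site_means=site_means,
        site_cov_total=cov,
        n_frames_used=pooled.shape[0],
    )


def build_titration_curve(
    cells: Sequence[Sequence[OccupancyTrajectory]],
) -> TitrationCurve:
    """Titration curve from per-pH replicate groups (sorted by pH)."""
    pts = sorted(
        (compute_titration_point(c) for c in cells), key=lambda p: p.pH
    )
    form = cells[0][0].form if not isinstance(cells[0], OccupancyTrajectory) else cells[0].form
    return TitrationCurve(form=form, points=list(pts))


def titration_slope_total(point: TitrationPoint) -> float:
    """dn̄/dpH = −ln10 · var(n); always ≤ 0."""
    return -LN10 * point.n_var


def titration_slope_site(point: TitrationPoint, site: str) -> float:
    """dn̄_i/dpH = −ln10 · cov(n_i, n). Site slopes sum to the total slope."""
    return -LN10 * float(point.site_cov_total[point.site_index(site)])


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

@dataclass
class HillFit:
    """Hill-curve fit n̄(pH) = 1 / (1 + 10^{h (pH − pKa)})."""

    pKa: float
    h: float
    rss: float
    converged: bool
    se_pKa: float | None = None
    se_h: float | None = None


def hill_curve(pH, pKa: float, h: float):
    """The fitted titration curve; value in (0, 1) for finite pH."""
    x = np.asarray(pH, dtype=float)
    # stable logistic: 1/(1+10^y) = exp(-softplus(y ln10))
    y = h * (x - pKa) * LN10
    out = np.exp(-np.logaddexp(0.0, y))
    return out if out.ndim else float(out)


_H_BOUNDS = (0.05, 10.0)


def fit_hill(
    pH_values: Sequence[float],
    mean_occupancies: Sequence[float],
    init: tuple[float, float] | None = None,
) -> HillFit:
    """Least-squares Hill fit of per-site mean protonations.

    Initialisation: pKa0 at the (interpolated) half-protonation pH, h0 = 1;
    h is bounded to [0.05, 10] to keep flat curves from collapsing the fit.
    The fit is flagged not-converged when the solver fails or the fitted
    pKa lands more than 2 units outside the sampled pH window (an
    extrapolated midpoint is indicative only).
    """
    x = np.asarray(pH_values, dtype=float)
    y = np.asarray(mean_occupancies, dtype=float)
    if x.size < 3:
        raise ValueError("Hill fit requires at least 3 points")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("mean occupancies must lie in [0, 1]")

    if init is not None:
        pka0, h0 = init
    else:
        h0 = 1.0
        # linear interpolation of the 0.5 crossing; fall back to range centre
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        crossings = np.flatnonzero(np.diff(np.sign(ys - 0.5)) != 0)
        if crossings.size:
            k = crossings[0]
            x0, x1, y0, y1 = xs[k], xs[k + 1], ys[k], ys[k + 1]
            pka0 = x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0) if y1 != y0 else x0
        else:
            pka0 = float(xs[np.argmin(np.abs(ys - 0.5))])

    if np.ptp(y) == 0.0:
        return HillFit(pKa=float(pka0), h=h0, rss=0.0, converged=False)

    def resid(theta):
        return hill_curve(x, theta[0], theta[1]) - y

    lo = [x.min() - 10.0, _H_BOUNDS[0]]
    hi = [x.max() + 10.0, _H_BOUNDS[1]]
    try:
        sol = least_squares(
            resid,
            x0=[float(np.clip(pka0, lo[0], hi[0])), h0],
            bounds=(lo, hi),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except Exception:
        return HillFit(pKa=float(pka0), h=h0, rss=float("inf"), converged=False)
    pka, h = float(sol.x[0]), float(sol.x[1])
    rss = float(np.sum(sol.fun**2))
    inside = (x.min() - 2.0) <= pka <= (x.max() + 2.0)
    return HillFit(pKa=pka, h=h, rss=rss, converged=bool(sol.success and inside))


# ---------------------------------------------------------------------------
# Charge curve and isoionic point
# ---------------------------------------------------------------------------

def protein_charge_curve(
    curve: TitrationCurve, sites: Sequence[SiteDefinition]
) -> np.ndarray:
    """Mean protein charge per pH: Σ_acids (n̄_i − 1) + Σ_bases n̄_i."""
    by_label = {s.label: s for s in sites}
    missing = [lab for lab in curve.site_labels if lab not in by_label]
    if missing:
        raise KeyError(f"missing residue_kind for sites {missing}")
    n_acid = sum(
        1 for lab in curve.site_labels if by_label[lab].residue_kind == ACID
    )
    return curve.n_means - n_acid


def isoionic_point(
    curve: TitrationCurve,
    sites: Sequence[SiteDefinition],
    *,
    resolution: float | None = 0.1,
) -> float:
    """pH at which the spline interpolant of the charge curve crosses zero.

    The charge spline is the total-protonation Hermite spline shifted by
    the (constant) number of acids, with slopes from the fluctuation
    relation; for fixed site composition the charge and protonation
    interpolants cross zero at the same pH.
    """
    from scipy.interpolate import CubicHermiteSpline

    charge = protein_charge_curve(curve, sites)
    if not (charge.min() < 0.0 < charge.max() or np.any(charge == 0.0)):
        raise ValueError(
            "charge does not change sign within the sampled pH range "
            f"[{curve.pH_values[0]}, {curve.pH_values[-1]}]"
        )
    spline = CubicHermiteSpline(curve.pH_values, charge, curve.total_slopes)
    phs = curve.pH_values
    # bracket the first sign change between knots (or hit an exact zero)
    for a, b, ca, cb in zip(phs, phs[1:], charge, charge[1:]):
        if ca == 0.0:
            root = float(a)
            break
        if ca * cb < 0 or cb == 0.0:
            root = float(brentq(spline, a, b, xtol=1e-10))
            break
    else:  # pragma: no cover - excluded by the sign-change guard
        raise ValueError("no bracketing interval found")
    if resolution:
        return round(root / resolution) * resolution
    return root


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def block_bootstrap_indices(
    n_frames: int, block_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Circular moving-block resample of frame indices (length preserved)."""
    block_frames = max(1, min(block_frames, n_frames))
    n_blocks = int(np.ceil(n_frames / block_frames))
    starts = rng.integers(0, n_frames, size=n_blocks)
    idx = (starts[:, None] + np.arange(block_frames)[None, :]) % n_frames
    return idx.reshape(-1)[:n_frames]


def _resample_trajectory(
    traj: OccupancyTrajectory, block_ps: float, rng: np.random.Generator
) -> np.ndarray:
    occ = traj.retained()
    n = occ.shape[0]
    if n == 0:
        return occ
    dt = float(np.median(np.diff(traj.times))) if traj.n_frames > 1 else 1.0
    block_frames = max(1, int(round(block_ps / dt)))
    return occ[block_bootstrap_indices(n, block_frames, rng)]


def bootstrap_errors(
    trajs: Sequence[OccupancyTrajectory],
    statistic: Callable[[np.ndarray], np.ndarray | float],
    *,
    B: int = 200,
    seed: int,
    block_ps: float = 1000.0,
) -> np.ndarray | float:
    """Two-level bootstrap standard error of a pooled-frame statistic.

    Level 1 resamples replicates with replacement; level 2 resamples
    contiguous (circular moving) blocks of retained frames within each
    chosen replicate. ``statistic`` maps a pooled (frames, sites) occupancy
    matrix to a scalar or vector; the returned SE is the standard deviation
    of the statistic across the B resamples. Occupancy series are strongly
    autocorrelated, hence the block default of 1 ns.
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    trajs = list(trajs)
    if len(trajs) == 1:
        warnings.warn(
            "single replicate: falling back to block-only bootstrap",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    stats = []
    n_rep = len(trajs)
    for _ in range(B):
        chosen = (
            trajs
            if n_rep == 1
            else [trajs[k] for k in rng.integers(0, n_rep, size=n_rep)]
        )
        pooled = np.vstack([_resample_trajectory(t, block_ps, rng) for t in chosen])
        stats.append(statistic(pooled))
    return np.std(np.asarray(stats, dtype=float), axis=0)
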