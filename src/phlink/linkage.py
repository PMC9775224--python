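"""pH-dependent relative association free energies by linkage integration.

Wyman–Tanford linkage for a homodimerization reaction 2M → D states that

    dΔG°/dpH = RT ln10 · (n̄^D − 2 n̄^M)

where n̄^D and n̄^M are the mean numbers of protons bound to the dimer and
the monomer. Integrating from a reference pH gives the *shape* of the
pH-dependent dimerization free energy,

    ΔΔG°(pH) = RT ln10 ∫_{pH_ref}^{pH} (n̄^D − 2 n̄^M) dpH′ ,

up to a pH-independent constant recoverable only by anchoring to
experiment. Constant-pH MD samples n̄ at a handful of pH values, so the
integrand must be interpolated — and the key point is that the slope of
each titration curve is known *exactly* at every sampled pH through the
fluctuation relations (dn̄/dpH = −ln10 var(n), per site −ln10 cov(n_i, n)).
Interpolation therefore uses cubic Hermite splines anchored to both the
sampled means and their thermodynamic slopes, integrated in closed form,
rather than fitted Hill curves. A Hill-integral route is provided for
comparison, and the total integral splits exactly into per-site
contributions because protonation is a sum over sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .constants import DEFAULT_TEMPERATURE, KJ_PER_KCAL, LN10, rt_ln10
from .occupancy import OccupancyTrajectory, SystemSet
from .titration import (
    HillFit,
    TitrationCurve,
    _moments,
    _resample_trajectory,
    fit_hill,
)

__all__ = [
    "HermiteSpline",
    "FreeEnergyProfile",
    "ExperimentalPoints",
    "build_spline",
    "integrate_spline",
    "thermodynamic_spline",
    "site_thermodynamic_spline",
    "ddG_profile",
    "ddG_site_decomposition",
    "hill_antiderivative",
    "ddG_profile_hill",
    "anchor_to_experiment",
    "profile_bootstrap_envelope",
    "pair_sites",
    "read_experimental_points",
]


# ---------------------------------------------------------------------------
# Hermite splines
# ---------------------------------------------------------------------------

@dataclass
class HermiteSpline:
    """Piecewise-cubic interpolant matching values and slopes at knots."""

    knots: np.ndarray
    values: np.ndarray
    slopes: np.ndarray
    _pp: CubicHermiteSpline = field(repr=False, default=None)  # type: ignore

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        if self.knots.ndim != 1 or self.knots.size < 2:
            raise ValueError("at least 2 knots required")
        if not np.all(np.diff(self.knots) > 0):
            raise ValueError("knots must be strictly increasing")
        if self.values.shape != self.knots.shape or self.slopes.shape != self.knots.shape:
            raise ValueError("values/slopes must match knots in length")
        if self._pp is None:
            self._pp = CubicHermiteSpline(self.knots, self.values, self.slopes)

    def __call__(self, x):
        return self._pp(x)

    def derivative(self, x):
        return self._pp(x, 1)

    def __add__(self, other: "HermiteSpline") -> "HermiteSpline":
        if not np.array_equal(self.knots, other.knots):
            raise ValueError("splines must share knots to be added")
        return HermiteSpline(
            self.knots, self.values + other.values, self.slopes + other.slopes
        )

    def scaled(self, c: float) -> "HermiteSpline":
        return HermiteSpline(self.knots, c * self.values, c * self.slopes)


def build_spline(
    knots: Sequence[float], values: Sequence[float], slopes: Sequence[float]
) -> HermiteSpline:
    """Cubic Hermite spline through (pH, value) with prescribed slopes."""
    return HermiteSpline(np.asarray(knots), np.asarray(values), np.asarray(slopes))


def integrate_spline(s: HermiteSpline, a: float, b: float) -> float:
    """Closed-form integral of the piecewise cubic on [a, b].

    Extrapolation is refused: the spline carries no physical information
    outside its knot range.
    """
    lo, hi = s.knots[0], s.knots[-1]
    eps = 1e-12 * max(1.0, abs(lo), abs(hi))
    for x in (a, b):
        if x < lo - eps or x > hi + eps:
            raise ValueError(
                f"integration limit {x} outside knot range [{lo}, {hi}]"
            )
    return float(s._pp.antiderivative()(b) - s._pp.antiderivative()(a))


def thermodynamic_spline(curve: TitrationCurve) -> HermiteSpline:
    """Total-protonation spline: values n̄, slopes −ln10·var(n)."""
    return build_spline(curve.pH_values, curve.n_means, curve.total_slopes)


def site_thermodynamic_spline(curve: TitrationCurve, label: str) -> HermiteSpline:
    """Per-site spline: values n̄_i, slopes −ln10·cov(n_i, n)."""
    return build_spline(
        curve.pH_values,
        curve.site_mean_series(label),
        curve.site_slope_series(label),
    )


# ---------------------------------------------------------------------------
# Free-energy profiles
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyProfile:
    """ΔΔG°(pH) on a dense grid, kJ/mol, relative to pH_ref."""

    pH_grid: np.ndarray
    ddG: np.ndarray
    pH_ref: float
    temperature: float
    per_site: dict[str, np.ndarray] = field(default_factory=dict)
    envelope: tuple[np.ndarray, np.ndarray] | None = None
    units: str = "kJ/mol"

    def in_kcal(self) -> "FreeEnergyProfile":
        """The same profile converted to kcal/mol."""
        c = 1.0 / KJ_PER_KCAL
        return FreeEnergyProfile(
            pH_grid=self.pH_grid,
            ddG=self.ddG * c,
            pH_ref=self.pH_ref,
            temperature=self.temperature,
            per_site={k: v * c for k, v in self.per_site.items()},
            envelope=None
            if self.envelope is None
            else (self.envelope[0] * c, self.envelope[1] * c),
            units="kcal/mol",
        )

    def at(self, pH: float) -> float:
        return float(np.interp(pH, self.pH_grid, self.ddG))


def _profile_from_integrand(
    integrand: HermiteSpline,
    pH_ref: float,
    temperature: float,
    grid_step: float,
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = integrand.knots[0], integrand.knots[-1]
    n = int(round((hi - lo) / grid_step))
    grid = np.linspace(lo, hi, n + 1)
    anti = integrand._pp.antiderivative()
    pref = rt_ln10(temperature)
    ddg = pref * (anti(grid) - anti(pH_ref))
    return grid, ddg


def linkage_integrand(
    curve_M: TitrationCurve, curve_D: TitrationCurve
) -> HermiteSpline:
    """The spline of n̄^D − 2 n̄^M with thermodynamic slopes."""
    if curve_M.pH_values.shape != curve_D.pH_values.shape or not np.allclose(
        curve_M.pH_values, curve_D.pH_values
    ):
        raise ValueError("monomer and dimer curves must share pH knots")
    sm = thermodynamic_spline(curve_M)
    sd = thermodynamic_spline(curve_D)
    return sd + sm.scaled(-2.0)


def ddG_profile(
    curve_M: TitrationCurve,
    curve_D: TitrationCurve,
    pH_ref: float | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    *,
    grid_step: float = 0.01,
    decompose: bool = True,
) -> FreeEnergyProfile:
    """Spline-linkage ΔΔG°(pH) (and per-site split) relative to pH_ref.

    ``pH_ref`` defaults to the lowest sampled pH. The dimer curve counts
    protons over both chains.
    """
    integrand = linkage_integrand(curve_M, curve_D)
    if pH_ref is None:
        pH_ref = float(integrand.knots[0])
    grid, ddg = _profile_from_integrand(integrand, pH_ref, temperature, grid_step)
    per_site: dict[str, np.ndarray] = {}
    if decompose:
        per_site = ddG_site_decomposition(
            curve_M, curve_D, pH_ref, temperature, grid=grid
        )
    return FreeEnergyProfile(
        pH_grid=grid,
        ddG=ddg,
        pH_ref=pH_ref,
        temperature=temperature,
        per_site=per_site,
    )


def pair_sites(
    curve_M: TitrationCurve, curve_D: TitrationCurve
) -> dict[str, tuple[str, str]]:
    """Map each monomer site label to its (chain A, chain B) dimer labels.

    Pairing is by chain-stripped label: monomer ``ASP137`` (or ``A:ASP137``)
    pairs with dimer ``A:ASP137`` / ``B:ASP137``.
    """
    def base(lab: str) -> str:
        return lab.split(":", 1)[1] if ":" in lab else lab

    dimer_by_chain: dict[str, dict[str, str]] = {}
    for lab in curve_D.site_labels:
        chain = lab.split(":", 1)[0]
        dimer_by_chain.setdefault(chain, {})[base(lab)] = lab
    chains = sorted(dimer_by_chain)
    if len(chains) != 2:
        raise ValueError(f"dimer must have exactly 2 chains, found {chains}")
    a, b = chains
    pairing = {}
    for lab in curve_M.site_labels:
        bl = base(lab)
        try:
            pairing[lab] = (dimer_by_chain[a][bl], dimer_by_chain[b][bl])
        except KeyError:
            raise ValueError(f"monomer site {lab!r} unpaired in the dimer") from None
    return pairing


def ddG_site_decomposition(
    curve_M: TitrationCurve,
    curve_D: TitrationCurve,
    pH_ref: float | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    *,
    grid: np.ndarray | None = None,
    grid_step: float = 0.01,
) -> dict[str, np.ndarray]:
    """Per-site ΔΔG_i°(pH): RT ln10 ∫ (n̄_i^{A,D} + n̄_i^{B,D} − 2 n̄_i^M).

    Hermite interpolation is linear in the (value, slope) data, so the
    per-site splines sum to the total spline and the decomposition sums to
    the total profile to machine precision.
    """
    pairing = pair_sites(curve_M, curve_D)
    if pH_ref is None:
        pH_ref = float(curve_M.pH_values[0])
    if grid is None:
        lo, hi = curve_M.pH_values[0], curve_M.pH_values[-1]
        grid = np.linspace(lo, hi, int(round((hi - lo) / grid_step)) + 1)
    pref = rt_ln10(temperature)
    out: dict[str, np.ndarray] = {}
    for mono_label, (lab_a, lab_b) in pairing.items():
        s = (
            site_thermodynamic_spline(curve_D, lab_a)
            + site_thermodynamic_spline(curve_D, lab_b)
            + site_thermodynamic_spline(curve_M, mono_label).scaled(-2.0)
        )
        anti = s._pp.antiderivative()
        out[mono_label] = pref * (anti(grid) - anti(pH_ref))
    return out


# ---------------------------------------------------------------------------
# Hill-integral route
# ---------------------------------------------------------------------------

def hill_antiderivative(pH, pKa: float, h: float):
    """Closed-form antiderivative of the Hill curve 1/(1 + 10^{h(pH−pKa)}).

    A(pH) = pH − ln(1 + 10^{h(pH−pKa)}) / (h ln10), evaluated stably.
    """
    x = np.asarray(pH, dtype=float)
    y = h * (x - pKa) * LN10
    out = x - np.logaddexp(0.0, y) / (h * LN10)
    return out if out.ndim else float(out)


def ddG_profile_hill(
    hill_fits_M: Mapping[str, HillFit],
    hill_fits_D: Mapping[str, HillFit],
    pH_knots: Sequence[float],
    pH_ref: float | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    *,
    grid_step: float = 0.01,
) -> FreeEnergyProfile:
    """Linkage profile from per-site Hill fits (the comparison route).

    ``hill_fits_D`` must cover both dimer chains; the integrand is
    Σ_dimer-sites hill − 2 Σ_monomer-sites hill, integrated in closed form.
    """
    bad = [k for k, f in {**hill_fits_M, **hill_fits_D}.items() if not f.converged]
    if bad:
        raise ValueError(f"non-converged Hill fits for sites: {sorted(bad)}")
    pH_knots = np.asarray(pH_knots, dtype=float)
    lo, hi = float(pH_knots[0]), float(pH_knots[-1])
    if pH_ref is None:
        pH_ref = lo
    n = int(round((hi - lo) / grid_step))
    grid = np.linspace(lo, hi, n + 1)

    def total_anti(x):
        acc = np.zeros_like(np.asarray(x, dtype=float))
        for f in hill_fits_D.values():
            acc = acc + hill_antiderivative(x, f.pKa, f.h)
        for f in hill_fits_M.values():
            acc = acc - 2.0 * hill_antiderivative(x, f.pKa, f.h)
        return acc

    pref = rt_ln10(temperature)
    ddg = pref * (total_anti(grid) - total_anti(np.array([pH_ref]))[0])
    return FreeEnergyProfile(
        pH_grid=grid, ddG=ddg, pH_ref=pH_ref, temperature=temperature
    )


def fit_hill_curves(curve: TitrationCurve) -> dict[str, HillFit]:
    """Per-site Hill fits of a titration curve (convenience wrapper)."""
    return {
        lab: fit_hill(curve.pH_values, curve.site_mean_series(lab))
        for lab in curve.site_labels
    }


# ---------------------------------------------------------------------------
# Experimental anchoring
# ---------------------------------------------------------------------------

@dataclass
class ExperimentalPoints:
    """Experimental ΔG°(pH) points, kJ/mol; upper bounds excluded from fits."""

    pH: np.ndarray
    dG: np.ndarray
    is_upper_bound: np.ndarray
    source: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pH = np.asarray(self.pH, dtype=float)
        self.dG = np.asarray(self.dG, dtype=float)
        self.is_upper_bound = np.asarray(self.is_upper_bound, dtype=bool)
        if not (np.isfinite(self.pH).all() and np.isfinite(self.dG).all()):
            raise ValueError("experimental points must be finite")


def read_experimental_points(path: str | Path) -> ExperimentalPoints:
    """Read a TSV with columns pH, dG, is_upper_bound, source."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return ExperimentalPoints(
        pH=df["pH"].to_numpy(float),
        dG=df["dG"].to_numpy(float),
        is_upper_bound=df.get("is_upper_bound", 0).astype(bool).to_numpy()
        if "is_upper_bound" in df
        else np.zeros(len(df), dtype=bool),
        source=tuple(df["source"]) if "source" in df else (),
    )


def anchor_to_experiment(
    profile: FreeEnergyProfile, exp: ExperimentalPoints
) -> tuple[FreeEnergyProfile, float, np.ndarray]:
    """Vertically least-squares anchor the relative profile to experiment.

    Returns (absolute profile, fitted offset c, residuals at all points).
    The offset minimises Σ (ΔΔG(pH_k) + c − ΔG_exp,k)² over non-bound
    points; upper-bound points contribute residuals but not to the fit.
    """
    usable = ~exp.is_upper_bound
    if not usable.any():
        raise ValueError("no non-bound experimental points to anchor to")
    model = np.interp(exp.pH, profile.pH_grid, profile.ddG)
    c = float(np.mean(exp.dG[usable] - model[usable]))
    residuals = model + c - exp.dG
    shifted = FreeEnergyProfile(
        pH_grid=profile.pH_grid,
        ddG=profile.ddG + c,
        pH_ref=profile.pH_ref,
        temperature=profile.temperature,
        per_site=dict(profile.per_site),
        envelope=None
        if profile.envelope is None
        else (profile.envelope[0] + c, profile.envelope[1] + c),
        units=profile.units,
    )
    return shifted, c, residuals


# ---------------------------------------------------------------------------
# Bootstrap envelope
# ---------------------------------------------------------------------------

def _curve_from_pooled(
    pH_values: np.ndarray,
    site_labels: tuple[str, ...],
    pooled_per_ph: list[np.ndarray],
    form: str,
) -> TitrationCurve:
    from .titration import TitrationPoint

    pts = []
    for ph, pooled in zip(pH_values, pooled_per_ph):
        n_mean, n_var, site_means, cov = _moments(pooled)
        pts.append(
            TitrationPoint(
                pH=float(ph),
                site_labels=site_labels,
                n_mean=n_mean,
                n_var=n_var,
                site_means=site_means,
                site_cov_total=cov,
                n_frames_used=pooled.shape[0],
            )
        )
    return TitrationCurve(form=form, points=pts)


def profile_bootstrap_envelope(
    systems: SystemSet,
    pH_ref: float | None = None,
    temperature: float | None = None,
    *,
    B: int = 100,
    seed: int,
    block_ps: float = 1000.0,
    percentiles: tuple[float, float] = (2.5, 97.5),
    grid_step: float = 0.01,
) -> FreeEnergyProfile:
    """ΔΔG profile with a bootstrap envelope from raw occupancy data.

    The whole spline pipeline (moments → thermodynamic slopes → Hermite
    splines → closed-form integral) is recomputed for each of B two-level
    (replicate, block) resamples; the envelope is the pointwise percentile
    band across resamples. The central profile uses the unresampled data.
    """
    if B < 50:
        raise ValueError("B must be >= 50")
    if temperature is None:
        temperature = systems.temperature
    phs = np.asarray(systems.pH_values, dtype=float)
    cells = {
        form: [systems.select(form, ph) for ph in phs]
        for form in ("monomer", "dimer")
    }
    from .titration import build_titration_curve

    curve_M = build_titration_curve(cells["monomer"])
    curve_D = build_titration_curve(cells["dimer"])
    central = ddG_profile(
        curve_M, curve_D, pH_ref, temperature, grid_step=grid_step, decompose=False
    )

    rng = np.random.default_rng(seed)
    samples = np.empty((B, central.pH_grid.size))
    for b in range(B):
        resampled = {}
        for form in ("monomer", "dimer"):
            pooled_per_ph = []
            for reps in cells[form]:
                n_rep = len(reps)
                chosen = (
                    reps
                    if n_rep == 1
                    else [reps[k] for k in rng.integers(0, n_rep, size=n_rep)]
                )
                pooled_per_ph.append(
                    np.vstack(
                        [_resample_trajectory(t, block_ps, rng) for t in chosen]
                    )
                )
            resampled[form] = _curve_from_pooled(
                phs, reps[0].site_labels, pooled_per_ph, form
            )
        prof_b = ddG_profile(
            resampled["monomer"],
            resampled["dimer"],
            central.pH_ref,
            temperature,
            grid_step=grid_step,
            decompose=False,
        )
        samples[b] = prof_b.ddG
    lower = np.percentile(samples, percentiles[0], axis=0)
    upper = np.percentile(samples, percentiles[1], axis=0)
    central.envelope = (np.minimum(lower, central.ddG), np.maximum(upper, central.ddG))
    return central
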