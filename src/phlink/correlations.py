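"""Proton-occupancy correlations, networks, and exchange kinetics.

Pairwise Pearson coefficients between binary occupancy series detect
electrostatic coupling between titratable sites: direct repulsion between
like charges typically shows up as negative correlation, while positive
correlation between two sites usually signals mediation through a third.
Correlation networks threshold |ρ|; autocorrelation functions of the
occupancy series measure proton-exchange kinetics, summarised as the first
lag at which the ACF drops below a threshold (default 0.1).

Zero-variance sites (fully (de)protonated at that pH) are flagged invalid
rather than set to zero, so networks cannot contain spurious null edges.
ACFs are computed on the longest contiguous retained stretches only —
dissociation masking would otherwise splice distant frames together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .occupancy import OccupancyTrajectory, SystemSet
from .titration import compute_titration_point

__all__ = [
    "CorrelationMatrix",
    "CorrelationTimeTable",
    "pearson_matrix",
    "correlation_network",
    "occupancy_acf",
    "correlation_time",
    "site_summary_scatter",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix with per-entry validity flags."""

    site_labels: tuple[str, ...]
    rho: np.ndarray  # (M, M), NaN where invalid
    valid: np.ndarray  # (M, M) bool
    pH: float
    form: str

    def get(self, i_label: str, j_label: str) -> float:
        i = self.site_labels.index(i_label)
        j = self.site_labels.index(j_label)
        return float(self.rho[i, j])


def pearson_matrix(
    trajs: Sequence[OccupancyTrajectory] | OccupancyTrajectory,
) -> CorrelationMatrix:
    """ρ_ij = cov(n_i, n_j) / sqrt(var(n_i) var(n_j)) over pooled frames."""
    if isinstance(trajs, OccupancyTrajectory):
        trajs = [trajs]
    labels = trajs[0].site_labels
    if len(labels) < 2:
        raise ValueError("at least 2 sites required")
    pooled = np.vstack([t.retained() for t in trajs])
    if pooled.shape[0] == 0:
        raise ValueError("zero retained frames")
    centered = pooled - pooled.mean(axis=0)
    cov = centered.T @ centered / pooled.shape[0]
    var = np.diag(cov)
    ok = var > 0
    valid = np.outer(ok, ok)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        rho = np.where(valid, cov / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(rho, np.where(ok, 1.0, np.nan))
    rho = np.clip(rho, -1.0, 1.0)  # guard round-off past ±1
    return CorrelationMatrix(
        site_labels=labels,
        rho=rho,
        valid=valid,
        pH=trajs[0].pH,
        form=trajs[0].form,
    )


def correlation_network(
    m: CorrelationMatrix, cutoff: float = 0.15
) -> list[tuple[str, str, float]]:
    """Undirected edges (i, j, ρ) with |ρ| ≥ cutoff, sorted by |ρ| desc."""
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    edges = []
    M = len(m.site_labels)
    for i in range(M):
        for j in range(i + 1, M):
            if m.valid[i, j] and abs(m.rho[i, j]) >= cutoff:
                edges.append((m.site_labels[i], m.site_labels[j], float(m.rho[i, j])))
    edges.sort(key=lambda e: abs(e[2]), reverse=True)
    return edges


def occupancy_acf(
    trajs: Sequence[OccupancyTrajectory] | OccupancyTrajectory,
    site: str,
    max_lag_ps: float,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Normalised occupancy autocorrelation for one site.

    Computed per replicate on its longest contiguous retained stretch, then
    averaged across replicates with frame-count weights. Returns
    (lag_times_ps, acf) or None when every stretch has zero variance.
    """
    if isinstance(trajs, OccupancyTrajectory):
        trajs = [trajs]
    idx_site = trajs[0].site_labels.index(site)
    curves = []
    weights = []
    dt = None
    for t in trajs:
        stretches = t.contiguous_retained_stretches()
        if not stretches:
            continue
        longest = max(stretches, key=len)
        x = t.occupancies[longest, idx_site].astype(float)
        if t.n_frames > 1:
            dt_t = float(np.median(np.diff(t.times)))
        else:
            dt_t = 1.0
        dt = dt_t if dt is None else dt
        n_lags = min(len(x) - 1, int(max_lag_ps / dt_t))
        if n_lags < 1:
            continue
        mu = x.mean()
        var = np.mean((x - mu) ** 2)
        if var == 0:
            continue
        xc = x - mu
        # lag-count-normalised (1/(N-k)) autocovariance via FFT, so a
        # strictly alternating series yields ACF(1) = -1 exactly
        n = len(xc)
        f = np.fft.rfft(xc, 2 * n)
        acov = np.fft.irfft(f * np.conj(f))[: n_lags + 1]
        acov /= n - np.arange(n_lags + 1)
        curves.append(acov / acov[0])
        weights.append(n)
    if not curves:
        return None
    n_lags = min(len(c) for c in curves)
    w = np.asarray(weights, dtype=float)
    acf = np.average([c[:n_lags] for c in curves], axis=0, weights=w)
    lags = dt * np.arange(n_lags)
    return lags, acf


def correlation_time(
    lags: np.ndarray, acf: np.ndarray, threshold: float = 0.1
) -> tuple[float, bool]:
    """First lag at which the ACF drops below the threshold.

    Returns (tau_ps, censored); censored=True when the ACF never crosses
    within the available lags, in which case tau is the last lag time.
    """
    below = np.flatnonzero(acf < threshold)
    if below.size == 0:
        return float(lags[-1]), True
    return float(lags[below[0]]), False


@dataclass
class CorrelationTimeTable:
    """Per-site correlation times at one (form, pH)."""

    site_labels: tuple[str, ...]
    tau_ps: np.ndarray
    censored: np.ndarray
    pH: float
    form: str
    threshold: float = 0.1


def correlation_times(
    trajs: Sequence[OccupancyTrajectory],
    *,
    max_lag_ps: float,
    threshold: float = 0.1,
) -> CorrelationTimeTable:
    """Correlation time per site (NaN where the ACF is undefined)."""
    trajs = [trajs] if isinstance(trajs, OccupancyTrajectory) else list(trajs)
    labels = trajs[0].site_labels
    tau = np.full(len(labels), np.nan)
    cens = np.zeros(len(labels), dtype=bool)
    for k, lab in enumerate(labels):
        res = occupancy_acf(trajs, lab, max_lag_ps)
        if res is None:
            cens[k] = True
            continue
        tau[k], cens[k] = correlation_time(*res, threshold=threshold)
    return CorrelationTimeTable(
        site_labels=labels,
        tau_ps=tau,
        censored=cens,
        pH=trajs[0].pH,
        form=trajs[0].form,
        threshold=threshold,
    )


def site_summary_scatter(
    systems: SystemSet,
    *,
    max_lag_ps: float = 10_000.0,
    acf_threshold: float = 0.1,
):
    """Per (monomer site, pH) summary joining coupling, kinetics and shift.

    Columns: max |ρ| over valid partners (dimer matrix, chain-A label),
    the standard deviation and mean of the signed ρ over partners, the
    correlation time τ, and the absolute monomer→dimer protonation shift
    |n̄_i^D(per-chain mean) − n̄_i^M|. Returns a pandas DataFrame.
    """
    import pandas as pd

    from .linkage import pair_sites
    from .titration import build_titration_curve

    phs = systems.pH_values
    rows = []
    for ph in phs:
        try:
            mono = systems.select("monomer", ph)
            dim = systems.select("dimer", ph)
        except KeyError:
            warnings.warn(f"missing form at pH {ph}; row omitted", stacklevel=2)
            continue
        pt_m = compute_titration_point(mono)
        pt_d = compute_titration_point(dim)
        mat = pearson_matrix(dim)
        taus = correlation_times(
            dim, max_lag_ps=max_lag_ps, threshold=acf_threshold
        )
        curve_m = build_titration_curve([mono])
        curve_d = build_titration_curve([dim])
        pairing = pair_sites(curve_m, curve_d)
        for mono_label, (lab_a, lab_b) in pairing.items():
            i = mat.site_labels.index(lab_a)
            partners = [
                mat.rho[i, j]
                for j in range(len(mat.site_labels))
                if j != i and mat.valid[i, j]
            ]
            max_rho = max((abs(r) for r in partners), default=np.nan)
            mean_rho = float(np.mean(partners)) if partners else np.nan
            sd_rho = float(np.std(partners)) if partners else np.nan
            mi = pt_m.site_means[pt_m.site_index(mono_label)]
            da = pt_d.site_means[pt_d.site_index(lab_a)]
            db = pt_d.site_means[pt_d.site_index(lab_b)]
            shift = abs(0.5 * (da + db) - mi)
            k = taus.site_labels.index(lab_a)
            rows.append(
                {
                    "site": mono_label,
                    "pH": ph,
                    "max_abs_rho": max_rho,
                    "mean_rho": mean_rho,
                    "sd_rho": sd_rho,
                    "tau_ps": taus.tau_ps[k],
                    "tau_censored": bool(taus.censored[k]),
                    "abs_protonation_shift": shift,
                }
            )
    return pd.DataFrame(rows)
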