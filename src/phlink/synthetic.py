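"""Exactly solvable multi-site titration models and synthetic data generators.

The heart of the test strategy: a coupled-site titration Hamiltonian whose
semi-grand (binding-polynomial) thermodynamics can be computed exactly by
microstate enumeration, a Metropolis sampler producing occupancy
trajectories with that exact stationary distribution, and rigid-body /
ion-cloud generators with known geometric structure. Every downstream
pipeline stage is validated against these oracles.

Model
-----
A system of M titratable sites, each protonated (s_i = 1) or not (s_i = 0).
The statistical weight of microstate s at a given pH is

    ln w(s) = sum_i s_i ln10 (pKa_i - pH)  -  beta * sum_{i<j} W_ij s_i s_j

where pKa_i is the intrinsic pKa of site i and W_ij (kJ/mol, symmetric) is
a pairwise coupling paid when *both* members of the pair are protonated
(one standard convention of the pairwise titration Hamiltonian; any
consistent convention serves the oracle role). The binding polynomial is
Xi(pH) = sum_s w(s), and -RT ln Xi is the proton-linked free energy.

A dimer model is two chain copies of a monomer model plus an interchain
coupling block; the exact relative dimerization free energy follows from
the binding polynomials alone, giving an independent target for the
spline-linkage route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, LN10, rt
from .occupancy import (
    DIMER,
    MONOMER,
    OccupancyTrajectory,
    SiteDefinition,
)

__all__ = [
    "TitrationModelSpec",
    "ExactTitrationResult",
    "dimerize",
    "demo_study_specs",
    "enumerate_exact",
    "exact_ddG",
    "oracle_model_pairs",
    "titration_curve_from_exact",
    "sample_occupancies",
    "generate_ion_cloud",
    "generate_dimer_ensemble",
    "helix_backbone_template",
]

_MAX_ENUMERABLE_SITES = 20


def demo_study_specs() -> tuple["TitrationModelSpec", "TitrationModelSpec"]:
    """The shipped synthetic study: a 4-site monomer and its dimer.

    Three acids and one base with intrinsic pKas spread over the 3–8
    window, mixed intrachain couplings, and a repulsive interchain
    coupling concentrated on the interface acid (GLU45↔GLU45), which is
    what makes the dimer's titration — and hence the linkage free
    energy — pH dependent.
    """
    sites = (
        SiteDefinition("ASP33", "acid"),
        SiteDefinition("GLU45", "acid"),
        SiteDefinition("HIS146", "base"),
        SiteDefinition("CTER", "acid"),
    )
    pkas = (4.0, 4.8, 6.5, 3.4)
    W = np.array(
        [
            [0.0, 2.5, -1.5, 0.0],
            [2.5, 0.0, 0.0, 1.0],
            [-1.5, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
        ]
    )
    monomer = TitrationModelSpec(sites=sites, pkas=pkas, coupling=W)
    inter = np.zeros((4, 4))
    inter[1, 1] = 6.0  # interface GLU45 pair
    inter[0, 1] = inter[1, 0] = 1.5
    dimer = dimerize(monomer, inter)
    return monomer, dimer


@dataclass(frozen=True)
class TitrationModelSpec:
    """A coupled-site titration model.

    Parameters
    ----------
    sites:
        Site definitions (labels + acid/base kind).
    pkas:
        Intrinsic pKa per site.
    coupling:
        Symmetric (M, M) matrix W in kJ/mol, zero diagonal; W_ij is added
        to the microstate energy when sites i and j are both protonated.
    temperature:
        K.
    form:
        ``"monomer"`` or ``"dimer"`` tag.
    association_offset:
        pH-independent free-energy offset (kJ/mol) carried by dimer specs;
        it cancels in relative free energies and exists only to document
        that the oracle fixes shapes, not absolute binding constants.
    """

    sites: tuple[SiteDefinition, ...]
    pkas: tuple[float, ...]
    coupling: np.ndarray = field(default=None)  # type: ignore[assignment]
    temperature: float = DEFAULT_TEMPERATURE
    form: str = MONOMER
    association_offset: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "pkas", tuple(float(p) for p in self.pkas))
        M = len(self.sites)
        if len(self.pkas) != M:
            raise ValueError("one intrinsic pKa per site required")
        W = self.coupling
        W = np.zeros((M, M)) if W is None else np.array(W, dtype=float)
        if W.shape != (M, M):
            raise ValueError(f"coupling must be ({M},{M})")
        if not np.allclose(W, W.T):
            raise ValueError("coupling matrix must be symmetric")
        if not np.allclose(np.diag(W), 0.0):
            raise ValueError("coupling diagonal must be zero")
        object.__setattr__(self, "coupling", W)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def dimerize(
    monomer: TitrationModelSpec,
    interchain: np.ndarray | None = None,
    *,
    pka_shifts: Sequence[float] | None = None,
    association_offset: float = 0.0,
) -> TitrationModelSpec:
    """Build a homodimer spec from a monomer spec.

    Sites are duplicated as chains A and B (labels prefixed ``A:``/``B:``,
    any existing chain prefix replaced). Intrachain couplings are copied
    into each diagonal block; ``interchain`` (M, M) fills the off-diagonal
    block, W[A_i, B_j] = interchain[i, j]. ``pka_shifts`` optionally shifts
    both chains' intrinsic pKas, emulating association-induced pKa changes.
    """
    M = monomer.n_sites
    inter = np.zeros((M, M)) if interchain is None else np.asarray(interchain, float)
    if inter.shape != (M, M):
        raise ValueError(f"interchain block must be ({M},{M})")
    shifts = np.zeros(M) if pka_shifts is None else np.asarray(pka_shifts, float)
    sites = []
    for chain in ("A", "B"):
        for s in monomer.sites:
            sites.append(SiteDefinition(f"{chain}:{s.base_label}", s.residue_kind))
    pkas = np.concatenate([np.array(monomer.pkas) + shifts] * 2)
    W = np.zeros((2 * M, 2 * M))
    W[:M, :M] = monomer.coupling
    W[M:, M:] = monomer.coupling
    W[:M, M:] = inter
    W[M:, :M] = inter.T
    return TitrationModelSpec(
        sites=tuple(sites),
        pkas=tuple(pkas),
        coupling=W,
        temperature=monomer.temperature,
        form=DIMER,
        association_offset=association_offset,
    )


def oracle_model_pairs() -> list[tuple["TitrationModelSpec", "TitrationModelSpec"]]:
    """Three enumerable monomer/dimer pairs with mixed couplings.

    The benchmark set for the linkage pipeline: a 4-site mixed acid/base
    monomer with a strong interface coupling (the shipped demo), a 5-site
    chain with alternating couplings and association-induced pKa shifts,
    and a 4-site acid cluster with dense intrachain repulsion and a weaker
    spread-out interchain block. Dimers have 8–10 sites, all enumerable.
    """
    pairs = [demo_study_specs()]

    sites5 = (
        SiteDefinition("ASP11", "acid"),
        SiteDefinition("GLU44", "acid"),
        SiteDefinition("HIS161", "base"),
        SiteDefinition("GLU74", "acid"),
        SiteDefinition("NTER", "base"),
    )
    W5 = np.zeros((5, 5))
    for i, j, w in [(0, 1, 3.0), (1, 2, -2.0), (2, 3, -1.5), (3, 4, 2.0)]:
        W5[i, j] = W5[j, i] = w
    m5 = TitrationModelSpec(sites=sites5, pkas=(3.6, 4.4, 6.2, 5.0, 7.2), coupling=W5)
    inter5 = np.zeros((5, 5))
    inter5[1, 1] = 4.0
    inter5[3, 3] = 2.5
    inter5[1, 3] = inter5[3, 1] = 1.0
    pairs.append((m5, dimerize(m5, inter5, pka_shifts=[0.0, -0.3, 0.2, 0.0, 0.0])))

    sites4 = tuple(
        SiteDefinition(lab, "acid") for lab in ("ASP28", "ASP33", "GLU51", "GLU62")
    )
    W4 = np.full((4, 4), 1.2)
    np.fill_diagonal(W4, 0.0)
    m4 = TitrationModelSpec(sites=sites4, pkas=(3.4, 4.1, 4.7, 5.3), coupling=W4)
    inter4 = np.full((4, 4), 0.8)
    pairs.append((m4, dimerize(m4, inter4)))
    return pairs


@dataclass
class ExactTitrationResult:
    """Exact per-pH moments of a titration model (enumeration)."""

    pH_values: np.ndarray  # (P,)
    ln_xi: np.ndarray  # (P,) log binding polynomial
    n_mean: np.ndarray  # (P,)
    n_var: np.ndarray  # (P,)
    site_means: np.ndarray  # (P, M)
    cov_site_total: np.ndarray  # (P, M)  cov(n_i, n)
    cov_pair: np.ndarray  # (P, M, M)  cov(n_i, n_j)
    spec: TitrationModelSpec


def _microstates(M: int) -> np.ndarray:
    """(2^M, M) array of all binary occupancy vectors."""
    states = np.arange(2**M, dtype=np.int64)
    return ((states[:, None] >> np.arange(M)) & 1).astype(float)


def enumerate_exact(
    spec: TitrationModelSpec, pH_values: Sequence[float]
) -> ExactTitrationResult:
    """Exact moments by summation over all 2^M protonation microstates.

    Uses log-sum-exp stabilisation; guarded at 20 sites (≈10^6 states).
    """
    M = spec.n_sites
    if M > _MAX_ENUMERABLE_SITES:
        raise ValueError(f"{M} sites exceeds the enumerability guard "
                         f"({_MAX_ENUMERABLE_SITES})")
    pH_values = np.asarray(pH_values, dtype=float)
    S = _microstates(M)  # (K, M)
    beta = 1.0 / rt(spec.temperature)
    pair_energy = 0.5 * np.einsum("ki,ij,kj->k", S, spec.coupling, S)
    pka = np.asarray(spec.pkas)

    P = len(pH_values)
    ln_xi = np.empty(P)
    n_mean = np.empty(P)
    n_var = np.empty(P)
    site_means = np.empty((P, M))
    cov_tot = np.empty((P, M))
    cov_pair = np.empty((P, M, M))
    n_tot = S.sum(axis=1)

    for a, ph in enumerate(pH_values):
        ln_w = S @ (LN10 * (pka - ph)) - beta * pair_energy
        ln_xi[a] = logsumexp(ln_w)
        p = np.exp(ln_w - ln_xi[a])  # normalized microstate probabilities
        mi = p @ S
        site_means[a] = mi
        n_mean[a] = mi.sum()
        second = (S * p[:, None]).T @ S  # E[n_i n_j]
        cp = second - np.outer(mi, mi)
        cov_pair[a] = cp
        cov_tot[a] = cp.sum(axis=1)
        n_var[a] = float(p @ n_tot**2 - n_mean[a] ** 2)

    return ExactTitrationResult(
        pH_values=pH_values,
        ln_xi=ln_xi,
        n_mean=n_mean,
        n_var=n_var,
        site_means=site_means,
        cov_site_total=cov_tot,
        cov_pair=cov_pair,
        spec=spec,
    )


def titration_curve_from_exact(result: ExactTitrationResult):
    """Bridge an exact enumeration result into the pipeline's curve type.

    The resulting :class:`~phlink.titration.TitrationCurve` carries the
    exact moments, so the spline pipeline runs on noise-free input — the
    configuration in which it must reproduce the binding-polynomial free
    energy.
    """
    from .titration import TitrationCurve, TitrationPoint

    labels = tuple(s.label for s in result.spec.sites)
    pts = [
        TitrationPoint(
            pH=float(ph),
            site_labels=labels,
            n_mean=float(result.n_mean[a]),
            n_var=float(result.n_var[a]),
            site_means=result.site_means[a],
            site_cov_total=result.cov_site_total[a],
            n_frames_used=0,
        )
        for a, ph in enumerate(result.pH_values)
    ]
    return TitrationCurve(form=result.spec.form, points=pts)


def exact_ddG(
    spec_M: TitrationModelSpec,
    spec_D: TitrationModelSpec,
    pH,
    pH_ref: float,
    temperature: float | None = None,
) -> np.ndarray | float:
    """Exact relative dimerization free energy, kJ/mol.

    ΔΔG(pH) = −RT { [lnΞ_D − 2 lnΞ_M](pH) − [lnΞ_D − 2 lnΞ_M](pH_ref) }.

    pH-independent association offsets cancel by construction.
    """
    if spec_D.n_sites != 2 * spec_M.n_sites:
        raise ValueError("dimer must have two copies of the monomer's sites")
    T = temperature if temperature is not None else spec_M.temperature
    scalar = np.isscalar(pH)
    ph = np.atleast_1d(np.asarray(pH, dtype=float))
    grid = np.append(ph, pH_ref)
    lx_m = enumerate_exact(spec_M, grid).ln_xi
    lx_d = enumerate_exact(spec_D, grid).ln_xi
    g = -(rt(T)) * (lx_d - 2.0 * lx_m)
    ddg = g[:-1] - g[-1]
    return float(ddg[0]) if scalar else ddg


def sample_occupancies(
    spec: TitrationModelSpec,
    pH: float,
    n_steps: int,
    *,
    record_every: int = 10,
    seed: int,
    replicate_id: str = "r1",
    dt_ps: float = 1.0,
    flip_attempt_weights: Sequence[float] | None = None,
    burn_in: int = 0,
) -> OccupancyTrajectory:
    """Metropolis single-site-flip sampler of the model's microstates.

    Each step proposes flipping one site (chosen with the given attempt
    weights — unequal weights create designed slow-exchanging sites) and
    accepts with min(1, w_new/w_old). The recorded series has the model's
    exact stationary distribution asymptotically. One step advances the
    nominal clock by ``dt_ps``.
    """
    if n_steps < 1_000:
        raise ValueError("n_steps must be >= 1000")
    M = spec.n_sites
    rng = np.random.default_rng(seed)
    if flip_attempt_weights is None:
        site_p = np.full(M, 1.0 / M)
    else:
        w = np.asarray(flip_attempt_weights, dtype=float)
        if w.shape != (M,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("flip_attempt_weights must be M non-negative values")
        site_p = w / w.sum()

    beta = 1.0 / rt(spec.temperature)
    # ln-weight change for protonating site i given current state s:
    #   ln10*(pKa_i - pH) - beta * sum_j W_ij s_j
    field_const = LN10 * (np.asarray(spec.pkas) - pH)
    W = spec.coupling

    total = burn_in + n_steps
    pick = rng.choice(M, size=total, p=site_p)
    log_u = np.log(rng.random(total))

    s = (rng.random(M) < 0.5).astype(np.int8)
    local = W @ s  # maintained incrementally
    n_rec = n_steps // record_every
    rec = np.empty((n_rec, M), dtype=np.uint8)
    r = 0
    fc = field_const.tolist()
    for t in range(total):
        i = pick[t]
        si = s[i]
        delta = fc[i] - beta * local[i]  # ln-weight gain of protonating i
        if si:
            delta = -delta
        if delta >= 0.0 or log_u[t] < delta:
            new = 1 - si
            s[i] = new
            sign = 1.0 if new else -1.0
            local += sign * W[i]
        if t >= burn_in and (t - burn_in) % record_every == record_every - 1:
            rec[r] = s
            r += 1
    times = dt_ps * record_every * (np.arange(n_rec) + 1.0)
    return OccupancyTrajectory(
        sites=spec.sites,
        times=times,
        occupancies=rec,
        pH=pH,
        replicate_id=replicate_id,
        form=spec.form,
    )


# ---------------------------------------------------------------------------
# Ion-cloud generator (fixtures for the ionic-density stage)
# ---------------------------------------------------------------------------

def generate_ion_cloud(
    density_spec: dict,
    n_ions: int,
    n_frames: int,
    box: Sequence[float],
    *,
    seed: int,
) -> np.ndarray:
    """iid ion positions per frame from a specified density.

    ``density_spec`` is one of
      {"kind": "uniform"}
      {"kind": "gaussian_mixture", "means": (k,3), "sigmas": (k,), "weights": (k,)}
      {"kind": "boltzmann", "phi": callable(r)->V, "z": int, "temperature": K}
    The Boltzmann spec is drawn by rejection sampling against the uniform
    envelope, so the empirical density follows exp(-z F phi / RT) within
    the box. Returns an (n_frames, n_ions, 3) array in Å.
    """
    from .constants import FARADAY

    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    kind = density_spec["kind"]
    shape = (n_frames, n_ions, 3)
    if kind == "uniform":
        return rng.random(shape) * box
    if kind == "gaussian_mixture":
        means = np.asarray(density_spec["means"], float)
        sigmas = np.asarray(density_spec["sigmas"], float)
        weights = np.asarray(density_spec["weights"], float)
        weights = weights / weights.sum()
        comp = rng.choice(len(weights), size=(n_frames, n_ions), p=weights)
        out = means[comp] + rng.normal(size=shape) * sigmas[comp][..., None]
        return out
    if kind == "boltzmann":
        phi = density_spec["phi"]
        z = float(density_spec["z"])
        T = float(density_spec.get("temperature", DEFAULT_TEMPERATURE))
        # exponent: -z F phi / (R T), phi in V, F in C/mol, R T in J/mol
        beta_e = z * FARADAY / (rt(T) * 1000.0)

        def log_w(r):
            return -beta_e * phi(r)

        # bound the acceptance ratio by scanning a coarse lattice
        probe = np.stack(
            np.meshgrid(*[np.linspace(0, b, 25) for b in box], indexing="ij"), -1
        ).reshape(-1, 3)
        lw_max = float(np.max(log_w(probe)))
        out = np.empty(shape)
        need = n_frames * n_ions
        got = 0
        flat = out.reshape(-1, 3)
        while got < need:
            m = max(2 * (need - got), 1024)
            cand = rng.random((m, 3)) * box
            acc = np.log(rng.random(m)) < (log_w(cand) - lw_max)
            take = cand[acc][: need - got]
            flat[got : got + len(take)] = take
            got += len(take)
        return out
    raise ValueError(f"unknown density spec kind {kind!r}")


# ---------------------------------------------------------------------------
# Rigid-body dimer ensemble generator (fixtures for the structural stage)
# ---------------------------------------------------------------------------

def helix_backbone_template(
    n_residues: int = 10, rise: float = 0.15, radius: float = 0.23
) -> tuple[np.ndarray, list[tuple[str, str, int]]]:
    """An idealised helix-like backbone trace (N, CA, C per residue), nm.

    Returns coordinates (3*n_residues, 3) and per-atom metadata
    (name, resname, resid). Purely geometric — a stand-in chain used by
    the synthetic dimer ensembles.
    """
    coords = []
    meta = []
    per_res_twist = np.deg2rad(100.0)
    for r in range(n_residues):
        base = r * per_res_twist
        for k, name in enumerate(("N", "CA", "C")):
            ang = base + k * per_res_twist / 3.0
            z = (r + k / 3.0) * rise
            coords.append(
                [radius * np.cos(ang), radius * np.sin(ang), z]
            )
            meta.append((name, "ALA", r + 1))
    return np.asarray(coords), meta


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(axis * angle_rad).as_matrix()


def generate_dimer_ensemble(
    *,
    angles_deg: Sequence[float],
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    translation: Sequence[float] = (1.5, 0.0, 0.0),
    extra_translations: Sequence[Sequence[float]] | None = None,
    noise_sigma: float = 0.0,
    n_residues: int = 10,
    seed: int = 0,
):
    """Rigid-motion dimer ensemble: chain A fixed, chain B transformed.

    Frame f places chain B at ``translation`` (nm) rotated about ``axis``
    by ``angles_deg[f]`` (about the chain-B centroid), plus an optional
    per-frame extra translation and isotropic Gaussian coordinate noise.
    Returns a :class:`phlink.conformation.ConformationEnsemble`.
    """
    from .conformation import AtomRecord, ConformationEnsemble

    coords_a, meta = helix_backbone_template(n_residues)
    rng = np.random.default_rng(seed)
    n_frames = len(angles_deg)
    extra = (
        np.zeros((n_frames, 3))
        if extra_translations is None
        else np.asarray(extra_translations, float)
    )
    atoms = [
        AtomRecord(name=n, resname=rn, resid=ri, chain="A") for n, rn, ri in meta
    ] + [
        AtomRecord(name=n, resname=rn, resid=ri, chain="B") for n, rn, ri in meta
    ]
    centroid = coords_a.mean(axis=0)
    frames = np.empty((n_frames, 2 * len(coords_a), 3))
    for f, ang in enumerate(angles_deg):
        R = _rotation_matrix(np.asarray(axis, float), np.deg2rad(ang))
        b = (coords_a - centroid) @ R.T + centroid
        b = b + np.asarray(translation, float) + extra[f]
        frame = np.vstack([coords_a, b])
        if noise_sigma > 0:
            frame = frame + rng.normal(scale=noise_sigma, size=frame.shape)
        frames[f] = frame
    return ConformationEnsemble(atoms=atoms, frames=frames)
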