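"""Ionic concentration fingerprints around a protein.

Two complementary routes to a 3-D ion concentration map:

* a Gaussian kernel density estimate of ion positions accumulated over
  trajectory frames (after rigid-body fitting of the protein onto a common
  reference structure), converted to mM on a regular grid; and
* the Boltzmann relation c_k(r) = c_bulk exp(−z_k F φ(r) / RT) applied to
  an electrostatic potential grid produced by an external
  Poisson–Boltzmann solver.

Comparing the two maps probes how far the mean-field PB picture tracks
the explicitly sampled ion atmosphere. Grids are exchanged in the OpenDX
scalar format (via gridDataFormats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, FARADAY, N_AVOGADRO, rt
from .conformation import superpose
from .occupancy import OccupancyTrajectory

__all__ = [
    "IonDensityGrid",
    "PotentialGrid",
    "GridSpec",
    "fit_frames_to_reference",
    "kde_concentration",
    "boltzmann_concentration",
    "iso_contour_mask",
    "average_charge_assignment",
    "read_dx_potential",
    "write_dx",
    "read_ion_track",
    "write_ion_track",
]

#: mM per (ions / Å³): mol/L = ρ·10²⁷/N_A, mM = ×10³
_MM_PER_PER_A3 = 1.0e30 / N_AVOGADRO


@dataclass(frozen=True)
class GridSpec:
    """Regular orthogonal grid: point (i,j,k) at origin + (i,j,k)·spacing."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(
            o[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        )

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3


@dataclass
class IonDensityGrid:
    """Concentration grid (mM) for one ion species."""

    grid: GridSpec
    values: np.ndarray  # (nx, ny, nz), mM
    species: str
    n_frames: int
    n_ions: int
    bandwidth: float  # Å

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape must match the grid")
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    def total_ions(self) -> float:
        """Ion count implied by the grid (should conserve the input count)."""
        return float(
            self.values.sum() * self.grid.voxel_volume / _MM_PER_PER_A3
        )


@dataclass
class PotentialGrid:
    """Electrostatic potential grid (V) with Boltzmann-map metadata."""

    grid: GridSpec
    values: np.ndarray  # V
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape must match the grid")
        if not np.isfinite(self.values).all():
            raise ValueError("potential values must be finite")


# ---------------------------------------------------------------------------
# Frame fitting
# ---------------------------------------------------------------------------

def fit_frames_to_reference(
    protein_frames: np.ndarray,
    ion_frames: np.ndarray,
    reference: np.ndarray,
    *,
    weights: np.ndarray | None = None,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """Transform per-frame ion positions into the reference protein frame.

    For every frame the least-squares rigid transform (rotation +
    translation, no scaling) of the protein selection onto ``reference``
    is applied to that frame's ion positions. With an orthorhombic ``box``
    (per frame or constant), each ion is first moved to its minimum-image
    position relative to the protein centroid, resolving the periodic
    ambiguity before fitting. Shapes: protein (F, P, 3), ions (F, I, 3),
    reference (P, 3); any length unit, as long as it is consistent.
    """
    protein_frames = np.asarray(protein_frames, float)
    ion_frames = np.asarray(ion_frames, float)
    if protein_frames.shape[0] != ion_frames.shape[0]:
        raise ValueError("protein and ion tracks must have equal frame counts")
    if protein_frames.shape[1:] != np.asarray(reference, float).shape:
        raise ValueError("reference does not match the protein selection")
    out = np.empty_like(ion_frames)
    for f in range(protein_frames.shape[0]):
        ions = ion_frames[f]
        if box is not None:
            L = np.asarray(box, float)
            L = L[f] if L.ndim == 2 else L
            center = protein_frames[f].mean(axis=0)
            ions = ions - L * np.round((ions - center) / L)
        R, t = superpose(protein_frames[f], reference, weights)
        out[f] = ions @ R.T + t
    return out


# ---------------------------------------------------------------------------
# KDE concentration grids
# ---------------------------------------------------------------------------

def kde_concentration(
    ion_frames: np.ndarray,
    grid: GridSpec,
    *,
    bandwidth: float = 2.0,
    species: str = "ion",
    truncation_sigmas: float = 4.0,
) -> IonDensityGrid:
    """Gaussian-KDE ion concentration grid, mM.

    The per-frame number density (Å⁻³) is the sum of isotropic Gaussians
    of width ``bandwidth`` (Å) centred on each ion, averaged over frames
    and converted to mM. Kernels are truncated at ``truncation_sigmas``·σ
    (mass loss ≪ the 1% conservation tolerance). Ions are positions in Å,
    shaped (n_frames, n_ions, 3) or (n_ions, 3) for a single frame.
    """
    ions = np.asarray(ion_frames, float)
    if ions.ndim == 2:
        ions = ions[None]
    n_frames, n_ions = ions.shape[0], ions.shape[1]
    values = np.zeros(grid.shape)
    if n_ions > 0:
        ax = grid.axes()
        sig = bandwidth
        reach = truncation_sigmas * sig
        norm = 1.0 / (sig * np.sqrt(2.0 * np.pi))
        flat = ions.reshape(-1, 3)
        for pos in flat:
            # separable Gaussian on the local patch only
            sl = []
            g1d = []
            ok = True
            for d in range(3):
                axis = ax[d]
                lo = np.searchsorted(axis, pos[d] - reach, side="left")
                hi = np.searchsorted(axis, pos[d] + reach, side="right")
                if hi <= lo:
                    ok = False
                    break
                sl.append(slice(lo, hi))
                u = (axis[lo:hi] - pos[d]) / sig
                g1d.append(norm * np.exp(-0.5 * u * u))
            if not ok:
                continue
            values[sl[0], sl[1], sl[2]] += (
                g1d[0][:, None, None] * g1d[1][None, :, None] * g1d[2][None, None, :]
            )
        values /= n_frames
    return IonDensityGrid(
        grid=grid,
        values=values * _MM_PER_PER_A3,
        species=species,
        n_frames=n_frames,
        n_ions=n_ions,
        bandwidth=bandwidth,
    )


def boltzmann_concentration(
    phi: PotentialGrid,
    z: int,
    c_bulk: float,
    *,
    species: str = "ion",
) -> IonDensityGrid:
    """Boltzmann-relation concentration map: c(r) = c_bulk e^{−zFφ(r)/RT} (mM)."""
    # RT in J/mol; φ in V; F in C/mol
    beta_e = z * FARADAY / (rt(phi.temperature) * 1000.0)
    values = c_bulk * np.exp(-beta_e * phi.values)
    return IonDensityGrid(
        grid=phi.grid,
        values=values,
        species=species,
        n_frames=0,
        n_ions=0,
        bandwidth=0.0,
    )


def iso_contour_mask(grid: IonDensityGrid, level: float = 200.0) -> np.ndarray:
    """Boolean mask of voxels with concentration ≥ level (mM)."""
    if level <= 0:
        raise ValueError("contour level must be positive")
    return grid.values >= level


# ---------------------------------------------------------------------------
# Average charges for downstream PB input
# ---------------------------------------------------------------------------

def average_charge_assignment(
    mean_occupancies: Mapping[str, float] | OccupancyTrajectory,
    charge_templates: Mapping[str, dict],
    base_charges: np.ndarray,
) -> np.ndarray:
    """Per-atom mean partial charges from mean site occupancies.

    ``charge_templates`` maps each site label to
    ``{"atoms": indices, "protonated": q_array, "deprotonated": q_array}``;
    titrating atoms get p·q_prot + (1−p)·q_deprot with p the site's mean
    occupancy, all other atoms keep their base charge. The result is the
    charge set the linear-response PB picture calls for on a single
    representative structure.
    """
    if isinstance(mean_occupancies, OccupancyTrajectory):
        occ = mean_occupancies.retained()
        mean_occupancies = dict(
            zip(mean_occupancies.site_labels, occ.mean(axis=0))
        )
    charges = np.array(base_charges, dtype=float)
    for label, p in mean_occupancies.items():
        try:
            tmpl = charge_templates[label]
        except KeyError:
            raise KeyError(f"no charge template for site {label!r}") from None
        idx = np.asarray(tmpl["atoms"], dtype=int)
        qp = np.asarray(tmpl["protonated"], dtype=float)
        qd = np.asarray(tmpl["deprotonated"], dtype=float)
        charges[idx] = p * qp + (1.0 - p) * qd
    return charges


# ---------------------------------------------------------------------------
# Ion-track TSV I/O (frame<TAB>x<TAB>y<TAB>z, Å, '#' comments)
# ---------------------------------------------------------------------------

def write_ion_track(frames: np.ndarray, path: str | Path) -> None:
    """Write per-frame ion positions (F, I, 3) in Å as a plain TSV."""
    frames = np.asarray(frames, float)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("frame\tx\ty\tz\n")
        for f in range(frames.shape[0]):
            for pos in frames[f]:
                fh.write(f"{f}\t{pos[0]:.6f}\t{pos[1]:.6f}\t{pos[2]:.6f}\n")


def read_ion_track(path: str | Path) -> np.ndarray:
    """Read a TSV ion track back into an (F, I, 3) array (Å)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    n_frames = int(df["frame"].max()) + 1
    groups = [
        df[df.frame == f][["x", "y", "z"]].to_numpy(float)
        for f in range(n_frames)
    ]
    counts = {g.shape[0] for g in groups}
    if len(counts) != 1:
        raise ValueError("unequal ion counts across frames")
    return np.stack(groups)


# ---------------------------------------------------------------------------
# OpenDX I/O (gridDataFormats)
# ---------------------------------------------------------------------------

def read_dx_potential(
    path: str | Path, temperature: float = DEFAULT_TEMPERATURE
) -> PotentialGrid:
    """Read an OpenDX scalar grid as an electrostatic potential (V)."""
    from gridData import Grid

    g = Grid(str(path))
    deltas = np.diag(np.atleast_2d(g.delta)) if np.ndim(g.delta) == 2 else np.asarray(g.delta)
    if not np.allclose(deltas, deltas[0]):
        raise ValueError("only cubic-voxel grids are supported")
    spec = GridSpec(
        origin=tuple(np.asarray(g.origin, float)),
        spacing=float(deltas[0]),
        shape=tuple(g.grid.shape),
    )
    return PotentialGrid(grid=spec, values=np.asarray(g.grid, float), temperature=temperature)


def write_dx(grid: IonDensityGrid | PotentialGrid, path: str | Path) -> None:
    """Write a grid (or a boolean contour mask cast to 0/1) as OpenDX."""
    from gridData import Grid

    spec = grid.grid
    ax = spec.axes()
    edges = [np.append(a - spec.spacing / 2, a[-1] + spec.spacing / 2) for a in ax]
    g = Grid(np.asarray(grid.values, float), edges=edges)
    g.export(str(path), file_format="dx")
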