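"""Structural analyses of association ensembles.

Covers the geometry side of the pipeline: center-of-mass separation and
dissociation filtering of dimer trajectories, Kabsch-superposed RMSD and
central structures, Shrake–Rupley solvent-accessible surface areas and the
contact area buried at a dimer interface, interface torsion angles,
decoupled-fit PCA (fitting atoms and analysed atoms disjoint, so the
components capture relative motion rather than overall tumbling), and
free-energy landscapes F = −k_B T ln(P / P_max) over the leading
principal components.

Coordinates are in nm throughout. Structure and trajectory files are read
through MDAnalysis (which reports Å; the adapter converts).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .constants import DEFAULT_TEMPERATURE, rt

__all__ = [
    "AtomRecord",
    "ConformationEnsemble",
    "PCAModel",
    "FreeEnergyLandscape",
    "load_ensemble",
    "write_ensemble_pdb",
    "default_radii",
    "select_atoms",
    "com_distance",
    "superpose",
    "rmsd",
    "dissociation_mask",
    "central_structure",
    "sasa",
    "contact_area",
    "interface_dihedral",
    "pca_decoupled",
    "landscape",
    "histogram_1d",
]

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45,
}

#: default van der Waals radii, nm (Bondi)
VDW_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180, "P": 0.180,
}

BACKBONE_NAMES = ("N", "CA", "C")


@dataclass(frozen=True)
class AtomRecord:
    name: str
    resname: str
    resid: int
    chain: str
    mass: float | None = None

    @property
    def element(self) -> str:
        head = re.sub(r"\d", "", self.name)[:1].upper()
        return head or "C"

    def mass_or_guess(self) -> float:
        if self.mass is not None:
            return self.mass
        return _ELEMENT_MASSES.get(self.element, 12.011)


@dataclass
class ConformationEnsemble:
    """Atom metadata plus per-frame Cartesian coordinates (nm)."""

    atoms: list[AtomRecord]
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray | None = None  # (n_frames, 3) orthorhombic lengths, nm
    form: str = "dimer"
    pH: float | None = None
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.atoms):
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if not np.isfinite(self.frames).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass_or_guess() for a in self.atoms])


def load_ensemble(
    topology: str,
    trajectory: str | None = None,
    *,
    form: str = "dimer",
    pH: float | None = None,
    replicate_id: str = "r1",
) -> ConformationEnsemble:
    """Read a PDB (optionally multi-model) or PDB+trajectory via MDAnalysis."""
    import MDAnalysis as mda

    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    atoms = []
    for a in u.atoms:
        try:
            chain = a.chainID or a.segid or "A"
        except AttributeError:
            chain = getattr(a, "segid", "A") or "A"
        mass = float(a.mass) if a.mass > 0 else None
        atoms.append(
            AtomRecord(
                name=a.name,
                resname=a.resname,
                resid=int(a.resid),
                chain=str(chain).strip() or "A",
                mass=mass,
            )
        )
    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory]) * 0.1
    return ConformationEnsemble(
        atoms=atoms, frames=frames, form=form, pH=pH, replicate_id=replicate_id
    )


def write_ensemble_pdb(ensemble: ConformationEnsemble, path: str) -> None:
    """Write the ensemble as a multi-model PDB (via MDAnalysis, Å units)."""
    import warnings

    import MDAnalysis as mda

    n = len(ensemble.atoms)
    u = mda.Universe.empty(
        n, n_residues=n, atom_resindex=np.arange(n),
        residue_segindex=np.zeros(n, dtype=int), trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in ensemble.atoms])
    u.add_TopologyAttr("resnames", [a.resname for a in ensemble.atoms])
    u.add_TopologyAttr("resids", [a.resid for a in ensemble.atoms])
    u.add_TopologyAttr("chainIDs", [a.chain for a in ensemble.atoms])
    u.add_TopologyAttr("elements", [a.element for a in ensemble.atoms])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for frame in ensemble.frames:
                u.atoms.positions = frame * 10.0  # nm -> Å
                w.write(u.atoms)


def default_radii(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """Per-atom van der Waals radii (nm) from element symbols."""
    return np.array(
        [VDW_RADII_NM.get(a.element, 0.17) for a in atoms]
    )


# ---------------------------------------------------------------------------
# Selections — minimal grammar: terms joined by `and`;
# terms: `chain A`, `backbone`, `name N CA C`, `resid 84-90`, `resname ALA`
# ---------------------------------------------------------------------------

def select_atoms(atoms: Sequence[AtomRecord], expression: str) -> np.ndarray:
    """Indices of atoms matching the selection expression."""
    mask = np.ones(len(atoms), dtype=bool)
    for term in [t.strip() for t in expression.split(" and ")]:
        tokens = term.split()
        if not tokens:
            continue
        key = tokens[0].lower()
        if key == "backbone":
            term_mask = np.array([a.name in BACKBONE_NAMES for a in atoms])
        elif key == "chain":
            wanted = set(tokens[1:])
            term_mask = np.array([a.chain in wanted for a in atoms])
        elif key == "name":
            wanted = set(tokens[1:])
            term_mask = np.array([a.name in wanted for a in atoms])
        elif key == "resname":
            wanted = set(tokens[1:])
            term_mask = np.array([a.resname in wanted for a in atoms])
        elif key == "resid":
            wanted: set[int] = set()
            for tok in tokens[1:]:
                if "-" in tok:
                    a_, b_ = tok.split("-")
                    wanted.update(range(int(a_), int(b_) + 1))
                else:
                    wanted.add(int(tok))
            term_mask = np.array([a.resid in wanted for a in atoms])
        else:
            raise ValueError(f"unknown selection term {term!r}")
        mask &= term_mask
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Distances, superposition, RMSD
# ---------------------------------------------------------------------------

def com_distance(
    frame: np.ndarray,
    selection_A: np.ndarray,
    selection_B: np.ndarray,
    masses: np.ndarray | None = None,
) -> float:
    """Distance between mass-weighted centroids of two selections (nm)."""
    if len(selection_A) == 0 or len(selection_B) == 0:
        raise ValueError("selections must be non-empty")
    frame = np.asarray(frame, dtype=float)
    if masses is None:
        ca = frame[selection_A].mean(axis=0)
        cb = frame[selection_B].mean(axis=0)
    else:
        wa = masses[selection_A]
        wb = masses[selection_B]
        ca = (frame[selection_A] * wa[:, None]).sum(0) / wa.sum()
        cb = (frame[selection_B] * wb[:, None]).sum(0) / wb.sum()
    return float(np.linalg.norm(ca - cb))


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (proper rotation R, translation t).

    Kabsch via quaternion SVD; applying ``x @ R.T + t`` maps mobile onto
    the reference in the least-squares sense. No reflections.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("matched selections of >=3 atoms required")
    w = None if weights is None else np.asarray(weights, float)
    mc = np.average(mobile, axis=0, weights=w)
    rc = np.average(reference, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc, weights=w)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    return R, t


def rmsd(
    frame: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
    *,
    superposition: bool = True,
    weights: np.ndarray | None = None,
) -> float:
    """Minimum RMSD (nm) over rigid superpositions of the selection."""
    frame = np.asarray(frame, float)
    reference = np.asarray(reference, float)
    if selection is not None:
        frame = frame[selection]
        reference = reference[selection]
        if weights is not None:
            weights = weights[selection]
    if superposition:
        R, t = superpose(frame, reference, weights)
        frame = frame @ R.T + t
    d2 = np.sum((frame - reference) ** 2, axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, float)
    return float(np.sqrt(np.sum(w * d2) / w.sum()))


def dissociation_mask(
    ensemble: ConformationEnsemble,
    reference: np.ndarray,
    *,
    selection_A: np.ndarray,
    selection_B: np.ndarray,
    rmsd_selection: np.ndarray | None = None,
    d_max: float = 3.3,
    rmsd_max: float = 1.2,
) -> np.ndarray:
    """Retention mask for dimer frames: True where still associated.

    A frame is flagged dissociated (False) when the partner COM distance
    exceeds ``d_max`` (nm) or the superposed RMSD to the reference dimer
    exceeds ``rmsd_max`` (nm). Defaults 3.3 nm / 1.2 nm.
    """
    masses = ensemble.masses
    if rmsd_selection is None:
        rmsd_selection = select_atoms(ensemble.atoms, "backbone")
    keep = np.empty(ensemble.n_frames, dtype=bool)
    for k in range(ensemble.n_frames):
        d = com_distance(ensemble.frames[k], selection_A, selection_B, masses)
        r = rmsd(ensemble.frames[k], reference, rmsd_selection)
        keep[k] = (d <= d_max) and (r <= rmsd_max)
    return keep


def central_structure(
    ensemble: ConformationEnsemble, selection: np.ndarray | None = None
) -> int:
    """Frame index minimising the mean squared pairwise RMSD (ties → lowest)."""
    n = ensemble.n_frames
    if n == 0:
        raise ValueError("empty ensemble")
    if n == 1:
        return 0
    sel = (
        selection
        if selection is not None
        else np.arange(len(ensemble.atoms))
    )
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = rmsd(ensemble.frames[i], ensemble.frames[j], sel)
            d2[i, j] = d2[j, i] = r * r
    return int(np.argmin(d2.mean(axis=1)))


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA and contact area
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 0.14,
    n_sphere_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area (nm²).

    Returns (per-atom areas, total). Test points on each atom's expanded
    sphere (radius + probe) are counted accessible when outside every
    neighbour's expanded sphere; the point set is a fixed golden-spiral
    lattice, so results are deterministic.
    """
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be >= 32")
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n_atoms = coords.shape[0]
    rexp = radii + probe
    sphere = _golden_spiral(n_sphere_points)
    tree = cKDTree(coords)
    cutoff = 2.0 * rexp.max()
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + rexp[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], cutoff)
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < rexp[i] + rexp[j]]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > rexp[j] ** 2
        areas[i] = 4.0 * np.pi * rexp[i] ** 2 * accessible.mean()
    return areas, float(areas.sum())


def contact_area(
    frame: np.ndarray,
    radii: np.ndarray,
    selection_A: np.ndarray,
    selection_B: np.ndarray,
    *,
    probe: float = 0.14,
    n_sphere_points: int = 960,
    convention: str = "half",
) -> float:
    """Surface area buried at the A/B interface (nm²).

    buried = SASA(A alone) + SASA(B alone) − SASA(A∪B); the ``half``
    convention (default) returns buried/2 — the area lost per partner —
    while ``full`` returns the total buried area.
    """
    if convention not in ("half", "full"):
        raise ValueError("convention must be 'half' or 'full'")
    if np.intersect1d(selection_A, selection_B).size:
        raise ValueError("selections must be disjoint")
    frame = np.asarray(frame, float)
    _, a_alone = sasa(frame[selection_A], radii[selection_A], probe, n_sphere_points)
    _, b_alone = sasa(frame[selection_B], radii[selection_B], probe, n_sphere_points)
    both = np.concatenate([selection_A, selection_B])
    _, ab = sasa(frame[both], radii[both], probe, n_sphere_points)
    buried = a_alone + b_alone - ab
    return buried / 2.0 if convention == "half" else buried


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def interface_dihedral(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Torsion angle of four points (e.g. atom-group centroids), degrees.

    Returned in (−180, 180]; 180° is the planar trans arrangement, 0° cis.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("collinear points: dihedral undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(m @ n2, n1 @ n2))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


# ---------------------------------------------------------------------------
# Decoupled-fit PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """PCA of transform-selection coordinates after fit-selection superposition."""

    fit_selection: np.ndarray
    transform_selection: np.ndarray
    reference: np.ndarray  # (n_atoms, 3) reference coordinates
    mean: np.ndarray  # flattened mean of transform coords
    components: np.ndarray  # (n_components, 3 * n_transform_atoms)
    explained_variance_ratio: np.ndarray
    projections: np.ndarray  # (n_frames_total, n_components)

    def transform(self, frames: np.ndarray) -> np.ndarray:
        """Project new frames (same atom indexing) onto the components."""
        X = _superposed_transform_coords(
            frames, self.reference, self.fit_selection, self.transform_selection
        )
        return (X - self.mean) @ self.components.T


def _superposed_transform_coords(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_sel: np.ndarray,
    tr_sel: np.ndarray,
) -> np.ndarray:
    out = np.empty((frames.shape[0], 3 * len(tr_sel)))
    ref_fit = reference[fit_sel]
    for k in range(frames.shape[0]):
        R, t = superpose(frames[k][fit_sel], ref_fit)
        out[k] = (frames[k][tr_sel] @ R.T + t).reshape(-1)
    return out


def pca_decoupled(
    ensembles: Sequence[ConformationEnsemble] | ConformationEnsemble,
    fit_selection: np.ndarray,
    transform_selection: np.ndarray,
    reference: np.ndarray,
    *,
    n_components: int | None = None,
) -> PCAModel:
    """PCA in which fitting atoms and analysed atoms are disjoint.

    Each frame is rigid-body superposed on the reference using only
    ``fit_selection``; the Cartesian coordinates of ``transform_selection``
    are then decomposed by PCA. Whole-system rigid motions are removed by
    the fit, so the leading components capture the relative motion of the
    analysed atoms (e.g. one dimer chain relative to the other, or a loop
    relative to the core). Frames from all provided ensembles are pooled.
    """
    from sklearn.decomposition import PCA

    if np.intersect1d(fit_selection, transform_selection).size:
        raise ValueError("fit and transform selections must be disjoint")
    if isinstance(ensembles, ConformationEnsemble):
        ensembles = [ensembles]
    X = np.vstack(
        [
            _superposed_transform_coords(
                e.frames, reference, fit_selection, transform_selection
            )
            for e in ensembles
        ]
    )
    n_comp = n_components or min(X.shape)
    pca = PCA(n_components=min(n_comp, *X.shape), svd_solver="full")
    proj = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    # a rigid ensemble has no variance at all; report fractions of zero
    # rather than sklearn's normalisation of numerical dust
    if float(X.var(axis=0).sum()) < 1e-20:
        evr = np.zeros_like(evr)
    return PCAModel(
        fit_selection=np.asarray(fit_selection),
        transform_selection=np.asarray(transform_selection),
        reference=np.asarray(reference, float),
        mean=pca.mean_,
        components=pca.components_,
        explained_variance_ratio=evr,
        projections=proj,
    )


# ---------------------------------------------------------------------------
# Free-energy landscapes and 1-D histograms
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyLandscape:
    """F = −k_B T ln(P / P_max) on a 2-D grid over (PC1, PC2)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # (nx, ny) probability density
    free_energy: np.ndarray  # (nx, ny), min exactly 0 at the density max
    bandwidth: tuple[float, float]
    temperature: float


def _kde_bandwidth(std: float, n: int) -> float:
    """Kernel bandwidth σ(4N/3)^(−1/5) (decreasing in N)."""
    return std * (4.0 * n / 3.0) ** (-0.2)


def landscape(
    projections: np.ndarray,
    mesh: float,
    temperature: float = DEFAULT_TEMPERATURE,
    *,
    bandwidth: tuple[float, float] | None = None,
    padding_bw: float = 3.0,
) -> FreeEnergyLandscape:
    """2-D Gaussian-KDE free-energy landscape over the first two columns.

    The per-axis bandwidth defaults to σ(4N/3)^(−1/5) with σ the axis
    standard deviation; the grid spans the data range padded by
    ``padding_bw`` bandwidths at mesh spacing ``mesh`` (PC units).
    """
    pts = np.asarray(projections, float)[:, :2]
    n = pts.shape[0]
    if n < 2:
        raise ValueError("at least 2 points required")
    stds = pts.std(axis=0)
    if np.any(stds == 0):
        raise ValueError("degenerate (zero-variance) projections")
    if bandwidth is None:
        bandwidth = tuple(_kde_bandwidth(s, n) for s in stds)
    bx, by = bandwidth
    gx = np.arange(
        pts[:, 0].min() - padding_bw * bx, pts[:, 0].max() + padding_bw * bx + mesh, mesh
    )
    gy = np.arange(
        pts[:, 1].min() - padding_bw * by, pts[:, 1].max() + padding_bw * by + mesh, mesh
    )
    dx = (gx[:, None] - pts[None, :, 0]) / bx
    dy = (gy[:, None] - pts[None, :, 1]) / by
    kx = np.exp(-0.5 * dx**2) / (bx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * dy**2) / (by * np.sqrt(2 * np.pi))
    density = kx @ ky.T / n  # (nx, ny)
    pmax = density.max()
    with np.errstate(divide="ignore"):
        F = -rt(temperature) * np.log(density / pmax)
    F[F == 0.0] = 0.0  # normalise -0.0 at the density maximum
    return FreeEnergyLandscape(
        x_edges=gx,
        y_edges=gy,
        density=density,
        free_energy=F,
        bandwidth=(bx, by),
        temperature=temperature,
    )


def histogram_1d(
    values: np.ndarray, *, bandwidth: float | None = None, n_grid: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel histogram with the σ(4N/3)^(−1/5) bandwidth, 1/N norm."""
    x = np.asarray(values, float)
    n = x.size
    if bandwidth is None:
        s = x.std()
        bandwidth = _kde_bandwidth(s if s > 0 else 1.0, n)
    grid = np.linspace(x.min() - 3 * bandwidth, x.max() + 3 * bandwidth, n_grid)
    d = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * d**2).sum(axis=1) / (n * bandwidth * np.sqrt(2 * np.pi))
    return grid, dens
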