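"""Proton-occupancy trajectories: data model, tabular I/O, frame masking.

A constant-pH MD engine emits, for every saved frame, the binary protonation
state of each titratable site. This module defines the in-memory container
for those series (:class:`OccupancyTrajectory`), a plain tab-separated
on-disk dialect for them, and the frame-masking operations (equilibration
discard, dissociation filtering) that all downstream statistics respect.

Frames are masked, never deleted: the time axis must stay intact so that
autocorrelation analyses can operate on contiguous retained stretches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SiteDefinition",
    "OccupancyTrajectory",
    "SystemSet",
    "OccupancyParseError",
    "read_occupancy_table",
    "write_occupancy_table",
    "read_site_definitions",
    "write_site_definitions",
    "discard_equilibration",
    "apply_frame_mask",
]

ACID = "acid"
BASE = "base"
MONOMER = "monomer"
DIMER = "dimer"


class OccupancyParseError(ValueError):
    """Raised when an occupancy table or site sidecar is malformed."""


@dataclass(frozen=True)
class SiteDefinition:
    """A titratable site.

    Parameters
    ----------
    label:
        Unique identifier, ``<chain>:<RESNAME><resnum>`` (e.g. ``A:ASP137``)
        or the ``NTER``/``CTER`` terminus forms, optionally chain-prefixed.
    residue_kind:
        ``"acid"`` (charge = occupancy − 1, i.e. −1 when deprotonated) or
        ``"base"`` (charge = occupancy, i.e. +1 when protonated).
    """

    label: str
    residue_kind: str

    def __post_init__(self) -> None:
        if self.residue_kind not in (ACID, BASE):
            raise ValueError(
                f"residue_kind must be 'acid' or 'base', got {self.residue_kind!r}"
            )

    @property
    def chain(self) -> str | None:
        """Chain tag if the label carries one (``A:ASP137`` → ``A``)."""
        if ":" in self.label:
            return self.label.split(":", 1)[0]
        return None

    @property
    def base_label(self) -> str:
        """Label with any chain prefix stripped (used for A/B pairing)."""
        if ":" in self.label:
            return self.label.split(":", 1)[1]
        return self.label

    def charge(self, occupancy):
        """Charge in protonic units for the given occupancy (0/1 or mean)."""
        occ = np.asarray(occupancy, dtype=float)
        return occ - 1.0 if self.residue_kind == ACID else occ


@dataclass
class OccupancyTrajectory:
    """Binary proton-occupancy matrix with frame metadata.

    ``occupancies`` has shape (n_frames, n_sites) and entries in {0, 1}
    (1 = proton bound). ``frame_mask`` marks retained frames; all statistics
    downstream consume only retained frames.
    """

    sites: tuple[SiteDefinition, ...]
    times: np.ndarray  # ps, strictly increasing
    occupancies: np.ndarray  # (n_frames, n_sites) in {0,1}
    pH: float
    replicate_id: str = "r1"
    form: str = MONOMER
    frame_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)
        self.times = np.asarray(self.times, dtype=float)
        self.occupancies = np.asarray(self.occupancies, dtype=np.uint8)
        if self.occupancies.ndim != 2:
            raise ValueError("occupancies must be 2-D (n_frames, n_sites)")
        n_frames, n_sites = self.occupancies.shape
        if n_sites != len(self.sites):
            raise ValueError(
                f"{n_sites} occupancy columns but {len(self.sites)} sites"
            )
        if self.times.shape != (n_frames,):
            raise ValueError("times length must equal the number of frames")
        if n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.isfinite(self.pH):
            raise ValueError("pH must be finite")
        if self.form not in (MONOMER, DIMER):
            raise ValueError(f"form must be 'monomer' or 'dimer', got {self.form!r}")
        if np.any(self.occupancies > 1):
            raise ValueError("occupancy entries must be 0 or 1")
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError("site labels must be unique")
        if self.frame_mask is None:
            self.frame_mask = np.ones(n_frames, dtype=bool)
        else:
            self.frame_mask = np.asarray(self.frame_mask, dtype=bool)
            if self.frame_mask.shape != (n_frames,):
                raise ValueError("frame_mask length must equal the number of frames")
        if self.form == DIMER:
            for s in self.sites:
                if s.chain is None:
                    raise ValueError(
                        f"dimer site {s.label!r} must carry a chain tag"
                    )

    @property
    def n_frames(self) -> int:
        return self.occupancies.shape[0]

    @property
    def n_sites(self) -> int:
        return self.occupancies.shape[1]

    @property
    def site_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sites)

    def retained(self) -> np.ndarray:
        """Occupancy rows of retained frames, as float64."""
        return self.occupancies[self.frame_mask].astype(float)

    @property
    def n_retained(self) -> int:
        return int(self.frame_mask.sum())

    def contiguous_retained_stretches(self) -> list[np.ndarray]:
        """Index arrays of maximal contiguous runs of retained frames."""
        idx = np.flatnonzero(self.frame_mask)
        if idx.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(idx) > 1)
        return np.split(idx, breaks + 1)

    def equal(self, other: "OccupancyTrajectory", time_tol: float = 1e-6) -> bool:
        """Structural equality (sites, times within tol, occupancies, mask)."""
        return (
            self.site_labels == other.site_labels
            and tuple(s.residue_kind for s in self.sites)
            == tuple(s.residue_kind for s in other.sites)
            and self.occupancies.shape == other.occupancies.shape
            and np.allclose(self.times, other.times, atol=time_tol, rtol=0.0)
            and np.array_equal(self.occupancies, other.occupancies)
            and np.array_equal(self.frame_mask, other.frame_mask)
        )


@dataclass
class SystemSet:
    """All occupancy trajectories of a study: {form} x {pH} x {replicate}."""

    trajectories: list[OccupancyTrajectory]
    temperature: float = 300.0

    def __post_init__(self) -> None:
        for form in (MONOMER, DIMER):
            labels = {
                t.site_labels for t in self.trajectories if t.form == form
            }
            if len(labels) > 1:
                raise ValueError(
                    f"inconsistent site lists among {form} trajectories"
                )

    @property
    def pH_values(self) -> list[float]:
        return sorted({t.pH for t in self.trajectories})

    def forms(self) -> set[str]:
        return {t.form for t in self.trajectories}

    def select(self, form: str, pH: float, tol: float = 1e-9) -> list[OccupancyTrajectory]:
        """All replicates at one (form, pH) cell."""
        out = [
            t
            for t in self.trajectories
            if t.form == form and abs(t.pH - pH) <= tol
        ]
        if not out:
            raise KeyError(f"no trajectories for form={form!r} pH={pH}")
        return out


# ---------------------------------------------------------------------------
# Tabular I/O — dialect: UTF-8, tab-separated, '#' comment lines,
# header `time_ps<TAB><site1><TAB>...`, one row per frame.
# ---------------------------------------------------------------------------

def read_occupancy_table(
    path: str | Path,
    *,
    pH: float,
    replicate_id: str = "r1",
    form: str = MONOMER,
    sites: Sequence[SiteDefinition] | None = None,
) -> OccupancyTrajectory:
    """Read an occupancy table.

    If ``sites`` is not given, site kinds are inferred from labels
    (``ASP``/``GLU``/``CTER`` → acid, ``HIS``/``LYS``/``ARG``/``NTER`` → base)
    or read from a ``<path>.sites`` sidecar when present.
    """
    path = Path(path)
    header: list[str] | None = None
    times: list[float] = []
    rows: list[list[int]] = []
    mask_col = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields[0] != "time_ps":
                    raise OccupancyParseError(
                        f"{path}:{lineno}: first header column must be "
                        f"'time_ps', got {fields[0]!r}"
                    )
                header = fields[1:]
                if header and header[-1] == "retained":
                    mask_col = True
                    header = header[:-1]
                if not header:
                    raise OccupancyParseError(
                        f"{path}:{lineno}: header names no sites"
                    )
                if len(set(header)) != len(header):
                    raise OccupancyParseError(
                        f"{path}:{lineno}: duplicate site labels in header"
                    )
                continue
            expected = 1 + len(header) + (1 if mask_col else 0)
            if len(fields) != expected:
                raise OccupancyParseError(
                    f"{path}:{lineno}: expected {expected} columns, "
                    f"got {len(fields)}"
                )
            try:
                t = float(fields[0])
            except ValueError:
                raise OccupancyParseError(
                    f"{path}:{lineno}: bad time value {fields[0]!r}"
                ) from None
            if times and t <= times[-1]:
                raise OccupancyParseError(
                    f"{path}:{lineno}: non-increasing time {t} after {times[-1]}"
                )
            occ_fields = fields[1 : 1 + len(header)]
            row = []
            for lab, v in zip(header, occ_fields):
                if v not in ("0", "1"):
                    raise OccupancyParseError(
                        f"{path}:{lineno}: non-binary occupancy {v!r} "
                        f"for site {lab}"
                    )
                row.append(int(v))
            if mask_col:
                mv = fields[-1]
                if mv not in ("0", "1"):
                    raise OccupancyParseError(
                        f"{path}:{lineno}: non-binary retained flag {mv!r}"
                    )
                row.append(int(mv))
            times.append(t)
            rows.append(row)
    if header is None:
        raise OccupancyParseError(f"{path}: no header line found")

    if rows:
        arr = np.array(rows, dtype=np.uint8)
        occ = arr[:, :-1] if mask_col else arr
        mask = arr[:, -1].astype(bool) if mask_col else None
    else:
        occ = np.zeros((0, len(header)), dtype=np.uint8)
        mask = np.zeros(0, dtype=bool) if mask_col else None

    if sites is None:
        sidecar = path.with_suffix(path.suffix + ".sites")
        if sidecar.exists():
            defs = {s.label: s for s in read_site_definitions(sidecar)}
            try:
                sites = [defs[lab] for lab in header]
            except KeyError as e:
                raise OccupancyParseError(
                    f"{sidecar}: missing definition for site {e.args[0]!r}"
                ) from None
        else:
            sites = [SiteDefinition(lab, _infer_kind(lab)) for lab in header]
    else:
        if tuple(s.label for s in sites) != tuple(header):
            raise OccupancyParseError(
                f"{path}: header sites do not match the provided definitions"
            )

    return OccupancyTrajectory(
        sites=tuple(sites),
        times=np.array(times, dtype=float),
        occupancies=occ,
        pH=pH,
        replicate_id=replicate_id,
        form=form,
        frame_mask=mask,
    )


_ACID_RESNAMES = {"ASP", "GLU", "CTER", "CTR", "TYR", "CYS"}
_BASE_RESNAMES = {"HIS", "LYS", "ARG", "NTER", "NTR"}


def _infer_kind(label: str) -> str:
    name = label.split(":", 1)[-1]
    resname = "".join(c for c in name if not c.isdigit())
    if resname in _ACID_RESNAMES:
        return ACID
    if resname in _BASE_RESNAMES:
        return BASE
    raise OccupancyParseError(
        f"cannot infer acid/base kind for site {label!r}; "
        "provide a site-definition sidecar"
    )


def write_occupancy_table(
    traj: OccupancyTrajectory,
    path: str | Path,
    *,
    write_sidecar: bool = True,
) -> None:
    """Write the trajectory in the tab-separated dialect.

    Masked frames are written too; the mask is stored in a trailing
    ``retained`` column (dropped when all frames are retained).
    """
    path = Path(path)
    with_mask = not traj.frame_mask.all()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pH={traj.pH:g} replicate={traj.replicate_id} form={traj.form}\n")
        cols = ["time_ps", *traj.site_labels]
        if with_mask:
            cols.append("retained")
        fh.write("\t".join(cols) + "\n")
        for k in range(traj.n_frames):
            fields = [repr(float(traj.times[k]))]
            fields += [str(int(v)) for v in traj.occupancies[k]]
            if with_mask:
                fields.append(str(int(traj.frame_mask[k])))
            fh.write("\t".join(fields) + "\n")
    if write_sidecar:
        write_site_definitions(traj.sites, path.with_suffix(path.suffix + ".sites"))


def read_site_definitions(path: str | Path) -> list[SiteDefinition]:
    """Read the `label<TAB>residue_kind` sidecar."""
    out: list[SiteDefinition] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise OccupancyParseError(
                    f"{path}:{lineno}: expected 'label<TAB>kind'"
                )
            label, kind = fields
            if kind not in (ACID, BASE):
                raise OccupancyParseError(
                    f"{path}:{lineno}: residue_kind must be acid|base, got {kind!r}"
                )
            out.append(SiteDefinition(label, kind))
    return out


def write_site_definitions(
    sites: Iterable[SiteDefinition], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sites:
            fh.write(f"{s.label}\t{s.residue_kind}\n")


# ---------------------------------------------------------------------------
# Frame masking
# ---------------------------------------------------------------------------

def discard_equilibration(
    traj: OccupancyTrajectory, t_start: float
) -> OccupancyTrajectory:
    """Mask all frames with time < ``t_start`` (ps). Frames are kept in place."""
    if t_start < 0:
        raise ValueError("t_start must be >= 0")
    new_mask = traj.frame_mask & (traj.times >= t_start)
    if traj.n_frames and not new_mask.any():
        warnings.warn(
            f"t_start={t_start} ps masks every frame "
            f"(last frame at {traj.times[-1]} ps)",
            stacklevel=2,
        )
    return replace(traj, frame_mask=new_mask)


def apply_frame_mask(
    traj: OccupancyTrajectory, mask: np.ndarray
) -> OccupancyTrajectory:
    """AND an additional retention mask into the trajectory's frame mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (traj.n_frames,):
        raise ValueError(
            f"mask length {mask.shape} does not match {traj.n_frames} frames"
        )
    return replace(traj, frame_mask=traj.frame_mask & mask)
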