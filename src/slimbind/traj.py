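"""Conformational analysis of peptide trajectories.

Backbone phi/psi dihedrals, Ramachandran free-energy surfaces
(Boltzmann inversion of the binned angle density) and combined-ensemble
Calpha principal components with least-squares superposition onto a
reference conformation.  The contrast of interest is how much of
Ramachandran space a residue samples: a proline-like centre is confined
to a narrow phi band while a leucine-like centre explores a much larger
area, which shows up directly in the occupied-bin count of the surface
and in the spread of the PCA projection cloud.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KJ_PER_MOL_K

__all__ = [
    "PeptideTrajectory",
    "DihedralSeries",
    "FreeEnergySurface",
    "PCAResult",
    "dihedral_angle",
    "compute_phi_psi",
    "free_energy_surface",
    "superpose",
    "pca_combined",
]


@dataclass
class PeptideTrajectory:
    """Multi-frame peptide coordinates with a constant atom table.

    coords : (n_frames, n_atoms, 3) array, angstrom internally
    atoms : list of (residue_index, residue_name, atom_name)
    dt_ps : spacing between frames in picoseconds
    """

    coords: np.ndarray
    atoms: list[tuple[int, str, str]]
    dt_ps: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table size does not match coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_indices(self) -> list[int]:
        seen: dict[int, None] = {}
        for ri, _, _ in self.atoms:
            seen.setdefault(ri, None)
        return list(seen)

    def atom_index(self, residue: int, atom_name: str) -> int:
        for i, (ri, _, an) in enumerate(self.atoms):
            if ri == residue and an == atom_name:
                return i
        raise KeyError(f"atom {atom_name!r} of residue {residue} not found")

    def ca_coords(self, exclude_terminal: bool = False) -> np.ndarray:
        res = self.residue_indices
        if exclude_terminal:
            if len(res) <= 2:
                raise ValueError("too few residues to exclude termini")
            res = res[1:-1]
        idx = [self.atom_index(r, "CA") for r in res]
        return self.coords[:, idx, :]


@dataclass
class DihedralSeries:
    """Per-frame (phi, psi) of one residue, degrees in (-180, 180]."""

    residue: int
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi lengths differ")


@dataclass
class FreeEnergySurface:
    """Binned phi/psi relative free energy in kJ/mol.

    ``delta_g`` is masked (NaN) on empty bins and zero at the global
    minimum of the occupied bins.
    """

    phi_edges: np.ndarray
    psi_edges: np.ndarray
    delta_g: np.ndarray
    occupied: np.ndarray
    temperature: float

    @property
    def occupied_bin_count(self) -> int:
        return int(np.count_nonzero(self.occupied))


@dataclass
class PCAResult:
    components: np.ndarray        # (n_components, 3*n_ca), orthonormal rows
    projections: np.ndarray       # (n_frames_total, n_components)
    explained_variance: np.ndarray
    explained_fraction: np.ndarray
    labels: list[str]             # per-frame source label


def _wrap_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-180, 180]."""
    wrapped = -((-np.asarray(angle) + 180.0) % 360.0 - 180.0)
    return wrapped


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees) of four points about the p1-p2 axis.

    IUPAC sign convention: looking from p1 to p2, a clockwise rotation
    of the far bond is positive.  Raises on degenerate (collinear)
    geometry where a plane normal vanishes.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b1n = np.linalg.norm(b1)
    if n1n < 1e-10 or n2n < 1e-10 or b1n < 1e-10:
        raise ValueError("degenerate (collinear) atoms: dihedral undefined")
    m1 = np.cross(n1, b1 / b1n)
    x = n1 @ n2
    y = m1 @ n2
    return float(_wrap_deg(math.degrees(math.atan2(y, x))))


def compute_phi_psi(traj: PeptideTrajectory, residue: int) -> DihedralSeries:
    """phi/psi time series of one residue.

    phi = C(i-1)-N(i)-CA(i)-C(i); psi = N(i)-CA(i)-C(i)-N(i+1).
    Terminal residues lacking a neighbour raise, naming the missing
    dihedral.
    """
    res = traj.residue_indices
    if residue not in res:
        raise KeyError(f"residue {residue} not in trajectory")
    pos = res.index(residue)
    if pos == 0:
        raise ValueError(f"residue {residue}: phi undefined (no preceding C)")
    if pos == len(res) - 1:
        raise ValueError(f"residue {residue}: psi undefined (no following N)")
    prev_res = res[pos - 1]
    next_res = res[pos + 1]
    i_cprev = traj.atom_index(prev_res, "C")
    i_n = traj.atom_index(residue, "N")
    i_ca = traj.atom_index(residue, "CA")
    i_c = traj.atom_index(residue, "C")
    i_nnext = traj.atom_index(next_res, "N")

    phi = np.empty(traj.n_frames)
    psi = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.coords[f]
        phi[f] = dihedral_angle(x[i_cprev], x[i_n], x[i_ca], x[i_c])
        psi[f] = dihedral_angle(x[i_n], x[i_ca], x[i_c], x[i_nnext])
    return DihedralSeries(residue=residue, phi=phi, psi=psi)


def free_energy_surface(
    dihedrals: DihedralSeries,
    n_bins: int = 36,
    temperature: float = 310.15,
) -> FreeEnergySurface:
    """Ramachandran free-energy surface by Boltzmann inversion.

    2D histogram over (-180, 180]^2 (periodic angles are pre-wrapped so
    no density is lost at the edges), then
    ``dG = -kB T ln(n_bin / n_max)`` in kJ/mol; the most populated bin
    defines dG = 0 and empty bins are masked, never infinite.
    """
    if n_bins < 4:
        raise ValueError("need at least 4 bins per axis")
    phi = np.asarray(_wrap_deg(dihedrals.phi))
    psi = np.asarray(_wrap_deg(dihedrals.psi))
    if phi.size == 0:
        raise ValueError("empty dihedral series")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _, _ = np.histogram2d(phi, psi, bins=[edges, edges])
    occupied = counts > 0
    n_max = counts.max()
    dg = np.full_like(counts, np.nan)
    kt = KB_KJ_PER_MOL_K * temperature
    dg[occupied] = -kt * np.log(counts[occupied] / n_max)
    return FreeEnergySurface(
        phi_edges=edges,
        psi_edges=edges,
        delta_g=dg,
        occupied=occupied,
        temperature=temperature,
    )


def superpose(
    frame: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares rigid-body superposition (Kabsch algorithm).

    Returns the transformed copy of ``frame`` and the residual RMSD.
    Raises on fewer than three points or degenerate (collinear) sets,
    for which the rotation is not unique.
    """
    X = np.asarray(frame, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("point sets must share shape (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need >= 3 points for a unique superposition")
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean(axis=0)
    # collinearity check: second singular value of either cloud ~ 0
    for cloud in (xc, yc):
        sv = np.linalg.svd(cloud, compute_uv=False)
        if sv[1] < 1e-8 * max(sv[0], 1e-8):
            raise ValueError("degenerate (collinear) point set")
    H = xc.T @ yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    aligned = xc @ R.T + Y.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - Y) ** 2, axis=1))))
    return aligned, rmsd


def pca_combined(
    traj_a: PeptideTrajectory,
    traj_b: PeptideTrajectory,
    reference: np.ndarray,
    exclude_terminal: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the concatenated Calpha coordinates of two ensembles.

    Every frame of both trajectories is superposed onto ``reference``
    (Calpha coordinates of the bound-state conformation, shape
    (n_ca, 3) after terminal exclusion), the flattened coordinates are
    mean-centred over the combined ensemble, and the covariance is
    eigendecomposed.  Projections carry a per-frame source label so the
    spread of the two ensembles can be compared.
    """
    ca_a = traj_a.ca_coords(exclude_terminal)
    ca_b = traj_b.ca_coords(exclude_terminal)
    if ca_a.shape[1] != ca_b.shape[1]:
        raise ValueError("Calpha atom counts differ between trajectories")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != ca_a.shape[1:]:
        raise ValueError(
            f"reference shape {reference.shape} does not match Calpha set "
            f"{ca_a.shape[1:]}"
        )
    frames = np.concatenate([ca_a, ca_b], axis=0)
    aligned = np.empty_like(frames)
    for i in range(frames.shape[0]):
        aligned[i], _ = superpose(frames[i], reference)
    flat = aligned.reshape(frames.shape[0], -1)
    mean = flat.mean(axis=0)
    centred = flat - mean
    cov = centred.T @ centred / (flat.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if n_components is None:
        n_components = evals.size
    comps = evecs[:, :n_components].T
    proj = centred @ comps.T
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    labels = [traj_a.label or "A"] * ca_a.shape[0] + [
        traj_b.label or "B"
    ] * ca_b.shape[0]
    return PCAResult(
        components=comps,
        projections=proj,
        explained_variance=evals[:n_components],
        explained_fraction=frac[:n_components],
        labels=labels,
    )
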