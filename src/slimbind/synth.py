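"""Synthetic-data generators with planted ground truth.

Every input class the analysis stages consume can be generated here
with known parameters, so parameter-recovery and bookkeeping tests run
without any external data: chemical-shift titrations (fast- and
slow-exchange residues), two-field CPMG dispersion datasets with a
duplicated point for error analysis, proteomes with disorder masks and
planted motifs, and peptide trajectories built from sampled backbone
dihedrals.  Each generator is a pure function of its arguments
(including the seed) and returns a machine-readable ground-truth ledger
alongside the dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binding import TitrationPoint, TitrationSeries, expected_bound_fraction
from .census import AMINO_ACIDS, DisorderMask, MotifQuery, ProteomeSet, scan_motifs
from .cpmg import DispersionCurve, DispersionDataset, ExchangeParams, simulate_dispersion
from .traj import PeptideTrajectory

__all__ = [
    "default_titration_residues",
    "default_nu_grid",
    "gen_titration",
    "gen_cpmg",
    "gen_proteome",
    "gen_peptide_traj",
    "AngleDistribution",
    "narrow_proline_like",
    "broad_leucine_like",
]


# ---------------------------------------------------------------------------
# titrations

#: The sixteen fast-exchange amide resonances followed in the titration,
#: with plausible saturating perturbations (ppm) in each dimension.
_FAST_RESIDUES = [
    ("T91", 0.055, 0.42), ("D93", 0.040, 0.30), ("W95", 0.070, 0.55),
    ("W95sc", 0.065, 0.24), ("S98", 0.030, 0.35), ("L99", 0.050, 0.28),
    ("D100", 0.024, 0.21), ("A105", 0.036, 0.44), ("I120", 0.060, 0.50),
    ("K123", 0.028, 0.18), ("R140", 0.033, 0.27), ("Y142", 0.047, 0.39),
    ("L144", 0.052, 0.31), ("V148", 0.041, 0.46), ("D149", 0.026, 0.23),
    ("V153", 0.058, 0.52),
]


def default_titration_residues() -> list[tuple[str, float, float]]:
    """(label, ddmax_h, ddmax_n) for the default 16-residue scenario."""
    return list(_FAST_RESIDUES)


def geometric_ladder(top: float = 2000.0, n_nonzero: int = 8) -> list[float]:
    """Zero plus a geometric ligand ladder up to ``top`` µM."""
    return [0.0] + [top / 2**k for k in reversed(range(n_nonzero))]


def gen_titration(
    kd: float,
    residues: list[tuple[str, float, float]] | None = None,
    protein_total: float = 200.0,
    ligand_ladder: list[float] | None = None,
    noise_sd: float = 0.002,
    slow_residues: list[str] | None = None,
    intensity_noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[TitrationSeries, dict]:
    """Simulate a two-state titration with planted Kd.

    Fast-exchange residues move by ``pB_calc * ddmax`` per dimension
    (the population-weighted average position), with Gaussian shift
    noise of ``noise_sd`` ppm on each axis; slow-exchange residues stay
    at their apo position and lose intensity in proportion to the bound
    fraction, emulating peaks that broaden away during the titration.
    """
    if residues is None:
        residues = default_titration_residues()
    if ligand_ladder is None:
        ligand_ladder = geometric_ladder()
    ladder = list(ligand_ladder)
    if ladder[0] != 0.0:
        ladder = [0.0] + ladder
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("ligand ladder must be strictly increasing")
    if kd <= 0:
        raise ValueError("kd must be positive")
    slow = list(slow_residues or [])

    rng = np.random.default_rng(seed)
    points: list[TitrationPoint] = []
    truth = {
        "kd": kd,
        "protein_total": protein_total,
        "ladder": ladder,
        "noise_sd": noise_sd,
        "ddmax": {},
        "slow_residues": slow,
        "bound_fraction": [
            expected_bound_fraction(kd, lig, protein_total) for lig in ladder
        ],
    }

    for k, (label, ddh, ddn) in enumerate(residues):
        sub = np.random.default_rng(np.random.SeedSequence([seed, 1, k]))
        apo_h = 7.6 + 0.9 * sub.random()
        apo_n = 108.0 + 22.0 * sub.random()
        truth["ddmax"][label] = math.hypot(ddh, 0.2 * ddn)
        for lig, pb in zip(ladder, truth["bound_fraction"]):
            nh = 0.0 if lig == 0.0 else sub.normal(0.0, noise_sd)
            nn = 0.0 if lig == 0.0 else sub.normal(0.0, noise_sd)
            points.append(
                TitrationPoint(
                    residue_id=label,
                    shift_h=apo_h + pb * ddh + nh,
                    shift_n=apo_n + pb * ddn + nn,
                    intensity=1.0,
                    ligand_total=lig,
                    protein_total=protein_total,
                )
            )

    for k, label in enumerate(slow):
        sub = np.random.default_rng(np.random.SeedSequence([seed, 2, k]))
        apo_h = 7.6 + 0.9 * sub.random()
        apo_n = 108.0 + 22.0 * sub.random()
        for lig, pb in zip(ladder, truth["bound_fraction"]):
            noise = 0.0 if lig == 0.0 else sub.normal(0.0, intensity_noise_sd)
            points.append(
                TitrationPoint(
                    residue_id=label,
                    shift_h=apo_h,
                    shift_n=apo_n,
                    intensity=max(1.0 * (1.0 - pb) + noise, 1e-6),
                    ligand_total=lig,
                    protein_total=protein_total,
                )
            )

    return TitrationSeries.from_points(points), truth


# ---------------------------------------------------------------------------
# CPMG dispersion

#: Ten residues flanking the peptide groove whose 15N dispersions carry
#: the binding exchange signal.
CPMG_RESIDUES = [
    "T110", "K112", "T113", "K114", "T151", "V153", "S154", "S156", "L157", "S158",
]


def default_nu_grid(t_cpmg: float = 0.039, duplicate: int = 1) -> np.ndarray:
    """19 nu_cpmg values with integer (even) echo counts in ``t_cpmg``,
    plus one duplicated value for error analysis."""
    echoes = np.array(
        [2, 4, 6, 8, 10, 12, 16, 20, 24, 28, 32, 36, 40, 46, 52, 58, 64, 70, 78]
    )
    nu = echoes / (2.0 * t_cpmg)
    return np.append(nu, nu[duplicate])


def gen_cpmg(
    params_per_residue: list[tuple[str, ExchangeParams]],
    fields: tuple[float, ...] = (500.0, 600.0),
    nu_grid: np.ndarray | None = None,
    t_cpmg: float = 0.039,
    intensity_noise_sd: float = 0.005,
    seed: int = 0,
) -> tuple[DispersionDataset, dict]:
    """Simulate dispersion datasets at several static fields.

    Peak intensities follow the exact two-state forward model with
    additive Gaussian noise of ``intensity_noise_sd`` (on the unit-I0
    scale), then R2,eff is recovered through the fixed-delay log-ratio,
    exactly as in the experiment.  A noise level of 0.005 reproduces an
    R2,eff scatter of roughly 0.3 /s at typical attenuations.
    """
    if nu_grid is None:
        nu_grid = default_nu_grid(t_cpmg)
    nu_grid = np.asarray(nu_grid, dtype=float)
    curves = []
    truth = {
        "t_cpmg": t_cpmg,
        "fields": list(fields),
        "intensity_noise_sd": intensity_noise_sd,
        "params": {
            rid: {
                "p_b": p.p_b, "k_ex": p.k_ex, "dw_ppm": p.dw_ppm,
                "r2_a": p.r2_a, "r2_b": p.r2_b,
            }
            for rid, p in params_per_residue
        },
    }
    for k, (rid, params) in enumerate(params_per_residue):
        for j, field in enumerate(fields):
            sub = np.random.default_rng(np.random.SeedSequence([seed, k, j]))
            r2 = simulate_dispersion(params, nu_grid, field, t_cpmg)
            intensity = np.exp(-r2 * t_cpmg) + sub.normal(
                0.0, intensity_noise_sd, nu_grid.shape
            )
            intensity = np.clip(intensity, 1e-8, None)
            r2_obs = -np.log(intensity) / t_cpmg
            curves.append(
                DispersionCurve(
                    residue_id=rid,
                    field_mhz=field,
                    t_cpmg=t_cpmg,
                    nu_cpmg=nu_grid,
                    r2_eff=r2_obs,
                    i0=1.0,
                )
            )
    return DispersionDataset(curves), truth


def wt_like_exchange_params(
    p_b: float = 0.024,
    k_off: float = 515.0,
    dw_range: tuple[float, float] = (1.0, 3.0),
    r2_a: float = 12.0,
    n_residues: int = 10,
) -> list[tuple[str, ExchangeParams]]:
    """Per-residue exchange parameters mirroring the peptide-binding
    scenario: shared p_b and k_ex (from k_off = (1 - p_b) k_ex), |dw|
    spread evenly over ``dw_range``."""
    k_ex = k_off / (1.0 - p_b)
    dws = np.linspace(dw_range[0], dw_range[1], n_residues)
    return [
        (rid, ExchangeParams(p_b=p_b, k_ex=k_ex, dw_ppm=float(dw), r2_a=r2_a, r2_b=r2_a))
        for rid, dw in zip(CPMG_RESIDUES[:n_residues], dws)
    ]


# ---------------------------------------------------------------------------
# proteomes

#: Human-like amino-acid frequencies (rounded); used as the default
#: background composition.
HUMAN_LIKE_FREQS = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}


def _sample_interval(rng, length: int, want: int) -> tuple[int, int]:
    start = int(rng.integers(0, length - want + 1))
    return start, start + want


def gen_proteome(
    n_proteins: int = 50,
    length_range: tuple[int, int] = (150, 400),
    aa_frequencies: dict[str, float] | None = None,
    disorder_fraction: float = 0.3,
    planted_motifs: list[tuple[str, str, int]] | None = None,
    seed: int = 0,
    max_attempts: int = 1000,
) -> tuple[ProteomeSet, DisorderMask, dict]:
    """Generate an i.i.d. proteome with disorder intervals and planted
    motifs.

    Each protein carries one disorder interval covering about
    ``disorder_fraction`` of its residues (>= 20 when it exists at
    all).  ``planted_motifs`` entries are (pattern, database, count),
    e.g. ``("IPV", "disordered", 37)``; plantings overwrite residues at
    recorded positions and are rejection-checked so no *unrecorded*
    extra matches of the same query appear (each successful write adds
    exactly one match in the target database).  The ground-truth ledger
    reports planted positions and the residual background counts of
    each planted query per database.
    """
    freqs = dict(aa_frequencies or HUMAN_LIKE_FREQS)
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("aa_frequencies must sum to 1")
    letters = np.array(list(freqs))
    probs = np.array([freqs[a] for a in letters])
    probs = probs / probs.sum()

    seqs: dict[str, np.ndarray] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for k in range(n_proteins):
        sub = np.random.default_rng(np.random.SeedSequence([seed, 10, k]))
        length = int(sub.integers(length_range[0], length_range[1] + 1))
        seqs[f"SYN{k:04d}"] = sub.choice(letters, size=length, p=probs)
        want = int(round(disorder_fraction * length))
        if disorder_fraction > 0 and want >= 1:
            want = max(want, 20)
            if want <= length:
                intervals[f"SYN{k:04d}"] = [_sample_interval(sub, length, want)]

    def db_of_window(pid: str, start: int, n: int) -> str:
        ivals = intervals.get(pid, [])
        if any(a <= start and start + n <= b for a, b in ivals):
            return "disordered"
        return "structured"

    plant_rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    planted: dict[tuple[str, str], list[tuple[str, int]]] = {}
    pids = list(seqs)
    for pattern, database, count in planted_motifs or []:
        if database not in ("proteome", "disordered", "structured"):
            raise ValueError(f"unknown database {database!r}")
        query = MotifQuery.from_pattern(pattern)
        key = (pattern, database)
        planted[key] = []
        for _ in range(count):
            placed = False
            for _attempt in range(max_attempts):
                pid = pids[int(plant_rng.integers(0, len(pids)))]
                arr = seqs[pid]
                if len(arr) < query.n:
                    continue
                start = int(plant_rng.integers(0, len(arr) - query.n + 1))
                wdb = db_of_window(pid, start, query.n)
                if database != "proteome" and wdb != database:
                    continue
                # count existing matches of the query in the affected
                # neighbourhood, write, re-count; require exactly +1
                lo = max(start - query.n + 1, 0)
                hi = min(start + 2 * query.n - 1, len(arr))
                region_old = "".join(arr[lo:hi])
                before = [
                    m for m in scan_motifs(region_old, query)
                    if db_of_window(pid, lo + m, query.n) == database
                    or database == "proteome"
                ]
                new_letters = [
                    sorted(s)[int(plant_rng.integers(0, len(s)))]
                    for s in query.positions
                ]
                old_letters = arr[start : start + query.n].copy()
                arr[start : start + query.n] = new_letters
                region_new = "".join(arr[lo:hi])
                after = [
                    m for m in scan_motifs(region_new, query)
                    if db_of_window(pid, lo + m, query.n) == database
                    or database == "proteome"
                ]
                gained = set(after) - set(before)
                if len(after) == len(before) + 1 and gained == {start - lo}:
                    planted[key].append((pid, start))
                    placed = True
                    break
                arr[start : start + query.n] = old_letters
            if not placed:
                raise RuntimeError(
                    f"could not plant {pattern!r} in {database} after "
                    f"{max_attempts} attempts (infeasible planting)"
                )

    proteome = ProteomeSet(
        records={pid: "".join(arr) for pid, arr in seqs.items()},
        provenance=f"synthetic i.i.d. proteome, seed={seed}",
    )
    mask = DisorderMask(intervals=intervals)

    background: dict[str, dict[str, int]] = {}
    for pattern in {pat for pat, _db, _c in planted_motifs or []}:
        query = MotifQuery.from_pattern(pattern)
        planted_set = {
            pos
            for (pat, _db), plist in planted.items()
            if pat == pattern
            for pos in plist
        }
        bg = {"proteome": 0, "disordered": 0, "structured": 0}
        for pid, seq in proteome.records.items():
            for m in scan_motifs(seq, query):
                if (pid, m) not in planted_set:
                    bg["proteome"] += 1
                    bg[db_of_window(pid, m, query.n)] += 1
        background[pattern] = bg

    truth = {
        "seed": seed,
        "frequencies": freqs,
        "disorder_fraction": disorder_fraction,
        "planted": {
            f"{pat}|{db}": pos for (pat, db), pos in planted.items()
        },
        "background": background,
    }
    return proteome, mask, truth


# ---------------------------------------------------------------------------
# peptide trajectories

@dataclass(frozen=True)
class AngleDistribution:
    """Mixture of von Mises components over an angle in degrees.

    ``mus``/``kappas``/``weights`` describe the components; a large
    kappa gives a tight unimodal distribution, several spread-out
    components a broad one.
    """

    mus: tuple[float, ...]
    kappas: tuple[float, ...]
    weights: tuple[float, ...]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        w = w / w.sum()
        comp = rng.choice(len(self.mus), size=n, p=w)
        out = np.empty(n)
        for k in range(len(self.mus)):
            m = comp == k
            if np.any(m):
                out[m] = np.degrees(
                    rng.vonmises(math.radians(self.mus[k]), self.kappas[k], m.sum())
                )
        return out


def narrow_proline_like() -> tuple[AngleDistribution, AngleDistribution]:
    """Tight phi band near -65 degrees with psi split between the
    polyproline/beta and alpha basins -- proline-like sampling."""
    phi = AngleDistribution((-65.0,), (60.0,), (1.0,))
    psi = AngleDistribution((150.0, -30.0), (30.0, 30.0), (0.7, 0.3))
    return phi, psi


def broad_leucine_like() -> tuple[AngleDistribution, AngleDistribution]:
    """Broad multi-basin sampling typical of an unconstrained residue."""
    phi = AngleDistribution((-120.0, -65.0, 55.0), (4.0, 4.0, 8.0), (0.45, 0.40, 0.15))
    psi = AngleDistribution((140.0, -40.0, 10.0), (3.0, 3.0, 3.0), (0.45, 0.40, 0.15))
    return phi, psi


# ideal backbone geometry (angstrom, degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_OMEGA = 180.0


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Natural-extension-of-reference-frame atom placement: position d
    such that |cd| = bond, angle(b,c,d) = angle, dihedral(a,b,c,d) =
    torsion."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            -bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Cartesian N/CA/C backbone for one frame from per-residue phi/psi.

    ``phi[0]`` and ``psi[-1]`` are ignored (undefined at the termini).
    Returns (3*n_res, 3) coordinates in N, CA, C order per residue.
    """
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi and psi must have equal length")
    coords = np.zeros((3 * n_res, 3))
    # first residue in a canonical pose
    coords[0] = [0.0, 0.0, 0.0]                      # N1
    coords[1] = [_BOND_N_CA, 0.0, 0.0]               # CA1
    ang = math.radians(_ANG_N_CA_C)
    coords[2] = coords[1] + _BOND_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0]
    )                                                # C1
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _BOND_C_N, _ANG_CA_C_N, psi[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        c_i = _place_atom(c_prev, n_i, ca_i, _BOND_CA_C, _ANG_N_CA_C, phi[i])
        coords[3 * i : 3 * i + 3] = [n_i, ca_i, c_i]
    return coords


def gen_peptide_traj(
    n_frames: int = 500,
    backbone_model: list[tuple[AngleDistribution, AngleDistribution]] | None = None,
    n_residues: int = 8,
    dt_ps: float = 100.0,
    seed: int = 0,
    label: str = "",
) -> tuple[PeptideTrajectory, dict]:
    """Sample per-frame backbone dihedrals and build ideal-geometry
    Cartesian frames.

    ``backbone_model`` gives one (phi, psi) distribution pair per
    residue; by default every residue uses the narrow proline-like
    model.  The sampled angles are returned in the ground-truth ledger;
    interior residues invert exactly through the dihedral analysis.
    """
    if backbone_model is None:
        backbone_model = [narrow_proline_like()] * n_residues
    n_res = len(backbone_model)
    rng = np.random.default_rng(seed)
    phi = np.stack(
        [dist[0].sample(rng, n_frames) for dist in backbone_model], axis=1
    )
    psi = np.stack(
        [dist[1].sample(rng, n_frames) for dist in backbone_model], axis=1
    )
    frames = np.stack([build_backbone(phi[f], psi[f]) for f in range(n_frames)])
    atoms = []
    for r in range(n_res):
        for an in ("N", "CA", "C"):
            atoms.append((r, "GLY", an))
    traj = PeptideTrajectory(coords=frames, atoms=atoms, dt_ps=dt_ps, label=label)
    truth = {"phi": phi, "psi": psi, "seed": seed}
    return traj, truth
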