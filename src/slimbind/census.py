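"""Proteome-wide census of [V/I]x[V/I] short linear motifs.

Counts tripeptide motifs of the four families IxI, IxV, VxI, VxV (with
the central position x iterated over the 20 amino acids) in a proteome,
in its intrinsically disordered regions (>= 20-residue intervals), and
-- by subtraction -- in the structured remainder.  Expected counts come
from a position-independence null based on per-database amino-acid
frequencies, and enrichment is tested with per-family and total
chi-square statistics.

Conventions: 0-based, half-open disorder intervals; overlapping motif
windows each count; a motif is "disordered" only when all of its
residues lie inside one disorder interval, so windows straddling an
interval boundary count as structured via the subtraction identity
M_structured = M_proteome - M_disordered (which the accessibility
argument for disordered motifs motivates).  Ambiguous residues
(B, J, O, U, X, Z) never match a positional set and are excluded from
frequency denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "AMINO_ACIDS",
    "ProteomeSet",
    "DisorderMask",
    "MotifQuery",
    "CensusResult",
    "scan_motifs",
    "census",
    "expected_count",
    "chi_square_total",
    "enrichment_profile",
    "intersect_interactors",
    "default_families",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DATABASES = ("proteome", "disordered", "structured")


@dataclass
class ProteomeSet:
    """Protein id -> uppercase amino-acid sequence."""

    records: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        for pid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for protein {pid!r}")
        self.records = {pid: seq.upper() for pid, seq in self.records.items()}


@dataclass
class DisorderMask:
    """Protein id -> sorted, non-overlapping [start, end) intervals."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    min_length: int = 20

    def validate_against(self, proteome: ProteomeSet) -> None:
        for pid, ivals in self.intervals.items():
            if pid not in proteome.records:
                raise ValueError(f"mask refers to unknown protein {pid!r}")
            n = len(proteome.records[pid])
            prev_end = -1
            for start, end in ivals:
                if not (0 <= start < end <= n):
                    raise ValueError(
                        f"interval [{start}, {end}) out of bounds for protein "
                        f"{pid!r} (length {n})"
                    )
                if start < prev_end:
                    raise ValueError(f"overlapping/unsorted intervals for {pid!r}")
                if end - start < self.min_length:
                    raise ValueError(
                        f"interval [{start}, {end}) for {pid!r} shorter than "
                        f"{self.min_length} residues"
                    )
                prev_end = end


@dataclass(frozen=True)
class MotifQuery:
    """Ordered positional residue sets, e.g. ({V,I}, ANY, {V,I})."""

    positions: tuple[frozenset, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValueError("query must have length >= 1")
        for s in self.positions:
            if not s or not set(s) <= set(AMINO_ACIDS):
                raise ValueError("positional sets must be non-empty subsets of the 20 AAs")

    @property
    def n(self) -> int:
        return len(self.positions)

    @classmethod
    def from_pattern(cls, pattern: str, name: str = "") -> "MotifQuery":
        """Build from a compact pattern such as ``"[VI]x[VI]"`` or ``"IxI"``.

        ``x`` (or ``X``) is the any-residue wildcard; brackets enclose
        alternative residues.
        """
        sets: list[frozenset] = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "[":
                j = pattern.index("]", i)
                sets.append(frozenset(pattern[i + 1 : j].upper()))
                i = j + 1
            elif ch in "xX":
                sets.append(frozenset(AMINO_ACIDS))
                i += 1
            else:
                sets.append(frozenset(ch.upper()))
                i += 1
        return cls(tuple(sets), name=name or pattern)


def default_families() -> list[MotifQuery]:
    """The four [V/I]x[V/I] families with the central position free."""
    out = []
    for left in "IV":
        for right in "IV":
            out.append(
                MotifQuery(
                    (frozenset(left), frozenset(AMINO_ACIDS), frozenset(right)),
                    name=f"{left}x{right}",
                )
            )
    return out


def scan_motifs(sequence: str, query: MotifQuery) -> list[int]:
    """0-based start positions of every window matching the query.

    Overlapping windows each count; residues outside the 20-letter
    alphabet never match.
    """
    seq = sequence.upper()
    n = query.n
    hits = []
    for i in range(len(seq) - n + 1):
        if all(seq[i + q] in query.positions[q] for q in range(n)):
            hits.append(i)
    return hits


def _window_in_intervals(start: int, n: int, ivals: list[tuple[int, int]]) -> bool:
    return any(a <= start and start + n <= b for a, b in ivals)


def _aa_frequencies(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts[a] for a in AMINO_ACIDS)
    if total == 0:
        return {a: 0.0 for a in AMINO_ACIDS}
    return {a: counts[a] / total for a in AMINO_ACIDS}


@dataclass
class CensusResult:
    """Observed/expected motif counts and enrichment statistics.

    ``observed[db][family][x]`` and ``expected[db][family][x]`` hold the
    per-cell counts for the central residue x; ``total_windows[db]`` is
    M_r,n (all length-n windows of database r, ambiguous-letter windows
    included in sequence space but unmatched); ``frequencies[db]`` holds
    p_r,AA over unambiguous residues.
    """

    families: list[str]
    observed: dict[str, dict[str, dict[str, int]]]
    expected: dict[str, dict[str, dict[str, float]]]
    total_windows: dict[str, int]
    frequencies: dict[str, dict[str, float]]
    motif_positions: dict[str, dict[str, list[tuple[str, int]]]]

    def observed_matrix(self, db: str) -> np.ndarray:
        return np.array(
            [[self.observed[db][f][x] for x in AMINO_ACIDS] for f in self.families],
            dtype=float,
        )

    def expected_matrix(self, db: str) -> np.ndarray:
        return np.array(
            [[self.expected[db][f][x] for x in AMINO_ACIDS] for f in self.families],
            dtype=float,
        )


def expected_count(
    query: MotifQuery,
    frequencies: dict[str, float],
    total_windows: int,
) -> float:
    """Independence-null expectation N = M * prod_q p(position q).

    For a set-valued position the probability is the sum of its member
    frequencies.  Assumes residues appear independently of their
    neighbours (no co-evolutionary coupling).
    """
    if total_windows < 0:
        raise ValueError("total_windows must be >= 0")
    p = 1.0
    for s in query.positions:
        p *= sum(frequencies.get(a, 0.0) for a in s)
    return total_windows * p


def census(
    proteome: ProteomeSet,
    mask: DisorderMask,
    families: list[MotifQuery] | None = None,
) -> CensusResult:
    """Count motifs per (family, central residue) in the whole proteome
    and its disordered segments; structured counts follow by subtraction.

    Every family must be a tripeptide query whose central position is
    iterated over the 20 amino acids (the family's own central set is
    replaced by each candidate x in turn).
    """
    if families is None:
        families = default_families()
    mask.validate_against(proteome)
    fam_names = [f.name for f in families]

    observed = {
        db: {f: {x: 0 for x in AMINO_ACIDS} for f in fam_names} for db in DATABASES
    }
    positions: dict[str, dict[str, list[tuple[str, int]]]] = {
        db: {f: [] for f in fam_names} for db in ("proteome", "disordered")
    }
    aa_counts = {db: {a: 0 for a in AMINO_ACIDS} for db in DATABASES}
    total_windows = {db: 0 for db in DATABASES}

    aa_codes = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for fam in families:
        if fam.n != 3:
            raise ValueError("census families must be tripeptide queries")

    for pid, seq in proteome.records.items():
        raw_ivals = mask.intervals.get(pid, [])
        # contiguous intervals form one disordered region
        ivals: list[tuple[int, int]] = []
        for a, b in raw_ivals:
            if ivals and a <= ivals[-1][1]:
                ivals[-1] = (ivals[-1][0], max(ivals[-1][1], b))
            else:
                ivals.append((a, b))
        n_len = 3
        total_windows["proteome"] += max(len(seq) - n_len + 1, 0)
        for a, b in ivals:
            total_windows["disordered"] += max(b - a - n_len + 1, 0)
        in_disorder = np.zeros(len(seq), dtype=bool)
        for a, b in ivals:
            in_disorder[a:b] = True

        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        valid = np.isin(arr, aa_codes)
        for db_mask, db in ((in_disorder, "disordered"), (~in_disorder, "structured")):
            sub = arr[valid & db_mask]
            if sub.size:
                codes, cnts = np.unique(sub, return_counts=True)
                for code, cnt in zip(codes, cnts):
                    aa = chr(code)
                    aa_counts["proteome"][aa] += int(cnt)
                    aa_counts[db][aa] += int(cnt)

        if len(seq) < 3:
            continue
        window_disordered = in_disorder[:-2] & in_disorder[1:-1] & in_disorder[2:]
        central_ok = valid[1:-1]
        for fam in families:
            left, _, right = fam.positions
            lcodes = np.frombuffer("".join(sorted(left)).encode(), dtype=np.uint8)
            rcodes = np.frombuffer("".join(sorted(right)).encode(), dtype=np.uint8)
            hit = (
                np.isin(arr[:-2], lcodes)
                & np.isin(arr[2:], rcodes)
                & central_ok
            )
            starts = np.nonzero(hit)[0]
            for i in starts:
                x = seq[i + 1]
                observed["proteome"][fam.name][x] += 1
                positions["proteome"][fam.name].append((pid, int(i)))
                if window_disordered[i]:
                    observed["disordered"][fam.name][x] += 1
                    positions["disordered"][fam.name].append((pid, int(i)))

    total_windows["structured"] = (
        total_windows["proteome"] - total_windows["disordered"]
    )
    for f in fam_names:
        for x in AMINO_ACIDS:
            observed["structured"][f][x] = (
                observed["proteome"][f][x] - observed["disordered"][f][x]
            )

    frequencies = {db: _aa_frequencies(aa_counts[db]) for db in DATABASES}

    expected: dict[str, dict[str, dict[str, float]]] = {}
    for db in DATABASES:
        expected[db] = {}
        for fam in families:
            expected[db][fam.name] = {}
            for x in AMINO_ACIDS:
                q = MotifQuery(
                    (fam.positions[0], frozenset(x), fam.positions[2]),
                    name=f"{fam.name}|{x}",
                )
                expected[db][fam.name][x] = expected_count(
                    q, frequencies[db], total_windows[db]
                )

    return CensusResult(
        families=fam_names,
        observed=observed,
        expected=expected,
        total_windows=total_windows,
        frequencies=frequencies,
        motif_positions=positions,
    )


def chi_square_total(
    observed: np.ndarray,
    expected: np.ndarray,
) -> tuple[float, int, float]:
    """Total chi-square over families x central residues.

    chi2_tot = sum_j sum_i (obs_ij - exp_ij)^2 / exp_ij with
    nu = n_cells - n_families degrees of freedom (one totals constraint
    per motif family), and the upper-tail p-value from the chi-square
    survival function.  Raises on any zero expected cell.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected shapes differ")
    if np.any(expected <= 0):
        raise ValueError(
            "zero expected count in a cell; merge or drop it explicitly"
        )
    chi2_tot = float(np.sum((observed - expected) ** 2 / expected))
    n_fam = observed.shape[0] if observed.ndim == 2 else 1
    nu = observed.size - n_fam
    p = float(chi2_dist.sf(chi2_tot, nu))
    return chi2_tot, nu, p


def chi_square_per_family(
    result: CensusResult, db: str
) -> dict[str, float]:
    """Per-family chi-square over the 20 central residues."""
    out = {}
    for f in result.families:
        obs = np.array([result.observed[db][f][x] for x in AMINO_ACIDS], float)
        exp = np.array([result.expected[db][f][x] for x in AMINO_ACIDS], float)
        if np.any(exp <= 0):
            raise ValueError(f"zero expected count in family {f}")
        out[f] = float(np.sum((obs - exp) ** 2 / exp))
    return out


def enrichment_profile(result: CensusResult) -> dict[str, float]:
    """Percentage-point enrichment of each central residue x.

    For each x: (share of disordered [V/I]x[V/I] motifs with centre x)
    minus (same share among structured motifs), in percent.  Positive
    values mark centres over-represented in disordered regions; the
    profile sums to zero.
    """
    shares = {}
    for db in ("disordered", "structured"):
        tot = sum(
            result.observed[db][f][x] for f in result.families for x in AMINO_ACIDS
        )
        shares[db] = {
            x: (
                100.0
                * sum(result.observed[db][f][x] for f in result.families)
                / tot
                if tot
                else 0.0
            )
            for x in AMINO_ACIDS
        }
    return {x: shares["disordered"][x] - shares["structured"][x] for x in AMINO_ACIDS}


def intersect_interactors(
    binder_ids: list[str],
    result: CensusResult,
    proteome: ProteomeSet,
    family_names: tuple[str, ...] = ("IxI", "IxV", "VxI", "VxV"),
    central: str = "P",
    db: str = "disordered",
) -> tuple[dict[str, int], list[str]]:
    """Binders carrying >= 1 qualifying motif (default: disordered
    [V/I]P[V/I]).

    Returns ``(counts, unknown)`` where ``counts`` maps each qualifying
    binder id to its motif count (> 1 flags multi-motif proteins) and
    ``unknown`` lists ids absent from the proteome (reported, never
    silently dropped).
    """
    unknown = [b for b in binder_ids if b not in proteome.records]
    known = [b for b in binder_ids if b in proteome.records]
    per_protein: dict[str, int] = {}
    for f in family_names:
        for pid, start in result.motif_positions[db][f]:
            seq = proteome.records[pid]
            if seq[start + 1] == central:
                per_protein[pid] = per_protein.get(pid, 0) + 1
    counts = {b: per_protein[b] for b in known if b in per_protein}
    return counts, unknown
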