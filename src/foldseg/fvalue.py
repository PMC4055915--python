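"""F-value analysis: coarse-grained Metropolis Monte Carlo on a Cα bead chain.

Each pair (i, j) with |i - j| >= 2 feels a Gaussian restraint toward its
statistical mean distance,

    epsilon(i, j) / kT = (r - rbar)^2 / (2 sigma^2) + const,

where rbar/sigma come from the distance statistics via the residue types and
the separation range M.  The pair constant is conformation-independent and
cancels in Metropolis ratios, so the reduced energy used throughout is the
bare quadratic; the Metropolis temperature kT scales that reduced energy
and is calibrated so the acceptance ratio hits a target (0.5).

A sweep visits each joint i = 1..N-1 once, perturbing the local bend and
torsion angles by independent uniform draws in [-10 deg, +10 deg], rigidly
rotating the downstream segment (bond lengths are exactly conserved), and
applying the Metropolis test.  Contact indicators (Ca-Ca distance below a
cutoff) accumulated over sampled conformations give the contact frequency
g(i, j); range-wise z-scoring of g gives Q(i, j), and the per-residue sums
F_i = sum_j Q(i, j) form the F profile whose interior peaks mark putative
hydrophobic-cluster centers at folding initiation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from foldseg.distance_stats import DistanceStatistics, range_of_separation
from foldseg.structure_io import SequenceRecord

logger = logging.getLogger(__name__)

VIRTUAL_BOND_LENGTH = 3.8  # Å, trans Ca-Ca distance
DEFAULT_MAX_ANGLE = 10.0  # degrees, move amplitude for bend and torsion
DEFAULT_CONTACT_CUTOFF = 8.0  # Å, simulation-time contact radius
DEFAULT_BURN_IN_FRACTION = 0.1
DEFAULT_TARGET_ACCEPTANCE = 0.5
DEFAULT_TERMINAL_EXCLUSION = 5
SIGMA_FLOOR = 0.1  # Å, lower bound on sigma to keep forces finite


@dataclass
class ChainState:
    """A fixed-bond-length Cα bead chain.

    Holds the Cartesian coordinates plus a cached inter-bead distance matrix
    that the sweep keeps in sync with the coordinates.
    """

    coordinates: np.ndarray  # (N, 3) Å
    virtual_bond_length: float = VIRTUAL_BOND_LENGTH
    _distances: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")

    @property
    def n_residues(self) -> int:
        return self.coordinates.shape[0]

    @property
    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coordinates, axis=0), axis=1)

    @property
    def bond_angles(self) -> np.ndarray:
        """Bond angle (degrees) at each interior residue."""
        v = np.diff(self.coordinates, axis=0)
        a, b = -v[:-1], v[1:]
        cos = (a * b).sum(axis=1) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))

    @property
    def dihedral_angles(self) -> np.ndarray:
        """Torsion angle (degrees) around each interior virtual bond."""
        b = np.diff(self.coordinates, axis=0)
        b0, b1, b2 = b[:-2], b[1:-1], b[2:]
        n1 = np.cross(b0, b1)
        n2 = np.cross(b1, b2)
        m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=1, keepdims=True))
        x = (n1 * n2).sum(axis=1)
        y = (m1 * n2).sum(axis=1)
        # sign convention matches build_chain_from_angles (NeRF frame)
        return np.degrees(np.arctan2(-y, x))

    @property
    def distances(self) -> np.ndarray:
        if self._distances is None:
            self._distances = cdist(self.coordinates, self.coordinates)
        return self._distances

    def invalidate(self) -> None:
        self._distances = None


def build_chain_from_angles(
    bond_angles_deg: np.ndarray,
    dihedral_angles_deg: np.ndarray,
    bond_length: float = VIRTUAL_BOND_LENGTH,
) -> np.ndarray:
    """Cartesian coordinates from internal coordinates (NeRF-style placement).

    ``bond_angles_deg`` has N-2 entries (angle at residues 2..N-1),
    ``dihedral_angles_deg`` has N-3 entries.
    """
    n = len(bond_angles_deg) + 2
    if len(dihedral_angles_deg) != max(n - 3, 0):
        raise ValueError("need N-2 bond angles and N-3 dihedrals")
    coords = np.zeros((n, 3))
    coords[1] = [bond_length, 0.0, 0.0]
    if n == 2:
        return coords
    theta0 = math.radians(bond_angles_deg[0])
    coords[2] = coords[1] + bond_length * np.array(
        [-math.cos(theta0), math.sin(theta0), 0.0]
    )
    for k in range(3, n):
        theta = math.radians(bond_angles_deg[k - 2])
        phi = math.radians(dihedral_angles_deg[k - 3])
        a, b_, c = coords[k - 3], coords[k - 2], coords[k - 1]
        bc = c - b_
        bc /= np.linalg.norm(bc)
        n_vec = np.cross(b_ - a, bc)
        norm = np.linalg.norm(n_vec)
        if norm < 1e-12:  # collinear history: pick any perpendicular
            n_vec = _any_perpendicular(bc)
        else:
            n_vec /= norm
        m_vec = np.cross(n_vec, bc)
        d = (
            -bc * math.cos(theta)
            + m_vec * math.sin(theta) * math.cos(phi)
            + n_vec * math.sin(theta) * math.sin(phi)
        )
        coords[k] = c + bond_length * d
    return coords


def random_chain(
    n: int,
    rng: np.random.Generator,
    bond_length: float = VIRTUAL_BOND_LENGTH,
    bend_range: tuple[float, float] = (60.0, 160.0),
) -> ChainState:
    """Chain with random bond and dihedral angles (the random initial conformation)."""
    if n < 2:
        raise ValueError("chain needs at least 2 residues")
    angles = rng.uniform(*bend_range, size=max(n - 2, 0))
    dihedrals = rng.uniform(-180.0, 180.0, size=max(n - 3, 0))
    return ChainState(build_chain_from_angles(angles, dihedrals, bond_length), bond_length)


@dataclass
class PairPotential:
    """Per-pair Gaussian restraint parameters derived from distance statistics."""

    sequence: str
    rbar: np.ndarray  # (N, N) mean distances, 0 where unused
    weight: np.ndarray  # (N, N) = 1/(2 sigma^2), 0 for |i-j| < 2
    sigma: np.ndarray  # (N, N) floored sigma

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_statistics(
        cls,
        sequence: SequenceRecord | str,
        stats: DistanceStatistics,
        sigma_floor: float = SIGMA_FLOOR,
    ) -> "PairPotential":
        seq = sequence.sequence if isinstance(sequence, SequenceRecord) else sequence
        n = len(seq)
        rbar = np.zeros((n, n))
        sigma = np.zeros((n, n))
        weight = np.zeros((n, n))
        for i in range(n - 2):
            for j in range(i + 2, n):
                mean, sd = stats.lookup(seq[i], seq[j], range_of_separation(j - i))
                sd = max(sd, sigma_floor)
                rbar[i, j] = rbar[j, i] = mean
                sigma[i, j] = sigma[j, i] = sd
                weight[i, j] = weight[j, i] = 1.0 / (2.0 * sd * sd)
        return cls(seq, rbar, weight, sigma)


def pair_energy(r: float, rbar: float, sigma: float, kT: float = 1.0) -> float:
    """Gaussian pair energy kT (r - rbar)^2 / (2 sigma^2).

    The conformation-independent pair constant -kT ln(Z / (sqrt(2 pi) sigma))
    is omitted: it cancels in every Metropolis energy difference.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return kT * (r - rbar) ** 2 / (2.0 * sigma * sigma)


def reduced_energy(state: ChainState, potential: PairPotential) -> float:
    """Total reduced energy: sum over pairs of (r - rbar)^2 / (2 sigma^2)."""
    d = state.distances
    iu = np.triu_indices(state.n_residues, k=2)
    return float(((d[iu] - potential.rbar[iu]) ** 2 * potential.weight[iu]).sum())


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    perp = np.cross(v, ref)
    return perp / np.linalg.norm(perp)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    t = 1.0 - c
    return np.array(
        [
            [t * x * x + c, t * x * y - s * z, t * x * z + s * y],
            [t * x * y + s * z, t * y * y + c, t * y * z - s * x],
            [t * x * z - s * y, t * y * z + s * x, t * z * z + c],
        ]
    )


def _sweep_numpy(
    coords: np.ndarray,
    dist: np.ndarray,
    rbar: np.ndarray,
    weight: np.ndarray,
    kT: float,
    deltas: np.ndarray,
    uniforms: np.ndarray,
) -> int:
    n = coords.shape[0]
    accepted = 0
    for p in range(n - 1):  # pivot residue index (0-based); downstream = p+1..N-1
        pivot = coords[p]
        bond_prev = coords[p] - coords[p - 1] if p > 0 else coords[p + 1] - coords[p]
        u_tors = bond_prev / np.linalg.norm(bond_prev)
        bond_next = coords[p + 1] - coords[p]
        bend_axis = np.cross(u_tors, bond_next)
        norm = np.linalg.norm(bend_axis)
        bend_axis = bend_axis / norm if norm > 1e-9 else _any_perpendicular(u_tors)
        d_bend, d_tors = deltas[p]
        rot = _rotation_matrix(u_tors, d_tors) @ _rotation_matrix(bend_axis, d_bend)
        moved = (coords[p + 1 :] - pivot) @ rot.T + pivot
        up = coords[: p + 1]
        diff = up[:, None, :] - moved[None, :, :]
        d_new = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        d_old = dist[: p + 1, p + 1 :]
        w = weight[: p + 1, p + 1 :]
        rb = rbar[: p + 1, p + 1 :]
        delta_e = float((w * ((d_new - rb) ** 2 - (d_old - rb) ** 2)).sum())
        if delta_e <= 0.0 or uniforms[p] < math.exp(-delta_e / kT):
            coords[p + 1 :] = moved
            dist[: p + 1, p + 1 :] = d_new
            dist[p + 1 :, : p + 1] = d_new.T
            accepted += 1
    return accepted


try:  # compiled inner loop; the numpy path above is the reference fallback
    from numba import njit

    @njit(cache=True)
    def _sweep_numba(coords, dist, rbar, weight, kT, deltas, uniforms):  # pragma: no cover
        n = coords.shape[0]
        accepted = 0
        newc = np.empty((n, 3))
        dnew = np.empty((n, n))
        for p in range(n - 1):
            px, py, pz = coords[p, 0], coords[p, 1], coords[p, 2]
            if p > 0:
                ux, uy, uz = px - coords[p - 1, 0], py - coords[p - 1, 1], pz - coords[p - 1, 2]
            else:
                ux, uy, uz = coords[1, 0] - px, coords[1, 1] - py, coords[1, 2] - pz
            un = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux, uy, uz = ux / un, uy / un, uz / un
            vx, vy, vz = coords[p + 1, 0] - px, coords[p + 1, 1] - py, coords[p + 1, 2] - pz
            ax = uy * vz - uz * vy
            ay = uz * vx - ux * vz
            az = ux * vy - uy * vx
            an = math.sqrt(ax * ax + ay * ay + az * az)
            if an > 1e-9:
                ax, ay, az = ax / an, ay / an, az / an
            else:  # collinear bonds: any perpendicular to u works
                if abs(ux) < 0.9:
                    ax, ay, az = 0.0, uz, -uy
                else:
                    ax, ay, az = -uz, 0.0, ux
                an = math.sqrt(ax * ax + ay * ay + az * az)
                ax, ay, az = ax / an, ay / an, az / an
            d_bend = deltas[p, 0]
            d_tors = deltas[p, 1]
            # R = R(u, d_tors) @ R(a, d_bend)
            c1, s1 = math.cos(d_tors), math.sin(d_tors)
            t1 = 1.0 - c1
            r1 = np.empty((3, 3))
            r1[0, 0] = t1 * ux * ux + c1
            r1[0, 1] = t1 * ux * uy - s1 * uz
            r1[0, 2] = t1 * ux * uz + s1 * uy
            r1[1, 0] = t1 * ux * uy + s1 * uz
            r1[1, 1] = t1 * uy * uy + c1
            r1[1, 2] = t1 * uy * uz - s1 * ux
            r1[2, 0] = t1 * ux * uz - s1 * uy
            r1[2, 1] = t1 * uy * uz + s1 * ux
            r1[2, 2] = t1 * uz * uz + c1
            c2, s2 = math.cos(d_bend), math.sin(d_bend)
            t2 = 1.0 - c2
            r2 = np.empty((3, 3))
            r2[0, 0] = t2 * ax * ax + c2
            r2[0, 1] = t2 * ax * ay - s2 * az
            r2[0, 2] = t2 * ax * az + s2 * ay
            r2[1, 0] = t2 * ax * ay + s2 * az
            r2[1, 1] = t2 * ay * ay + c2
            r2[1, 2] = t2 * ay * az - s2 * ax
            r2[2, 0] = t2 * ax * az - s2 * ay
            r2[2, 1] = t2 * ay * az + s2 * ax
            r2[2, 2] = t2 * az * az + c2
            rot = r1 @ r2
            for b in range(p + 1, n):
                dx = coords[b, 0] - px
                dy = coords[b, 1] - py
                dz = coords[b, 2] - pz
                newc[b, 0] = rot[0, 0] * dx + rot[0, 1] * dy + rot[0, 2] * dz + px
                newc[b, 1] = rot[1, 0] * dx + rot[1, 1] * dy + rot[1, 2] * dz + py
                newc[b, 2] = rot[2, 0] * dx + rot[2, 1] * dy + rot[2, 2] * dz + pz
            de = 0.0
            for a in range(p + 1):
                for b in range(p + 1, n):
                    ddx = coords[a, 0] - newc[b, 0]
                    ddy = coords[a, 1] - newc[b, 1]
                    ddz = coords[a, 2] - newc[b, 2]
                    dn = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                    dnew[a, b] = dn
                    w = weight[a, b]
                    if w > 0.0:
                        r0 = rbar[a, b]
                        de += w * ((dn - r0) ** 2 - (dist[a, b] - r0) ** 2)
            if de <= 0.0 or uniforms[p] < math.exp(-de / kT):
                accepted += 1
                for b in range(p + 1, n):
                    coords[b, 0] = newc[b, 0]
                    coords[b, 1] = newc[b, 1]
                    coords[b, 2] = newc[b, 2]
                for a in range(p + 1):
                    for b in range(p + 1, n):
                        dist[a, b] = dnew[a, b]
                        dist[b, a] = dnew[a, b]
        return accepted

    _SWEEP_KERNEL = _sweep_numba
except ImportError:  # pragma: no cover
    _SWEEP_KERNEL = _sweep_numpy


def sweep(
    state: ChainState,
    potential: PairPotential,
    kT: float,
    rng: np.random.Generator,
    max_angle_deg: float = DEFAULT_MAX_ANGLE,
) -> int:
    """One Monte-Carlo sweep: N-1 joint moves in order; returns accepted count.

    At joint i (pivot residue i, 1-based) the local bend and torsion angles
    each get an independent uniform perturbation in [-max_angle, +max_angle];
    the downstream segment rotates rigidly about the pivot, so all bond
    lengths are conserved exactly.  Acceptance is min(1, exp(-dE/kT)) on the
    reduced energy.  All randomness for the sweep (N-1 angle pairs plus N-1
    acceptance uniforms) is drawn up-front from ``rng``.
    """
    amp = math.radians(max_angle_deg)
    n = state.n_residues
    deltas = rng.uniform(-amp, amp, size=(n - 1, 2))
    uniforms = rng.random(n - 1)
    return int(
        _SWEEP_KERNEL(
            state.coordinates,
            state.distances,
            potential.rbar,
            potential.weight,
            float(kT),
            deltas,
            uniforms,
        )
    )


def calibrate_kT(
    potential: PairPotential,
    rng: np.random.Generator,
    target_ratio: float = DEFAULT_TARGET_ACCEPTANCE,
    tolerance: float = 0.02,
    pilot_sweeps: int = 800,
    max_iterations: int = 20,
    max_angle_deg: float = DEFAULT_MAX_ANGLE,
    bond_length: float = VIRTUAL_BOND_LENGTH,
) -> float:
    """Bisection on log kT until the pilot acceptance ratio hits the target.

    Each evaluation runs ``pilot_sweeps`` sweeps from a fresh random chain
    and measures acceptance over the second half (the first half serves as
    equilibration at the candidate kT).
    """
    if not 0.0 < target_ratio < 1.0:
        raise ValueError("target_ratio must be in (0, 1)")
    n = potential.n_residues

    def measured_acceptance(kT: float) -> float:
        chain = random_chain(n, rng, bond_length)
        half = pilot_sweeps // 2
        for _ in range(half):
            sweep(chain, potential, kT, rng, max_angle_deg)
        acc = sum(sweep(chain, potential, kT, rng, max_angle_deg) for _ in range(pilot_sweeps - half))
        return acc / ((pilot_sweeps - half) * (n - 1))

    # expand to bracket the target on log kT
    lo, hi = None, None
    kT = 1.0
    evaluations = 0
    acc = measured_acceptance(kT)
    evaluations += 1
    if abs(acc - target_ratio) <= tolerance:
        return kT
    if acc < target_ratio:
        lo, acc_lo = kT, acc
        while evaluations < max_iterations:
            kT *= 8.0
            acc = measured_acceptance(kT)
            evaluations += 1
            if abs(acc - target_ratio) <= tolerance:
                return kT
            if acc > target_ratio:
                hi = kT
                break
            lo = kT
        if hi is None:
            raise RuntimeError(
                f"failed to bracket target acceptance {target_ratio} after "
                f"{evaluations} evaluations (last kT={kT:g}, acc={acc:.3f})"
            )
    else:
        hi, acc_hi = kT, acc
        while evaluations < max_iterations:
            kT /= 8.0
            acc = measured_acceptance(kT)
            evaluations += 1
            if abs(acc - target_ratio) <= tolerance:
                return kT
            if acc < target_ratio:
                lo = kT
                break
            hi = kT
        if lo is None:
            raise RuntimeError(
                f"failed to bracket target acceptance {target_ratio} after "
                f"{evaluations} evaluations (last kT={kT:g}, acc={acc:.3f})"
            )
    best_kT, best_err = kT, abs(acc - target_ratio)
    while evaluations < max_iterations:
        mid = math.sqrt(lo * hi)
        acc = measured_acceptance(mid)
        evaluations += 1
        err = abs(acc - target_ratio)
        if err < best_err:
            best_kT, best_err = mid, err
        if err <= tolerance:
            return mid
        if acc < target_ratio:
            lo = mid
        else:
            hi = mid
    logger.warning(
        "kT calibration stopped at |acc-target|=%.3f > tolerance %.3f; returning best kT=%g",
        best_err,
        tolerance,
        best_kT,
    )
    return best_kT


@dataclass
class ContactFrequencyMap:
    """Fraction of sampled conformations with each pair in contact."""

    g: np.ndarray  # (N, N) symmetric in [0, 1], zero for |i-j| < 2
    n_samples: int
    contact_cutoff: float
    production_acceptance: float
    kT_values: list[float] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return self.g.shape[0]


def run_simulation(
    sequence: SequenceRecord | str,
    stats: DistanceStatistics,
    n_steps: int = 60000,
    n_runs: int = 100,
    seed: int = 0,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    bond_length: float = VIRTUAL_BOND_LENGTH,
    max_angle_deg: float = DEFAULT_MAX_ANGLE,
    burn_in_fraction: float = DEFAULT_BURN_IN_FRACTION,
    target_acceptance: float = DEFAULT_TARGET_ACCEPTANCE,
    kT: float | None = None,
    sigma_floor: float = SIGMA_FLOOR,
) -> ContactFrequencyMap:
    """Full contact-frequency simulation: independent runs averaged into g.

    Each run starts from a random conformation, calibrates kT (unless one is
    supplied), discards the burn-in fraction of sweeps, then accumulates the
    contact indicator (Ca-Ca distance <= cutoff, |i-j| >= 2) every sweep.
    Reproducible bit-for-bit from the seed: per-run substreams are spawned
    deterministically from one seed sequence.
    """
    seq = sequence.sequence if isinstance(sequence, SequenceRecord) else sequence
    n = len(seq)
    if n < 10:
        raise ValueError(f"chain too short for simulation ({n} < 10)")
    potential = PairPotential.from_statistics(seq, stats, sigma_floor)
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    eligible = sep >= 2
    counts = np.zeros((n, n))
    burn_in = int(burn_in_fraction * n_steps)
    n_recorded = n_steps - burn_in
    if n_recorded <= 0:
        raise ValueError("burn-in leaves no production sweeps")
    streams = np.random.SeedSequence(seed).spawn(n_runs)
    kT_values: list[float] = []
    accepted_prod = 0
    for run, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        kT_run = kT if kT is not None else calibrate_kT(
            potential,
            rng,
            target_ratio=target_acceptance,
            max_angle_deg=max_angle_deg,
            bond_length=bond_length,
        )
        kT_values.append(kT_run)
        chain = random_chain(n, rng, bond_length)
        for s in range(n_steps):
            acc = sweep(chain, potential, kT_run, rng, max_angle_deg)
            if s >= burn_in:
                accepted_prod += acc
                counts += (chain.distances <= contact_cutoff) & eligible
        logger.debug("run %d: kT=%g", run, kT_run)
    g = counts / (n_recorded * n_runs)
    production_acceptance = accepted_prod / (n_recorded * n_runs * (n - 1))
    return ContactFrequencyMap(
        g=g,
        n_samples=n_recorded * n_runs,
        contact_cutoff=contact_cutoff,
        production_acceptance=production_acceptance,
        kT_values=kT_values,
    )


def normalize_contacts(g: np.ndarray) -> np.ndarray:
    """Range-wise z-scoring of the contact frequencies.

    For each separation range M, over pairs with |i-j| in M (and >= 2):
    D_M is the population SD of g and Q = (g - mean_M) / D_M; a range with
    zero variance gets Q = 0.  Q sums to zero within every range.
    """
    g = np.asarray(g, dtype=float)
    n = g.shape[0]
    q = np.zeros_like(g)
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    max_m = range_of_separation(n - 1)
    for M in range(1, max_m + 1):
        iu = np.triu_indices(n, k=2)
        mask = np.zeros((n, n), dtype=bool)
        mask[iu] = True
        in_range = np.array(
            [range_of_separation(int(k)) == M for k in sep[mask]]
        )
        rows, cols = iu[0][in_range], iu[1][in_range]
        if rows.size == 0:
            continue
        values = g[rows, cols]
        if np.ptp(values) == 0.0:  # constant within the range: Q = 0 there
            continue
        d_m = values.std()
        if d_m == 0.0:
            continue
        z = (values - values.mean()) / d_m
        q[rows, cols] = z
        q[cols, rows] = z
    return q


@dataclass
class FProfile:
    """Per-residue relative contact frequency F_i with detected interior peaks."""

    Q: np.ndarray
    F: np.ndarray
    peaks: list[int]  # 1-based residue positions
    terminal_exclusion: int


def f_profile(
    Q: np.ndarray,
    terminal_exclusion: int = DEFAULT_TERMINAL_EXCLUSION,
    window: int = 2,
) -> FProfile:
    """F_i = sum_j Q(i, j); peaks are strict local maxima over a +-window.

    Peaks within ``terminal_exclusion`` residues of either terminus are
    discarded (terminal F values are artificially inflated by end
    flexibility).
    """
    Q = np.asarray(Q, dtype=float)
    F = Q.sum(axis=1)
    n = F.size
    peaks = []
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        neighbors = np.delete(F[lo:hi], i - lo)
        if neighbors.size and np.all(F[i] > neighbors):
            pos = i + 1
            if terminal_exclusion < pos <= n - terminal_exclusion:
                peaks.append(pos)
    return FProfile(Q=Q, F=F, peaks=peaks, terminal_exclusion=terminal_exclusion)


def match_peaks(
    peaks_a: list[int], peaks_b: list[int], tolerance: int = 3
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy nearest matching of two peak lists within a residue tolerance.

    Returns (matched pairs, unmatched from a, unmatched from b); every peak
    is used at most once and pairs are taken globally nearest-first.
    """
    pairs = sorted(
        (
            (abs(a - b), a, b)
            for a in peaks_a
            for b in peaks_b
            if abs(a - b) <= tolerance
        ),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, a, b in pairs:
        if a in used_a or b in used_b:
            continue
        matched.append((a, b))
        used_a.add(a)
        used_b.add(b)
    unmatched_a = [a for a in peaks_a if a not in used_a]
    unmatched_b = [b for b in peaks_b if b not in used_b]
    return matched, unmatched_a, unmatched_b
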