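"""Shrake-Rupley solvent accessibility and SASA-loss hydrophobic contacts.

Per-atom SASA is estimated by sampling a deterministic golden-spiral point
lattice on each atom's probe-expanded sphere and counting points not buried
inside any neighbour's expanded sphere.  A hydrophobic residue pair is a
native contact when removing one residue's atoms raises the other's
side-chain SASA by at least a threshold (default 27 A^2, the burial of one
carbon by another at van-der-Waals contact, 27.27 A^2 analytically).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from foldseg.structure_io import ProteinStructure

logger = logging.getLogger(__name__)

PROBE_RADIUS = 1.4  # Å, water probe
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70  # fallback for unusual heavy elements
DEFAULT_N_POINTS = 960
CONTACT_THRESHOLD = 27.0  # Å^2, SASA decrease defining a contact
HYDROPHOBIC_RESIDUES = frozenset("AMWLFVIY")
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
DEFAULT_SMOOTHING_BANDWIDTH = 2.0  # residues


@dataclass
class SphereSet:
    """Atoms as spheres plus the probe radius and sampling density."""

    elements: list[str]
    centers: np.ndarray  # (n, 3) Å
    radii: np.ndarray  # (n,) vdW radii Å
    probe_radius: float = PROBE_RADIUS
    n_points: int = DEFAULT_N_POINTS

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("vdW radii must be positive")
        if self.n_points < 100:
            raise ValueError("need at least 100 sphere points")

    @classmethod
    def from_structure(
        cls,
        structure: ProteinStructure,
        probe_radius: float = PROBE_RADIUS,
        n_points: int = DEFAULT_N_POINTS,
    ) -> "SphereSet":
        elements, centers = [], []
        for res in structure.residues:
            for atom in res.heavy_atoms:
                elements.append(atom.element)
                centers.append(atom.coord)
        radii = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements])
        return cls(elements, np.array(centers), radii, probe_radius, n_points)


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (evenly spaced in z)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = math.pi * (3.0 - math.sqrt(5.0)) * k
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    spheres: SphereSet, subset: np.ndarray | None = None
) -> np.ndarray:
    """Per-atom SASA (Å^2) via point sampling on the probe-expanded spheres.

    ``subset`` optionally restricts which atoms get a SASA value (occluders
    are always the full set); the returned array then has one entry per
    subset index.  Deterministic: the point lattice is fixed.
    """
    centers = spheres.centers
    expanded = spheres.radii + spheres.probe_radius
    n_atoms = centers.shape[0]
    idx = np.arange(n_atoms) if subset is None else np.asarray(subset, dtype=int)
    points = golden_spiral_points(spheres.n_points)
    tree = cKDTree(centers)
    max_reach = expanded.max()
    out = np.zeros(idx.size)
    for out_i, i in enumerate(idx):
        r_i = expanded[i]
        neighbor_ids = [
            j
            for j in tree.query_ball_point(centers[i], r_i + max_reach)
            if j != i and np.linalg.norm(centers[j] - centers[i]) < r_i + expanded[j]
        ]
        for j in neighbor_ids:
            if np.linalg.norm(centers[j] - centers[i]) < 1e-9:
                raise ValueError(f"coincident atom centers at indices {i} and {j}")
        surface = centers[i] + r_i * points
        accessible = np.ones(spheres.n_points, dtype=bool)
        for j in neighbor_ids:
            d2 = ((surface - centers[j]) ** 2).sum(axis=1)
            accessible &= d2 >= expanded[j] ** 2
        out[out_i] = accessible.mean() * 4.0 * math.pi * r_i * r_i
    return out


def two_carbon_reference(
    probe_radius: float = PROBE_RADIUS, vdw_carbon: float = VDW_RADII["C"]
) -> float:
    """Analytic SASA loss on one carbon when a second sits at vdW contact.

    Two carbons at separation d = 2 vdw: the buried spherical cap on the
    expanded sphere (R = vdw + probe) has height h = R - d/2 and area 2 pi R h.
    Defaults give 27.27 Å^2, the threshold used for native contacts.
    """
    r_expanded = vdw_carbon + probe_radius
    h = r_expanded - vdw_carbon  # = R - d/2 with d = 2 vdw
    if h <= 0:
        return 0.0
    return 2.0 * math.pi * r_expanded * h


@dataclass
class NativeContactMap:
    """SASA-defined hydrophobic contacts of one structure.

    ``pairs`` maps (pos_i, pos_j) (1-based chain positions, i < j) to the
    two directional SASA losses (dsasa_i, dsasa_j); a pair is present iff
    max(dsasa) >= threshold.
    """

    pairs: dict[tuple[int, int], tuple[float, float]]
    threshold: float
    n_residues: int

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_residues, dtype=int)
        for i, j in self.pairs:
            deg[i - 1] += 1
            deg[j - 1] += 1
        return deg


def _sidechain_atom_indices(structure: ProteinStructure) -> dict[int, list[int]]:
    """Per residue position (1-based), flat indices of its side-chain heavy atoms."""
    out: dict[int, list[int]] = {}
    flat = 0
    for pos, res in enumerate(structure.residues, start=1):
        ids = []
        for atom in res.heavy_atoms:
            if atom.name.strip() not in BACKBONE_ATOMS:
                ids.append(flat)
            flat += 1
        out[pos] = ids
    return out


def sidechain_contacts(
    structure: ProteinStructure,
    threshold: float = CONTACT_THRESHOLD,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    max_pair_distance: float = 12.0,
) -> NativeContactMap:
    """Hydrophobic residue pairs in contact by the SASA-decrease criterion.

    For a candidate pair (i, j) the directional loss for i is the side-chain
    SASA of i computed with residue j's atoms deleted minus that in the full
    structure; the pair is a contact when either direction's loss reaches
    the threshold.  Glycines have no side-chain heavy atoms and are never in
    contact.  ``max_pair_distance`` (Cα-Cα) prunes hopeless pairs.
    """
    spheres = SphereSet.from_structure(structure, probe_radius, n_points)
    sidechains = _sidechain_atom_indices(structure)
    seq = structure.sequence
    n = len(seq)
    coords = structure.ca_coordinates
    hydrophobic = [
        pos for pos in range(1, n + 1) if seq[pos - 1] in HYDROPHOBIC_RESIDUES
    ]
    for pos in hydrophobic:
        if not sidechains[pos]:
            logger.info("residue %d (%s) has no side-chain heavy atoms", pos, seq[pos - 1])

    # flat atom index -> owning residue position
    owner = np.empty(sum(len(r.heavy_atoms) for r in structure.residues), dtype=int)
    flat = 0
    for pos, res in enumerate(structure.residues, start=1):
        for _ in res.heavy_atoms:
            owner[flat] = pos
            flat += 1

    full_sasa_cache: dict[int, np.ndarray] = {}

    def sidechain_sasa(pos: int, excluded_pos: int | None) -> float:
        ids = sidechains[pos]
        if not ids:
            return 0.0
        if excluded_pos is None:
            if pos not in full_sasa_cache:
                full_sasa_cache[pos] = shrake_rupley(spheres, subset=np.array(ids))
            return float(full_sasa_cache[pos].sum())
        keep = owner != excluded_pos
        sub = SphereSet(
            [e for e, k in zip(spheres.elements, keep) if k],
            spheres.centers[keep],
            spheres.radii[keep],
            probe_radius,
            n_points,
        )
        remap = np.cumsum(keep) - 1
        return float(shrake_rupley(sub, subset=remap[np.array(ids)]).sum())

    pairs: dict[tuple[int, int], tuple[float, float]] = {}
    for a_idx, i in enumerate(hydrophobic):
        for j in hydrophobic[a_idx + 1 :]:
            if not sidechains[i] or not sidechains[j]:
                continue
            if np.linalg.norm(coords[i - 1] - coords[j - 1]) > max_pair_distance:
                continue
            dsasa_i = sidechain_sasa(i, excluded_pos=j) - sidechain_sasa(i, None)
            dsasa_j = sidechain_sasa(j, excluded_pos=i) - sidechain_sasa(j, None)
            dsasa_i, dsasa_j = max(dsasa_i, 0.0), max(dsasa_j, 0.0)
            if max(dsasa_i, dsasa_j) >= threshold:
                pairs[(i, j)] = (dsasa_i, dsasa_j)
    return NativeContactMap(pairs=pairs, threshold=threshold, n_residues=n)


@dataclass
class ContactProfile:
    """Raw per-residue conserved-contact counts with a smoothed curve and peaks."""

    counts: np.ndarray  # non-negative integers
    smoothed: np.ndarray = field(default=None)  # type: ignore[assignment]
    peaks: list[int] = field(default_factory=list)  # 1-based positions


def conserved_contact_profile(
    contact_map: NativeContactMap, conserved_flags: np.ndarray
) -> ContactProfile:
    """Per-residue count of contacts whose both partners are conserved hydrophobic."""
    flags = np.asarray(conserved_flags, dtype=bool)
    if flags.size != contact_map.n_residues:
        raise ValueError("conserved flag length does not match structure length")
    counts = np.zeros(contact_map.n_residues, dtype=int)
    for i, j in contact_map.pairs:
        if flags[i - 1] and flags[j - 1]:
            counts[i - 1] += 1
            counts[j - 1] += 1
    return ContactProfile(counts=counts)


def smooth_profile(
    counts: np.ndarray, bandwidth: float = DEFAULT_SMOOTHING_BANDWIDTH
) -> ContactProfile:
    """Gaussian smoothing (reflecting edges) plus peak detection.

    The symmetric reflecting boundary keeps both the total mass and constant
    inputs unchanged.  Peaks are strict local maxima of the smoothed curve.
    """
    from scipy.ndimage import gaussian_filter1d

    counts = np.asarray(counts, dtype=float)
    n = counts.size
    smoothed = gaussian_filter1d(counts, sigma=bandwidth, mode="reflect", truncate=8.0)
    peaks = [
        i + 1
        for i in range(n)
        if (i == 0 or smoothed[i] > smoothed[i - 1])
        and (i == n - 1 or smoothed[i] > smoothed[i + 1])
        and 0 < i < n - 1
    ]
    return ContactProfile(counts=counts, smoothed=smoothed, peaks=peaks)
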