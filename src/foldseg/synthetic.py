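"""Synthetic fixtures: compact Cα chains, two-domain families with planted
block structure, alignments with controlled conservation, and small
heavy-atom arrangements with analytically known solvent burial.

Every generator is a pure function of its seed and returns its ground truth
alongside the data, so tests never have to re-derive what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from foldseg.adm import RegionAssignment
from foldseg.distance_stats import DistanceStatistics, build_statistics
from foldseg.structure_io import Alignment, Atom, ProteinStructure, Residue, SequenceRecord

HYDROPHOBIC = "AMWLFVIY"
OTHER_AA = "CDEGHKNPQRST"
NONHYDROPHOBIC = OTHER_AA  # letters that never count as hydrophobic
BOND_LENGTH = 3.8
MIN_SEPARATION = 3.0  # Å, self-avoidance distance between non-bonded beads
RG_COEFFICIENT = 2.2  # target radius of gyration = RG_COEFFICIENT * n^(1/3)


def _grow_chain(
    n: int,
    rng: np.random.Generator,
    centers: np.ndarray,
    container_radius: float,
    bond_length: float = BOND_LENGTH,
    min_separation: float = MIN_SEPARATION,
    candidates_per_step: int = 80,
) -> np.ndarray | None:
    """Self-avoiding fixed-bond random walk attracted to per-residue centers.

    ``centers`` is (n, 3): the blob center each bead is pulled toward.
    Returns None when growth gets stuck.
    """
    coords = np.empty((n, 3))
    coords[0] = centers[0] + rng.normal(scale=1.0, size=3)
    for i in range(1, n):
        cur = coords[i - 1]
        to_center = centers[i] - cur
        reach = np.linalg.norm(to_center)
        # pull harder the further the bead strays from its blob
        pull = min(2.5, 0.35 + reach / container_radius)
        placed = False
        for _ in range(candidates_per_step):
            direction = rng.normal(size=3) + pull * to_center / max(reach, 1e-9)
            direction /= np.linalg.norm(direction)
            candidate = cur + bond_length * direction
            if np.linalg.norm(candidate - centers[i]) > container_radius and reach <= container_radius:
                continue
            if i > 1:
                d = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
                if d.min() < min_separation:
                    continue
            coords[i] = candidate
            placed = True
            break
        if not placed:
            return None
    return coords


def _random_sequence(n: int, rng: np.random.Generator, hydrophobic_fraction: float = 0.6) -> str:
    letters = []
    for _ in range(n):
        if rng.random() < hydrophobic_fraction:
            letters.append(HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))])
        else:
            letters.append(OTHER_AA[rng.integers(len(OTHER_AA))])
    return "".join(letters)


def _to_structure(coords: np.ndarray, sequence: str, chain_id: str = "A") -> ProteinStructure:
    residues = [
        Residue(
            number=i + 1,
            amino_acid=aa,
            ca_coordinate=coords[i],
            heavy_atoms=[Atom("CA", "C", coords[i])],
        )
        for i, aa in enumerate(sequence)
    ]
    return ProteinStructure(chain_id=chain_id, residues=residues)


def make_compact_chain(
    n: int,
    seed: int,
    rg_coefficient: float = RG_COEFFICIENT,
    max_attempts: int = 40,
    max_reseeds: int = 3,
) -> ProteinStructure:
    """A compact self-avoiding Cα chain with a hydrophobic-rich random sequence.

    Bond lengths are exactly 3.8 Å, non-bonded beads keep >= 3.0 Å apart and
    the radius of gyration targets ``rg_coefficient * n^(1/3)`` Å.
    """
    if n < 20:
        raise ValueError(f"compact chain needs n >= 20, got {n}")
    target_rg = rg_coefficient * n ** (1.0 / 3.0)
    # a uniform ball of radius a has Rg = a sqrt(3/5); pad the container slightly
    container = target_rg / np.sqrt(3.0 / 5.0) * 1.12
    for reseed in range(max_reseeds + 1):
        rng = np.random.default_rng(seed + 1_000_003 * reseed)
        centers = np.zeros((n, 3))
        for _ in range(max_attempts):
            coords = _grow_chain(n, rng, centers, container)
            if coords is not None:
                sequence = _random_sequence(n, rng)
                return _to_structure(coords, sequence)
    raise RuntimeError(
        f"failed to grow a compact {n}-mer after {max_attempts} attempts x {max_reseeds + 1} seeds"
    )


@dataclass
class TwoDomainTruth:
    """Planted ground truth of a two-domain family."""

    n: int
    boundary: int  # last position of the first block (1-based)
    blocks: tuple[tuple[int, int], tuple[int, int]]
    block_alphabets: tuple[str, str]
    probe_sequence: str


BLOCK_A_ALPHABET = "AVLI"
BLOCK_B_ALPHABET = "FYWM"


def _block_sequence(
    n: int, boundary: int, rng: np.random.Generator
) -> str:
    first = [BLOCK_A_ALPHABET[rng.integers(4)] for _ in range(boundary)]
    second = [BLOCK_B_ALPHABET[rng.integers(4)] for _ in range(n - boundary)]
    return "".join(first + second)


def make_two_domain_family(
    n: int,
    boundary: int,
    n_structures: int,
    seed: int,
    blob_gap: float = 8.0,
) -> tuple[list[ProteinStructure], DistanceStatistics, TwoDomainTruth]:
    """Structures with two spatial blobs whose statistics encode the block split.

    Residues 1..boundary form one compact blob drawn from one residue
    alphabet; the rest form a second, spatially separated blob over a
    disjoint alphabet.  The two blobs are grown as independent compact
    sub-chains (the pseudo-bond across the boundary is a deliberate chain
    break), so intra-block distances are uniformly short at every separation
    range while inter-block distances are uniformly long.  The derived
    statistics therefore encode the planted block split exactly.
    """
    if not 0.2 * n <= boundary <= 0.8 * n:
        raise ValueError(f"boundary {boundary} outside [0.2 n, 0.8 n] for n={n}")
    rng = np.random.default_rng(seed)
    len_a, len_b = boundary, n - boundary
    # unpadded containers: keeps every intra-block expected distance safely
    # below the default ADM contact cutoff at all separation ranges
    rad_a = RG_COEFFICIENT * len_a ** (1.0 / 3.0) / np.sqrt(3.0 / 5.0)
    rad_b = RG_COEFFICIENT * len_b ** (1.0 / 3.0) / np.sqrt(3.0 / 5.0)
    separation = rad_a + rad_b + blob_gap
    offset_b = np.array([separation, 0.0, 0.0])
    structures: list[ProteinStructure] = []
    for _ in range(n_structures):
        blobs = []
        for length, radius, offset in (
            (len_a, rad_a, np.zeros(3)),
            (len_b, rad_b, offset_b),
        ):
            coords = None
            for _attempt in range(60):
                coords = _grow_chain(length, rng, np.zeros((length, 3)), radius)
                if coords is not None:
                    break
            if coords is None:
                raise RuntimeError("failed to grow a two-domain blob")
            blobs.append(coords - coords.mean(axis=0) + offset)
        structures.append(
            _to_structure(np.vstack(blobs), _block_sequence(n, boundary, rng))
        )
    stats = build_statistics(structures)
    probe = _block_sequence(n, boundary, rng)
    truth = TwoDomainTruth(
        n=n,
        boundary=boundary,
        blocks=((1, boundary), (boundary + 1, n)),
        block_alphabets=(BLOCK_A_ALPHABET, BLOCK_B_ALPHABET),
        probe_sequence=probe,
    )
    return structures, stats, truth


@dataclass
class MSASpec:
    """Recipe for a synthetic family alignment.

    ``conserved_sites`` are 0-based alignment sites planted as fully
    conserved hydrophobic positions; ``near_conserved_sites`` get the stated
    sub-threshold conservation fraction.  Gaps are only ever placed outside
    the reference region and away from planted sites, at a rate <= 0.1 (the
    similarity metric is documented as unsuitable for gap-rich alignments).
    """

    seed: int
    n_records: int = 20
    length: int = 80
    conserved_sites: tuple[int, ...] = ()
    near_conserved_sites: tuple[int, ...] = ()
    near_conserved_fraction: float = 0.95
    background_conservation: float = 0.7
    gap_rate: float = 0.05
    region: tuple[int, int] = (0, 0)  # 0-based inclusive site span of the reference region
    region_jitter: int = 0

    def __post_init__(self) -> None:
        if self.gap_rate > 0.1:
            raise ValueError("gap rate must be <= 0.1")
        if self.n_records < 2:
            raise ValueError("need at least 2 records")


@dataclass
class MSATruth:
    """What was planted into a synthetic alignment."""

    reference_id: str
    conserved_sites: np.ndarray  # 0-based
    near_conserved_sites: np.ndarray
    regions: dict[str, tuple[int, int]]  # per record, 0-based inclusive site span


def make_msa(spec: MSASpec) -> tuple[Alignment, list[RegionAssignment], MSATruth]:
    """Build an alignment with exact planted conservation counts and regions.

    At a planted conserved site every record carries a hydrophobic letter
    (interchange within the hydrophobic set).  At near-conserved and
    background sites an exact number of records (at least one) is mutated to
    a non-hydrophobic letter, so the realized fractions are deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    L, R = spec.length, spec.n_records
    conserved = set(spec.conserved_sites)
    near = set(spec.near_conserved_sites)
    ref_letters = []
    for s in range(L):
        if s in conserved or s in near:
            ref_letters.append(HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))])
        else:
            ref_letters.append(
                HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))]
                if rng.random() < 0.4
                else OTHER_AA[rng.integers(len(OTHER_AA))]
            )
    reference = "".join(ref_letters)
    ids = ["ref"] + [f"hom{r:03d}" for r in range(1, R)]
    rows = {ident: list(reference) for ident in ids}

    for s in range(L):
        ref_aa = reference[s]
        if s in conserved:
            for ident in ids[1:]:
                rows[ident][s] = HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))]
            continue
        target = spec.near_conserved_fraction if s in near else spec.background_conservation
        n_mut = max(1, round((1.0 - target) * R))
        mutants = rng.choice(R - 1, size=min(n_mut, R - 1), replace=False)
        for ident in ids[1:]:
            if rows[ident][s] == ref_aa and ref_aa in HYDROPHOBIC and rng.random() < 0.3:
                rows[ident][s] = HYDROPHOBIC[rng.integers(len(HYDROPHOBIC))]
        for m in mutants:
            rows[ids[1 + m]][s] = NONHYDROPHOBIC[rng.integers(len(NONHYDROPHOBIC))]

    # gaps: outside the reference region and never at planted sites
    lo, hi = spec.region
    protected = conserved | near | set(range(lo, hi + 1))
    gap_candidates = [s for s in range(L) if s not in protected]
    for ident in ids[1:]:
        for s in gap_candidates:
            if rng.random() < spec.gap_rate:
                rows[ident][s] = "-"

    regions: dict[str, tuple[int, int]] = {"ref": (lo, hi)}
    for ident in ids[1:]:
        j1 = int(rng.integers(-spec.region_jitter, spec.region_jitter + 1)) if spec.region_jitter else 0
        j2 = int(rng.integers(-spec.region_jitter, spec.region_jitter + 1)) if spec.region_jitter else 0
        regions[ident] = (max(0, lo + j1), min(L - 1, hi + j2))

    alignment = Alignment([(ident, "".join(rows[ident])) for ident in ids])
    assignments = []
    for ident in ids:
        a, b = regions[ident]
        gap = np.array([c == "-" for c in rows[ident]], dtype=bool)
        in_region = np.zeros(L, dtype=bool)
        in_region[a : b + 1] = True
        assignments.append(RegionAssignment(ident, gap, in_region))
    truth = MSATruth(
        reference_id="ref",
        conserved_sites=np.array(sorted(conserved), dtype=int),
        near_conserved_sites=np.array(sorted(near), dtype=int),
        regions=regions,
    )
    return alignment, assignments, truth


def make_sasa_fixture(kind: str) -> ProteinStructure:
    """Small heavy-atom arrangements with analytically known burial.

    ``isolated_pair``: two leucine side-chain carbons 10 Å apart (no mutual
    burial).  ``packed_pair``: side-chain carbons at exact vdW contact
    (3.4 Å), burying the analytic 27.27 Å^2 cap on each.  ``buried_atom``:
    one carbon enclosed by a dense shell (SASA ~ 0).
    """
    if kind == "isolated_pair":
        d = 10.0
    elif kind == "packed_pair":
        d = 3.4
    elif kind == "buried_atom":
        from foldseg.sasa import golden_spiral_points

        shell = 2.6 * golden_spiral_points(80)
        residues = [
            Residue(1, "L", np.zeros(3), [Atom("CB", "C", np.zeros(3))]),
            Residue(
                2,
                "L",
                np.array([30.0, 0.0, 0.0]),
                [Atom(f"C{k}", "C", shell[k]) for k in range(shell.shape[0])],
            ),
        ]
        return ProteinStructure("A", residues)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    residues = [
        Residue(
            1,
            "L",
            np.array([-3.4, 0.0, 0.0]),
            [Atom("CA", "C", np.array([-3.4, 0.0, 0.0])), Atom("CB", "C", np.zeros(3))],
        ),
        Residue(
            2,
            "L",
            np.array([d + 3.4, 0.0, 0.0]),
            [
                Atom("CA", "C", np.array([d + 3.4, 0.0, 0.0])),
                Atom("CB", "C", np.array([d, 0.0, 0.0])),
            ],
        ),
    ]
    return ProteinStructure("A", residues)
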