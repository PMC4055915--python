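"""Average distance map (ADM) construction, compact-region extraction and
family-level comparison of predicted regions.

An ADM is a predicted contact map: for every residue pair the statistically
expected Cα-Cα distance (conditioned on residue types and sequence
separation) is looked up, and pairs at or below a cutoff are counted as
predicted contacts.  A compact region is a contiguous interval whose
predicted-contact density exceeds the whole-map background; its strength is
the eta value

    eta(a, b) = contact_density(a, b) - contact_density(1, N).

Candidate intervals are produced by a recursive boundary scan along the
diagonal, overlaps are resolved in favour of the higher eta, whole-sequence
candidates are never reported, and a kept region covering >= 70 % of the
sequence triggers a second, restricted search inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from foldseg.distance_stats import DistanceStatistics, range_of_separation
from foldseg.structure_io import Alignment, SequenceRecord

DEFAULT_CONTACT_CUTOFF = 13.0  # Å, expected-distance cutoff for a predicted contact
DEFAULT_ETA_THRESHOLD = 0.03
DEFAULT_MIN_REGION_LENGTH = 10
WHOLE_SEQUENCE_COVERAGE = 0.70  # fraction triggering the secondary sub-search


@dataclass
class AverageDistanceMap:
    """Predicted contact map for one sequence."""

    sequence: SequenceRecord
    expected_distance: np.ndarray  # (N, N) symmetric, nan on the diagonal
    contact_cutoff: float
    predicted_contact: np.ndarray  # (N, N) bool, False on the diagonal

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


@dataclass
class CompactRegion:
    """A predicted folding segment: inclusive 1-based interval with eta score.

    ``start_source``/``end_source`` carry the source-file (e.g. PDB) residue
    numbers; ``dominance`` names the terminal half holding the midpoint.
    """

    start: int
    end: int
    eta: float
    rank: str = "auxiliary"  # "primary" | "auxiliary"
    dominance: str = "N"  # "N" | "C"
    start_source: int = 0
    end_source: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "CompactRegion") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class RegionAssignment:
    """Predicted region membership of one aligned record, per alignment site."""

    identifier: str
    gap: np.ndarray  # bool per site, True where the record is gapped
    in_region: np.ndarray  # bool per site, meaningful only at non-gap sites

    def __post_init__(self) -> None:
        self.gap = np.asarray(self.gap, dtype=bool)
        self.in_region = np.asarray(self.in_region, dtype=bool) & ~self.gap
        if self.gap.shape != self.in_region.shape:
            raise ValueError("gap/in_region length mismatch")

    @property
    def n_sites(self) -> int:
        return self.gap.size

    @classmethod
    def from_regions(
        cls,
        identifier: str,
        aligned_sequence: str,
        regions: Iterable[tuple[int, int]],
    ) -> "RegionAssignment":
        """Map regions given in ungapped residue coordinates onto alignment sites."""
        gap = np.array([c == "-" for c in aligned_sequence], dtype=bool)
        in_region = np.zeros(len(aligned_sequence), dtype=bool)
        pos = 0
        spans = list(regions)
        for site, is_gap in enumerate(gap):
            if is_gap:
                continue
            pos += 1
            if any(start <= pos <= end for start, end in spans):
                in_region[site] = True
        return cls(identifier, gap, in_region)


def build_adm(
    sequence: SequenceRecord | str,
    stats: DistanceStatistics,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> AverageDistanceMap:
    """Fill the expected-distance matrix from the statistics and threshold it."""
    if isinstance(sequence, str):
        sequence = SequenceRecord("query", sequence)
    seq = sequence.sequence
    n = len(seq)
    if n < 20:
        raise ValueError(f"sequence too short for ADM analysis ({n} < 20)")
    if seq.count("X") > n / 2:
        raise ValueError("more than 50% unknown residues")
    expected = np.full((n, n), np.nan)
    for i in range(n - 1):
        for j in range(i + 1, n):
            mean, _ = stats.lookup(seq[i], seq[j], range_of_separation(j - i))
            expected[i, j] = expected[j, i] = mean
    contact = np.zeros((n, n), dtype=bool)
    off = ~np.isnan(expected)
    contact[off] = expected[off] <= contact_cutoff
    return AverageDistanceMap(sequence, expected, float(contact_cutoff), contact)


def _contact_prefix(adm: AverageDistanceMap) -> np.ndarray:
    """2D prefix sums of the upper-triangular contact matrix for O(1) interval counts."""
    upper = np.triu(adm.predicted_contact, k=1).astype(np.int64)
    return upper.cumsum(axis=0).cumsum(axis=1)


def _contacts_in(prefix: np.ndarray, a: int, b: int) -> int:
    """Number of predicted contacts among pairs a <= i < j <= b (1-based)."""
    lo, hi = a - 1, b - 1
    total = prefix[hi, hi]
    if lo > 0:
        total -= prefix[lo - 1, hi] + prefix[hi, lo - 1] - prefix[lo - 1, lo - 1]
    return int(total)


def region_density(adm: AverageDistanceMap, a: int, b: int) -> float:
    """Predicted-contact density over all pairs inside [a, b] (1-based inclusive)."""
    n = adm.n_residues
    if not (1 <= a < b <= n):
        raise ValueError(f"invalid interval [{a}, {b}] for N={n}")
    count = _contacts_in(_contact_prefix(adm), a, b)
    length = b - a + 1
    return count / (length * (length - 1) / 2)


def region_eta(adm: AverageDistanceMap, a: int, b: int) -> float:
    """eta(a, b): interval contact density minus whole-map density."""
    return region_density(adm, a, b) - region_density(adm, 1, adm.n_residues)


class _Scanner:
    """Recursive diagonal boundary scan producing candidate intervals."""

    def __init__(self, adm: AverageDistanceMap, min_length: int, threshold: float):
        self.prefix = _contact_prefix(adm)
        self.min_length = min_length
        self.threshold = threshold
        self.global_density = self._density(1, adm.n_residues)

    def _density(self, a: int, b: int) -> float:
        length = b - a + 1
        return _contacts_in(self.prefix, a, b) / (length * (length - 1) / 2)

    def eta(self, a: int, b: int) -> float:
        return self._density(a, b) - self.global_density

    def candidates(self, lo: int, hi: int) -> list[tuple[int, int]]:
        found: list[tuple[int, int]] = []
        self._recurse(lo, hi, found)
        return found

    def _recurse(self, a: int, b: int, found: list[tuple[int, int]]) -> None:
        if b - a + 1 < 2 * self.min_length:
            return
        best_score, best_p = -np.inf, None
        for p in range(a + self.min_length - 1, b - self.min_length + 1):
            score = self.eta(a, p) + self.eta(p + 1, b)
            if score > best_score:  # ties keep the smallest p
                best_score, best_p = score, p
        if best_p is None:
            return
        for x, y in ((a, best_p), (best_p + 1, b)):
            found.append((x, y))
            if self.eta(x, y) > self.threshold:
                self._recurse(x, y, found)


def _resolve_overlaps(
    scanner: _Scanner, candidates: Sequence[tuple[int, int]]
) -> list[tuple[int, int, float]]:
    scored = sorted(
        {(a, b) for a, b in candidates},
        key=lambda ab: (-scanner.eta(*ab), -(ab[1] - ab[0]), ab[0]),
    )
    kept: list[tuple[int, int, float]] = []
    for a, b in scored:
        eta = scanner.eta(a, b)
        if eta <= scanner.threshold:
            continue
        if all(not (a <= kb and ka <= b) for ka, kb, _ in kept):
            kept.append((a, b, eta))
    return kept


def extract_regions(
    adm: AverageDistanceMap,
    eta_threshold: float = DEFAULT_ETA_THRESHOLD,
    min_length: int = DEFAULT_MIN_REGION_LENGTH,
) -> list[CompactRegion]:
    """Extract compact regions (predicted folding segments) from an ADM.

    Candidates come from the recursive boundary scan; whole-sequence
    candidates are discarded, overlaps keep the higher eta, and a kept
    region covering >= 70 % of the sequence gets a second scan restricted to
    its interior whose regions are reported alongside it.  The returned list
    is sorted by eta descending; the first region is ranked primary.
    """
    n = adm.n_residues
    scanner = _Scanner(adm, min_length, eta_threshold)
    candidates = [c for c in scanner.candidates(1, n) if c != (1, n)]
    kept = _resolve_overlaps(scanner, candidates)
    for a, b, _ in list(kept):
        if (b - a + 1) / n >= WHOLE_SEQUENCE_COVERAGE:
            sub = [c for c in scanner.candidates(a, b) if c != (a, b)]
            existing = {(x, y) for x, y, _ in kept}
            kept.extend(
                (x, y, eta)
                for x, y, eta in _resolve_overlaps(scanner, sub)
                if (x, y) not in existing
            )
    kept.sort(key=lambda t: (-t[2], t[0]))
    offset = adm.sequence.numbering_offset
    regions = [
        CompactRegion(
            start=a,
            end=b,
            eta=eta,
            rank="primary" if idx == 0 else "auxiliary",
            dominance="N" if (a + b) / 2 <= n / 2 else "C",
            start_source=a + offset,
            end_source=b + offset,
        )
        for idx, (a, b, eta) in enumerate(kept)
    ]
    return regions


def adm_similarity(assign_a: RegionAssignment, assign_b: RegionAssignment) -> float:
    """Percent agreement of region membership over mutually non-gapped sites.

    Sites gapped in either record are removed; among the remaining sites the
    fraction on which the two assignments agree (both in-region or both
    out-of-region) is returned as a percentage in [0, 100].
    """
    if assign_a.n_sites != assign_b.n_sites:
        raise ValueError("assignments live on different alignments")
    mutual = ~assign_a.gap & ~assign_b.gap
    total = int(mutual.sum())
    if total == 0:
        raise ValueError("no mutually non-gapped sites; similarity undefined")
    agree = int((assign_a.in_region[mutual] == assign_b.in_region[mutual]).sum())
    return 100.0 * agree / total


def site_inclusion_profile(
    alignment: Alignment, assignments: Sequence[RegionAssignment]
) -> np.ndarray:
    """Per alignment site, the fraction of non-gapped records in-region there.

    Sites where every record is gapped get nan.
    """
    if len(assignments) != len(alignment.records):
        raise ValueError("need one assignment per alignment record")
    gap = np.array([a.gap for a in assignments])
    in_region = np.array([a.in_region for a in assignments])
    present = (~gap).sum(axis=0)
    covered = (in_region & ~gap).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(present > 0, covered / np.maximum(present, 1), np.nan)
    return frac


def pairwise_identity(alignment: Alignment, id_a: str, id_b: str) -> float:
    """Percent identity over mutually non-gapped alignment sites."""
    seq_a = np.frombuffer(alignment.sequence_of(id_a).encode(), dtype="S1")
    seq_b = np.frombuffer(alignment.sequence_of(id_b).encode(), dtype="S1")
    mutual = (seq_a != b"-") & (seq_b != b"-")
    total = int(mutual.sum())
    if total == 0:
        raise ValueError(f"no mutually non-gapped sites between {id_a!r} and {id_b!r}")
    return 100.0 * int((seq_a[mutual] == seq_b[mutual]).sum()) / total


def similarity_identity_curve(
    alignment: Alignment,
    assignments: Sequence[RegionAssignment],
    reference_id: str,
    limits: Iterable[float] = tuple(range(30, 101, 5)),
) -> list[tuple[float, float]]:
    """Average ADM similarity to the reference vs a lower limit on sequence identity.

    For each identity lower limit, the mean similarity between the reference
    assignment and every other record whose identity to the reference is at
    least the limit.  Empty bins are omitted.
    """
    by_id = {a.identifier: a for a in assignments}
    if reference_id not in by_id:
        raise KeyError(f"reference {reference_id!r} has no assignment")
    ref = by_id[reference_id]
    pairs = []
    for ident, _ in alignment.records:
        if ident == reference_id:
            continue
        pairs.append(
            (
                pairwise_identity(alignment, reference_id, ident),
                adm_similarity(ref, by_id[ident]),
            )
        )
    curve = []
    for limit in limits:
        sims = [s for ident_pct, s in pairs if ident_pct >= limit]
        if sims:
            curve.append((float(limit), float(np.mean(sims))))
    return curve


def nj_tree(similarity: np.ndarray, identifiers: Sequence[str]) -> str:
    """Neighbor-joining tree (Newick) from an ADM-similarity matrix.

    Similarities (percent) become distances d = 1 - s/100 before standard
    neighbor joining (delegated to scikit-bio).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    similarity = np.asarray(similarity, dtype=float)
    if similarity.ndim != 2 or similarity.shape[0] != similarity.shape[1]:
        raise ValueError("similarity matrix must be square")
    if similarity.shape[0] != len(identifiers):
        raise ValueError("matrix size and identifier count differ")
    if similarity.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(similarity, similarity.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    dist = 1.0 - similarity / 100.0
    np.fill_diagonal(dist, 0.0)
    tree = nj(DistanceMatrix(dist, ids=list(identifiers)))
    return str(tree).strip()


def plot_adm(
    adm: AverageDistanceMap,
    regions: Sequence[CompactRegion],
    path: str,
) -> None:
    """Render the predicted contact map with region triangles annotated by eta.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = adm.n_residues
    fig, ax = plt.subplots(figsize=(6, 6))
    rows, cols = np.where(np.triu(adm.predicted_contact, k=1))
    ax.scatter(cols + 1, rows + 1, s=4, c="0.4", marker="s", linewidths=0)
    for region in regions:
        color = "red" if region.rank == "primary" else "black"
        a, b = region.start, region.end
        ax.plot([a, b, b, a], [a, a, b, a], color=color, linewidth=1.2)
        ax.annotate(
            f"{region.eta:.3f}",
            ((a + b) / 2, a - 1.5),
            color=color,
            fontsize=8,
            ha="center",
        )
    ax.set_xlim(0, n + 1)
    ax.set_ylim(n + 1, 0)
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    ax.set_title(f"ADM (cutoff {adm.contact_cutoff:g} Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
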