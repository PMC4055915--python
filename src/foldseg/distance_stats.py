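"""Inter-residue average-distance statistics.

For every Cα pair (i < j) in a structure set, the Euclidean distance
contributes to the key (type_i, type_j, M) where M bins the sequence
separation k = j - i: k 1-8 -> M 1, 9-20 -> M 2, 21-30 -> M 3, and
width-10 bins from there on.  The table stores the mean, the population
standard deviation and the sample count per key and is symmetric under
swapping the two residue types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from foldseg.structure_io import STANDARD_AA, ProteinStructure

_STATS_FORMAT_VERSION = "1"


def range_of_separation(k: int) -> int:
    """Map a sequence separation k >= 1 to its range index M.

    k in [1, 8] -> 1; [9, 20] -> 2; [21, 30] -> 3; thereafter width-10 bins
    ([31, 40] -> 4, [41, 50] -> 5, ...).
    """
    if k <= 0:
        raise ValueError(f"sequence separation must be positive, got {k}")
    if k <= 8:
        return 1
    if k <= 20:
        return 2
    return (k - 1) // 10 + 1


def separation_bounds(M: int) -> tuple[int, int]:
    """Inclusive (k_min, k_max) separation bounds of range M."""
    if M < 1:
        raise ValueError(f"range index must be >= 1, got {M}")
    if M == 1:
        return 1, 8
    if M == 2:
        return 9, 20
    return 10 * (M - 1) + 1, 10 * M


def _key(aa_a: str, aa_b: str, M: int) -> tuple[str, str, int]:
    a, b = sorted((aa_a, aa_b))
    return a, b, M


@dataclass
class DistanceStatistics:
    """Mean/SD Cα-Cα distance per (residue-type pair, separation range)."""

    table: dict[tuple[str, str, int], tuple[float, float, int]] = field(default_factory=dict)

    def __contains__(self, key: tuple[str, str, int]) -> bool:
        aa_a, aa_b, M = key
        return _key(aa_a, aa_b, M) in self.table

    @property
    def ranges(self) -> list[int]:
        return sorted({M for (_, _, M) in self.table})

    def get(self, aa_a: str, aa_b: str, M: int) -> tuple[float, float, int]:
        """Exact lookup; raises KeyError when the key was never observed."""
        return self.table[_key(aa_a, aa_b, M)]

    def lookup(self, aa_a: str, aa_b: str, M: int) -> tuple[float, float]:
        """Total lookup with fallback, returning (mean, sd).

        A pair type never observed in range M backs off to the pooled mean/SD
        over all pairs observed in M; an entirely unobserved M backs off to
        the nearest observed range.  This keeps map construction total over
        any query sequence even for sparse statistics sets.
        """
        key = _key(aa_a, aa_b, M)
        if key in self.table:
            mean, sd, _ = self.table[key]
            return mean, sd
        ranges = self.ranges
        if not ranges:
            raise KeyError("empty statistics table")
        if M not in ranges:
            M = min(ranges, key=lambda m: (abs(m - M), m))
            key = _key(aa_a, aa_b, M)
            if key in self.table:
                mean, sd, _ = self.table[key]
                return mean, sd
        rows = [(mean, sd) for (a, b, m), (mean, sd, _) in self.table.items() if m == M]
        means = np.array([r[0] for r in rows])
        sds = np.array([r[1] for r in rows])
        return float(means.mean()), float(sds.mean())

    def merge_observations(self, observations: dict[tuple[str, str, int], list[float]]) -> None:
        for key, dists in observations.items():
            arr = np.asarray(dists, dtype=float)
            prev = self.table.get(key)
            if prev is not None:
                mean0, sd0, n0 = prev
                n = n0 + arr.size
                mean = (mean0 * n0 + arr.sum()) / n
                sq = n0 * (sd0**2 + mean0**2) + np.sum(arr**2)
                var = max(sq / n - mean**2, 0.0)
                self.table[key] = (float(mean), float(np.sqrt(var)), int(n))
            else:
                self.table[key] = (float(arr.mean()), float(arr.std()), int(arr.size))


def build_statistics(structures: Iterable[ProteinStructure]) -> DistanceStatistics:
    """Accumulate Cα-Cα distance statistics over a set of chains.

    Every ordered pair i < j contributes its Euclidean distance to the key
    (aa_i, aa_j, M(j - i)).  Residues typed ``X`` are skipped.  SDs are
    population SDs (the potential treats them as distribution parameters).
    """
    structures = list(structures)
    if not structures:
        raise ValueError("need at least one structure")
    observations: dict[tuple[str, str, int], list[float]] = {}
    for structure in structures:
        coords = structure.ca_coordinates
        seq = structure.sequence
        n = len(seq)
        if n < 2:
            continue
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        for i in range(n - 1):
            if seq[i] == "X":
                continue
            for j in range(i + 1, n):
                if seq[j] == "X":
                    continue
                key = _key(seq[i], seq[j], range_of_separation(j - i))
                observations.setdefault(key, []).append(float(dist[i, j]))
    stats = DistanceStatistics()
    stats.merge_observations(observations)
    return stats


def save_statistics(stats: DistanceStatistics, path: str | Path, provenance: str = "") -> None:
    """Write the table as TSV with full float precision."""
    lines = [
        f"# foldseg distance statistics v{_STATS_FORMAT_VERSION}",
    ]
    if provenance:
        lines.append(f"# {provenance}")
    lines.append("aa_a\taa_b\tM\tmean\tsd\tn")
    for (aa_a, aa_b, M) in sorted(stats.table):
        mean, sd, n = stats.table[(aa_a, aa_b, M)]
        lines.append(f"{aa_a}\t{aa_b}\t{M}\t{mean!r}\t{sd!r}\t{n}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_statistics(path: str | Path) -> DistanceStatistics:
    """Read a statistics TSV written by :func:`save_statistics`."""
    stats = DistanceStatistics()
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# foldseg distance statistics"):
        raise ValueError(f"{path}: not a foldseg statistics file")
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            if line.split("\t") != ["aa_a", "aa_b", "M", "mean", "sd", "n"]:
                raise ValueError(f"{path}:{lineno}: unexpected header {line!r}")
            header_seen = True
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        try:
            aa_a, aa_b, M = fields[0], fields[1], int(fields[2])
            mean, sd, n = float(fields[3]), float(fields[4]), int(fields[5])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
        if aa_a not in STANDARD_AA or aa_b not in STANDARD_AA:
            raise ValueError(f"{path}:{lineno}: invalid residue codes {aa_a!r}/{aa_b!r}")
        stats.table[_key(aa_a, aa_b, M)] = (mean, sd, n)
    if not header_seen:
        raise ValueError(f"{path}: missing column header")
    return stats
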