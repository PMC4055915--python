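"""Shared fixtures: tiny hand-written structures and statistics tables."""

from __future__ import annotations

import numpy as np
import pytest

from foldseg.distance_stats import DistanceStatistics
from foldseg.structure_io import Atom, ProteinStructure, Residue


def make_ca_structure(sequence: str, coords: np.ndarray, chain_id: str = "A") -> ProteinStructure:
    residues = [
        Residue(i + 1, aa, coords[i], [Atom("CA", "C", coords[i])])
        for i, aa in enumerate(sequence)
    ]
    return ProteinStructure(chain_id, residues)


@pytest.fixture
def uniform_stats() -> DistanceStatistics:
    """One residue type, fixed mean/sd per range: the simplest total table."""
    stats = DistanceStatistics()
    for M in range(1, 8):
        stats.table[("A", "A", M)] = (6.0 + 3.0 * M, 2.0, 10)
    return stats


@pytest.fixture
def two_letter_stats() -> DistanceStatistics:
    """Hand-built table over {A, B->G} used as a lookup oracle target."""
    stats = DistanceStatistics()
    values = {
        ("A", "A"): 5.0,
        ("A", "G"): 9.0,
        ("G", "G"): 14.0,
    }
    for (a, b), base in values.items():
        for M in range(1, 6):
            stats.table[(a, b, M)] = (base + M, 1.5, 4)
    return stats


@pytest.fixture
def toy_pdb_text() -> str:
    """Three residues (ALA, GLY, LEU), full backbone for the first."""
    return "\n".join(
        [
            "HEADER    TOY FIXTURE",
            "ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N",
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
            "ATOM      3  C   ALA A   1       2.000   0.500   1.300  1.00  0.00           C",
            "ATOM      4  O   ALA A   1       2.200   1.690   1.450  1.00  0.00           O",
            "ATOM      5  CB  ALA A   1       1.800  -1.200  -0.800  1.00  0.00           C",
            "ATOM      6  N   GLY A   2       3.000   0.000   2.000  1.00  0.00           N",
            "ATOM      7  CA  GLY A   2       4.300   0.500   2.400  1.00  0.00           C",
            "ATOM      8  C   GLY A   2       5.300   0.000   1.400  1.00  0.00           C",
            "ATOM      9  N   LEU A   3       6.500   0.500   1.500  1.00  0.00           N",
            "ATOM     10  CA  LEU A   3       7.700   0.100   0.800  1.00  0.00           C",
            "ATOM     11  CB  LEU A   3       8.900   1.000   1.100  1.00  0.00           C",
            "TER",
            "END",
        ]
    )
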