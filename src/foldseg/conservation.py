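"""Evolutionarily conserved hydrophobic residues from a multiple alignment.

A site is eligible when no record is gapped there.  At an eligible site
whose reference residue is hydrophobic, the conservation fraction is the
share of records carrying any hydrophobic residue (interchange within the
hydrophobic set {A, M, W, L, F, V, I, Y} still counts as conserved), and the
site is flagged when that fraction strictly exceeds 0.99.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from foldseg.structure_io import Alignment

HYDROPHOBIC_RESIDUES = frozenset("AMWLFVIY")
CONSERVATION_THRESHOLD = 0.99  # strict ">"


@dataclass
class ConservationProfile:
    """Per-site conservation state tied to one reference record."""

    reference_id: str
    eligible: np.ndarray  # bool per site: no gap in any record
    fraction: np.ndarray  # hydrophobic fraction, nan where not evaluated
    is_conserved: np.ndarray  # bool per site
    site_to_residue: np.ndarray  # 1-based reference residue number per site, 0 at ref gaps

    @property
    def n_sites(self) -> int:
        return self.eligible.size


def hydrophobic_conservation(
    alignment: Alignment,
    reference_id: str,
    threshold: float = CONSERVATION_THRESHOLD,
) -> ConservationProfile:
    """Score hydrophobic conservation per alignment site against a reference.

    Only sites where the reference residue is hydrophobic are evaluated;
    sites with any gap are ineligible.  The flag requires fraction strictly
    greater than the threshold.
    """
    ids = alignment.identifiers
    if reference_id not in ids:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    matrix = np.array([list(seq) for _, seq in alignment.records])
    ref_seq = np.array(list(alignment.sequence_of(reference_id)))
    n_sites = alignment.length
    eligible = ~(matrix == "-").any(axis=0)
    hydro = np.isin(matrix, list(HYDROPHOBIC_RESIDUES))
    fraction = np.full(n_sites, np.nan)
    is_conserved = np.zeros(n_sites, dtype=bool)
    ref_hydrophobic = np.isin(ref_seq, list(HYDROPHOBIC_RESIDUES))
    evaluate = eligible & ref_hydrophobic
    fraction[evaluate] = hydro[:, evaluate].mean(axis=0)
    is_conserved[evaluate] = fraction[evaluate] > threshold

    site_to_residue = np.zeros(n_sites, dtype=int)
    pos = 0
    for site, ch in enumerate(ref_seq):
        if ch != "-":
            pos += 1
            site_to_residue[site] = pos
    return ConservationProfile(
        reference_id=reference_id,
        eligible=eligible,
        fraction=fraction,
        is_conserved=is_conserved,
        site_to_residue=site_to_residue,
    )


def map_sites_to_reference(profile: ConservationProfile) -> np.ndarray:
    """Project site flags onto the ungapped reference sequence.

    Returns a boolean array with one entry per reference residue; sites
    gapped in the reference are dropped.
    """
    n_residues = int(profile.site_to_residue.max())
    flags = np.zeros(n_residues, dtype=bool)
    for site in range(profile.n_sites):
        residue = profile.site_to_residue[site]
        if residue > 0 and profile.is_conserved[site]:
            flags[residue - 1] = True
    return flags
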