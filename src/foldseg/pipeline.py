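"""End-to-end orchestration: configuration, the Φ-value comparison report,
and the full analysis chain wired together.

Secondary-structure segments and experimental Φ values are consumed as
annotations (TSV), never computed.  Every artifact is TSV with a
provenance header so runs are diffable and reproducible from the config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from foldseg import adm as adm_mod
from foldseg import conservation as cons_mod
from foldseg import fvalue as fv_mod
from foldseg import sasa as sasa_mod
from foldseg.distance_stats import build_statistics, load_statistics, save_statistics
from foldseg.structure_io import read_alignment, read_fasta, read_pdb

logger = logging.getLogger(__name__)

HELIX_PREFIXES = ("a", "h", "α")  # alpha helix labels: a1, H1, α1...
STRAND_PREFIXES = ("b", "e", "β")


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameters; unknown keys are rejected."""

    # inputs
    stats_path: str | None = None
    structure_paths: list[str] = field(default_factory=list)  # "path:chain" entries
    query_pdb: str | None = None
    query_chain: str = "A"
    query_fasta: str | None = None
    alignment_path: str | None = None
    phi_path: str | None = None
    ss_path: str | None = None
    out_dir: str = "foldseg_out"
    seed: int = 0
    # ADM
    adm_contact_cutoff: float = adm_mod.DEFAULT_CONTACT_CUTOFF
    eta_threshold: float = adm_mod.DEFAULT_ETA_THRESHOLD
    min_region_length: int = adm_mod.DEFAULT_MIN_REGION_LENGTH
    # F-value MC
    mc_steps: int = 60000
    mc_runs: int = 100
    mc_contact_cutoff: float = fv_mod.DEFAULT_CONTACT_CUTOFF
    bond_length: float = fv_mod.VIRTUAL_BOND_LENGTH
    max_angle_deg: float = fv_mod.DEFAULT_MAX_ANGLE
    burn_in_fraction: float = fv_mod.DEFAULT_BURN_IN_FRACTION
    target_acceptance: float = fv_mod.DEFAULT_TARGET_ACCEPTANCE
    terminal_exclusion: int = fv_mod.DEFAULT_TERMINAL_EXCLUSION
    peak_tolerance: int = 3
    # SASA
    probe_radius: float = sasa_mod.PROBE_RADIUS
    sasa_n_points: int = sasa_mod.DEFAULT_N_POINTS
    contact_threshold: float = sasa_mod.CONTACT_THRESHOLD
    smoothing_bandwidth: float = sasa_mod.DEFAULT_SMOOTHING_BANDWIDTH
    # conservation
    conservation_threshold: float = cons_mod.CONSERVATION_THRESHOLD

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def log_parameters(self) -> None:
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


@dataclass
class SegmentPhi:
    label: str
    start: int
    end: int
    mean_phi: float | None  # None when no Φ value falls in the segment


@dataclass
class PhiComparison:
    """Mean Φ per secondary-structure segment plus the folding-segment call."""

    segments: list[SegmentPhi]
    folding_segment_labels: list[str]
    reference_helix: str | None  # helix with the lower mean Φ


def _is_helix(label: str) -> bool:
    return label.strip().lower().startswith(HELIX_PREFIXES)


def _is_strand(label: str) -> bool:
    return label.strip().lower().startswith(STRAND_PREFIXES)


def average_phi_by_ss(
    phi_values: dict[int, float], segments: list[tuple[str, int, int]]
) -> PhiComparison:
    """Average Φ per segment and call the experimental folding segment.

    The call takes the two α helices, uses the one with the *lower* mean Φ
    as the reference, and selects the other helix together with every β
    strand whose mean Φ exceeds the reference helix's mean.
    Segments without any Φ value are reported with mean None ("missing").
    """
    seg_means: list[SegmentPhi] = []
    for label, start, end in segments:
        values = [phi_values[r] for r in range(start, end + 1) if r in phi_values]
        seg_means.append(
            SegmentPhi(label, start, end, float(np.mean(values)) if values else None)
        )
    helices = [s for s in seg_means if _is_helix(s.label) and s.mean_phi is not None]
    call: list[str] = []
    reference_helix = None
    if len(helices) >= 2:
        helices_sorted = sorted(helices, key=lambda s: s.mean_phi)
        low, high = helices_sorted[0], helices_sorted[-1]
        reference_helix = low.label
        call.append(high.label)
        for s in seg_means:
            if _is_strand(s.label) and s.mean_phi is not None and s.mean_phi > low.mean_phi:
                call.append(s.label)
    return PhiComparison(
        segments=seg_means, folding_segment_labels=call, reference_helix=reference_helix
    )


def read_phi_tsv(path: str | Path) -> dict[int, float]:
    """TSV with columns residue, phi; '#' comments allowed."""
    values: dict[int, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.lower().startswith("residue"):
            continue
        residue, phi = line.split("\t")[:2]
        values[int(residue)] = float(phi)
    return values


def read_segments_tsv(path: str | Path) -> list[tuple[str, int, int]]:
    """TSV with columns label, start, end."""
    segments = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.lower().startswith("label"):
            continue
        label, start, end = line.split("\t")[:3]
        segments.append((label, int(start), int(end)))
    return segments


def _write_tsv(path: Path, header: list[str], rows: list[list[Any]], provenance: str) -> None:
    lines = [f"# foldseg {provenance}", "\t".join(header)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


def write_regions_tsv(path: Path, identifier: str, regions, provenance: str) -> None:
    _write_tsv(
        path,
        ["id", "start", "end", "start_source", "end_source", "eta", "rank", "dominance"],
        [
            [identifier, r.start, r.end, r.start_source, r.end_source, f"{r.eta:.6f}", r.rank, r.dominance]
            for r in regions
        ],
        provenance,
    )


def write_matrix_tsv(path: Path, matrix: np.ndarray, provenance: str) -> None:
    lines = [f"# foldseg {provenance}"]
    lines += ["\t".join(f"{v:.8g}" for v in row) for row in np.asarray(matrix)]
    path.write_text("\n".join(lines) + "\n")


def segments_consistent_with_regions(
    comparison: PhiComparison, regions
) -> bool:
    """True when every called segment's midpoint lies inside a predicted region."""
    called = {label for label in comparison.folding_segment_labels}
    for seg in comparison.segments:
        if seg.label not in called:
            continue
        mid = (seg.start + seg.end) // 2
        if not any(r.start_source <= mid <= r.end_source for r in regions):
            return False
    return True


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage the config provides inputs for.

    statistics -> ADM + regions -> F-value profile -> SASA contacts (if a
    structure is given) -> conservation + family analyses (if an alignment
    is given) -> Φ comparison (if Φ values are given).  Returns the bundle
    of in-memory results; artifacts land under ``config.out_dir``.
    """
    config.log_parameters()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}

    # --- statistics ---
    if config.stats_path:
        stats = load_statistics(config.stats_path)
    elif config.structure_paths:
        structures = []
        for entry in config.structure_paths:
            path, _, chain = entry.rpartition(":")
            structures.append(read_pdb(path or entry, chain or "A"))
        stats = build_statistics(structures)
        save_statistics(stats, out / "statistics.tsv", provenance=f"built from {len(structures)} structures")
    else:
        raise ValueError("config needs stats_path or structure_paths")
    results["stats"] = stats

    # --- query sequence ---
    native = None
    if config.query_pdb:
        native = read_pdb(config.query_pdb, config.query_chain)
        query = native.to_sequence_record("query")
    elif config.query_fasta:
        query = read_fasta(config.query_fasta)[0]
    else:
        raise ValueError("config needs query_pdb or query_fasta")
    results["query"] = query

    # --- ADM ---
    adm = adm_mod.build_adm(query, stats, config.adm_contact_cutoff)
    regions = adm_mod.extract_regions(adm, config.eta_threshold, config.min_region_length)
    results["adm"], results["regions"] = adm, regions
    write_regions_tsv(out / "regions.tsv", query.identifier, regions, "compact regions")
    write_matrix_tsv(out / "adm_expected_distance.tsv", adm.expected_distance, "ADM expected distances (Å)")

    # --- F-value MC ---
    contact_map = fv_mod.run_simulation(
        query,
        stats,
        n_steps=config.mc_steps,
        n_runs=config.mc_runs,
        seed=config.seed,
        contact_cutoff=config.mc_contact_cutoff,
        bond_length=config.bond_length,
        max_angle_deg=config.max_angle_deg,
        burn_in_fraction=config.burn_in_fraction,
        target_acceptance=config.target_acceptance,
    )
    Q = fv_mod.normalize_contacts(contact_map.g)
    profile = fv_mod.f_profile(Q, config.terminal_exclusion)
    results["contact_map"], results["f_profile"] = contact_map, profile
    write_matrix_tsv(out / "g.tsv", contact_map.g, "contact frequencies g(i,j)")
    write_matrix_tsv(out / "Q.tsv", Q, "normalized contact frequencies Q(i,j)")
    _write_tsv(
        out / "f_profile.tsv",
        ["residue", "F", "is_peak"],
        [
            [i + 1, f"{profile.F[i]:.6f}", int(i + 1 in profile.peaks)]
            for i in range(profile.F.size)
        ],
        f"F profile (acceptance {contact_map.production_acceptance:.3f})",
    )

    # --- SASA contacts ---
    contacts = None
    if native is not None and any(len(r.heavy_atoms) > 1 for r in native.residues):
        contacts = sasa_mod.sidechain_contacts(
            native,
            threshold=config.contact_threshold,
            probe_radius=config.probe_radius,
            n_points=config.sasa_n_points,
        )
        results["native_contacts"] = contacts
        _write_tsv(
            out / "contacts.tsv",
            ["res_i", "res_j", "dsasa_i", "dsasa_j"],
            [[i, j, f"{a:.2f}", f"{b:.2f}"] for (i, j), (a, b) in sorted(contacts.pairs.items())],
            "SASA-defined hydrophobic contacts",
        )

    # --- family analyses ---
    if config.alignment_path:
        alignment = read_alignment(config.alignment_path)
        profile_cons = cons_mod.hydrophobic_conservation(
            alignment, alignment.identifiers[0], config.conservation_threshold
        )
        conserved_flags = cons_mod.map_sites_to_reference(profile_cons)
        results["conservation"] = profile_cons
        _write_tsv(
            out / "conservation.tsv",
            ["site", "reference_residue", "fraction", "conserved"],
            [
                [
                    s + 1,
                    profile_cons.site_to_residue[s] or "-",
                    "nan" if np.isnan(profile_cons.fraction[s]) else f"{profile_cons.fraction[s]:.4f}",
                    int(profile_cons.is_conserved[s]),
                ]
                for s in range(profile_cons.n_sites)
            ],
            "hydrophobic conservation",
        )
        if contacts is not None and conserved_flags.size == len(native.residues):
            cc = sasa_mod.conserved_contact_profile(contacts, conserved_flags)
            smoothed = sasa_mod.smooth_profile(cc.counts, config.smoothing_bandwidth)
            matched, only_f, only_cc = fv_mod.match_peaks(
                profile.peaks, smoothed.peaks, config.peak_tolerance
            )
            results["conserved_contact_profile"] = smoothed
            results["peak_matches"] = matched
            _write_tsv(
                out / "conserved_contacts.tsv",
                ["residue", "count", "smoothed", "is_peak"],
                [
                    [i + 1, int(cc.counts[i]), f"{smoothed.smoothed[i]:.4f}", int(i + 1 in smoothed.peaks)]
                    for i in range(cc.counts.size)
                ],
                f"conserved hydrophobic contacts (matched peaks: {matched})",
            )

        # per-record ADM regions mapped into the alignment
        assignments = []
        for ident, aligned in alignment.records:
            ungapped = aligned.replace("-", "")
            try:
                rec_adm = adm_mod.build_adm(ungapped, stats, config.adm_contact_cutoff)
                rec_regions = adm_mod.extract_regions(
                    rec_adm, config.eta_threshold, config.min_region_length
                )
            except ValueError:
                rec_regions = []
            assignments.append(
                adm_mod.RegionAssignment.from_regions(
                    ident, aligned, [(r.start, r.end) for r in rec_regions]
                )
            )
        results["assignments"] = assignments
        n_rec = len(assignments)
        sim = np.full((n_rec, n_rec), 100.0)
        for i in range(n_rec):
            for j in range(i + 1, n_rec):
                sim[i, j] = sim[j, i] = adm_mod.adm_similarity(assignments[i], assignments[j])
        results["similarity_matrix"] = sim
        write_matrix_tsv(out / "adm_similarity.tsv", sim, "ADM similarity matrix (%)")
        inclusion = adm_mod.site_inclusion_profile(alignment, assignments)
        _write_tsv(
            out / "site_inclusion.tsv",
            ["site", "fraction"],
            [[s + 1, f"{inclusion[s]:.4f}"] for s in range(inclusion.size)],
            "per-site region inclusion",
        )
        curve = adm_mod.similarity_identity_curve(
            alignment, assignments, alignment.identifiers[0]
        )
        _write_tsv(
            out / "similarity_identity.tsv",
            ["identity_lower_limit", "mean_similarity"],
            [[f"{a:.0f}", f"{b:.2f}"] for a, b in curve],
            "similarity vs identity",
        )
        if n_rec >= 3:
            newick = adm_mod.nj_tree(sim, alignment.identifiers)
            (out / "similarity_tree.nwk").write_text(newick + "\n")
            results["tree"] = newick

    # --- Φ comparison ---
    if config.phi_path and config.ss_path:
        phi = read_phi_tsv(config.phi_path)
        segments = read_segments_tsv(config.ss_path)
        comparison = average_phi_by_ss(phi, segments)
        results["phi_comparison"] = comparison
        results["phi_consistent"] = segments_consistent_with_regions(comparison, regions)
        _write_tsv(
            out / "phi_comparison.tsv",
            ["label", "start", "end", "mean_phi", "in_folding_segment"],
            [
                [
                    s.label,
                    s.start,
                    s.end,
                    "missing" if s.mean_phi is None else f"{s.mean_phi:.3f}",
                    int(s.label in comparison.folding_segment_labels),
                ]
                for s in comparison.segments
            ],
            f"phi comparison (consistent with regions: {results['phi_consistent']})",
        )
    return results
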