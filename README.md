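# foldseg

Sequence-based prediction of protein folding-initiation segments.

Given inter-residue average-distance statistics (mean and standard
deviation of the Cα–Cα distance per residue-type pair per sequence-separation
range), the package

- builds an **average distance map (ADM)** for a query sequence and extracts
  **compact regions** — contiguous intervals whose predicted-contact density
  exceeds the whole-map background — scored by an η value and ranked
  primary/auxiliary with N/C terminal dominance;
- runs a coarse-grained **Metropolis Monte-Carlo simulation** of a Cα bead
  chain under a Gaussian distance potential, accumulates contact
  frequencies g(i,j), z-scores them per separation range into Q(i,j), and
  reports the per-residue **F profile** F_i = Σ_j Q(i,j) with interior peak
  detection (putative hydrophobic-cluster centers at folding initiation);
- computes **Shrake–Rupley solvent accessibility** and defines native
  hydrophobic contacts by a pairwise side-chain SASA decrease of ≥ 27 Å²
  (the analytic burial of one carbon by another at van-der-Waals contact is
  27.27 Å²), plus Gaussian-smoothed conserved-contact profiles;
- identifies **conserved hydrophobic residues** (> 99 % conservation with
  interchange inside {A, M, W, L, F, V, I, Y} tolerated) from a multiple
  alignment;
- compares predicted regions across a family: pairwise **ADM similarity**
  (% agreement over mutually ungapped alignment sites), per-site inclusion
  histograms, similarity-vs-identity curves and a neighbor-joining tree of
  the similarity matrix;
- ships **synthetic-data generators** (compact Cα chains, two-domain
  families with planted block structure, alignments with exact planted
  conservation, analytic SASA fixtures) so the whole pipeline is testable
  offline.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked similarity
example, two-carbon SASA reference, kT-calibration acceptance band,
property suite, synthetic parameter recovery). The tests in
`tests/test_integration_optional.py` need real PDB files and a statistics
table; point `FOLDSEG_PDB_DIR` at a directory containing them to enable.

## CLI

```bash
# materialize a synthetic demo workspace (statistics, query, alignment, config)
foldseg fixtures make --out-dir demo --seed 1

# full report (ADM regions, F profile, family analyses, ...)
foldseg report all --config demo/config.yaml

# individual stages
foldseg stats build chain1.pdb:A chain2.pdb:B --out stats.tsv
foldseg adm run --stats stats.tsv --fasta query.fasta --out regions.tsv
foldseg fvalue run --stats stats.tsv --fasta query.fasta --out fprofile.tsv --steps 60000 --runs 100
foldseg contacts run --pdb native.pdb --chain A --out contacts.tsv
foldseg conserve run --alignment family.afa --out conservation.tsv
foldseg adm family --stats stats.tsv --alignment family.afa --out-dir family_out
```

All outputs are TSV (plus Newick for trees) with provenance headers.

## Layout

| module | contents |
| --- | --- |
| `foldseg.structure_io` | PDB / FASTA / aligned-FASTA readers and writers, domain types |
| `foldseg.distance_stats` | separation ranges M, statistics builder, TSV persistence |
| `foldseg.adm` | ADM construction, compact-region extraction, family similarity, NJ tree |
| `foldseg.fvalue` | Cα-chain Metropolis MC, kT calibration, g/Q/F profiles, peak matching |
| `foldseg.sasa` | Shrake–Rupley SASA, ΔSASA contacts, conserved-contact smoothing |
| `foldseg.conservation` | hydrophobic conservation from alignments |
| `foldseg.synthetic` | seeded generators with returned ground truth |
| `foldseg.pipeline` / `foldseg.cli` | orchestration, Φ-value comparison, `foldseg` command |
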