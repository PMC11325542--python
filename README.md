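# hispi

Mining, geometric characterization and classification of histidine pairwise
interactions in protein structures.

`hispi` reads PDB/mmCIF structures (X-ray or neutron), enumerates His–aromatic
and His–cation residue pairs, computes ring/cation geometric descriptors
(centroid distance *D*, inter-plane angle *P*, elevation angles Tθ₁/Tθ₂,
cation axis/plane angles θ₁/θ₂), classifies interactions (stacked π–π, CH–π,
cation–π, H-bond), infers His protonation/tautomer states (from deuterium
positions in neutron structures, or from three-scenario H-bond patterns in
X-ray structures), clusters geometry space with Gaussian mixtures for
representative selection, stratifies interactions by pKa category, and
extracts methyl-capped model-compound fragments (4-methylimidazole, toluene,
…) as XYZ input for external QM engines.

A first-class synthetic-structure generator (`hispi.synthetic_data`) places
residue pairs at *exact* target descriptor values and assembles whole
fixtures (His-tag runs, metal sites, deuterated His, designed H-bond
micro-environments), so the entire pipeline is testable without downloading
any structures.

## Package layout

| module                 | role |
|------------------------|------|
| `structure_io`         | PDB/mmCIF reading (deuterium-aware), altloc resolution, resolution/R-factor/method filters, metal lookup, PDB writing |
| `ring_geometry`        | least-squares ring planes, pairwise descriptors, cation sites, idealized hydrogen placement (HID/HIE/HIP, aromatic C–H, Lys ammonium, Arg guanidinium) |
| `pair_mining`          | carbon–carbon aromatic pair mining, cation–centroid mining, His-tag (≥5 run) and metal (5 Å) exclusions |
| `interaction_classify` | threshold-based labels (sets, non-exclusive), binding-energy filter (< −1 kcal/mol), mean±SD summaries |
| `protonation`          | tautomer calls from deuterium, three-scenario H-bond inference, metal-coordination shortcut, pKa categories (<5.3 / 5.3–7.3 / >7.3) and group fractions |
| `ensemble_stats`       | full-covariance GMM clustering (BIC-selected k), representative export, 2-D density maps, tautomer census |
| `synthetic_data`       | residue templates, exact-geometry pair placement, fixture manifests, QM fragment extraction, XYZ I/O |

## CLI

```bash
hispi filter --max-res 1.8 --max-r 0.18 --min-len 40 --max-len 10000 *.pdb
hispi mine structure.pdb --config mining.json
hispi geom structure.pdb
hispi classify structure.pdb --scenario HIE --energies energies.tsv
hispi tautomers neutron1.pdb neutron2.pdb
hispi protonate structure.pdb
hispi pka-groups --pka pka.txt --labels labels.tsv
hispi cluster structure.pdb --family aromatic --k auto --seed 17
hispi density structure.pdb --x T_theta2 --y P --symmetrize
hispi synth --manifest manifest.json --out fixture.pdb
hispi fragment structure.pdb --residue A:42 --scenario HIP --xyz frag.xyz
```

Every command writes its effective configuration into `#` header lines.
The synth manifest is JSON mirroring `synthetic_data.FixtureManifest`
(`aromatic_pairs`, `cation_pairs`, `his_tag_runs`, `metal_his`, `deuterated`,
`microenvironments`, `waters`, `spacing`).

## Notes

- Default thresholds and cutoffs (stacking D ≤ 5.5 Å / P ≤ 30°, cation–π
  D ≤ 6 Å / θ₁ ≤ 60°, CH–π, H-bond, mining cutoffs) are standard literature
  criteria and are configurable everywhere; outputs record the values used.
- Classification labels are sets: mixed geometries may satisfy several
  criteria simultaneously.
- Only the first model of multi-model files is used; altlocs resolve to the
  highest-occupancy conformer.
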