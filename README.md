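# vasco

Correction ("re-referencing") and validation of protein NMR chemical shifts
against 3D coordinates.

Archived chemical shifts are relative values: when the reference frequency of
an entry was set incorrectly, every shift of a nucleus group is offset by a
constant. This package estimates that offset per entry and per nucleus group
(H, N, aliphatic C, aromatic C, proton-less C) by comparing each shift with a
class-conditional Gaussian reference distribution, where a class is an
(atom type, secondary structure, solvent-accessibility bin) cell. With a flat
prior the group posterior is Gaussian in closed form:

    K     = sum over classes of  n_a * k_a            (total precision)
    c_bar = sum of  n_a * k_a * mean-residual_a  / K  (correction factor)
    sigma = K ** -0.5                                 (uncertainty)

A correction is applied (subtracted) only when |c_bar| >= 3 sigma; each
classified shift also gets a Z-score against its class distribution so
outliers can be flagged.

## Layout

| module             | contents |
|--------------------|----------|
| `vasco.core`       | domain types, residue topology, nucleus-group assignment |
| `vasco.io`         | shift lists (TSV / NMR-STAR loop), PDB models, report files |
| `vasco.annotate`   | Shrake–Rupley ASA fractions, six-state secondary structure, Needleman–Wunsch residue mapping |
| `vasco.refdb`      | equal-count ASA binning, class statistics, two-pass iterative build, serialization |
| `vasco.correction` | classification, posterior corrections, retention, Z-scores, stability experiment |
| `vasco.synthetic`  | seeded fixture generators: refdbs, entries with injected offsets, toy structures |
| `vasco.cli`        | `vasco` command-line front end |

## CLI

```sh
# synthetic fixtures (no archive data needed)
vasco synth refdb --out refdb.tsv
vasco synth entry --refdb refdb.tsv --n-shifts 400 --offset C_ali=2.0 \
    --seed 3 --out-shifts shifts.tsv --out-annotations ann.tsv
vasco synth structure --kind ideal_helix --n-residues 12 --out helix.pdb

# correct + validate one entry (report: per-group corrections, per-atom Z)
vasco run --shifts shifts.tsv --annotations ann.tsv --refdb refdb.tsv --out report.tsv
vasco run --shifts shifts.tsv --structure model.pdb --refdb refdb.tsv --model 0 --out report.tsv

# build reference statistics from (shifts, structure) pairs
vasco refdb-build --pairs pairs.txt --out refdb.tsv --bin-count 200

# random-deletion robustness test
vasco stability --shifts shifts.tsv --annotations ann.tsv --refdb refdb.tsv \
    --fractions 0.1:0.9:0.1 --samples 1000 --seed 42 --out stability.tsv
```

Thresholds (bin count 200, 3-sigma retention, 0.43% ASA discretization,
identity floor 0.8, 2 build iterations) are config keys; pass
`--config file` with flat `key = value` lines, CLI flags win.

## Notes

- ASA is computed with a 960-point Shrake–Rupley quadrature on heavy atoms
  (probe 1.4 Å, Chothia-style radii); proton shifts inherit the ASA of their
  bonded heavy atom. Values are reported as the fraction of the
  probe-inflated sphere surface that is exposed, discretized to multiples of
  0.43%.
- The builtin secondary-structure assigner uses Kabsch–Sander hydrogen-bond
  energies with helix/strand/turn pattern rules; supply STRIDE/DSSP-style
  states via `--ss-backend precomputed --ss-file ...` for exact fidelity.
- Shift and structure residue numberings are reconciled only through global
  sequence alignment; mismatched and gapped positions are excluded.
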