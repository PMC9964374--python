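# lipscreen

In silico screening and characterization of triacylglycerol-lipase
candidates in a proteome.

The package implements a multi-stage analysis pipeline as tested, reusable
library code plus a CLI:

- **`seqio`** — FASTA / aligned-FASTA / TSV readers and a PDB v3.3
  ATOM-record parser (backbone atoms + per-residue confidence from the
  B-factor field).
- **`motif_scan`** — exact residue-class motif grammars: the catalytic
  G-X-S-X-G pentapeptide (with X₁/X₂ extraction), the GDS(L) N-terminal
  motif, di-leucine sorting signals, ER-retention (KDEL-like), and
  PTS1/PTS2 peroxisomal signals with C-terminal anchoring.
- **`screen_funnel`** — the candidate-retention funnel: keyword query →
  E-value significance (< 1e-5) → motif requirement (GDSL exempt) →
  functional-homology exclusion → family assignment → inactive-motif
  (GDS→GDE) exclusion, with a per-protein audit trail.
- **`physchem`** — ProtParam-convention descriptor panel: molecular weight,
  charge counts, extinction coefficients at 280 nm, isoelectric point
  (Bjellqvist pKa set, bisection), instability index (threshold 40),
  aliphatic index (threshold 80), GRAVY, N-end-rule half-life.
- **`msa_analysis`** — per-column conservation (strict > 80% highlight
  rule, gap-aware), gap-coordinate lifting of motif hits, catalytic-partner
  candidate listing, oxyanion-hole typing (GX / GGGX / GDSL-type).
- **`localization`** — rule-based assignment to one of seven compartments
  from external-predictor tables plus motif evidence, vacuole-candidate
  flagging, and lipid-modification site summaries.
- **`regulation`** — signed maximal log2 fold change per gene across
  datasets/timepoints, classification at |log2| thresholds 1 and 2, and
  candidate ranking.
- **`structure_qc`** — backbone phi/psi dihedrals, Ramachandran region
  fractions (pluggable 10°×10° region map), plDDT band summaries at
  50/70/90, and centered rolling means.
- **`synthetic_data`** — deterministic generators for every input format
  with planted ground truth (random proteins, motif planting, screen sets,
  predictor tables, regulation tables, ideal-geometry backbone PDB files).

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (property suites,
planted-truth integration, worked-example checks). The real-sequence checks
are skipped unless `data/phatr3_table1.fasta` is supplied (it requires an
Ensembl Protists download and is not bundled).

## CLI

```sh
lipscreen simulate --seed 1 --out sim/            # synthetic input bundle
lipscreen report --fasta sim/proteins.fasta \
    --annotations sim/annotations.tsv \
    --predictors sim/predictors.tsv \
    --regulation sim/regulation.tsv --out out/    # full pipeline
```

Individual stages: `screen`, `motifs`, `physchem`, `msa`, `localize`,
`regulate`, `structqc`. Every flag mirrors a YAML config key (`--config`);
flags win. Outputs are TSV tables plus a plain-text log; the merged
candidate report has columns id / family / regulation / GRAVY /
localization.

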