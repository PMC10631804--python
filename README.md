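# secretome

Kinetic classification and donor-effect analysis of mesenchymal stromal
cell (MSC) conditioned-media proteomes.

MSCs exert much of their therapeutic effect through the proteins they
secrete, but a conditioned-medium (CM) proteome mixes genuinely secreted
proteins with intracellular proteins leaked from dying cells. This package
implements the two computational halves of a dynamic-labeling secretome
study:

1. **Dynamic stable-isotope labeling kinetics.** During a pulse of heavy
   lysine/arginine, newly synthesised (classically secreted) proteins
   incorporate label fast while the leaked intracellular pool labels
   slowly. Per peptide, the relative isotope abundance is

   RIA(t) = H / (H + L),

   and pooling peptides by their leading razor protein, the package fits

   RIA(t) = A·(1 − e^(−k·t))

   by nonlinear least squares. Proteins with rate constant k > 0.01 h⁻¹
   are classified secreted, the rest intracellular. Extracellular flux is
   P·k, where P is the gain in mean total peptide abundance (H+L) between
   the 6 h and 24 h collections. The classification is validated by
   hypergeometric over-representation of GO cellular-component terms.

2. **Donor-effect modelling on label-free quantification (LFQ) data.**
   Protein-group tables are filtered (≥2 unique peptides, ≤30% missing
   values), optionally imputed (complete-case, down-shifted per-sample
   draws, or per-protein means), and explored by PCA, fuzzy c-means and
   DTW time-course clustering over donor age, and NMF consensus clustering
   with cophenetic rank selection. Per secreted protein, abundance is
   modelled with a Gamma GLM (log link),

   log E[y] = β₀ + β_age·age + β_sex·1[M] + β_tissue·1[BMSC],

   on complete cases, with Benjamini–Hochberg adjustment per predictor
   across proteins and log2 fold changes for the categorical contrasts.
   The same machinery covers the orthogonal assays: a Gaussian
   random-intercept mixed model for the enzymatic-activity time course
   (time, age, time×age fixed effects) and a Gamma GLM for immunoassay
   concentrations.

A fully seeded synthetic-data module generates MaxQuant-dialect evidence
and proteinGroups tables, donor metadata, and assay measurements with
known ground truth for every stage.

## Worked example

```python
import numpy as np
from secretome.simulate import (EvidenceSimConfig, simulate_evidence,
                                evidence_raw_file_hours)
from secretome.kinetics import analyze_kinetics
from secretome.mq_tables import SchemaConfig, read_evidence, filter_evidence

config = EvidenceSimConfig(n_proteins=12, noise_cv=0.1)
evidence, truth = simulate_evidence(config, seed=17)
evidence.to_csv("evidence.txt", sep="\t", index=False)

schema = SchemaConfig(raw_file_hours=evidence_raw_file_hours(config))
records = filter_evidence(read_evidence("evidence.txt", schema))
kinetics = analyze_kinetics(records, cutoff=0.01)
print(kinetics[["k", "plateau", "P", "flux", "classification"]].round(4).head(6))
```

prints

```
                 k  plateau             P         flux classification
protein_id
P0000       0.0013   1.0000 -6.684237e+03      -8.5998  intracellular
P0001       0.0664   0.7577  2.944520e+05   19553.5601       secreted
P0002       0.2863   0.8874  1.595826e+05   45696.4420       secreted
P0003       0.0024   1.0000  5.522390e+04     131.1551  intracellular
P0004       0.1266   0.8518  1.078869e+06  136608.5977       secreted
P0005       0.9536   0.7925  9.008498e+05  859038.2945       secreted
```

Each row is one protein: `k` is the fitted label-incorporation rate
(per hour), `plateau` the asymptotic RIA, `P` the 24 h − 6 h abundance
gain (arbitrary intensity units), `flux = P·k` the cell-to-medium flow
rate, and the classification thresholds `k` at 0.01 h⁻¹. On this fixture
all 12 calls agree with the generator's truth; P0000 shows the slow
labeling and near-flat abundance of leaked intracellular protein, P0005
the fast labeling of an actively secreted one.

The same stages are scriptable from the shell:

```sh
secretome simulate evidence --n-proteins 200 --out sim/
secretome sidls --evidence sim/evidence.txt \
    --timepoints "SIDLS_001.0h=1,SIDLS_002.0h=2,SIDLS_006.0h=6,SIDLS_024.0h=24" \
    --cutoff 0.01 --out results/
secretome labelfree --proteingroups pg.txt --metadata meta.csv --impute none --out results/
secretome associate --lfq pg.txt --metadata meta.csv --secreted-list results/secreted_proteins.csv --out results/
secretome run --config config.yaml   # full pipeline with manifest
```

## Layout

- `src/secretome/mq_tables.py` — MaxQuant-style table readers and filters
- `src/secretome/kinetics.py` — RIA trajectories, first-order fits, flux
- `src/secretome/ora.py` — hypergeometric enrichment, BH adjustment
- `src/secretome/labelfree.py` — missingness, imputation, PCA, fuzzy
  c-means, DTW, NMF consensus
- `src/secretome/association.py` — Gamma GLMs, mixed model, fold changes
- `src/secretome/simulate.py` — ground-truth generators
- `src/secretome/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
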