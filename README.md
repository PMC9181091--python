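# netproxrx

Network-proximity drug repurposing on a protein–protein interactome,
with signature-reversal cross-checking and combined candidate ranking.

`netproxrx` is for computational biologists who want to prioritize
approved drugs for a new disease indication from three standard
ingredients: an interactome edge list, a disease-associated gene set,
and a drug→target table — optionally refined with disease expression
datasets and a library of drug perturbation signatures.

## The method

**Network proximity.** For a drug with target set *T* and a disease
gene set *D* on an interactome with hop distances *sp(·,·)*, the
closest-distance proximity is

```
d(T, D) = (1/|T|) Σ_{t∈T} min_{g∈D} sp(t, g)
```

Significance comes from a degree-preserving permutation null: both *T*
and *D* are replaced by random gene sets drawn from degree-matched bins
(preserving each set's hub/leaf profile), giving a z-score and an
empirical p-value

```
p = (#{d_rand < d_obs} + ½·#{d_rand = d_obs} + 1) / (n_perm + 1)
```

(ties counted at half weight because hop-count proximities are
discrete; the +1 pseudocount keeps p > 0). Within a scored batch,
distances are min–max rescaled into a **network similarity** on [0, 1]
— 1 for the most proximal drug, 0 for the most distant.

**Signature reversal.** Each disease expression dataset is reduced to a
signature (up/down gene sets at Benjamini–Hochberg adjusted p < 0.05).
A two-sided weighted Kolmogorov–Smirnov connectivity score in [−1, 1]
compares each drug's ranked expression profile to each signature;
negative means the drug shifts disease-up genes down and disease-down
genes up. The integer **GSEA score** of a drug is the number of
datasets (0..N) it reverses; drugs without a profile get NA.

**Prioritization.** Drugs with p < 0.05 are ranked by similarity
(descending), then GSEA score (descending, NA last), then name
(alphabetical). A radial-plot export places each candidate at radius
1 − similarity, colored by GSEA score.

## Worked example

Every input can be simulated with planted ground truth, so the full
pipeline runs without any external database:

```sh
cat > sim.yaml <<EOF
n_nodes: 2000
module_size: 25
n_drugs_proximal: 10
n_drugs_random: 40
seed: 7
EOF
netproxrx simulate --config sim.yaml --outdir fx
netproxrx score --graph fx/edge_list.tsv --disease fx/disease.gmt \
    --drugs fx/drug_targets.tsv --n-perm 1000 --seed 7 --out scores.tsv
netproxrx gsea --de fx/de_DS1.tsv --de fx/de_DS2.tsv --de fx/de_DS3.tsv \
    --drug-sigs fx/drug_signatures.tsv --scores scores.tsv --out gsea.tsv
netproxrx prioritize --scores scores.tsv --gsea gsea.tsv --alpha 0.05 \
    --out ranked.tsv --radial radial.tsv
```

The run prints `11 of 50 drugs significant at p < 0.05`, and
`ranked.tsv` begins:

```
rank  drug_name     similarity  p_value   gsea_score  drug_id
1     proxidrug-00  1.0         0.003497  3           DSYN0000
2     proxidrug-04  1.0         0.000999  3           DSYN0004
3     proxidrug-01  0.857143    0.002498  3           DSYN0001
```

All ten drugs planted near the disease module (and built to reverse the
three disease signatures) occupy the top ten ranks with GSEA score 3;
the one surviving decoy is a distant 11th. Similarity 1.0 means the
drug's targets are the closest of the batch to the disease module;
p_value is the permutation p; gsea_score 3 means all three expression
datasets are reversed.

The same ranking logic applies to real tables. With precomputed
similarity/p/GSEA values for nine histaminergic candidates against
multiple sclerosis (`examples/histaminergic_candidates.tsv`), the
three-key ordering puts the HNMT inhibitor amodiaquine (similarity 1,
p = 0.00806, GSEA 3) in rank 1, ahead of the H1 antagonists rupatadine
and diphenhydramine — see `tests/test_prioritize.py::TestWorkedExample`.

## Layout

| Module | Role |
| --- | --- |
| `netproxrx.interactome` | graph loading, LCC, BFS distances, degree bins, degree-matched sampling |
| `netproxrx.entity_io` | GMT gene sets, drug–target TSVs, id mapping, graph restriction |
| `netproxrx.proximity` | closest proximity, permutation significance, similarity, cluster adjustment |
| `netproxrx.signatures` | BH selection, weighted-KS connectivity, GSEA scores |
| `netproxrx.prioritize` | significance filter, three-key ranking, radial export |
| `netproxrx.synthetic` | synthetic interactomes, planted drugs, signature libraries |
| `netproxrx.cli` | `netproxrx` command-line entry points |
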