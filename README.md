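# multinet

Multilayer subject-similarity networks for multimodal disease subtyping.

Alzheimer's disease is heterogeneous: structural MRI, amyloid-PET, CSF
analytes, cognitive scores and genetic risk each capture part of the
picture, and analyses that treat the modalities one at a time miss the
signal they share. `multinet` models a cohort as a **multiplex network**:
one layer per modality, every subject present in every layer, intra-layer
edges weighted by the pairwise correlation between two subjects' feature
vectors, and interlayer edges tying each subject's copies together. A
single community detection pass over all layers then yields subject groups
("subtypes") that share profiles *across* modalities, which can be compared
against clinical diagnosis at baseline and at follow-up.

It is aimed at researchers with subject × feature tables per modality (e.g.
ADNI-style cohorts) who want a tested, reproducible implementation of the
multilayer pipeline plus a synthetic-cohort generator to validate it without
access to restricted data.

## The model

Communities maximize the multislice modularity

```
Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ_l M_ijl) δ_lr + δ_ij ω_jlr ] δ(g_il, g_jr)
```

where `A_ijl` is the similarity of subjects *i* and *j* in layer *l*,
`M_ijl` the per-layer configuration-model null (`k_il k_jl / 2m_l` for
nonnegative layers; positive and negative strengths are nulled separately
for signed layers), `γ_l` a per-layer resolution, `ω_jlr` the uniform
categorical interlayer coupling, `g_il` the community of subject *i* in
layer *l*, and `2μ` the total edge weight. Optimization is an iterated
generalized Louvain: greedy node moves on the supra-modularity matrix
`B`, community aggregation, random restarts, and re-iteration from the
flattened partition until `Q` converges. With one layer and `ω = 0` this
reduces exactly to classical Newman–Girvan modularity maximization.

The pipeline stages, each usable on its own:

| module                 | what it does |
| ---------------------- | ------------ |
| `multinet.cohort_io`   | CSV readers/writers, complete-case alignment, `RunConfig`, `run_pipeline` |
| `multinet.preprocess`  | mean centering → covariate residualization (age/sex/ICV, per-modality sets) → min–max or z-score normalization |
| `multinet.similarity`  | pairwise-correlation subject networks, optional sanitization of negative edges |
| `multinet.multilayer`  | supra-modularity assembly, modularity `Q`, generalized Louvain, consensus labels |
| `multinet.evaluation`  | community × diagnosis contingency, sensitivity/specificity with exact Clopper–Pearson CIs, amyloid SUVR stratification (cutoff 1.11), transition breakdowns, scaled Mann–Whitney U maps |
| `multinet.synthetic`   | planted-subtype multimodal cohort generator + adjusted-Rand recovery scoring |

## Worked example

Simulate a 60-subject cohort with two planted subtypes (effect size 1.5 SD,
per-layer expression probability 0.9), run the pipeline, and score it:

```sh
multinet simulate --config sim.yaml --out cohort/   # writes mri.csv ... truth.csv
multinet run --config run.yaml --out out/           # writes partition.csv, metrics.json, contingency.csv
multinet evaluate --partition out/partition.csv --labels cohort/labels.csv
```

which prints (abridged):

```
dx           CN   MCI    AD  CN_pct_within_dx  MCI_pct_within_dx  AD_pct_within_dx
community
0           2.0  10.0  13.0               7.7               47.6             100.0
1          24.0  11.0   0.0              92.3               52.4               0.0
{
  "sensitivity": 100.0,
  "specificity": 92.3,
  "sensitivity_ci": [75.29, 100.0],
  "specificity_ci": [74.87, 99.05],
  "community_labels": {"0": "AD-dominant", "1": "CN-dominant"}
}
```

Two communities emerged. Community 0 holds all 13 subjects whose final
diagnosis is AD (sensitivity 100%, exact 95% CI 75.3–100 — wide because only
13 AD cases exist) and community 1 holds 24 of the 26 cognitively normal
subjects (specificity 92.3%, CI 74.9–99.1); MCI subjects split between the
two, as expected for a prodromal group. Against the generator's planted
subtypes the consensus partition scores an adjusted Rand index of 0.75.

The same objects are available in Python:

```python
import multinet as mn
from multinet.synthetic import SyntheticConfig, generate_cohort

tables, covs, labels, truth = generate_cohort(SyntheticConfig(n_subjects=60, seed=3))
spec = mn.PreprocessSpec()
layers = [mn.build_similarity_layer(mn.preprocess_modality(t, covs, spec)) for t in tables]
net = mn.assemble_multilayer(layers, gamma=1.0, omega=1.0)
part = mn.genlouvain(net, restarts=20, seed=3)
consensus, split = mn.consensus_node_labels(part)
summary = mn.summarize_contingency(consensus, labels, "final")
```

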