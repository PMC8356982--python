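# spesnet

Effective-connectivity analysis of single-pulse electrical stimulation
(SPES) in intracranial EEG.

SPES probes causal ("effective") connectivity between intracranial
recording sites: brief biphasic current pulses are delivered to adjacent
electrode pairs while the evoked potentials at every other site are
recorded. `spesnet` implements the full analysis chain used to ask how the
mesial temporal region (MTR — amygdala, hippocampus, entorhinal cortex,
parahippocampal gyrus) behaves inside the wider epileptic network, and how
that behaviour changes with the epileptogenicity of the MTR (focal,
multifocal, or non-epileptogenic seizure onset). It is written for
epilepsy-surgery and systems-neuroscience researchers who want a tested,
reusable version of this pipeline — together with a synthetic iEEG cohort
generator with known ground truth, so every stage is verifiable without
patient data.

## The method

For each stimulated pair (50 biphasic pulses, 0.3 ms width, 1 or 2 s ISI):

1. **Preprocess** — reject noisy channels (robust-SD criterion), bipolar
   re-reference, replace the stimulation artifact in −5..+10 ms with
   reversed, tapered copies of the flanking signal, low-pass filter at
   50 Hz (zero phase), and epoch into −500..1500 ms windows (2 s ISI;
   −250..750 ms for 1 s ISI).
2. **Evoked Z-score** — baseline-mean-center each trial, average, and divide
   by the baseline SD of the average. The edge weight is
   `Z = |N1|`, the absolute amplitude of the early (10–50 ms) deflection in
   baseline-SD units; `Z > 6` marks a significant effective connection.
3. **Network** — significant Z-scores form one row of a weighted directed
   adjacency per stimulated pair (attributed to both pair electrodes).
   Ordered node pairs are classed *within / out / in / outside* by MTR
   membership of source and target; connections touching seizure-onset
   tissue outside the MTR are excluded. The **weighted density** of a class
   is ΣZ over its significant connections divided by its possible-connection
   count.
4. **Centrality** — per node: possible-normalized in/outdegree, HITS
   authority/hub, and Katz receive/broadcast (α = 0.9/λ, β = 1), each
   unit-normalized per patient; outgoing measures are reported only for
   stimulated nodes.
5. **Statistics** — pooled Z-scores and node centralities: grouped
   Kruskal–Wallis + Dunn post hoc; per-patient densities and mean
   centralities: linear mixed-effects models (patient random intercept) with
   likelihood-ratio tests of full vs reduced ML fits, Shapiro–Wilk residual
   checks, and pairwise t contrasts with model-pooled SE and containment
   degrees of freedom. All p-values are Benjamini–Hochberg FDR adjusted
   within their analysis family.

The synthetic generator (`spesnet.synthetic`) renders whole cohorts of
bilateral SPES sessions — coloured 1/f²-plus-white noise, confined
broadband artifacts, jittered N1/N2 deflections — on top of a ground-truth
connectivity matrix whose entries are the target Z-scores, with elevated
within-MTR connectivity everywhere and group-dependent MTR in/out
connectivity (focal elevated).

## Worked example

```
$ spesnet run-all --seed 1 --n-per-group 2 --out results/demo
pipeline complete; outputs under results/demo
```

This simulates six bilateral patients (two per group), runs every stage,
and writes tidy TSVs. `results/demo/densities.tsv` starts:

```
conn_type  side  n_possible  n_significant  weighted_density  patient_id  group
within     left  24          16             12.173            S01         focal_mtr
out        left  96          32             4.067             S01         focal_mtr
in         left  72          22             4.268             S01         focal_mtr
outside    left  168         26             1.903             S01         focal_mtr
```

Read: for patient S01 (focal epileptogenic MTR, seizure onset left), 16 of
the 24 orderable within-MTR pairs carried significant evoked potentials,
giving a within-MTR weighted density of 12.2 baseline-SD units — several
times the density of the *out*, *in*, and *outside* subnetworks, and the
*out*/*in* densities in turn exceed those of non-focal patients in the same
run. `stats.tsv` holds the corresponding Kruskal–Wallis/Dunn and
mixed-model LRT results with FDR-adjusted p-values, and
`centrality_pooled.tsv` / `centrality_means.tsv` the six per-node
centrality measures grouped by location.

A Python entry point mirrors the CLI:

```python
from spesnet.pipeline import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig(n_per_group=2, rng_seed=1), "results/demo")
```

The packaged 18-patient reference cohort reproduces the published
aggregates:

```python
>>> from spesnet.cohort_io import load_reference_cohort, cohort_summary
>>> _, patients = load_reference_cohort()
>>> s = cohort_summary(patients)
>>> s["electrodes_implanted"]["median"], s["mtr_implanted_per_side"]["median"]
(100.5, 9.0)
>>> s["group_counts"]
{'focal_mtr': 4, 'multifocal_mtr': 9, 'non_epileptogenic_mtr': 5}
```

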