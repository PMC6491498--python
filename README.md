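# ftdnet

Functional brain-network resilience analysis for presymptomatic genetic
frontotemporal dementia (FTD), exercised end to end on synthetic cohorts.

## The problem

Carriers of pathogenic C9orf72, MAPT, or GRN variants accumulate brain
atrophy and lose functional connections years before FTD symptoms appear,
yet remain cognitively well.  One candidate explanation is *functional
network resilience*: the brain maintains an efficient small-world topology
of its functional connectome until close to the expected age of symptom
onset, and that topological efficiency — rather than raw connectivity —
tracks cognitive health.  Testing this requires a pipeline that (i)
estimates frequency-specific functional connectivity from parcellated fMRI
time series, (ii) reduces each subject's connectome to interpretable graph
measures referenced to degree-preserving null networks, and (iii) relates
those measures to group, proximity to expected onset, atrophy, and
cognition with mixed-effects models.  `ftdnet` implements that pipeline as
a tested, reusable library plus a small set of analysis drivers, for
researchers who want to run or probe this class of analysis without access
to restricted cohort data.

## The measures

For each subject the region × time signal matrix is bandpass-decomposed
with the maximal-overlap discrete wavelet transform (Daubechies-4), and
connectivity is the Pearson correlation of the wavelet coefficients at the
dyadic scale that best overlaps 0.0675–0.125 Hz (scale 2 for TR ≈ 2.2 s).
The correlation matrix is thresholded to a target edge density over a
maximum-spanning-tree backbone, and with edge length d = 1/w the package
computes, per node, the connection strength s_i = Σ_j w_ij (weighted
degree), the farness (mean shortest-path length; the closeness-centrality
variant where lower is better), and the nodal efficiency (mean inverse
shortest-path length); globally, the total connection strength Σ_i s_i and
the global efficiency E = mean over ordered pairs of 1/d_ij.  Efficiency
measures are normalized by their means over degree-preserving,
weight-multiset-preserving random graphs.  Hubs are regions whose strength
in the gene-negative group exceeds the across-region mean by > 2 SD.

Inference follows the study design: mixed-effects contrasts
`outcome ~ group + age + (1|site) + (1|gene)` with Satterthwaite degrees of
freedom (validated against lmerTest), discontinuous piecewise ("breakpoint")
regression of each outcome on years to expected onset with a joint 2-df
test of the slope and level change at onset, a hub × group interaction for
hub vulnerability, and per-group strength–volume / strength–cognition
associations with slope-difference tests.

Because no public data accompany this design, the `cohort` module generates
seeded synthetic cohorts (default 80 gene-negative / 68 carrier / 24 FTD)
whose covariance structure, disease trajectories, and outcome couplings
emulate the study's statistical structure with known ground truth; see
`docs/methods.md` for the generative model and its limitations.

## Worked example

Run the numbered analysis drivers (or equivalently `ftdnet run`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_connectivity.py
python analysis/03_network_metrics.py
python analysis/04_inference.py
```

The final step prints the headline pattern of the default run
(172 subjects, 90 regions, TR 2.2 s, density 10%, 50 nulls, seed 0):

```
connection strength, carrier - FTD: +25.11 (p = 9.2e-13)
normalized efficiency, carrier - FTD: -0.0054 (p = 0.29)
efficiency breakpoint at onset: p = 5.8e-05 (post-onset slope -0.0022/yr vs pre +0.0018/yr)
strength breakpoint at onset: p = 0.19
strength-volume correlation: FTD r = 0.58 (p = 0.0033); carriers r = 0.00 (p = 0.99)
hub-gap interaction on strength: +0.262 (p = 0.00039)
hub-gap interaction on farness: -0.118 (p = 4.6e-05)
```

Read: symptomatic FTD subjects have lost connection strength relative to
presymptomatic carriers (first line), but the *topological* efficiency of
their networks does not separate the groups on average (second line);
instead efficiency is maintained up to the expected onset age and declines
afterwards (a significant breakpoint for efficiency, none for strength);
and the strength–atrophy correlation is confined to the symptomatic group.
The hub-gap lines reflect the generator's pruning rule, which spares hub
connections: the hub-minus-nonhub strength gap widens in FTD and hubs
remain relatively close to the rest of the network.  (Hub *weakening* is
exercised separately, through the regional outcome simulator's hub-attack
dial, in the test suite.)  All of these patterns are imposed by the cohort
generator; the run demonstrates that the pipeline recovers them at the
study's sample sizes.

Each stage writes its tables under `results/run/` (`subjects.tsv`,
`connectivity/*.tsv`, `metrics.tsv`, `nodal_metrics.tsv`, `contrasts.tsv`,
`breakpoints.tsv`, `associations.tsv`, `run_report.json`).

The same pipeline is scriptable from a shell:

```bash
ftdnet run --config configs/demo.yaml --seed 7 --output-dir results/run7
```

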