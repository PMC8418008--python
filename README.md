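# retinotarget

Multi-omic prioritization of retinoid-receptor target genes in hepatocellular
carcinoma tumor-repopulating cells (TRCs).

## The problem

Retinoid treatment of TRCs induces the transcription factor RARα, which in
turn represses a small set of driver genes. Identifying *which* repressed
gene is the functional driver requires integrating several weak signals:
dose-dependent down-regulation in expression, RARα binding at the promoter,
centrality in the co-expression network, and membership in oncogenic
pathways. This package implements that integration as a reusable, tested
pipeline, together with a synthetic-data generator that plants a known
driver so every stage can be validated against ground truth.

The pipeline ranks candidate genes by four priorities applied
lexicographically:

1. **Network degree** — the number of neighbors in the Pearson co-expression
   network built over all samples with edges at |r| > 0.9 and two-sided
   P < 0.05 (t statistic r·√((n−2)/(1−r²)) on n−2 df); candidates must have
   degree ≥ 18.
2. **Pathway burden** — the number of catalog pathways containing the gene,
   with oncogenic families (RAS signaling, cell cycle, stem-cell
   pluripotency, ubiquitin-mediated proteolysis) counted first.
3. **Binding evidence** — the maximum M-value over the gene's promoter
   peaks, retained at M ≥ 0.5 and P < 0.05.
4. **Cluster membership** — the gene's fuzzy c-means membership (threshold
   ≥ 0.2) in a dose-down-regulated cluster. Profiles are condition means
   standardized per gene; clustering uses Bezdek fuzzy c-means with c = 8
   and fuzzifier m = 1.25 on the objective Σᵢⱼ uᵢⱼᵐ‖xᵢ − vⱼ‖².

Two companion analyses round out the study: super-enhancer calling by the
rank-ordering construction (regions sorted by ascending H3K27ac signal, both
axes scaled to [0, 1], cutoff at the slope-1 tangent point of the curve),
and plate pharmacology — the inhibition rate
[(OD_control − OD_treated)/(OD_control − OD_blank)] × 100, four-parameter
logistic IC50 fitting, and the Chou–Talalay combination index
CI = d_a/Dx_a + d_b/Dx_b from median-effect fits
log(fa/(1−fa)) = h(log D − log Dm), with CI < 1 indicating synergy.

## Worked example

Run the numbered analysis scripts in order (each writes tables under
`results/`):

```sh
python analysis/01_simulate_study.py
python analysis/02_cluster_dose_response.py
python analysis/03_integrate_peaks.py
python analysis/04_rank_candidates.py
python analysis/05_call_super_enhancers.py
python analysis/06_pharmacology.py
```

Output of a run (seed 1):

```
simulated 200 genes x 27 samples; driver = G0170 with 25 planted neighbors
8 clusters in 134 iterations; down-regulated clusters [1, 3, 6, 8] select 96 genes (membership >= 0.2)
44/104 peaks pass M >= 0.5, P < 0.05; 14 promoter peaks back 14 of 96 responsive genes
gene_id  degree  n_pathways  oncogenic_pathways  peak_m  membership  priority_rank
  G0170      25           4                   4     1.2         1.0              1
top gene G0170 (25 network neighbors); planted driver G0170 recovered at rank 1
50 super-enhancers above cutoff 40.0 (2 with factor co-occupancy); 50/50 planted recovered, 0 false calls
IC50: drug A 2.87 uM, drug B 6.98 uM; CI at fa=0.5: 0.63 (synergy)
```

Reading the numbers: the simulated study has 3 cell contexts × 3 doses × 3
replicates. Fuzzy clustering finds the dose-down-regulated clusters and
selects 96 responsive genes; peak filtering and promoter assignment leave 14
of them with binding evidence; the degree filter and four-priority sort
place the planted driver (G0170, 25 network neighbors, 4 oncogenic pathways,
promoter peak M = 1.2) at rank 1. The enhancer landscape yields exactly the
50 planted super-enhancers, and the pharmacology module recovers the planted
IC50s (2.83 and 7.0 µM) and calls the potency-shifted combination plate
synergistic (CI < 1).

The same stages are available as a CLI (`retinotarget simulate | cluster |
integrate | rank | enhancers | pharm`); rerunning any stage with the same
seed and configuration reproduces its outputs byte for byte.

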