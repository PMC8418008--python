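# Methods

## Study design emulated by the simulator

The pipeline targets a dose-escalation design: three cellular contexts — a
tumor-repopulating-cell (TRC) population, its parental cancer line, and a
normal-liver analog — treated at 0, 1 and 5 µM of a retinoid, three
replicates each, profiled as log2 expression. The synthetic generator
(`retinotarget.synth`) reproduces this layout with planted structure so the
pipeline's behavior can be measured against known truth.

**Expression.** Each non-driver gene follows one of eight archetype
dose-response templates; three (indices 0, 2, 4) are strictly decreasing in
dose and play the role of the down-regulated clusters from which oncogene
candidates are drawn. The dose response is attenuated per context (TRC 1.0,
parental 0.6, liver 0.25), reflecting TRC-selective drug action. A gene's
condition-level value is baseline (N(8, 1.5²) log2 units) + amplitude 1.0 ×
template × context attenuation + per-gene condition jitter N(0, 0.5²) +
replicate noise N(0, noise_sd²), noise_sd = 0.05 by default. The jitter
magnitude is deliberately half the pattern amplitude: large enough that
unrelated same-pattern genes stay below the |r| > 0.9 edge threshold
(typical r ≈ 0.55), small enough that genes still cluster with their
archetype.

**The planted driver.** One gene is designated the driver: it follows a
decreasing template, carries a promoter peak at M = 1.2 (P = 0.005), sits
in all four oncogenic pathway families, and receives `target_degree` (25)
companion genes built as affine copies of its realized profile. Companion
noise is drawn Gaussian at the condition level, then centered,
orthogonalized against the centered driver profile, and rescaled to a fixed
magnitude of 0.38 × the driver's realized profile sd. This pins every
driver–companion correlation at 1/√(1 + 0.38²) ≈ 0.935 — safely above the
0.9 edge threshold — while companion–companion correlations scatter around
0.935² ≈ 0.87, mostly below it. The driver is therefore the unique hub of
its neighborhood with degree equal to `target_degree` by construction.
Earlier iid-noise designs were discarded: the smallest-noise companion
approaches a duplicate of the driver and can out-degree it through
borderline edges, which breaks the required recoverability of the planted
driver. With the fixed-magnitude design, the full pipeline ranks the driver
first in ≥ 98 of 100 seeds across independent seed pools (measured
300/300, 100/100, 98/100, 99/100).

**Peaks, pathways, enhancers, plates.** Genes are tiled every 50 kb on one
synthetic chromosome (TSS at gene start, all forward strand; the
assignment code handles both strands and is tested on mixed-strand
layouts). Besides the driver peak, three companions receive weaker passing
promoter peaks, and 100 decoy peaks are split between promoter and distal
locations with 40% passing the M ≥ 0.5, P < 0.05 filter. The pathway
catalog holds the four oncogenic families plus 16 generic sets with random
membership; companions receive only generic memberships, realizing the
design assumption that co-expressed neighbors need not share the driver's
pathway centrality. The enhancer landscape is 1,000 tiles whose signals mix
a Uniform(0, 40) background with a heavy-tailed super component
80·(1 + Pareto(1.5)); tiles cover the promoter zones of the gene tiling so
factor co-occupancy is a real, measurable overlap. Viability plates follow
a symmetric four-parameter logistic with control OD 1.2 and blank OD 0.08,
in the µM IC50 range reported for retinoid/kinase-inhibitor treatment of
TRCs; combination plates are generated under Loewe additivity with an
optional potency shift (< 1 synergy, > 1 antagonism).

## Clustering

Profiles are condition means (replicates averaged) standardized per gene to
mean 0, sd 1. Standardization divides by the sample sd (n − 1), matching
the convention of the Mfuzz-style `standardise` step used for expression
time-courses; population sd is available via `ddof=0`. Zero-variance genes
go to a skip list rather than the cluster input.

Fuzzy c-means minimizes Σᵢⱼ uᵢⱼᵐ‖xᵢ − vⱼ‖² with memberships
uᵢⱼ = [Σₖ (dᵢⱼ/dᵢₖ)^(2/(m−1))]⁻¹; an exact centroid hit receives membership
1. Defaults: c = 8 clusters, fuzzifier m = 1.25 (a common choice for
standardized expression profiles; the selection results are stable over
m ∈ [1.15, 1.5]), tolerance 1e-6 on the maximum centroid shift, 300
iterations maximum. Initialization is deterministic farthest-point seeding
starting from the point farthest from the data mean — fully data-dependent,
so permuting the gene order permutes the memberships without changing them,
and reruns are bit-identical. Membership ratios are computed relative to
the row-minimum distance so the near-hard limit (m → 1⁺) cannot overflow.

A cluster is called *down-regulated* when its centroid at the top dose lies
below its value at dose zero within the TRC context block (the first
context by default, configurable) — the direction call uses endpoints
rather than strict monotonicity because intermediate-dose behavior varies
across archetypes. A gene is selected when its argmax-membership cluster is
down-regulated and that membership is ≥ 0.2 (boundary included).

## Peak integration

Peaks are retained at M ≥ 0.5 (inclusive) and P < 0.05 (strict); the
inclusive/strict split follows the stated filter convention of the
differential-binding statistic. Retained peaks are assigned to a gene when
they overlap the strand-oriented promoter window, default 2,000 bp upstream
to 500 bp downstream of the TSS (half-open intervals); the window is a
standard regulatory-genomics convention and configurable. A peak
overlapping several promoters goes to the nearest TSS (peak-center
distance), exact ties to the lexicographically smaller gene id. Candidate
genes are responsive genes with at least one retained assigned peak —
promoter-class by default, switchable to any assigned peak — with evidence
the maximum M over their peaks.

## Network and ranking

The co-expression network is built over all samples (contexts × doses ×
replicates), not condition means, to maximize n for the edge test. Edges
require |r| > 0.9 strictly and two-sided P < 0.05 from
t = r√((n−2)/(1−r²)) on n − 2 df; no multiple-testing correction is
applied, matching the raw threshold convention. Zero-variance genes remain
isolated nodes. The network spans every gene in the matrix — a candidate's
neighbors need not themselves be candidates — while the degree filter
(≥ 18, boundary included) and the ranking apply to candidates only.

The four priorities combine as filters followed by a lexicographic sort:
degree desc, then oncogenic pathway count desc, total pathway count desc,
peak M desc, membership desc, residual ties by gene id. Oncogenic pathways
outrank the raw count within the pathway criterion, reflecting the emphasis
on tumorigenesis-associated families. The ego subnetwork of any gene is the
induced subgraph on the gene and its direct neighbors.

## Super-enhancer calling

Regions on one chromosome are optionally stitched (gap < 12.5 kb, the
community-standard distance; signal summed) and sorted by ascending signal.
Both rank and signal are min-max scaled to [0, 1]; the cutoff sits at the
point of maximal vertical gap below the diagonal — equivalently, where the
tangent of the convex rank curve has slope 1. Regions with signal strictly
above the cutoff signal are super-enhancers, so the SE/TE partition is
monotone in signal and invariant to positive rescaling. Degenerate curves
need a guard: when the maximal gap is below `min_gap` = 0.05 (constant or
near-linear landscapes, where the tangent construction is meaningless) no
region is called. Factor co-occupancy flags any region overlapping a
retained binding peak by ≥ 1 bp.

## Pharmacology

The inhibition rate is [(OD_control − OD_treated)/(OD_control − OD_blank)]
× 100, unclipped by default (noisy plates may legitimately fall outside
[0, 100]); OD_control ≤ OD_blank is an error, not a warning. Replicates are
averaged per dose before fitting, matching plate practice.

IC50s come from a four-parameter logistic
inhibition = bottom + (top − bottom)/(1 + (IC50/dose)^h), fitted by
least squares in log-IC50 parameterization with a deterministic multi-start
(geometric IC50 grid across the dose range × Hill grid {0.5, 1, 2, 4});
the lowest-SSE start wins, so the fit is reproducible. Flat responses
return `converged=False` instead of raising. The 4PL model and the
variable slope are assumptions documented here — the plate protocol itself
does not prescribe a model.

Drug interaction uses the median-effect line
log(fa/(1−fa)) = h(log D − log Dm) fitted by least squares per agent and
for the fixed-ratio combination, and the two-term (mutually
nonexclusive-free) combination index CI = d_a/Dx_a + d_b/Dx_b, where Dx is
each single agent's dose for the chosen effect level and (d_a, d_b) are the
combination's component doses at that effect, interpolated on the
combination's own median-effect fit. The headline effect level defaults to
fa = 0.5 and is exposed as a parameter since combination reports rarely
state it. A drug combined with itself at half doses yields CI = 1
identically; Loewe-additive simulations recover CI = 1 within 0.02 even
when the two agents' Hill slopes differ (the combination's median-effect
line is then only approximately straight, which is the dominant error
term).

## What the synthetic data does and does not show

The generator plants profile structure directly (cluster templates, an
engineered driver neighborhood, labeled enhancer tails, exact 4PL plates);
it does not simulate reads, sequence content, differential-expression
calling, or real genome geometry, and its planted correlation structure is
cleaner than biological co-expression. Passing tests therefore demonstrate
that each stage recovers structure *of the kind it assumes* at realistic
noise, sizes and thresholds — not that the thresholds themselves are
optimal for any particular real dataset. Problem sizes (200 genes × 27
samples, 100 recovery seeds, 1,000 enhancer regions, 50 pharmacology
curves) were chosen so the full validation runs in minutes on one CPU while
keeping every rate estimate at a meaningful resolution.

## Known limitations

* The four-priority combination is a lexicographic order; when degree ties
  are pervasive (dense networks) the lower priorities dominate, and no
  weighted alternative is provided.
* Edge P-values are uncorrected for multiple testing by design; on large
  gene sets the network is permissive and the |r| > 0.9 threshold does the
  real work.
* The SE caller assumes a single convex rank curve; multimodal signal
  landscapes yield a single cutoff regardless.
* The median-effect fit weights all doses equally on the logit scale, so
  extreme fa values (near 0 or 1) carry disproportionate leverage on noisy
  plates; such doses are dropped only when fa leaves (0, 1) entirely.
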