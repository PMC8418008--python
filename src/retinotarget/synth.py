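"""Synthetic multi-omic dataset generator with planted ground truth.

Emulates the study design the pipeline analyzes: log2 expression for three
cellular contexts (tumor-repopulating cells, parental cancer line,
normal-liver analog) across an escalating retinoid dose ladder in
triplicate, together with factor-binding peaks, an H3K27ac enhancer signal
landscape, a pathway catalog, and viability plate readings.

Planted structure
-----------------
* Every non-driver gene follows one of eight archetype dose-response
  patterns (at least three strictly decreasing, playing the role of the
  down-regulated clusters) plus per-gene condition-level biological jitter
  and replicate noise.
* One driver gene follows a decreasing pattern, and ``target_degree``
  companion genes are noisy affine copies of its realized profile — these
  become its co-expression neighbors above the |r| > 0.9 edge threshold.
* The driver carries a promoter peak with M-value above the filter, sits in
  several oncogenic pathways, and a handful of companions also get passing
  peaks so the ranking has real competitors.
* The enhancer landscape is hockey-stick shaped: a low uniform background
  plus a heavy-tailed (Pareto) super-enhancer component.
* Viability plates follow a four-parameter logistic inhibition curve.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import SimulationConfig, ONCOGENIC_PATHWAY_IDS
from .io import (
    ExpressionMatrix,
    Pathway,
    PathwayCatalog,
    PROMOTER,
    NON_PROMOTER,
    make_sample_id,
    sample_meta_from_ids,
    validate_enhancers,
    validate_peaks,
    validate_viability,
)

# Eight archetype dose-response templates over (dose_0, dose_mid, dose_max).
# Indices 0, 2, 4 are strictly decreasing (the down-regulated trio); every
# other template ends clearly above its zero-dose level so centroid direction
# calls are unambiguous.
PATTERN_TEMPLATES: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.0, -1.0),   # 0: linear decrease
    (-1.0, 0.0, 1.0),   # 1: linear increase
    (1.0, -0.4, -1.0),  # 2: convex decrease
    (-1.0, 1.0, 0.3),   # 3: early induction, partial relaxation
    (1.0, 0.8, -1.0),   # 4: late decrease
    (-0.2, -1.0, 1.0),  # 5: transient repression then induction
    (-1.0, -0.6, 1.0),  # 6: convex increase
    (-0.3, 1.0, 0.5),   # 7: induction with plateau
)

#: template indices whose dose response is decreasing (planted "down" truth)
DOWN_PATTERNS: frozenset[int] = frozenset({0, 2, 4})

#: context attenuation of the dose response (TRC strongest)
_CONTEXT_ALPHA = (1.0, 0.6, 0.25)

GENE_SPACING_BP = 50_000
_BASE_EXPR_MEAN = 8.0
_BASE_EXPR_SD = 1.5


def _context_alphas(n: int) -> np.ndarray:
    alphas = list(_CONTEXT_ALPHA)
    while len(alphas) < n:
        alphas.append(alphas[-1] * 0.5)
    return np.asarray(alphas[:n])


def gene_ids(config: SimulationConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(config.n_genes)]


@dataclass(frozen=True)
class SimulationPlan:
    """Seed-determined layout shared by all generators of one config."""

    driver_gene: str
    companion_genes: tuple[str, ...]
    pattern_of_gene: dict[str, int]
    peak_companions: tuple[str, ...]


@dataclass
class ExpressionTruth:
    driver_gene: str
    companion_genes: tuple[str, ...]
    pattern_of_gene: dict[str, int]

    @property
    def down_genes(self) -> set[str]:
        return {g for g, p in self.pattern_of_gene.items() if p in DOWN_PATTERNS}


@dataclass
class SimulatedExpression:
    matrix: ExpressionMatrix
    truth: ExpressionTruth


@dataclass
class PeakTruth:
    passing_peak_ids: tuple[str, ...]
    genes_with_passing_promoter_peak: tuple[str, ...]


@dataclass
class SimulatedPeaks:
    peaks: pd.DataFrame
    truth: PeakTruth


def build_plan(config: SimulationConfig) -> SimulationPlan:
    """Derive the planted layout deterministically from the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    ids = gene_ids(config)
    spec = config.driver_spec
    picked = rng.choice(config.n_genes, size=spec.target_degree + 1, replace=False)
    driver = ids[picked[0]]
    companions = tuple(sorted(ids[i] for i in picked[1:]))
    rest = [g for g in ids if g != driver and g not in companions]
    # balanced pattern assignment over the remaining genes
    patterns = np.resize(np.arange(config.n_clusters_planted), len(rest))
    rng.shuffle(patterns)
    pattern_of_gene = dict(zip(rest, (int(p) for p in patterns)))
    pattern_of_gene[driver] = spec.cluster_pattern
    for c in companions:
        pattern_of_gene[c] = spec.cluster_pattern
    peak_companions = companions[: spec.n_companion_peaks]
    return SimulationPlan(
        driver_gene=driver,
        companion_genes=companions,
        pattern_of_gene=pattern_of_gene,
        peak_companions=peak_companions,
    )


def _pattern_values(config: SimulationConfig, pattern: int) -> np.ndarray:
    """Condition-level pattern deltas, ordered context-major then dose."""
    tmpl = np.asarray(PATTERN_TEMPLATES[pattern % len(PATTERN_TEMPLATES)])
    n_doses = len(config.doses)
    # interpolate the 3-point template onto the dose ladder rank positions
    t = np.linspace(0.0, 1.0, n_doses) if n_doses > 1 else np.array([0.0])
    shape = np.interp(t, [0.0, 0.5, 1.0], tmpl)
    alphas = _context_alphas(config.n_contexts)
    return (alphas[:, None] * shape[None, :]).ravel() * config.pattern_amplitude


def condition_labels(config: SimulationConfig) -> list[tuple[str, float]]:
    return [(ctx, dose) for ctx in config.contexts for dose in config.doses]


def generate_expression(config: SimulationConfig) -> SimulatedExpression:
    """Simulate the genes x samples log2 expression matrix.

    Non-driver genes: per-gene baseline + archetype pattern (attenuated per
    context) + condition-level jitter + replicate noise.  Companion genes
    are noisy affine copies of the driver's realized condition profile with
    fixed relative noise magnitude (see the inline comment), so the driver's
    planted network degree equals ``target_degree`` by construction.
    """
    plan = build_plan(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    ids = gene_ids(config)
    n_cond = config.n_conditions

    base = rng.normal(_BASE_EXPR_MEAN, _BASE_EXPR_SD, size=config.n_genes)
    jitter = rng.normal(0.0, config.gene_jitter_sd, size=(config.n_genes, n_cond))

    cond_profile = np.empty((config.n_genes, n_cond))
    for gi, g in enumerate(ids):
        pat = _pattern_values(config, plan.pattern_of_gene[g])
        cond_profile[gi] = base[gi] + pat + jitter[gi]

    # Companions: noisy affine copies of the driver's realized condition
    # profile.  Their condition-level noise is sized so that each companion
    # stays correlated with the driver above the |r| > 0.9 edge threshold
    # while companion pairs fall below it: the driver becomes the unique hub
    # of its neighborhood rather than one member of an indistinguishable
    # clique.
    driver_idx = ids.index(plan.driver_gene)
    dprof = cond_profile[driver_idx]
    dsd = dprof.std() if dprof.std() > 0 else 1.0
    dcent = dprof - dprof.mean()
    slopes = rng.uniform(0.7, 1.3, size=len(plan.companion_genes))
    offsets = rng.normal(0.0, 1.0, size=len(plan.companion_genes))
    for ci, c in enumerate(plan.companion_genes):
        # Noise of fixed relative magnitude, centered and orthogonal to the
        # driver profile: every companion's condition-level correlation with
        # the driver is exactly 1/sqrt(1 + companion_rel_sd^2), independent
        # of the draw.  This pins the planted hub degree at target_degree
        # and rules out degenerate near-duplicate companions.
        e = rng.normal(0.0, 1.0, size=n_cond)
        e -= e.mean()
        if dcent @ dcent > 0:
            e -= (e @ dcent) / (dcent @ dcent) * dcent
        norm = np.linalg.norm(e)
        if norm > 1e-12:
            e *= config.companion_rel_sd * dsd * np.sqrt(n_cond) / norm
        else:
            e[:] = 0.0
        cond_profile[ids.index(c)] = slopes[ci] * (dprof + e) + offsets[ci]

    sample_ids = [
        make_sample_id(ctx, dose, rep)
        for ctx in config.contexts
        for dose in config.doses
        for rep in range(1, config.n_replicates + 1)
    ]
    values = np.repeat(cond_profile, config.n_replicates, axis=1)
    values = values + rng.normal(0.0, config.noise_sd, size=values.shape)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=ids, columns=sample_ids),
        sample_meta=sample_meta_from_ids(sample_ids),
    )
    truth = ExpressionTruth(
        driver_gene=plan.driver_gene,
        companion_genes=plan.companion_genes,
        pattern_of_gene=plan.pattern_of_gene,
    )
    return SimulatedExpression(matrix=matrix, truth=truth)


def generate_gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Single synthetic chromosome, genes tiled every 50 kb, TSS at gene start."""
    ids = gene_ids(config)
    return pd.DataFrame(
        {
            "gene_id": ids,
            "chrom": "chr1",
            "tss": [GENE_SPACING_BP * (i + 1) for i in range(len(ids))],
            "strand": "+",
        }
    )


def generate_peaks(config: SimulationConfig) -> SimulatedPeaks:
    """Simulate the factor-binding peak table.

    The driver gets a promoter peak at ``driver_spec.peak_m`` with P < 0.05;
    ``n_companion_peaks`` companions get weaker passing promoter peaks; decoy
    peaks are split between promoter/non-promoter locations with exactly
    ``round(peak_pass_fraction * n_decoy_peaks)`` passing the default filter.
    """
    plan = build_plan(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    genes = generate_gene_annotation(config)
    tss = dict(zip(genes["gene_id"], genes["tss"]))

    rows: list[tuple] = []

    def add(gene: str, promoter: bool, m: float, p: float) -> None:
        t = tss[gene]
        if promoter:
            start = t - int(rng.integers(400, 1600))  # inside (2000, 500) window
        else:
            start = t + int(rng.integers(10_000, 30_000))
        width = int(rng.integers(150, 400))
        rows.append(
            (
                "chr1",
                start,
                start + width,
                f"PK{len(rows):04d}",
                ".",
                ".",
                round(float(m), 6),
                round(float(p), 8),
                PROMOTER if promoter else NON_PROMOTER,
            )
        )

    add(plan.driver_gene, True, config.driver_spec.peak_m, 0.005)
    for c in plan.peak_companions:
        add(c, True, rng.uniform(0.6, 1.0), rng.uniform(0.001, 0.04))

    n_pass = round(config.peak_pass_fraction * config.n_decoy_peaks)
    all_ids = gene_ids(config)
    decoy_pool = [g for g in all_ids if g != plan.driver_gene]
    pass_promoter_genes: list[str] = []
    for i in range(config.n_decoy_peaks):
        gene = decoy_pool[int(rng.integers(len(decoy_pool)))]
        promoter = bool(rng.random() < 0.5)
        if i < n_pass:
            m = rng.uniform(0.55, 1.5)
            p = rng.uniform(1e-4, 0.045)
            if promoter:
                pass_promoter_genes.append(gene)
        elif rng.random() < 0.5:
            m = rng.uniform(0.05, 0.45)  # fails the M filter
            p = rng.uniform(1e-4, 0.045)
        else:
            m = rng.uniform(0.55, 1.5)
            p = rng.uniform(0.06, 0.9)  # fails the P filter
        add(gene, promoter, m, p)

    peaks = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "peak_id", "score", "strand",
            "m_value", "p_value", "location_class",
        ],
    )
    validate_peaks(peaks, source="generate_peaks")
    passing = peaks[(peaks["m_value"] >= 0.5) & (peaks["p_value"] < 0.05)]
    truth = PeakTruth(
        passing_peak_ids=tuple(passing["peak_id"]),
        genes_with_passing_promoter_peak=tuple(
            sorted({plan.driver_gene, *plan.peak_companions, *pass_promoter_genes})
        ),
    )
    return SimulatedPeaks(peaks=peaks, truth=truth)


def generate_pathway_catalog(config: SimulationConfig) -> PathwayCatalog:
    """Simulate a gene-set catalog in which the driver carries the planted
    pathway burden (oncogenic families first); companions receive only
    sporadic generic memberships."""
    plan = build_plan(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    all_ids = gene_ids(config)
    non_clique = [
        g for g in all_ids if g != plan.driver_gene and g not in plan.companion_genes
    ]

    pathways: dict[str, Pathway] = {}
    n_onco_for_driver = min(config.driver_spec.n_pathways, len(ONCOGENIC_PATHWAY_IDS))
    for i, pid in enumerate(ONCOGENIC_PATHWAY_IDS):
        members = list(
            rng.choice(non_clique, size=int(rng.integers(6, 15)), replace=False)
        )
        if i < n_onco_for_driver:
            members.append(plan.driver_gene)
        pathways[pid] = Pathway(
            name=pid.replace("_", " ").lower(), genes=tuple(sorted(members)),
            oncogenic=True,
        )

    n_generic_for_driver = config.driver_spec.n_pathways - n_onco_for_driver
    pool = non_clique + list(plan.companion_genes)
    for i in range(16):
        pid = f"PW_{i + 5:02d}"
        members = list(rng.choice(pool, size=int(rng.integers(5, 16)), replace=False))
        if i < n_generic_for_driver:
            members.append(plan.driver_gene)
        pathways[pid] = Pathway(
            name=f"generic pathway {i + 5}", genes=tuple(sorted(members)),
            oncogenic=False,
        )
    return PathwayCatalog(pathways=pathways)


# ---------------------------------------------------------------------------
# enhancer landscape
# ---------------------------------------------------------------------------


@dataclass
class SimulatedEnhancers:
    regions: pd.DataFrame          # BED4+1 columns
    is_super_truth: pd.Series      # indexed by region_id


def generate_enhancer_signal(
    n_regions: int,
    n_super: int,
    seed: int,
    background_high: float = 40.0,
    super_scale: float = 80.0,
) -> SimulatedEnhancers:
    """Hockey-stick H3K27ac landscape: ``n_regions - n_super`` background
    regions with signal ~ Uniform(0, background_high) and ``n_super``
    super-enhancers with a heavy Pareto tail starting above the background.
    """
    if n_super >= n_regions:
        raise ValueError("n_super must be < n_regions")
    rng = np.random.default_rng(seed)
    signal = np.empty(n_regions)
    n_bg = n_regions - n_super
    signal[:n_bg] = rng.uniform(0.0, background_high, size=n_bg)
    signal[n_bg:] = super_scale * (1.0 + rng.pareto(1.5, size=n_super))
    labels = np.zeros(n_regions, dtype=bool)
    labels[n_bg:] = True
    order = rng.permutation(n_regions)
    signal, labels = signal[order], labels[order]

    # one tile per 50 kb, covering the upstream promoter zone of the gene
    # tiling so factor peaks can co-occupy enhancer regions; inter-tile gaps
    # stay well beyond the default stitch distance
    spacing = 50_000
    starts = np.arange(n_regions) * spacing + 48_000
    regions = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + 2_500,
            "region_id": [f"E{i:05d}" for i in range(n_regions)],
            "signal": np.round(signal, 6),
        }
    )
    validate_enhancers(regions, source="generate_enhancer_signal")
    truth = pd.Series(labels, index=regions["region_id"], name="is_super_truth")
    return SimulatedEnhancers(regions=regions, is_super_truth=truth)


# ---------------------------------------------------------------------------
# viability plates
# ---------------------------------------------------------------------------

_OD_CONTROL = 1.2
_OD_BLANK = 0.08


def logistic_inhibition(
    dose: np.ndarray | float,
    ic50: float,
    hill: float,
    bottom: float = 0.0,
    top: float = 100.0,
) -> np.ndarray | float:
    """Four-parameter logistic inhibition (%) at the given dose."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / dose) ** hill)


def generate_viability(
    true_ic50: float,
    hill: float,
    doses: list[float] | np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    od_control: float = _OD_CONTROL,
    od_blank: float = _OD_BLANK,
    bottom: float = 0.0,
    top: float = 100.0,
) -> pd.DataFrame:
    """OD plate readings for control, blank and each dose of a 4PL curve."""
    doses = np.asarray(doses, dtype=float)
    if true_ic50 <= 0:
        raise ValueError("true_ic50 must be > 0")
    if (doses <= 0).any():
        raise ValueError("treated doses must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        rows.append((0.0, od_control + rng.normal(0, noise_sd), "control", rep))
        rows.append((0.0, od_blank + rng.normal(0, noise_sd), "blank", rep))
    span = od_control - od_blank
    for d in doses:
        inh = float(logistic_inhibition(d, true_ic50, hill, bottom, top))
        for rep in range(1, n_replicates + 1):
            od = od_control - inh / 100.0 * span + rng.normal(0, noise_sd)
            rows.append((float(d), od, "treated", rep))
    table = pd.DataFrame(rows, columns=["dose", "od", "role", "replicate"])
    return validate_viability(table, source="generate_viability")


def loewe_combo_fraction_affected(
    total_dose: float,
    ratio_a: float,
    ic50_a: float,
    hill_a: float,
    ic50_b: float,
    hill_b: float,
    potency_shift: float = 1.0,
) -> float:
    """Fraction affected by a fixed-ratio combination under Loewe additivity.

    Solves d_a/Dx_a(fa) + d_b/Dx_b(fa) = potency_shift for fa, where
    Dx(fa) = IC50 * (fa/(1-fa))^(1/h).  ``potency_shift`` < 1 simulates
    synergy (a given effect is reached at smaller component doses, so the
    recovered combination index approaches the shift), > 1 antagonism.
    """
    d_a, d_b = ratio_a * total_dose, (1.0 - ratio_a) * total_dose

    def excess(logit_fa: float) -> float:
        fa = 1.0 / (1.0 + np.exp(-logit_fa))
        dx_a = ic50_a * (fa / (1 - fa)) ** (1.0 / hill_a)
        dx_b = ic50_b * (fa / (1 - fa)) ** (1.0 / hill_b)
        return d_a / dx_a + d_b / dx_b - potency_shift

    logit = brentq(excess, -30.0, 30.0, xtol=1e-13)
    return float(1.0 / (1.0 + np.exp(-logit)))


def generate_combo_viability(
    ic50_a: float,
    hill_a: float,
    ic50_b: float,
    hill_b: float,
    ratio_a: float,
    total_doses: list[float] | np.ndarray,
    potency_shift: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    od_control: float = _OD_CONTROL,
    od_blank: float = _OD_BLANK,
) -> pd.DataFrame:
    """Fixed-ratio combination plate under (shifted) Loewe additivity.

    Returns a viability table with per-component dose columns ``dose_a`` and
    ``dose_b`` on treated rows.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        rows.append((0.0, od_control + rng.normal(0, noise_sd), "control", rep, 0.0, 0.0))
        rows.append((0.0, od_blank + rng.normal(0, noise_sd), "blank", rep, 0.0, 0.0))
    span = od_control - od_blank
    for d in np.asarray(total_doses, dtype=float):
        fa = loewe_combo_fraction_affected(
            d, ratio_a, ic50_a, hill_a, ic50_b, hill_b, potency_shift
        )
        for rep in range(1, n_replicates + 1):
            od = od_control - fa * span + rng.normal(0, noise_sd)
            rows.append((float(d), od, "treated", rep, ratio_a * d, (1 - ratio_a) * d))
    table = pd.DataFrame(
        rows, columns=["dose", "od", "role", "replicate", "dose_a", "dose_b"]
    )
    return validate_viability(table, source="generate_combo_viability")
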