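"""Factor-binding peak filtering, promoter assignment, and intersection with
the dose-responsive gene set.

Peaks are retained at M-value >= 0.5 and P-value < 0.05 (boundary semantics
follow the differential-binding filter: >= on M, strict < on P).  A retained
peak is assigned to a gene when it overlaps the strand-oriented promoter
window around the TSS; candidate genes are the responsive genes carrying at
least one retained assigned peak, with per-gene evidence the maximum M over
their peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import NON_PROMOTER, PROMOTER, validate_genes, validate_peaks

DEFAULT_M_MIN = 0.5
DEFAULT_P_MAX = 0.05
DEFAULT_PROMOTER_WINDOW = (2000, 500)  # (upstream, downstream) bp around TSS


@dataclass
class CandidateSet:
    """Responsive genes with retained peak evidence."""

    peak_m: dict[str, float]        # gene -> max M over its retained peaks
    n_peaks: dict[str, int]         # gene -> number of contributing peaks

    @property
    def genes(self) -> set[str]:
        return set(self.peak_m)

    @property
    def n_contributing_peaks(self) -> int:
        return sum(self.n_peaks.values())


def filter_peaks(
    peaks: pd.DataFrame,
    m_min: float = DEFAULT_M_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Retain peaks with m_value >= m_min and p_value < p_max, order kept."""
    validate_peaks(peaks, source="filter_peaks")
    keep = (peaks["m_value"] >= m_min) & (peaks["p_value"] < p_max)
    return peaks[keep].copy()


def promoter_interval(
    tss: int, strand: str, window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW
) -> tuple[int, int]:
    """Strand-oriented half-open promoter interval around the TSS."""
    up, down = window
    if strand == "+":
        return max(0, tss - up), tss + down
    return max(0, tss - down), tss + up


def assign_peaks_to_genes(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
) -> pd.DataFrame:
    """Assign each peak to the gene whose promoter window it overlaps.

    A peak overlapping several promoters goes to the gene with the nearest
    TSS (exact distance ties broken by lexicographically smaller gene_id).
    Unassigned peaks get location_class ``non_promoter``; assigned ones
    ``promoter``.
    """
    validate_peaks(peaks, source="assign_peaks_to_genes")
    validate_genes(genes, source="assign_peaks_to_genes")
    known_chroms = set(genes["chrom"])
    offenders = sorted(set(peaks["chrom"]) - known_chroms)
    if offenders:
        raise ValueError(
            f"peaks on chromosomes absent from the gene annotation: {offenders}"
        )

    gene_rows = [
        (g.gene_id, g.chrom, int(g.tss), *promoter_interval(int(g.tss), g.strand, promoter_window))
        for g in genes.itertuples(index=False)
    ]

    out = peaks.copy()
    assigned: list[str | None] = []
    classes: list[str] = []
    for pk in peaks.itertuples(index=False):
        best: tuple[int, str] | None = None  # (|peak-center - tss|, gene_id)
        center = (pk.start + pk.end) // 2
        for gene_id, chrom, tss, lo, hi in gene_rows:
            if chrom != pk.chrom:
                continue
            if pk.start < hi and lo < pk.end:  # half-open overlap
                key = (abs(center - tss), gene_id)
                if best is None or key < best:
                    best = key
        if best is None:
            assigned.append(None)
            classes.append(NON_PROMOTER)
        else:
            assigned.append(best[1])
            classes.append(PROMOTER)
    out["assigned_gene"] = assigned
    out["location_class"] = classes
    return out


def integrate_candidates(
    filtered_peaks: pd.DataFrame,
    responsive_genes: set[str],
    require_promoter: bool = True,
) -> CandidateSet:
    """Intersect peak-assigned genes with the responsive set.

    ``require_promoter`` restricts evidence to promoter-class peaks
    (disable to accept any assigned peak).
    """
    if "assigned_gene" not in filtered_peaks.columns:
        raise ValueError("peaks must be assigned to genes first")
    peaks = filtered_peaks[filtered_peaks["assigned_gene"].notna()]
    if require_promoter:
        peaks = peaks[peaks["location_class"] == PROMOTER]
    peak_m: dict[str, float] = {}
    n_peaks: dict[str, int] = {}
    for pk in peaks.itertuples(index=False):
        gene = pk.assigned_gene
        if gene not in responsive_genes:
            continue
        peak_m[gene] = max(peak_m.get(gene, float("-inf")), pk.m_value)
        n_peaks[gene] = n_peaks.get(gene, 0) + 1
    if not peak_m:
        warnings.warn("no responsive gene carries a retained assigned peak")
    return CandidateSet(peak_m=peak_m, n_peaks=n_peaks)
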