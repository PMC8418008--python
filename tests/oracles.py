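"""Independent brute-force oracles used to cross-check the pipeline.

Each oracle re-derives a result by the most literal possible route
(all-pairs scans, exhaustive enumeration) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats


def pcc_edges_bruteforce(
    values: pd.DataFrame, pcc_min: float, p_max: float
) -> set[tuple[str, str]]:
    """All-pairs Pearson edges via scipy.stats.pearsonr, one pair at a time."""
    edges = set()
    genes = list(values.index)
    for a, b in itertools.combinations(genes, 2):
        x = values.loc[a].to_numpy(dtype=float)
        y = values.loc[b].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            continue
        r, p = stats.pearsonr(x, y)
        if abs(r) > pcc_min and p < p_max:
            edges.add((min(a, b), max(a, b)))
    return edges


def filter_peaks_bruteforce(peaks: pd.DataFrame, m_min: float, p_max: float) -> list[str]:
    """Row-by-row re-filter returning retained peak IDs in input order."""
    kept = []
    for _, row in peaks.iterrows():
        if row["m_value"] >= m_min and row["p_value"] < p_max:
            kept.append(row["peak_id"])
    return kept


def assign_peaks_bruteforce(
    peaks: pd.DataFrame, genes: pd.DataFrame, window: tuple[int, int]
) -> dict[str, str | None]:
    """Exhaustive peak x gene promoter-overlap scan with nearest-TSS tie-break."""
    up, down = window
    out: dict[str, str | None] = {}
    for _, pk in peaks.iterrows():
        hits = []
        center = (pk["start"] + pk["end"]) // 2
        for _, g in genes.iterrows():
            if g["chrom"] != pk["chrom"]:
                continue
            if g["strand"] == "+":
                lo, hi = max(0, g["tss"] - up), g["tss"] + down
            else:
                lo, hi = max(0, g["tss"] - down), g["tss"] + up
            if pk["start"] < hi and lo < pk["end"]:
                hits.append((abs(center - g["tss"]), g["gene_id"]))
        out[pk["peak_id"]] = min(hits)[1] if hits else None
    return out


def gmt_counts_bruteforce(gene: str, catalog) -> tuple[int, int]:
    """Membership scan over every pathway of a PathwayCatalog."""
    total = onco = 0
    for pw in catalog.pathways.values():
        if gene in pw.genes:
            total += 1
            if pw.oncogenic:
                onco += 1
    return total, onco


def stitch_bruteforce(
    regions: pd.DataFrame, distance: int
) -> list[tuple[str, int, int, float]]:
    """One-pass interval merge per chromosome (chrom, start, end, signal)."""
    merged = []
    for chrom in sorted(set(regions["chrom"])):
        sub = regions[regions["chrom"] == chrom].sort_values(["start", "end"])
        rows = list(sub.itertuples(index=False))
        i = 0
        while i < len(rows):
            start, end, signal = rows[i].start, rows[i].end, rows[i].signal
            j = i + 1
            while j < len(rows) and rows[j].start - end < distance:
                end = max(end, rows[j].end)
                signal += rows[j].signal
                j += 1
            merged.append((chrom, start, end, signal))
            i = j
    return merged


def ego_bruteforce(edges: set[tuple[str, str]], center: str) -> set[str]:
    """Neighbor set of ``center`` by scanning the edge list."""
    out = set()
    for a, b in edges:
        if a == center:
            out.add(b)
        elif b == center:
            out.add(a)
    return out


def overlap_flags_bruteforce(
    regions: pd.DataFrame, peaks: pd.DataFrame
) -> dict[str, bool]:
    """All-pairs >=1 bp interval overlap between regions and peaks."""
    out = {}
    for _, reg in regions.iterrows():
        hit = False
        for _, pk in peaks.iterrows():
            if (
                pk["chrom"] == reg["chrom"]
                and reg["start"] < pk["end"]
                and pk["start"] < reg["end"]
            ):
                hit = True
                break
        out[reg["region_id"]] = hit
    return out


def best_two_partition(x: np.ndarray) -> np.ndarray:
    """Exhaustive 2-means: the binary labeling minimizing within-cluster SSE.

    Enumerates all 2^(n-1) bipartitions (point 0 fixed to cluster 0).
    Returns labels in {0, 1}.
    """
    n = len(x)
    best_sse, best_labels = np.inf, None
    for mask in range(2 ** (n - 1)):
        labels = np.array([0] + [(mask >> i) & 1 for i in range(n - 1)])
        sse = 0.0
        ok = True
        for k in (0, 1):
            pts = x[labels == k]
            if len(pts) == 0:
                ok = False
                break
            sse += float(((pts - pts.mean(axis=0)) ** 2).sum())
        if ok and sse < best_sse:
            best_sse, best_labels = sse, labels
    return best_labels
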