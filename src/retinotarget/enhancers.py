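"""Super-enhancer calling by the rank-ordering tangent construction.

Regions are sorted by ascending H3K27ac signal, both axes are min-max scaled
to [0, 1], and the cutoff is the point of maximal vertical gap below the
diagonal — the point where the tangent of the convex rank curve has slope 1.
Regions whose signal strictly exceeds the cutoff signal are super-enhancers;
everything else is a typical enhancer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import validate_enhancers, validate_peaks

DEFAULT_STITCH_DISTANCE = 12_500

#: minimal departure of the scaled curve from the diagonal for a cutoff to be
#: called; near-linear (or constant) curves yield zero super-enhancers.
DEFAULT_MIN_GAP = 0.05


@dataclass
class EnhancerCallResult:
    regions: pd.DataFrame       # + rank, scaled_x, scaled_y, is_super
    cutoff_signal: float

    @property
    def n_super(self) -> int:
        return int(self.regions["is_super"].sum())

    @property
    def n_super_with_factor(self) -> int:
        if "factor_overlap" not in self.regions.columns:
            return 0
        sup = self.regions["is_super"]
        return int((sup & self.regions["factor_overlap"]).sum())

    def super_region_ids(self) -> set[str]:
        return set(self.regions.loc[self.regions["is_super"], "region_id"])


def stitch_regions(
    regions: pd.DataFrame, stitch_distance: int = DEFAULT_STITCH_DISTANCE
) -> pd.DataFrame:
    """Merge same-chromosome regions whose gap is below ``stitch_distance``.

    Merged regions sum the member signals; the merged ID joins member IDs
    with '+'. Input is sorted internally if needed.
    """
    validate_enhancers(regions, source="stitch_regions")
    if stitch_distance <= 0:
        return regions.copy()
    out_rows = []
    for chrom, grp in regions.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None:
                cur = [row.chrom, row.start, row.end, [row.region_id], row.signal]
            elif row.start - cur[2] < stitch_distance:
                cur[2] = max(cur[2], row.end)
                cur[3].append(row.region_id)
                cur[4] += row.signal
            else:
                out_rows.append(cur)
                cur = [row.chrom, row.start, row.end, [row.region_id], row.signal]
        if cur is not None:
            out_rows.append(cur)
    return pd.DataFrame(
        [(c, s, e, "+".join(ids), sig) for c, s, e, ids, sig in out_rows],
        columns=["chrom", "start", "end", "region_id", "signal"],
    )


def call_super_enhancers(
    regions: pd.DataFrame, min_gap: float = DEFAULT_MIN_GAP
) -> EnhancerCallResult:
    """Rank regions by ascending signal and call SEs above the slope-1 point.

    The cutoff is the curve point with the largest vertical gap below the
    diagonal of the min-max-scaled rank/signal plot.  If that gap never
    reaches ``min_gap`` (constant or near-linear landscapes) no region is
    called.
    """
    validate_enhancers(regions, source="call_super_enhancers")
    if len(regions) < 3:
        raise ValueError("need >= 3 regions to call super-enhancers")
    out = regions.sort_values(
        ["signal", "region_id"], kind="mergesort"
    ).reset_index(drop=True)
    n = len(out)
    out["rank"] = np.arange(1, n + 1)
    sig = out["signal"].to_numpy(dtype=float)
    span = sig[-1] - sig[0]
    out["scaled_x"] = (out["rank"] - 1) / (n - 1)
    if span == 0:
        warnings.warn("constant enhancer signal: degenerate rank curve, no SEs")
        out["scaled_y"] = 0.0
        out["is_super"] = False
        return EnhancerCallResult(regions=out, cutoff_signal=float(sig[-1]))
    out["scaled_y"] = (sig - sig[0]) / span

    gap = out["scaled_x"].to_numpy() - out["scaled_y"].to_numpy()
    if gap.max() < min_gap:
        warnings.warn("rank curve is near-linear: no super-enhancer elbow")
        out["is_super"] = False
        return EnhancerCallResult(regions=out, cutoff_signal=float(sig[-1]))
    cutoff_signal = float(sig[int(np.argmax(gap))])
    out["is_super"] = out["signal"] > cutoff_signal
    return EnhancerCallResult(regions=out, cutoff_signal=cutoff_signal)


def annotate_factor_overlap(
    result: EnhancerCallResult, factor_peaks: pd.DataFrame
) -> EnhancerCallResult:
    """Flag regions overlapping >= 1 bp of any factor peak."""
    validate_peaks(factor_peaks, source="annotate_factor_overlap")
    regions = result.regions.copy()
    flags = []
    peaks_by_chrom = {
        chrom: grp[["start", "end"]].to_numpy()
        for chrom, grp in factor_peaks.groupby("chrom")
    }
    for row in regions.itertuples(index=False):
        arr = peaks_by_chrom.get(row.chrom)
        flags.append(
            bool(arr is not None and ((row.start < arr[:, 1]) & (arr[:, 0] < row.end)).any())
        )
    regions["factor_overlap"] = flags
    return EnhancerCallResult(regions=regions, cutoff_signal=result.cutoff_signal)
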