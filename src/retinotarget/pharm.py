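"""Concentration-response pharmacology: inhibition rate, 4PL IC50 fitting,
and the Chou-Talalay combination index.

The inhibition rate follows the plate formula
``[(OD_control - OD_treated) / (OD_control - OD_blank)] x 100``.  IC50s come
from a four-parameter logistic (variable-slope) least-squares fit; drug
interaction uses the median-effect line log(fa/(1-fa)) = h(log D - log Dm)
and the two-term (mutually nonexclusive-free) combination index
CI = d_a/Dx_a + d_b/Dx_b, with CI < 1 synergy and CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import validate_viability


def inhibition_rate(
    od_control: float, od_treated: float, od_blank: float, clip: bool = False
) -> float:
    """Percent inhibition from plate optical densities.

    Noisy readings may fall outside [0, 100]; set ``clip`` to bound them.
    """
    if od_control <= od_blank:
        raise ValueError(
            f"no dynamic range: OD control ({od_control}) must exceed "
            f"OD blank ({od_blank})"
        )
    rate = (od_control - od_treated) / (od_control - od_blank) * 100.0
    if clip:
        rate = min(100.0, max(0.0, rate))
    return rate


def dose_inhibition_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Per-dose mean inhibition (%) from a viability plate table.

    Control and blank ODs are averaged across their rows; treated replicates
    are averaged per dose before the rate is computed.
    """
    validate_viability(table)
    od_control = table.loc[table["role"] == "control", "od"].mean()
    od_blank = table.loc[table["role"] == "blank", "od"].mean()
    treated = table[table["role"] == "treated"]
    if treated.empty:
        raise ValueError("viability table has no treated rows")
    prof = (
        treated.groupby("dose", sort=True)["od"]
        .mean()
        .reset_index()
        .rename(columns={"od": "od_mean"})
    )
    prof["inhibition"] = [
        inhibition_rate(od_control, od, od_blank) for od in prof["od_mean"]
    ]
    return prof


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ic50: float
    hill: float
    residual_sse: float
    converged: bool
    doses: np.ndarray = field(repr=False, default=None)
    responses: np.ndarray = field(repr=False, default=None)

    def predict(self, dose: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (self.ic50 / d) ** self.hill)


def _4pl(dose: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + (np.exp(log_ic50) / dose) ** hill)


def fit_4pl(table: pd.DataFrame) -> DoseResponseFit:
    """Least-squares 4PL fit of inhibition(%) against dose.

    Deterministic multi-start: IC50 initial values on a geometric grid across
    the dose range crossed with a small Hill-slope grid; the start with the
    lowest residual SSE wins.  Non-convergence (e.g. flat response) is
    reported via ``converged=False`` rather than an exception.
    """
    prof = dose_inhibition_profile(table)
    doses = prof["dose"].to_numpy(dtype=float)
    resp = prof["inhibition"].to_numpy(dtype=float)
    if len(doses) < 4:
        raise ValueError("need >= 4 distinct positive doses for a 4PL fit")
    flat = DoseResponseFit(
        bottom=float(resp.mean()), top=float(resp.mean()), ic50=float(np.median(doses)),
        hill=1.0, residual_sse=float(((resp - resp.mean()) ** 2).sum()),
        converged=False, doses=doses, responses=resp,
    )
    if np.ptp(resp) == 0:
        return flat

    lo, hi = doses.min(), doses.max()
    bounds = (
        [-100.0, -100.0, np.log(lo / 100.0), 0.05],
        [200.0, 200.0, np.log(hi * 100.0), 10.0],
    )
    best = None
    for ic50_0 in np.geomspace(lo / 2.0, hi * 2.0, 5):
        for h0 in (0.5, 1.0, 2.0, 4.0):
            p0 = [float(resp.min()), float(resp.max()), float(np.log(ic50_0)), h0]
            try:
                popt, _ = curve_fit(
                    _4pl, doses, resp, p0=p0, bounds=bounds, maxfev=20_000
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(((resp - _4pl(doses, *popt)) ** 2).sum())
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        return flat
    sse, (bottom, top, log_ic50, hill) = best
    if bottom > top:  # canonical orientation: curve rises with dose
        bottom, top, hill = top, bottom, -hill
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), ic50=float(np.exp(log_ic50)),
        hill=float(hill), residual_sse=sse, converged=True,
        doses=doses, responses=resp,
    )


# ---------------------------------------------------------------------------
# median effect / combination index
# ---------------------------------------------------------------------------


@dataclass
class MedianEffectFit:
    dm: float       # median-effect dose (uM)
    h: float        # slope of the median-effect line
    r2: float
    fa_min: float
    fa_max: float

    def dose_at(self, fa: float) -> float:
        """Dose producing fraction affected ``fa`` on the fitted line."""
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.h)


@dataclass
class CombinationResult:
    fit_a: MedianEffectFit
    fit_b: MedianEffectFit
    fit_combo: MedianEffectFit
    effect_level: float
    d_a: float
    d_b: float
    dx_a: float
    dx_b: float
    ci: float


def median_effect_fit(table: pd.DataFrame, dose_column: str = "dose") -> MedianEffectFit:
    """Fit log(fa/(1-fa)) = h (log D - log Dm) by least squares.

    Doses with fraction affected outside (0, 1) carry no information on the
    median-effect line and are dropped.
    """
    prof = dose_inhibition_profile(table)
    if dose_column != "dose":
        treated = table[table["role"] == "treated"]
        per_dose = treated.groupby("dose", sort=True)[dose_column].mean()
        prof[dose_column] = per_dose.to_numpy()
    fa = prof["inhibition"].to_numpy(dtype=float) / 100.0
    d = prof[dose_column].to_numpy(dtype=float)
    keep = (fa > 0) & (fa < 1) & (d > 0)
    fa, d = fa[keep], d[keep]
    if len(fa) < 2:
        raise ValueError("median-effect fit needs >= 2 doses with fa in (0, 1)")
    y = np.log(fa / (1.0 - fa))
    x = np.log(d)
    h, intercept = np.polyfit(x, y, 1)
    if h <= 0:
        raise ValueError("median-effect slope must be positive (rising curve)")
    log_dm = -intercept / h
    resid = y - (h * x + intercept)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 1.0
    return MedianEffectFit(
        dm=float(np.exp(log_dm)), h=float(h), r2=r2,
        fa_min=float(fa.min()), fa_max=float(fa.max()),
    )


def ci_at_doses(d_a: float, d_b: float, dx_a: float, dx_b: float) -> float:
    """Two-term combination index for explicit component doses."""
    return d_a / dx_a + d_b / dx_b


def combination_index(
    single_a: pd.DataFrame,
    single_b: pd.DataFrame,
    combo: pd.DataFrame,
    effect_level: float = 0.5,
) -> CombinationResult:
    """Combination index of a fixed-ratio combination at ``effect_level``.

    ``combo`` must carry per-component doses in columns ``dose_a`` and
    ``dose_b`` on treated rows.  The combination's own median-effect fit
    interpolates the total dose achieving the effect level; its components
    are compared with each single agent's dose for the same effect.
    """
    if not (0.0 < effect_level < 1.0):
        raise ValueError("effect_level must lie in (0, 1)")
    for col in ("dose_a", "dose_b"):
        if col not in combo.columns:
            raise ValueError(f"combo table must record component doses ({col!r})")
    fit_a = median_effect_fit(single_a)
    fit_b = median_effect_fit(single_b)
    fit_c = median_effect_fit(combo)
    for name, fit in (("single_a", fit_a), ("single_b", fit_b), ("combo", fit_c)):
        if not (fit.fa_min <= effect_level <= fit.fa_max):
            raise ValueError(
                f"effect_level {effect_level} outside the fitted range "
                f"[{fit.fa_min:.3g}, {fit.fa_max:.3g}] of {name}; choose an "
                f"effect level inside every curve's observed range"
            )
    treated = combo[combo["role"] == "treated"]
    ratio_a = float((treated["dose_a"] / treated["dose"]).mean())
    total = fit_c.dose_at(effect_level)
    d_a, d_b = ratio_a * total, (1.0 - ratio_a) * total
    dx_a = fit_a.dose_at(effect_level)
    dx_b = fit_b.dose_at(effect_level)
    ci = ci_at_doses(d_a, d_b, dx_a, dx_b)
    return CombinationResult(
        fit_a=fit_a, fit_b=fit_b, fit_combo=fit_c, effect_level=effect_level,
        d_a=d_a, d_b=d_b, dx_a=dx_a, dx_b=dx_b, ci=float(ci),
    )
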