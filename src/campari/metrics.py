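"""Activity metrics from corrected two-channel fluorescence.

The per-cell readout is the red-to-green ratio (RGR) after
photoconversion: converted (red) protein over remaining (green) protein,
a snapshot of how active the cell was while the conversion light was on.
This module computes RGR (standard and pre/post-paired variants),
region-level summaries, the sensitivity index d' separating two RGR
distributions, photoconversion light-dose arithmetic, and two fitted
models in the Model/Results idiom: an exponential half-life decay model
for the post-conversion ratio and a polynomial dose-response model.
It also integrates stimulus-locked calcium responses for the
dynamic-indicator comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "compute_rgr",
    "summarize_region",
    "dprime",
    "DoseSpec",
    "DoseResult",
    "light_dose",
    "cycles_for_dose",
    "ExponentialDecayModel",
    "DecayResults",
    "DoseResponseModel",
    "DoseResponseResults",
    "integrate_grating_response",
]


# ---------------------------------------------------------------------------
# RGR and summaries

def compute_rgr(table: pd.DataFrame, variant: str = "standard") -> pd.DataFrame:
    """Per-cell red-to-green ratio from a corrected fluorescence table.

    ``standard``: RGR = red_corr / green_corr of the post-conversion row.
    ``paired``: RGR = (red_post - red_pre) / green_post for cells with
    both phases; subtracting the same cell's pre-conversion red removes
    any residual red offset (the hemisphere autofluorescence term cancels
    in the difference), the variant used for lines with pre-conversion
    red puncta.

    Cells failing correction QC (``qc_ok`` False) or with non-positive
    corrected green are excluded.
    """
    req = {"green_corr", "red_corr"}
    if not req.issubset(table.columns):
        raise ValueError("table must carry green_corr/red_corr (run corrections first)")
    t = table.copy()
    if "qc_ok" in t:
        t = t[t["qc_ok"]]
    if "phase" not in t:
        t["phase"] = "post"

    keep_cols = [c for c in ("cell_id", "region", "hemisphere", "depth") if c in t]
    if variant == "standard":
        post = t[t["phase"] == "post"]
        post = post[post["green_corr"] > 0]
        out = post[keep_cols].copy()
        out["rgr"] = post["red_corr"].to_numpy() / post["green_corr"].to_numpy()
    elif variant == "paired":
        post = t[t["phase"] == "post"].set_index("cell_id")
        pre = t[t["phase"] == "pre"].set_index("cell_id")
        common = post.index.intersection(pre.index)
        if len(common) == 0:
            raise ValueError("paired variant requires cells measured pre and post")
        post = post.loc[common]
        pre = pre.loc[common]
        ok = post["green_corr"] > 0
        post, pre = post[ok], pre[ok]
        out = post.reset_index()[["cell_id"] + [c for c in keep_cols if c != "cell_id"]]
        out["rgr"] = (
            post["red_corr"].to_numpy() - pre["red_corr"].to_numpy()
        ) / post["green_corr"].to_numpy()
    else:
        raise ValueError(f"unknown variant {variant!r}")
    out["variant"] = variant
    return out.reset_index(drop=True)


def summarize_region(rgr_table: pd.DataFrame, group_by: str = "region") -> pd.DataFrame:
    """Per-group RGR summary: n, median, mean, variance, percentile bands.

    ``group_by`` is any column of the RGR table (``region`` for the
    multi-region comparisons, ``fov`` for per-field medians). Percentiles
    use linear interpolation; the variance is the sample (n-1) variance.
    The 5-95 percentile range is the population-heterogeneity metric used
    to compare expression strategies.
    """
    if len(rgr_table) == 0:
        raise ValueError("empty RGR table")
    if group_by not in rgr_table:
        raise ValueError(f"no column {group_by!r} to group by")

    rows = []
    for key, g in rgr_table.groupby(group_by, dropna=False):
        v = g["rgr"].to_numpy(dtype=float)
        p5, p25, p75, p95 = np.percentile(v, [5, 25, 75, 95])
        rows.append(
            {
                group_by: key,
                "n_cells": len(v),
                "median_rgr": np.median(v),
                "mean_rgr": v.mean(),
                "var_rgr": v.var(ddof=1) if len(v) > 1 else 0.0,
                "p5": p5,
                "p25": p25,
                "p75": p75,
                "p95": p95,
                "range_5_95": p95 - p5,
            }
        )
    return pd.DataFrame(rows)


def dprime(group_a, group_b, ddof: int = 1) -> float:
    """Sensitivity index separating two RGR distributions.

    d' = (mean_a - mean_b) / sqrt(0.5 * (var_a + var_b)), with sample
    (ddof=1) variances by default. Two identical constant groups give 0;
    distinct constants give signed infinity (flagged with a warning).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    num = a.mean() - b.mean()
    pooled = 0.5 * (a.var(ddof=ddof) + b.var(ddof=ddof))
    if pooled == 0:
        if num == 0:
            return 0.0
        warnings.warn("zero pooled variance with unequal means; d' is infinite")
        return math.inf if num > 0 else -math.inf
    return float(num / math.sqrt(pooled))


# ---------------------------------------------------------------------------
# Light-dose arithmetic

@dataclass(frozen=True)
class DoseSpec:
    """One photoconversion illumination protocol.

    Intensity = power / (pi * (diameter/2)^2); the per-cycle dose is
    intensity x cycle duration, and the cumulative dose multiplies by the
    number of cycles. Doses are reported in mW/mm^2 * s (= mJ/mm^2),
    numerically the scale the protocol figures are printed on.
    """

    power_mw: float
    aperture_diameter_mm: float
    cycle_duration_s: float = 1.0
    n_cycles: int = 1

    def __post_init__(self) -> None:
        if self.power_mw <= 0 or self.aperture_diameter_mm <= 0 or self.cycle_duration_s <= 0:
            raise ValueError("power, aperture and duration must be positive")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be non-negative")


@dataclass(frozen=True)
class DoseResult:
    intensity_mw_per_mm2: float
    intensity_mw_per_cm2: float
    per_cycle_dose: float  # mJ/mm^2
    cumulative_dose: float  # mJ/mm^2


def light_dose(spec: DoseSpec) -> DoseResult:
    """Illumination intensity and delivered light dose for a protocol."""
    area_mm2 = math.pi * (spec.aperture_diameter_mm / 2.0) ** 2
    intensity = spec.power_mw / area_mm2
    per_cycle = intensity * spec.cycle_duration_s
    return DoseResult(
        intensity_mw_per_mm2=intensity,
        intensity_mw_per_cm2=intensity * 100.0,
        per_cycle_dose=per_cycle,
        cumulative_dose=per_cycle * spec.n_cycles,
    )


def cycles_for_dose(target_dose: float, per_cycle_dose: float) -> int:
    """Smallest whole number of cycles reaching a target cumulative dose."""
    if per_cycle_dose <= 0:
        raise ValueError("per-cycle dose must be positive")
    if target_dose < 0:
        raise ValueError("target dose must be non-negative")
    return int(math.ceil(target_dose / per_cycle_dose - 1e-12))


# ---------------------------------------------------------------------------
# Exponential ratio-decay model

class ExponentialDecayModel:
    """Half-life model for the normalised post-conversion ratio.

    y(t) = amplitude * 2^(-t / half_life) + offset, fitted by nonlinear
    least squares to (day, normalised RGR) points. Because trajectories
    are normalised to each cell's day-0 level, the amplitude is fixed at
    1 and the offset at 0 by default; both can be freed.
    """

    def __init__(self, days, values):
        self.days = np.asarray(days, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.days.shape != self.values.shape:
            raise ValueError("days and values must align")
        if self.days.size < 3:
            raise ValueError("need at least 3 time points")
        if 0.0 not in self.days:
            raise ValueError("day 0 must be included (it anchors the normalisation)")

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, agg: str = "median") -> "ExponentialDecayModel":
        """Build from a per-cell trajectory table (cell_id, day, normalized_rgr)."""
        med = cohort.groupby("day")["normalized_rgr"].agg(agg)
        return cls(med.index.to_numpy(), med.to_numpy())

    def fit(
        self,
        free_amplitude: bool = False,
        free_offset: bool = False,
        half_life_guess: float = 1.0,
    ) -> "DecayResults":
        t, y = self.days, self.values
        if np.all(np.diff(y[np.argsort(t)]) >= 0):
            warnings.warn("values are non-decreasing in time; decay fit may be meaningless")

        names = ["half_life"]
        p0 = [half_life_guess]
        if free_amplitude:
            names.append("amplitude")
            p0.append(1.0)
        if free_offset:
            names.append("offset")
            p0.append(0.0)

        def model(tt, *p):
            h = p[0]
            a = p[names.index("amplitude")] if free_amplitude else 1.0
            c = p[names.index("offset")] if free_offset else 0.0
            return a * 2.0 ** (-tt / h) + c

        lower = [1e-9] + [-np.inf] * (len(p0) - 1)
        popt, pcov = curve_fit(
            model, t, y, p0=p0, bounds=(lower, [np.inf] * len(p0)), maxfev=20000
        )
        resid = y - model(t, *popt)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        se = np.sqrt(np.diag(pcov))
        return DecayResults(
            model=self,
            params=dict(zip(names, map(float, popt))),
            bse=dict(zip(names, map(float, se))),
            r_squared=r2,
            free_amplitude=free_amplitude,
            free_offset=free_offset,
        )


@dataclass
class DecayResults:
    """Fitted half-life, uncertainty and goodness of fit."""

    model: ExponentialDecayModel
    params: dict[str, float]
    bse: dict[str, float]
    r_squared: float
    free_amplitude: bool
    free_offset: bool

    @property
    def half_life(self) -> float:
        return self.params["half_life"]

    @property
    def half_life_se(self) -> float:
        return self.bse["half_life"]

    def predict(self, days) -> np.ndarray:
        t = np.asarray(days, dtype=float)
        a = self.params.get("amplitude", 1.0)
        c = self.params.get("offset", 0.0)
        return a * 2.0 ** (-t / self.half_life) + c

    def fraction_lost(self, day: float) -> float:
        """Predicted fractional loss of the day-0 ratio by ``day``."""
        y0 = float(self.predict(0.0))
        return 1.0 - float(self.predict(day)) / y0

    def summary(self) -> str:
        lines = [
            "Exponential ratio-decay fit: y = a * 2^(-t/t_half) + c",
            f"  n points        : {self.model.days.size}",
            f"  half-life (days): {self.half_life:.4g} +/- {self.half_life_se:.3g} (SE)",
        ]
        if self.free_amplitude:
            lines.append(f"  amplitude       : {self.params['amplitude']:.4g} +/- {self.bse['amplitude']:.3g}")
        if self.free_offset:
            lines.append(f"  offset          : {self.params['offset']:.4g} +/- {self.bse['offset']:.3g}")
        lines.append(f"  R^2 (vs constant model): {self.r_squared:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Polynomial dose-response model

class DoseResponseModel:
    """Least-squares polynomial fit of a response measure against light dose.

    Cubic by default, matching how the sensitivity-vs-dose optimum is
    located; linear and quadratic degrees serve the normalised green and
    red channel trends.
    """

    def __init__(self, dose, response, degree: int = 3):
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.dose.shape != self.response.shape:
            raise ValueError("dose and response must align")
        if degree < 1:
            raise ValueError("degree must be at least 1")
        if self.dose.size < degree + 1:
            raise ValueError(f"need at least {degree + 1} points for degree {degree}")
        self.degree = degree

    def fit(self, grid_spacing: float = 1.0) -> "DoseResponseResults":
        # Vandermonde least squares in the plain power basis; rank check
        # guards against duplicated dose values.
        X = np.vander(self.dose, self.degree + 1, increasing=True)
        if np.linalg.matrix_rank(X) < self.degree + 1:
            raise ValueError("design matrix is rank deficient (too few distinct doses)")
        coef, _, _, _ = np.linalg.lstsq(X, self.response, rcond=None)
        fitted = X @ coef
        ss_res = float(np.sum((self.response - fitted) ** 2))
        ss_tot = float(np.sum((self.response - self.response.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        grid = np.arange(self.dose.min(), self.dose.max() + grid_spacing / 2.0, grid_spacing)
        vals = np.polynomial.polynomial.polyval(grid, coef)
        return DoseResponseResults(
            model=self,
            coef=coef,
            r_squared=r2,
            optimum_dose=float(grid[int(np.argmax(vals))]),
            grid_spacing=grid_spacing,
        )


@dataclass
class DoseResponseResults:
    """Polynomial coefficients (increasing powers) and the fitted optimum."""

    model: DoseResponseModel
    coef: np.ndarray
    r_squared: float
    optimum_dose: float
    grid_spacing: float

    def predict(self, dose) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(dose, dtype=float), self.coef)

    def summary(self) -> str:
        terms = " + ".join(f"{c:.4g}*d^{k}" if k else f"{c:.4g}" for k, c in enumerate(self.coef))
        return (
            f"Degree-{self.model.degree} dose-response fit\n"
            f"  y(d) = {terms}\n"
            f"  R^2 = {self.r_squared:.4f}\n"
            f"  fitted optimum at dose {self.optimum_dose:g} "
            f"(grid spacing {self.grid_spacing:g})"
        )


# ---------------------------------------------------------------------------
# Stimulus-locked calcium response integral

def integrate_grating_response(
    trace,
    epochs: pd.DataFrame,
    frame_rate: float,
    response_duration_s: float = 4.0,
    baseline_duration_s: float = 2.0,
) -> tuple[float, pd.DataFrame]:
    """Integrated stimulus response: sum(F_resp / 2) - sum(F_base) per epoch.

    F_resp covers the ``response_duration_s`` window from each grating
    onset; F_base covers the ``baseline_duration_s`` immediately before
    it. The /2 factor equates the 4-s response and 2-s baseline windows
    frame-for-frame. Epochs whose pre-window would start before the trace
    does are skipped with a warning. Returns the total over all grating
    appearances plus the per-epoch table.
    """
    trace = np.asarray(trace, dtype=float)
    n_resp = int(round(response_duration_s * frame_rate))
    n_base = int(round(baseline_duration_s * frame_rate))
    rows = []
    for row in epochs.itertuples():
        onset = int(row.onset_frame)
        if onset - n_base < 0:
            warnings.warn(f"epoch {row.epoch} lacks a full pre-stimulus window; skipped")
            continue
        if onset + n_resp > trace.size:
            raise ValueError(f"epoch {row.epoch} response window exceeds the trace")
        f_resp = trace[onset:onset + n_resp]
        f_base = trace[onset - n_base:onset]
        rows.append(
            {"epoch": row.epoch,
             "response": float(f_resp.sum() / 2.0 - f_base.sum())}
        )
    per_epoch = pd.DataFrame(rows, columns=["epoch", "response"])
    return float(per_epoch["response"].sum()), per_epoch
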