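"""Two-channel signal corrections.

Three nuisances contaminate the red channel readout of photoconverted
cells: PMT dark current (both channels), spectral bleed-through of the
green emission into the red channel (a fixed ratio rho of the green
signal), and a per-hemisphere additive red autofluorescence offset beta
from the cranial-window glass. All three are estimated from laser-off
frames and from pre-photoconversion acquisitions, where any red signal
is pure nuisance, and subtracted in a fixed order:

    g_corr = g - dark_green
    r_corr = r - dark_red - beta(hemisphere) - rho * g_corr
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrectionParams",
    "estimate_dark_current",
    "estimate_contamination_ratio",
    "estimate_autofluorescence_intercept",
    "fit_corrections",
    "apply_corrections",
    "correct_cell_table",
]


@dataclass
class CorrectionParams:
    """Estimated (or supplied) correction constants.

    ``contamination_ratio`` may be a single pooled value or a
    per-hemisphere mapping; ``autofluor_intercept`` is keyed by
    hemisphere (a regression intercept, so unrestricted in sign).
    """

    dark_green: float = 0.0
    dark_red: float = 0.0
    contamination_ratio: float | dict[str, float] = 0.0
    autofluor_intercept: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dark_green < 0 or self.dark_red < 0:
            raise ValueError("dark currents must be non-negative")
        rhos = (
            self.contamination_ratio.values()
            if isinstance(self.contamination_ratio, dict)
            else [self.contamination_ratio]
        )
        if any(r < 0 for r in rhos):
            raise ValueError("contamination ratio must be non-negative")

    def rho(self, hemisphere: str | None = None) -> float:
        if isinstance(self.contamination_ratio, dict):
            return self.contamination_ratio[hemisphere]
        return self.contamination_ratio

    def beta(self, hemisphere: str | None = None) -> float:
        if not self.autofluor_intercept:
            return 0.0
        if hemisphere in self.autofluor_intercept:
            return self.autofluor_intercept[hemisphere]
        if len(self.autofluor_intercept) == 1:
            return next(iter(self.autofluor_intercept.values()))
        raise KeyError(f"no autofluorescence intercept for hemisphere {hemisphere!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "dark_green": self.dark_green,
                    "dark_red": self.dark_red,
                    "contamination_ratio": self.contamination_ratio,
                    "autofluor_intercept": self.autofluor_intercept,
                    "diagnostics": self.diagnostics,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CorrectionParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def estimate_dark_current(frames_green, frames_red) -> tuple[float, float]:
    """Per-channel dark current: the mean over all laser-off pixels/frames."""
    fg = np.asarray(frames_green, dtype=float)
    fr = np.asarray(frames_red, dtype=float)
    if fg.size == 0 or fr.size == 0:
        raise ValueError("need at least one laser-off frame per channel")
    return float(fg.mean()), float(fr.mean())


def _ols_line(green: np.ndarray, red: np.ndarray):
    """Red-on-green OLS with slope stderr; raises on degenerate green."""
    if green.size < 3:
        raise ValueError("need at least 3 cells for the regression")
    if np.ptp(green) == 0:
        raise ValueError("green values are all equal; slope is unidentifiable")
    res = stats.linregress(green, red)
    return res.slope, res.intercept, res.stderr, res.intercept_stderr


def estimate_contamination_ratio(
    green,
    red,
    dark: tuple[float, float] = (0.0, 0.0),
) -> dict:
    """Bleed-through ratio rho from pre-conversion per-cell (green, red) pairs.

    rho is the OLS slope of dark-corrected red on dark-corrected green;
    the intercept of the same line is the autofluorescence estimate. A
    negative fitted slope is clamped to 0 with a warning (flagged in the
    result).
    """
    g = np.asarray(green, dtype=float) - dark[0]
    r = np.asarray(red, dtype=float) - dark[1]
    slope, intercept, slope_se, intercept_se = _ols_line(g, r)
    clamped = False
    if slope < 0:
        warnings.warn(
            f"fitted contamination ratio is negative ({slope:.4g}); clamping to 0"
        )
        slope, clamped = 0.0, True
    return {
        "rho": float(slope),
        "intercept": float(intercept),
        "rho_se": float(slope_se),
        "intercept_se": float(intercept_se),
        "clamped": clamped,
        "n": int(g.size),
    }


def estimate_autofluorescence_intercept(
    green,
    red,
    hemisphere,
    dark: tuple[float, float] = (0.0, 0.0),
) -> dict[str, float]:
    """Per-hemisphere red offset beta: OLS intercept of red vs green.

    Hemispheres are fitted independently (each cranial window sits at its
    own angle to the optical axis). A hemisphere with fewer than 3 cells
    is flagged and assigned beta = 0.
    """
    g = np.asarray(green, dtype=float) - dark[0]
    r = np.asarray(red, dtype=float) - dark[1]
    hemi = np.asarray(hemisphere)
    out: dict[str, float] = {}
    for h in pd.unique(hemi):
        m = hemi == h
        if m.sum() < 3:
            warnings.warn(f"hemisphere {h!r} has {int(m.sum())} cells (<3); beta set to 0")
            out[str(h)] = 0.0
            continue
        _, intercept, _, _ = _ols_line(g[m], r[m])
        out[str(h)] = float(intercept)
    return out


def fit_corrections(
    pre_table: pd.DataFrame,
    dark_green: float = 0.0,
    dark_red: float = 0.0,
    pooled_rho: bool = True,
    outlier_threshold: float = 4.0,
) -> CorrectionParams:
    """Joint estimate of rho and per-hemisphere beta from pre-conversion cells.

    ``pre_table`` needs columns ``mean_green``, ``mean_red`` and
    ``hemisphere``. By default a single bleed-through slope is shared
    across hemispheres (the spectral leak is a property of the sensor and
    filters, not the window) while the intercept is per-hemisphere; pass
    ``pooled_rho=False`` for fully independent per-hemisphere lines.
    Outlier cells (|studentized residual| > ``outlier_threshold``) are
    reported in the diagnostics, not removed.
    """
    import statsmodels.api as sm

    g = pre_table["mean_green"].to_numpy(dtype=float) - dark_green
    r = pre_table["mean_red"].to_numpy(dtype=float) - dark_red
    hemi = pre_table["hemisphere"].astype(str).to_numpy()
    hemis = list(pd.unique(hemi))
    if g.size < 3:
        raise ValueError("need at least 3 pre-conversion cells")
    if np.ptp(g) == 0:
        raise ValueError("green values are all equal; slope is unidentifiable")

    if pooled_rho:
        # red ~ rho * green + beta_h (one dummy intercept per hemisphere)
        X = np.column_stack([g] + [(hemi == h).astype(float) for h in hemis])
        fit = sm.OLS(r, X).fit()
        rho = float(fit.params[0])
        betas = {h: float(b) for h, b in zip(hemis, fit.params[1:])}
        infl = fit.get_influence().resid_studentized_internal
        outliers = np.nonzero(np.abs(infl) > outlier_threshold)[0]
        diag = {
            "pooled_rho": True,
            "rho_se": float(fit.bse[0]),
            "r_squared": float(fit.rsquared),
            "n": int(g.size),
            "outlier_rows": [int(i) for i in outliers],
        }
    else:
        rho_by, betas, diag = {}, {}, {"pooled_rho": False, "per_hemisphere": {}}
        for h in hemis:
            m = hemi == h
            est = estimate_contamination_ratio(g[m], r[m])
            rho_by[h] = est["rho"]
            betas[h] = est["intercept"]
            diag["per_hemisphere"][h] = est
        rho = rho_by

    clamped = False
    if pooled_rho and rho < 0:
        warnings.warn(f"fitted contamination ratio is negative ({rho:.4g}); clamping to 0")
        rho, clamped = 0.0, True
    if isinstance(rho, dict):
        for h, v in rho.items():
            if v < 0:
                warnings.warn(f"negative contamination ratio in {h}; clamping to 0")
                rho[h], clamped = 0.0, True
    diag["rho_clamped"] = clamped

    return CorrectionParams(
        dark_green=dark_green,
        dark_red=dark_red,
        contamination_ratio=rho,
        autofluor_intercept=betas,
        diagnostics=diag,
    )


def apply_corrections(green, red, params: CorrectionParams, hemisphere: str | None = None):
    """Correct raw channel values; returns (g_corr, r_corr).

    Order fixed: darks first, then the hemisphere's beta, then the
    bleed-through term rho * g_corr. Accepts scalars or arrays.
    """
    g_corr = np.asarray(green, dtype=float) - params.dark_green
    r_corr = (
        np.asarray(red, dtype=float)
        - params.dark_red
        - params.beta(hemisphere)
        - params.rho(hemisphere) * g_corr
    )
    if np.ndim(green) == 0:
        return float(g_corr), float(r_corr)
    return g_corr, r_corr


def correct_cell_table(table: pd.DataFrame, params: CorrectionParams) -> pd.DataFrame:
    """Apply the correction chain to a per-cell fluorescence table.

    Adds ``green_corr``, ``red_corr`` and ``qc_ok`` columns; cells whose
    corrected green is non-positive are flagged non-quantifiable (kept in
    the table for the QC report, excluded from ratio computation
    downstream).
    """
    out = table.copy()
    hemi = out["hemisphere"] if "hemisphere" in out else pd.Series([None] * len(out))
    g_corr = np.empty(len(out))
    r_corr = np.empty(len(out))
    for h in pd.unique(hemi):
        m = (hemi == h).to_numpy()
        g_corr[m], r_corr[m] = apply_corrections(
            out.loc[m, "mean_green"].to_numpy(),
            out.loc[m, "mean_red"].to_numpy(),
            params,
            None if pd.isna(h) else str(h),
        )
    out["green_corr"] = g_corr
    out["red_corr"] = r_corr
    out["qc_ok"] = out["green_corr"] > 0
    n_bad = int((~out["qc_ok"]).sum())
    if n_bad:
        warnings.warn(f"{n_bad} cells have non-positive corrected green; flagged in qc_ok")
    return out
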