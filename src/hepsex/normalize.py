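"""Two-color array normalization, replicate combination, and power analysis.

Each array's male/female log10 ratio is orientation-corrected, LOWESS
normalized against mean log intensity (removing intensity-dependent dye
bias), and median-centred.  The 16 replicate ratios per probe are combined by
inverse-variance weighting with per-array errors predicted from a pooled
intensity-vs-dispersion fit, giving a mean signed fold-change and a two-sided
normal p-value per probe.

``detectable_fold_change`` reproduces the design's power calculation: the
smallest fold change a two-sided one-sample t-test on n replicate log10
ratios detects with the requested power, via the noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .calling import composite_score_frame, signed_fold_change
from .synthetic import TwoColorArraySet


@dataclass
class PowerSpec:
    """Inputs of the minimal-detectable-fold-change calculation."""

    sd_log10: float = 0.0896
    n_arrays: int = 16
    alpha: float = 0.05
    power: float = 0.8

    def validate(self) -> None:
        if self.sd_log10 <= 0:
            raise ValueError("sd_log10 must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.power <= self.alpha:
            raise ValueError("power must exceed alpha")
        if self.n_arrays < 2:
            raise ValueError("need at least 2 arrays")


# ---------------------------------------------------------------------------
# LOWESS normalization
# ---------------------------------------------------------------------------


def _lowess_fit(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    # delta skips nearby points for large arrays; pure speed optimisation
    delta = 0.005 * (x.max() - x.min()) if len(x) > 5000 else 0.0
    return lowess(y, x, frac=span, delta=delta, return_sorted=False)


def lowess_normalize(
    array_set: TwoColorArraySet,
    span: float = 0.4,
    background: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-array normalized log10 male/female ratios.

    Returns ``(ratios, amean)``: probes x arrays matrices of normalized
    log10 ratios and of mean log10 intensities (the MA-plot abscissa).
    Probes with both channels at or below background are set to NaN.  The
    LOWESS trend of ratio vs mean intensity is subtracted per array, then the
    ratios are median-centred (the "linear" step).
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    bg = array_set.background if background is None else background

    ratios = {}
    ameans = {}
    for _, row in array_set.arrays.iterrows():
        aid = row["array_id"]
        a = array_set.channel_a[aid].to_numpy(dtype=float)
        b = array_set.channel_b[aid].to_numpy(dtype=float)
        if not (a > 0).any() or not (b > 0).any():
            raise ValueError(f"array {aid} has an all-zero channel")
        flagged = (a <= bg) & (b <= bg)
        a = np.clip(a, 1e-12, None)
        b = np.clip(b, 1e-12, None)
        log_a, log_b = np.log10(a), np.log10(b)
        amean = 0.5 * (log_a + log_b)
        ratio = log_a - log_b if row["dye_orientation"] == "male_in_A" else log_b - log_a
        ok = ~flagged
        corrected = np.full_like(ratio, np.nan)
        trend = _lowess_fit(amean[ok], ratio[ok], span)
        corrected[ok] = ratio[ok] - trend
        corrected[ok] -= np.median(corrected[ok])
        ratios[aid] = corrected
        ameans[aid] = np.where(flagged, np.nan, amean)

    idx = array_set.probe_ids
    return pd.DataFrame(ratios, index=idx), pd.DataFrame(ameans, index=idx)


# ---------------------------------------------------------------------------
# replicate combination
# ---------------------------------------------------------------------------


def estimate_replicate_errors(
    ratios: pd.DataFrame, amean: pd.DataFrame, span: float = 0.4
) -> pd.DataFrame:
    """Per-probe, per-array error estimates from a pooled dispersion fit.

    The replicate standard deviation of each probe's log10 ratios is
    regressed (LOWESS, on the log scale) against the probe's mean intensity,
    pooling all probes; the fitted curve evaluated at each probe/array
    intensity is the error estimate.  This plays the role of a
    technology-level error model: it stabilises per-probe variance estimates
    by borrowing strength across probes of similar intensity.
    """
    sd = ratios.std(axis=1, ddof=1)
    x = amean.mean(axis=1)
    ok = sd.notna() & (sd > 0) & x.notna()
    fit = lowess(np.log(sd[ok]), x[ok], frac=span, return_sorted=True)
    fx, fy = fit[:, 0], fit[:, 1]
    pred = np.exp(np.interp(amean.to_numpy(dtype=float), fx, fy))
    errors = pd.DataFrame(pred, index=ratios.index, columns=ratios.columns)
    return errors.where(ratios.notna())


def combine_replicates(
    ratios: pd.DataFrame,
    errors: pd.DataFrame,
    method: str = "inverse_variance",
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Error-weighted combination of replicate log10 ratios per probe.

    Weighted mean m = sum(w x)/sum(w) with w = 1/error^2, standard error
    sqrt(1/sum(w)), and a two-sided normal p-value for m = 0.  Probes with
    fewer than ``min_replicates`` usable ratios get p = 1 and are flagged.

    Returns a probe table with mean_log10_ratio, se, p_value, fold_change,
    composite_score, direction, n_arrays and low_replicate columns.
    """
    if method != "inverse_variance":
        raise ValueError(f"unknown combination method: {method}")
    if not ratios.index.equals(errors.index) or list(ratios.columns) != list(errors.columns):
        raise ValueError("ratios and errors must be aligned")
    err = errors.to_numpy(dtype=float)
    rat = ratios.to_numpy(dtype=float)
    usable = np.isfinite(rat) & np.isfinite(err)
    if (err[usable] < 0).any():
        raise ValueError("errors must be non-negative")
    if not (err[usable] > 0).any():
        raise ValueError("degenerate weights: all errors are zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(usable & (err > 0), 1.0 / err**2, 0.0)
    if np.isinf(w).any():
        raise ValueError("degenerate weights: zero error encountered")
    n = usable.sum(axis=1)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(wsum > 0, np.nansum(w * np.where(usable, rat, 0.0), axis=1), np.nan)
        mean = np.where(wsum > 0, mean / np.where(wsum > 0, wsum, 1.0), np.nan)
        se = np.where(wsum > 0, np.sqrt(1.0 / np.where(wsum > 0, wsum, 1.0)), np.nan)
    z = np.where(se > 0, np.abs(mean) / se, 0.0)
    p = 2.0 * stats.norm.sf(z)
    low = n < min_replicates
    p = np.where(low, 1.0, p)
    mean = np.where(low, np.nan, mean)

    score = composite_score_frame(ratios, log_scale=True)
    out = pd.DataFrame(
        {
            "mean_log10_ratio": mean,
            "se": se,
            "p_value": p,
            "fold_change": np.where(
                np.isfinite(mean), signed_fold_change(10.0 ** np.where(np.isfinite(mean), mean, 0.0)), np.nan
            ),
            "composite_score": score["score"],
            "direction": score["direction"],
            "n_arrays": n,
            "low_replicate": low,
        },
        index=ratios.index,
    )
    out.index.name = "probe_id"
    return out


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------


def detectable_fold_change(spec: PowerSpec | None = None, **kwargs) -> float:
    """Smallest fold change detectable at the requested power.

    Solves for the fold change FC whose noncentrality sqrt(n) log10(FC)/sd
    gives the target power in a two-sided one-sample t-test of mean log10
    ratio = 0 at level alpha (df = n - 1, noncentral t).  Monotone
    decreasing in n_arrays and increasing in sd_log10.
    """
    spec = spec or PowerSpec(**kwargs)
    spec.validate()
    df = spec.n_arrays - 1
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)

    def power_at(delta: float) -> float:
        return stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta)

    hi = 1.0
    while power_at(hi) < spec.power:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("power target unreachable")
    delta = optimize.brentq(lambda d: power_at(d) - spec.power, 0.0, hi, xtol=1e-10)
    return float(10.0 ** (delta * spec.sd_log10 / np.sqrt(spec.n_arrays)))
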