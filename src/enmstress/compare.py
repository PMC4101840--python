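"""Fit and compare the stress and flexibility models of site rates.

Both candidate models are simple linear regressions of the per-protein
z-scored evolutionary rate on a z-scored structural predictor:

* stress model:      zrate ~ a + b * z(MLmS)
* flexibility model: zrate ~ a + b * z(MSF)   (or z(B-factor))

Goodness of fit is summarized by the Akaike information criterion
``AIC = 2k - 2 ln L`` with the full Gaussian maximum likelihood and
``k = 3`` (intercept, slope, error variance) — the convention of
mainstream statistics packages for a simple linear model.  Relative
evidence is expressed as AIC weights ``w ~ exp(-dAIC/2)``.  Pearson and
first-order partial correlations (each predictor controlling the other)
complete the comparison, which is run protein by protein and pooled over
all sites.  Binned predictor-vs-rate profiles expose the shape of the
relationship: linear in stress, visibly curved in flexibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearFitResult",
    "ModelComparison",
    "BinnedProfile",
    "fit_linear",
    "aic_weights",
    "pearson",
    "partial_correlation",
    "compare_per_protein",
    "compare_pooled",
    "binned_profile",
    "curvature_ftest",
]

AIC_N_PARAMS = 3  # intercept, slope, residual variance
CI99_MULTIPLIER = 2.5758  # two-sided 99% normal quantile


@dataclass(frozen=True)
class LinearFitResult:
    """OLS fit of rate on one predictor with Gaussian-ML bookkeeping."""

    model_tag: str
    a: float  # intercept
    b: float  # slope
    n: int
    rss: float
    loglik: float
    aic: float
    r: float  # Pearson correlation of y with x


@dataclass(frozen=True)
class ModelComparison:
    """Stress-vs-flexibility comparison, per protein or pooled.

    ``summary`` has one row per model (aic, waic, r, pr, n_best);
    ``per_protein`` carries the protein-level detail for the per-protein
    scope and is None for the pooled scope.
    """

    scope: str  # "per_protein" | "pooled"
    x_stress: str
    x_flex: str
    summary: pd.DataFrame
    per_protein: pd.DataFrame | None
    excluded: tuple[str, ...]
    n_sites: int


@dataclass(frozen=True)
class BinnedProfile:
    """Equal-count binned profile of mean rate against a predictor."""

    predictor_tag: str
    n_bins: int
    table: pd.DataFrame  # columns: bin, n, mean_x, mean_y, ci99


def fit_linear(
    y: np.ndarray, x: np.ndarray, model_tag: str = "model"
) -> LinearFitResult:
    """Ordinary least squares of y on x with the k=3 Gaussian-ML AIC.

    loglik = -(n/2) (ln(2 pi rss / n) + 1); for z-scored inputs the
    intercept is ~0 and the slope equals the Pearson correlation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D arrays of equal length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 points for a linear fit")
    r = pearson(x, y)
    xm, ym = x.mean(), y.mean()
    b = float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))
    a = float(ym - b * xm)
    resid = y - (a + b * x)
    rss = float(resid @ resid)
    if rss < 1e-12:
        raise ValueError("degenerate perfect fit: rss ~ 0, log-likelihood undefined")
    loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    aic = 2.0 * AIC_N_PARAMS - 2.0 * loglik
    return LinearFitResult(
        model_tag=model_tag, a=a, b=b, n=n, rss=rss, loglik=loglik, aic=aic, r=r
    )


def aic_weights(aics) -> np.ndarray:
    """Akaike weights w_m ~ exp(-(AIC_m - min AIC)/2), normalized to sum 1."""
    aics = np.asarray(aics, dtype=float)
    if aics.size < 2:
        raise ValueError("need at least 2 AIC values to compare")
    if not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite")
    w = np.exp(-0.5 * (aics - aics.min()))
    return w / w.sum()


def pearson(x, y) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def partial_correlation(y, x, z) -> float:
    """First-order partial correlation of y with x controlling z.

    pr = (r_yx - r_yz r_xz) / sqrt((1 - r_yz^2)(1 - r_xz^2)).
    """
    r_yx = pearson(y, x)
    r_yz = pearson(y, z)
    r_xz = pearson(x, z)
    if abs(r_xz) >= 1.0 - 1e-12:
        raise ValueError("collinear control: |corr(x, z)| = 1")
    return float((r_yx - r_yz * r_xz) / np.sqrt((1 - r_yz**2) * (1 - r_xz**2)))


def _fit_pair(
    df: pd.DataFrame, y: str, x_stress: str, x_flex: str
) -> dict[str, float]:
    yv = df[y].to_numpy()
    xs = df[x_stress].to_numpy()
    xf = df[x_flex].to_numpy()
    fit_s = fit_linear(yv, xs, "stress")
    fit_f = fit_linear(yv, xf, "flexibility")
    w = aic_weights([fit_s.aic, fit_f.aic])
    return {
        "n": len(df),
        "aic_stress": fit_s.aic,
        "aic_flex": fit_f.aic,
        "waic_stress": float(w[0]),
        "waic_flex": float(w[1]),
        "r_stress": fit_s.r,
        "r_flex": fit_f.r,
        "pr_stress": partial_correlation(yv, xs, xf),
        "pr_flex": partial_correlation(yv, xf, xs),
    }


def _summary_frame(rows: pd.DataFrame, x_stress: str, x_flex: str) -> pd.DataFrame:
    n_prot = len(rows)
    return pd.DataFrame(
        {
            "model": ["stress", "flexibility"],
            "x": [x_stress, x_flex],
            "aic": [rows["aic_stress"].sum(), rows["aic_flex"].sum()],
            "mean_waic": [rows["waic_stress"].mean(), rows["waic_flex"].mean()],
            "n_best": [
                int((rows["aic_stress"] < rows["aic_flex"]).sum()),
                int((rows["aic_flex"] < rows["aic_stress"]).sum()),
            ],
            "mean_r": [rows["r_stress"].mean(), rows["r_flex"].mean()],
            "mean_pr": [rows["pr_stress"].mean(), rows["pr_flex"].mean()],
            "n_proteins": [n_prot, n_prot],
        }
    )


def compare_per_protein(
    table: pd.DataFrame,
    x_stress: str = "zmlms_pfanm",
    x_flex: str = "zmsf_pfanm",
    y: str = "zwr4s",
) -> ModelComparison:
    """Protein-by-protein stress vs flexibility comparison.

    For each protein both models are fitted, and the table aggregates the
    summed AIC, mean AIC weight, count of proteins where each model wins
    (lower AIC), and mean Pearson / partial correlations.  Proteins
    failing fit preconditions (too few sites, missing predictor) are
    excluded and listed in ``excluded``.
    """
    records, excluded = [], []
    for (pdb, chain), grp in table.groupby(["pdb", "chain"], sort=True):
        grp = grp.dropna(subset=[y, x_stress, x_flex])
        key = f"{pdb}/{chain}"
        if len(grp) < 4:
            excluded.append(key)
            continue
        try:
            rec = _fit_pair(grp, y, x_stress, x_flex)
        except ValueError:
            excluded.append(key)
            continue
        records.append({"pdb": pdb, "chain": chain, **rec})
    if not records:
        raise ValueError("no protein passed the fit preconditions")
    per_protein = pd.DataFrame(records)
    return ModelComparison(
        scope="per_protein",
        x_stress=x_stress,
        x_flex=x_flex,
        summary=_summary_frame(per_protein, x_stress, x_flex),
        per_protein=per_protein,
        excluded=tuple(excluded),
        n_sites=int(per_protein["n"].sum()),
    )


def compare_pooled(
    table: pd.DataFrame,
    x_stress: str = "zmlms_pfanm",
    x_flex: str = "zmsf_pfanm",
    y: str = "zwr4s",
) -> ModelComparison:
    """Global comparison over all sites pooled (already z-scored per protein)."""
    pooled = table.dropna(subset=[y, x_stress, x_flex])
    if pooled.empty:
        raise ValueError("pooled table is empty")
    rec = _fit_pair(pooled, y, x_stress, x_flex)
    summary = pd.DataFrame(
        {
            "model": ["stress", "flexibility"],
            "x": [x_stress, x_flex],
            "aic": [rec["aic_stress"], rec["aic_flex"]],
            "waic": [rec["waic_stress"], rec["waic_flex"]],
            "r": [rec["r_stress"], rec["r_flex"]],
            "pr": [rec["pr_stress"], rec["pr_flex"]],
        }
    )
    return ModelComparison(
        scope="pooled",
        x_stress=x_stress,
        x_flex=x_flex,
        summary=summary,
        per_protein=None,
        excluded=(),
        n_sites=int(rec["n"]),
    )


def binned_profile(x, y, n_bins: int = 20, predictor_tag: str = "x") -> BinnedProfile:
    """Equal-count binned profile of y against x.

    Sites are ranked by x (stable order for ties) and split into
    ``n_bins`` contiguous bins; when the count does not divide evenly the
    first ``n % n_bins`` bins take one extra site.  Each bin reports the
    mean predictor, the mean rate, and a 99% normal-approximation
    confidence half-width ``2.5758 * SD(y_bin) / sqrt(n_bin)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be aligned")
    n = x.size
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} points, got {n}")
    order = np.argsort(x, kind="stable")
    base, rem = divmod(n, n_bins)
    counts = np.full(n_bins, base)
    counts[:rem] += 1
    rows = []
    start = 0
    for b, c in enumerate(counts):
        idx = order[start : start + c]
        start += c
        yb = y[idx]
        ci = CI99_MULTIPLIER * yb.std(ddof=1) / np.sqrt(c) if c > 1 else 0.0
        rows.append(
            {"bin": b, "n": int(c), "mean_x": float(x[idx].mean()),
             "mean_y": float(yb.mean()), "ci99": float(ci)}
        )
    return BinnedProfile(
        predictor_tag=predictor_tag, n_bins=n_bins, table=pd.DataFrame(rows)
    )


def curvature_ftest(x, y) -> tuple[float, float]:
    """F-test of a quadratic term in y ~ x: (F statistic, p-value).

    Compares y ~ 1 + x against y ~ 1 + x + x^2; a small p-value flags a
    nonlinear predictor-rate relationship.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points for the quadratic F-test")
    X1 = np.column_stack([np.ones(n), x])
    X2 = np.column_stack([np.ones(n), x, x**2])
    rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
    rss2 = float(np.sum((y - X2 @ np.linalg.lstsq(X2, y, rcond=None)[0]) ** 2))
    df2 = n - 3
    f = (rss1 - rss2) / (rss2 / df2)
    p = float(stats.f.sf(f, 1, df2))
    return float(f), p
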