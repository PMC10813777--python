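"""Sloan neutral community model: fit, prediction band, partitioning.

The model predicts a taxon's occurrence frequency across local communities
from its metacommunity relative abundance p via the beta approximation

    F(p) = 1 - I_{d/N}(Nm*p, Nm*(1-p))

where I is the regularised incomplete beta function, N the community size
(mean reads per sample), d the detection limit in reads and Nm = N*m the
product of community size and immigration rate. Nm is estimated by
non-linear least squares of observed occurrence frequencies on F(p); taxa
whose observed frequency falls outside a 95% band around the fitted curve
are partitioned into `above` / `below`, the rest are `neutral`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datamodel import CountTable, TaxonomyTable, ValidationError

PARTITIONS = ("above", "neutral", "below")


class FitError(RuntimeError):
    """Raised when the least-squares fit cannot be completed."""


@dataclass
class NcmFit:
    """Fitted neutral model for one set of samples.

    ``per_zotu`` is indexed by ZOTU id with columns p, f_obs, f_pred,
    f_lower, f_upper, partition; taxa never detected in the fitted samples
    are excluded from the regression and listed in ``excluded_ids``.
    """

    nm: float
    m: float
    n_reads: float
    d: int
    r_squared: float
    ci_level: float
    n_samples: int
    per_zotu: pd.DataFrame
    excluded_ids: list
    band_method: str = "binomial"
    sst_convention: str = "around-mean"

    def partition_counts(self) -> dict:
        vc = self.per_zotu["partition"].value_counts()
        return {part: int(vc.get(part, 0)) for part in PARTITIONS}


def predict_frequency(p, Nm: float, N: float, d: float = 1.0):
    """Expected occurrence frequency F(p) under the neutral model.

    Scalar or vectorised over ``p``; monotone non-decreasing in p.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValidationError("relative abundance p must lie in [0, 1]")
    if Nm <= 0 or N <= d or d < 1:
        raise ValidationError("need Nm > 0 and N > d >= 1")
    a = Nm * p_arr
    b = Nm * (1.0 - p_arr)
    out = np.empty_like(p_arr)
    interior = (p_arr > 0) & (p_arr < 1)
    out[p_arr <= 0] = 0.0
    out[p_arr >= 1] = 1.0
    if interior.any():
        out[interior] = 1.0 - special.betainc(a[interior], b[interior], d / N)
    return out if out.shape else float(out)


def _wilson_band(f_pred: np.ndarray, n: int, ci_level: float):
    """Wilson score interval for a binomial proportion around the prediction."""
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    denom = 1.0 + z * z / n
    centre = (f_pred + z * z / (2 * n)) / denom
    half = (z / denom) * np.sqrt(f_pred * (1 - f_pred) / n + z * z / (4 * n * n))
    return np.clip(centre - half, 0.0, 1.0), np.clip(centre + half, 0.0, 1.0)


def _binomial_band(f_pred: np.ndarray, n: int, ci_level: float):
    """Binomial prediction band for an observed frequency over n samples.

    Under the fitted model a taxon's detection count across n samples is
    Binomial(n, f_pred); the band holds the central ci_level quantiles of
    the observed frequency itself. This is a prediction interval (for the
    data), deliberately wider than a Wilson confidence interval (for the
    estimated proportion).
    """
    alpha = (1.0 - ci_level) / 2.0
    lower = stats.binom.ppf(alpha, n, f_pred) / n
    upper = stats.binom.ppf(1.0 - alpha, n, f_pred) / n
    # discreteness can push a quantile past the prediction near f_pred ~ 0/1;
    # the band always contains the fitted curve
    lower = np.minimum(lower, f_pred)
    upper = np.maximum(upper, f_pred)
    return np.clip(lower, 0, 1), np.clip(upper, 0, 1)


_MULTISTART = (1.0, 10.0, 100.0, 1000.0, 10_000.0)


def fit_ncm(table: CountTable, d: int = 1, ci_level: float = 0.95,
            band: str = "binomial") -> NcmFit:
    """Fit Nm by least squares of occurrence frequency on the neutral curve.

    N is the mean sample read total; p_i the mean relative abundance of
    taxon i over samples; f_obs,i the fraction of samples where taxon i has
    at least ``d`` reads. Nm is optimised on the log scale from several
    starting points. R^2 = 1 - SSE/SST may be negative and is reported as-is.
    """
    if table.n_samples < 2:
        raise ValidationError("neutral model fit needs at least 2 samples")
    counts = table.counts
    detected = counts.sum(axis=1) > 0
    if int(detected.sum()) < 10:
        raise ValidationError("need at least 10 ZOTUs detected in >= 1 sample")
    excluded = table.zotu_ids[~detected].tolist()
    sub = counts[detected]
    ids = table.zotu_ids[detected]
    N = float(counts.sum(axis=0).mean())
    rel = sub / counts.sum(axis=0, keepdims=True)
    p = rel.mean(axis=1)
    f_obs = (sub >= d).mean(axis=1)
    if np.allclose(f_obs, f_obs[0]):
        raise FitError("degenerate frequency spectrum: all occurrence "
                       "frequencies identical")

    def residuals(log_nm):
        nm_val = float(np.exp(np.atleast_1d(log_nm)[0]))
        return f_obs - predict_frequency(p, nm_val, N, d)

    best = None
    diagnostics = []
    for start in _MULTISTART:
        try:
            sol = optimize.least_squares(residuals, x0=[np.log(start)],
                                         method="lm", max_nfev=200)
        except Exception as exc:  # pragma: no cover - optimizer edge
            diagnostics.append(f"start {start}: {exc}")
            continue
        if not np.isfinite(sol.cost):
            diagnostics.append(f"start {start}: non-finite cost")
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("Nm optimisation failed from every start: "
                       + "; ".join(diagnostics))
    nm = float(np.exp(best.x[0]))
    f_pred = predict_frequency(p, nm, N, d)
    sse = float(np.sum((f_obs - f_pred) ** 2))
    sst = float(np.sum((f_obs - f_obs.mean()) ** 2))
    r2 = 1.0 - sse / sst
    n = table.n_samples
    if band == "wilson":
        lower, upper = _wilson_band(f_pred, n, ci_level)
    elif band == "binomial":
        lower, upper = _binomial_band(f_pred, n, ci_level)
    else:
        raise ValidationError(f"unknown band method {band!r}")
    partition = np.where(f_obs > upper, "above",
                         np.where(f_obs < lower, "below", "neutral"))
    per_zotu = pd.DataFrame(
        {"p": p, "f_obs": f_obs, "f_pred": f_pred,
         "f_lower": lower, "f_upper": upper, "partition": partition},
        index=ids,
    )
    return NcmFit(nm=nm, m=nm / N, n_reads=N, d=d, r_squared=r2,
                  ci_level=ci_level, n_samples=n, per_zotu=per_zotu,
                  excluded_ids=excluded, band_method=band)


@dataclass
class PartitionSummary:
    """ZOTU counts and cumulative mean relative abundance per partition."""

    table: pd.DataFrame  # index: partition (or (family, partition))
    by_family: bool = False

    def cumulative_abundance(self, partition: str) -> float:
        if self.by_family:
            sub = self.table.xs(partition, level="partition")
            return float(sub["cum_abundance"].sum())
        if partition not in self.table.index:
            return 0.0
        return float(self.table.loc[partition, "cum_abundance"])


def partition_abundance(fit: NcmFit, table: CountTable | None = None) -> PartitionSummary:
    """Counts and cumulative mean relative abundance of each partition.

    Cumulative abundance is the sum over member ZOTUs of their mean relative
    abundance p_i; the three partitions sum to <= 1 (equality when every
    taxon was fitted).
    """
    if table is not None:
        missing = fit.per_zotu.index.difference(table.zotu_ids)
        if len(missing):
            raise ValidationError(
                f"fit contains ZOTUs absent from the table: {missing.tolist()[:5]}"
            )
    rows = []
    for part in PARTITIONS:
        members = fit.per_zotu[fit.per_zotu["partition"] == part]
        rows.append({"partition": part, "n_zotus": len(members),
                     "cum_abundance": float(members["p"].sum())})
    return PartitionSummary(pd.DataFrame(rows).set_index("partition"))


def partition_by_family(fit: NcmFit, taxonomy: TaxonomyTable) -> PartitionSummary:
    """Family-resolved partition summary, families sorted by total abundance."""
    fam = taxonomy.family_of(fit.per_zotu.index)
    df = fit.per_zotu.assign(family=fam.to_numpy())
    grouped = (df.groupby(["family", "partition"], observed=True)
               .agg(n_zotus=("p", "size"), cum_abundance=("p", "sum")))
    totals = grouped.groupby("family")["cum_abundance"].sum().sort_values(
        ascending=False)
    grouped = grouped.reindex(
        pd.MultiIndex.from_tuples(
            [(f, p) for f in totals.index for p in PARTITIONS
             if (f, p) in grouped.index],
            names=["family", "partition"],
        )
    )
    return PartitionSummary(grouped, by_family=True)
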