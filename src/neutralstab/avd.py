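"""Average variation degree (AVD): a community-stability index.

For each OTU i within a sample group of k samples, the variation degree in
sample j is a_ij = |x_ij - mean_i| / sd_i, where x are (rarefied) abundances
and mean/sd are taken over the group's samples. The AVD of the group is the
grand mean of a_ij over the n retained OTUs and k samples:

    AVD = sum_ij |x_ij - mean_i| / sd_i / (k * n)

Lower AVD means the community deviates less (in sd units) around its own
mean profile, i.e. is more stable. Zero-variance OTUs have an undefined
degree and are excluded by default (n shrinks accordingly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CountTable, SampleFrame, ValidationError
from .multivariate import anova_tukey


@dataclass
class AvdResult:
    group: str
    k: int                  # samples in the group
    n: int                  # OTUs retained
    avd: float
    degrees: pd.DataFrame   # a_ij for retained OTUs (rows) x samples (cols)
    n_excluded: int
    ddof: int = 1


def variation_degree(group_table: pd.DataFrame, ddof: int = 1):
    """Per-OTU, per-sample degrees |x - mean| / sd within one group.

    Returns (degrees DataFrame for retained OTUs, excluded-OTU index).
    """
    if group_table.shape[1] < 2:
        raise ValidationError("variation degree needs k >= 2 samples")
    x = group_table.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    retained = sd[:, 0] > 0
    degrees = np.abs(x[retained] - mean[retained]) / sd[retained]
    deg = pd.DataFrame(degrees, index=group_table.index[retained],
                       columns=group_table.columns)
    return deg, group_table.index[~retained]


def avd(group_table: pd.DataFrame, ddof: int = 1,
        zero_variance: str = "exclude", group: str = "") -> AvdResult:
    """AVD of one sample group (OTU x sample abundance matrix).

    ``zero_variance='exclude'`` drops sd=0 OTUs from numerator and n;
    ``'zero'`` keeps them with degree 0.
    """
    if zero_variance not in ("exclude", "zero"):
        raise ValidationError(f"unknown zero_variance policy {zero_variance!r}")
    deg, excluded = variation_degree(group_table, ddof=ddof)
    k = group_table.shape[1]
    if zero_variance == "zero":
        zeros = pd.DataFrame(0.0, index=excluded, columns=group_table.columns)
        deg = pd.concat([deg, zeros]).loc[group_table.index.intersection(
            list(deg.index) + list(excluded))]
        deg = deg.reindex(group_table.index)
        n = group_table.shape[0]
        n_excluded = 0
    else:
        n = deg.shape[0]
        n_excluded = len(excluded)
    if n == 0:
        raise ValidationError("degenerate group: every OTU has zero variance")
    value = float(deg.to_numpy().sum() / (k * n))
    return AvdResult(group=group, k=k, n=n, avd=value, degrees=deg,
                     n_excluded=n_excluded, ddof=ddof)


def avd_by_stratum(table: CountTable, frame: SampleFrame,
                   strata: tuple = ("group", "lifestyle"), ddof: int = 1,
                   zero_variance: str = "exclude",
                   replicate_column: str = "replicate"):
    """AVD per stratum plus replicate-level AVDs for significance testing.

    Strata default to group x lifestyle. Within each stratum, one AVD is
    computed over all its samples, and one AVD per replicate (across that
    replicate's timepoints) feeds downstream ANOVA/Tukey comparisons.

    Returns (list of AvdResult, DataFrame of replicate-level AVDs with
    columns stratum/replicate/avd).
    """
    meta = frame.aligned_to(table)
    df = table.data
    results = []
    rep_rows = []
    for key, sub in meta.data.groupby(list(strata), observed=True, sort=False):
        label = key if isinstance(key, str) else "_".join(str(v) for v in key)
        sample_ids = sub.index.tolist()
        if len(sample_ids) < 2:
            warnings.warn(f"stratum {label} has < 2 samples; skipped",
                          stacklevel=2)
            continue
        results.append(avd(df[sample_ids], ddof=ddof,
                           zero_variance=zero_variance, group=label))
        for rep, rep_sub in sub.groupby(replicate_column, observed=True):
            rep_ids = rep_sub.index.tolist()
            if len(rep_ids) < 2:
                continue
            res = avd(df[rep_ids], ddof=ddof, zero_variance=zero_variance,
                      group=f"{label}_rep{rep}")
            rep_rows.append({"stratum": label, "replicate": rep,
                             "avd": res.avd})
    return results, pd.DataFrame(rep_rows)


def compare_avd(replicate_avds: pd.DataFrame, group_column: str = "stratum",
                value_column: str = "avd"):
    """One-way ANOVA + Tukey HSD over replicate-level AVDs.

    Groups sharing a compact-display letter are not significantly different
    at alpha = 0.05. Groups with fewer than 2 values are excluded with a
    warning.
    """
    values, groups = [], []
    for g, sub in replicate_avds.groupby(group_column, sort=False):
        vals = sub[value_column].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"group {g} has < 2 replicate AVDs; excluded",
                          stacklevel=2)
            continue
        values.extend(vals)
        groups.extend([g] * len(vals))
    return anova_tukey(np.asarray(values), np.asarray(groups, dtype=object))
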