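"""Synthetic amplicon data with known community-assembly structure.

The generator is the sampling counterpart of the Sloan neutral model: each
local community draws, for every taxon with metacommunity relative abundance
p_i, a local relative abundance from Beta(Nm*p_i, Nm*(1-p_i)) and then reads
from Binomial(N, x). Nm (community size times immigration rate) controls how
tightly local communities track the metacommunity. On top of the neutral
backbone, taxa can be injected that occur more often (forced detection at low
abundance) or less often (zeroed out despite high abundance) than neutrality
predicts, and a full group x replicate x timepoint x lifestyle study design
with nutrient covariates can be emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    GROUPS,
    LIFESTYLES,
    TAXONOMY_RANKS,
    CountTable,
    SampleFrame,
    TaxonomyTable,
    ValidationError,
)

_PARAM_FLOOR = 1e-8
_ZERO_CUTOFF = 1e-6


@dataclass
class NeutralSimConfig:
    """One neutral community group: S taxa, k samples, N reads, immigration Nm."""

    S: int = 1000
    k: int = 50
    N: int = 10_000
    Nm: float = 500.0
    abundance_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2 or self.k < 2 or self.N < 10 or self.Nm <= 0:
            raise ValidationError(
                "need S >= 2, k >= 2, N >= 10, Nm > 0; got "
                f"S={self.S}, k={self.k}, N={self.N}, Nm={self.Nm}"
            )


# Trend defaults mirror the qualitative nutrient pattern of the shrimp-water
# experiment: nitrate and phosphate higher in the microalgae-added groups
# (N/T/M) than the control, ammonium/nitrite low and similar everywhere.
_DEFAULT_NUTRIENT_TRENDS = {
    "NH4N": {g: (0.35, -0.005, 0.05) for g in GROUPS},
    "NO2N": {g: (0.15, 0.001, 0.04) for g in GROUPS},
    "NO3N": {
        "C": (1.2, 0.04, 0.3),
        "N": (2.0, 0.14, 0.5),
        "T": (2.5, 0.21, 0.5),
        "M": (2.0, 0.15, 0.5),
    },
    "PO4P": {
        "C": (0.6, 0.02, 0.1),
        "N": (1.3, 0.04, 0.15),
        "T": (1.5, 0.05, 0.15),
        "M": (1.4, 0.04, 0.15),
    },
}

_DEFAULT_BIOMASS = {
    "n_oculata": {"C": 0.0, "N": 24.0, "T": 0.0, "M": 20.0},
    "t_weissflogii": {"C": 0.0, "N": 0.0, "T": 35.0, "M": 5.0},
}


@dataclass
class StudyDesignConfig:
    """Full factorial design: groups x replicates x timepoints x lifestyles."""

    groups: tuple = GROUPS
    replicates: int = 3
    timepoints: tuple = (0, 5, 8, 11, 15, 19, 22, 29)
    lifestyles: tuple = LIFESTYLES
    S: int = 1000
    N: int = 10_000
    # Per-group immigration parameter; control assembles most neutrally.
    group_nm: dict = field(
        default_factory=lambda: {"C": 1500.0, "N": 1000.0, "T": 600.0, "M": 800.0}
    )
    # Optional per-lifestyle Nm multiplier (defaults equal).
    lifestyle_nm_factor: dict = field(
        default_factory=lambda: {"PA": 1.0, "FL": 1.0}
    )
    abundance_sigma: float = 2.0
    n_above: int = 30
    n_below: int = 30
    nutrient_trends: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in _DEFAULT_NUTRIENT_TRENDS.items()
        }
    )
    biomass_levels: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_BIOMASS.items()}
    )
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return (len(self.groups) * self.replicates
                * len(self.timepoints) * len(self.lifestyles))


def simulate_metacommunity(S: int, abundance_sigma: float, seed: int) -> np.ndarray:
    """Lognormal rank-abundance source pool, normalised to sum to 1."""
    if S < 2:
        raise ValidationError("metacommunity needs at least 2 taxa")
    rng = np.random.default_rng([int(seed), 0])
    raw = rng.lognormal(mean=0.0, sigma=float(abundance_sigma), size=S)
    return raw / raw.sum()


def _draw_local_abundance(rng, p: np.ndarray, Nm: float, k: int) -> np.ndarray:
    """Beta(Nm p, Nm (1-p)) draws for k samples, with underflow guards."""
    a = np.maximum(Nm * p, _PARAM_FLOOR)
    b = np.maximum(Nm * (1.0 - p), _PARAM_FLOOR)
    x = rng.beta(a[None, :], b[None, :], size=(k, p.size))
    dead = (Nm * p < _ZERO_CUTOFF) & (Nm * (1.0 - p) < _ZERO_CUTOFF)
    x[:, dead] = 0.0
    x[:, p <= 0.0] = 0.0
    return x


def simulate_neutral_counts(p: np.ndarray, cfg: NeutralSimConfig):
    """Neutral count table for one community group plus the generative truth.

    Returns (CountTable, truth) where truth records Nm, the metacommunity
    abundances and the per-sample latent local abundances.
    """
    p = np.asarray(p, dtype=float)
    if p.size != cfg.S:
        raise ValidationError(f"metacommunity has {p.size} taxa, config says S={cfg.S}")
    rng = np.random.default_rng([int(cfg.seed), 1])
    x = _draw_local_abundance(rng, p, cfg.Nm, cfg.k)
    counts = rng.binomial(cfg.N, x)  # (k, S)
    zotu_ids = [f"ZOTU{i + 1}" for i in range(cfg.S)]
    sample_ids = [f"S{j + 1}" for j in range(cfg.k)]
    table = CountTable(pd.DataFrame(counts.T, index=zotu_ids, columns=sample_ids))
    truth = {
        "Nm": cfg.Nm,
        "N": cfg.N,
        "p": p,
        "x": x,
        "labels": pd.Series("neutral", index=pd.Index(zotu_ids)),
    }
    return table, truth


def inject_non_neutral(table: CountTable, truth: dict, n_above: int,
                       n_below: int, seed: int,
                       below_zero_fraction: float = 0.8):
    """Overwrite selected taxa so they defy the neutral occurrence prediction.

    ``above`` taxa are picked from the low-abundance half and forced to be
    detected in every sample (one read borrowed from the sample's most
    abundant taxon, so totals never change). ``below`` taxa are picked from
    the high-abundance decile and zeroed out in ``below_zero_fraction`` of
    samples, their reads redistributed proportionally over the other taxa
    (largest-remainder rounding keeps sample totals exact).
    """
    counts = table.counts.copy()  # (S, k)
    S, k = counts.shape
    if n_above + n_below > S:
        raise ValidationError(
            f"cannot inject {n_above}+{n_below} taxa into a table of {S}"
        )
    labels = truth["labels"].copy()
    if n_above == 0 and n_below == 0:
        return table, {**truth, "labels": labels}
    rng = np.random.default_rng([int(seed), 2])
    p = np.asarray(truth["p"], dtype=float)
    order = np.argsort(p)
    lower_half = order[: S // 2]
    # below candidates sit in the top abundance decile but exclude the few
    # dominant taxa: abundant enough to stay top-decile after zeroing (their
    # surviving occurrences are boosted below), yet not so dominant that
    # reallocating their reads distorts every other taxon's abundance
    dominants = max(1, S // 50)
    top_pool = order[-max(n_below + dominants, round(0.07 * S)):]
    preferred = top_pool[:-dominants] if len(top_pool) - dominants >= n_below \
        else top_pool
    above_idx = rng.choice(lower_half, size=n_above, replace=False)
    below_pool = np.setdiff1d(preferred, above_idx)
    below_idx = rng.choice(below_pool, size=n_below, replace=False)

    for i in above_idx:
        for j in range(k):
            if counts[i, j] == 0:
                donor_order = np.argsort(counts[:, j])[::-1]
                donor = next(d for d in donor_order if d != i and counts[d, j] > 0)
                counts[donor, j] -= 1
                counts[i, j] += 1

    def _move_reads(j, source_mask, amount, into=None):
        """Shift ``amount`` reads within sample j, preserving its total.

        With ``into`` None the reads are spread over ``source_mask`` taxa
        proportionally to their counts; otherwise they are taken from the
        mask and credited to taxon ``into``. Largest-remainder rounding
        keeps the ledger integral.
        """
        others = np.flatnonzero(source_mask & (counts[:, j] > 0))
        weights = counts[others, j].astype(float)
        share = amount * weights / weights.sum()
        base = np.floor(share).astype(np.int64)
        leftover = amount - int(base.sum())
        if leftover:
            frac_order = np.argsort(-(share - base))
            base[frac_order[:leftover]] += 1
        if into is None:
            counts[others, j] += base
        else:
            base = np.minimum(base, counts[others, j])
            counts[others, j] -= base
            counts[into, j] += int(base.sum())

    for i in below_idx:
        n_zero = int(round(below_zero_fraction * k))
        zero_samples = rng.choice(k, size=n_zero, replace=False)
        keep_samples = np.setdiff1d(np.arange(k), zero_samples)
        not_i = np.arange(S) != i
        for j in zero_samples:
            freed = int(counts[i, j])
            if freed == 0:
                continue
            counts[i, j] = 0
            _move_reads(j, not_i, freed)
        # boost the surviving occurrences so the across-sample mean stays
        # high (the taxon is abundant where present, just rarely present)
        boost = n_zero / max(k - n_zero, 1)
        for j in keep_samples:
            extra = int(round(counts[i, j] * boost))
            if extra > 0:
                _move_reads(j, not_i, extra, into=i)

    labels.iloc[above_idx] = "above"
    labels.iloc[below_idx] = "below"
    out = CountTable(pd.DataFrame(counts, index=table.zotu_ids,
                                  columns=table.sample_ids))
    new_truth = {**truth, "labels": labels,
                 "above_ids": table.zotu_ids[above_idx].tolist(),
                 "below_ids": table.zotu_ids[below_idx].tolist()}
    return out, new_truth


_SYNTH_FAMILIES = [
    "Rhodobacteraceae", "Flavobacteriaceae", "Sphingomonadaceae",
    "Devosiaceae", "Idiomarinaceae", "Aeromonadaceae", "Saprospiraceae",
    "Rhizobiaceae", "Vibrionaceae", "Alteromonadaceae",
    "Pseudomonadaceae", "Microbacteriaceae", "Nitrosomonadaceae",
    "Cryomorphaceae", "Halieaceae", "Hyphomonadaceae",
    "Cellvibrionaceae", "Moraxellaceae", "Puniceicoccaceae", "Ilumatobacteraceae",
]


def synthetic_taxonomy(zotu_ids, seed: int, n_families: int = 20) -> TaxonomyTable:
    """Assign synthetic SILVA-style family labels to the simulated ZOTUs."""
    rng = np.random.default_rng([int(seed), 3])
    families = _SYNTH_FAMILIES[:n_families]
    fam = rng.choice(families, size=len(zotu_ids))
    df = pd.DataFrame(
        {
            "domain": "Bacteria",
            "phylum": "SimPhylum",
            "class": "SimClass",
            "order": "SimOrder",
            "family": fam,
            "genus": [f"{f[:-4]}_genus" for f in fam],
        },
        index=pd.Index(zotu_ids, name="zotu_id"),
        columns=list(TAXONOMY_RANKS),
    )
    return TaxonomyTable(df)


def simulate_study(cfg: StudyDesignConfig):
    """Simulate the full rearing-water study.

    One sample per (group, replicate, timepoint, lifestyle) design cell, all
    sharing one metacommunity; each group's samples are drawn at that group's
    Nm (optionally scaled per lifestyle). Nutrients follow group-specific
    linear time trends with Gaussian noise. Returns (CountTable, SampleFrame,
    truth).
    """
    p = simulate_metacommunity(cfg.S, cfg.abundance_sigma, cfg.seed)
    zotu_ids = [f"ZOTU{i + 1}" for i in range(cfg.S)]
    columns = {}
    meta_rows = []
    rng = np.random.default_rng([int(cfg.seed), 4])
    x_rngs = {}
    for gi, g in enumerate(cfg.groups):
        for li, ls in enumerate(cfg.lifestyles):
            nm = float(cfg.group_nm[g]) * float(cfg.lifestyle_nm_factor[ls])
            x_rngs[(g, ls)] = (nm, np.random.default_rng([int(cfg.seed), 5, gi, li]))
    for g in cfg.groups:
        for rep in range(1, cfg.replicates + 1):
            for t in cfg.timepoints:
                for ls in cfg.lifestyles:
                    nm, cell_rng = x_rngs[(g, ls)]
                    x = _draw_local_abundance(cell_rng, p, nm, 1)[0]
                    counts = cell_rng.binomial(cfg.N, x)
                    sid = f"{g}{rep}_d{t}_{ls}"
                    columns[sid] = counts
                    row = {"sample_id": sid, "group": g, "time": t,
                           "replicate": rep, "lifestyle": ls}
                    for nut, per_group in cfg.nutrient_trends.items():
                        icpt, slope, sd = per_group[g]
                        val = icpt + slope * t + rng.normal(0.0, sd)
                        row[nut] = max(val, 0.0)
                    for bio, per_group in cfg.biomass_levels.items():
                        level = per_group[g]
                        row[bio] = max(level + rng.normal(0.0, 0.1 * level), 0.0) \
                            if level > 0 else 0.0
                    meta_rows.append(row)
    table = CountTable(pd.DataFrame(columns, index=pd.Index(zotu_ids)))
    frame = SampleFrame(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = {
        "p": p,
        "group_nm": dict(cfg.group_nm),
        "lifestyle_nm_factor": dict(cfg.lifestyle_nm_factor),
        "labels": pd.Series("neutral", index=table.zotu_ids),
        "config": asdict(cfg),
    }
    if cfg.n_above or cfg.n_below:
        table, truth = inject_non_neutral(
            table, truth, cfg.n_above, cfg.n_below, cfg.seed
        )
    truth["taxonomy"] = synthetic_taxonomy(table.zotu_ids, cfg.seed)
    return table, frame, truth
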