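"""Core tabular data types and transformations for amplicon count data.

The universal input is a ZOTU (zero-radius OTU) count table: taxa as rows,
samples as columns, integer read counts. Sample metadata carries the study
design (treatment group, sampling day, replicate tank, bacterial lifestyle)
plus nutrient covariates in mg/L. All downstream statistics consume these
two objects, optionally joined with a ranked taxonomy table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("C", "N", "T", "M")
LIFESTYLES = ("PA", "FL")
NUTRIENT_COLUMNS = ("NH4N", "NO2N", "NO3N", "PO4P")
BIOMASS_COLUMNS = ("n_oculata", "t_weissflogii")
REQUIRED_METADATA = ("sample_id", "group", "time", "replicate", "lifestyle")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")
MISSING_RANK = "Unassigned"


class ValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class CountTable:
    """Integer ZOTU x sample abundance matrix.

    ``data`` is indexed by ZOTU id with one column per sample id; all cells
    are non-negative integers (read counts).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "ZOTU id")
        _check_unique(self.data.columns, "sample id")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                bad = np.argwhere(values != np.round(values))[0]
                raise ValidationError(
                    "non-integer count at ZOTU "
                    f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
                )
            self.data = self.data.astype(np.int64)
            values = self.data.to_numpy()
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def zotu_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_zotus(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data[list(sample_ids)].copy())


@dataclass
class RelAbundanceTable:
    """Column-normalised relative abundance table; every column sums to 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "ZOTU id")
        _check_unique(self.data.columns, "sample id")
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any() or (values > 1).any():
            raise ValidationError("relative abundances must lie in [0, 1]")
        sums = values.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
        if bad.size:
            raise ValidationError(
                f"columns do not sum to 1: {self.data.columns[bad].tolist()}"
            )

    @property
    def zotu_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def mean_abundance(self) -> pd.Series:
        """Mean relative abundance of each ZOTU over samples (p_i)."""
        return self.data.mean(axis=1)


@dataclass
class SampleFrame:
    """Per-sample design factors and environmental covariates.

    Indexed by sample_id with mandatory columns group/time/replicate/lifestyle;
    any additional numeric columns (nutrients, microalgal biomass) ride along
    as covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("group", "time", "replicate", "lifestyle"):
            if col not in self.data.columns:
                raise ValidationError(f"missing required metadata column {col!r}")
        _check_unique(self.data.index, "sample id")
        bad_groups = set(self.data["group"]) - set(GROUPS)
        if bad_groups:
            raise ValidationError(
                f"unknown group value(s) {sorted(bad_groups)}; allowed: {GROUPS}"
            )
        bad_ls = set(self.data["lifestyle"]) - set(LIFESTYLES)
        if bad_ls:
            raise ValidationError(
                f"unknown lifestyle value(s) {sorted(bad_ls)}; allowed: {LIFESTYLES}"
            )
        self.data = self.data.assign(
            time=self.data["time"].astype(int),
            replicate=self.data["replicate"].astype(int),
        )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns
                if c not in ("group", "time", "replicate", "lifestyle")]

    def aligned_to(self, table: CountTable) -> "SampleFrame":
        """Rows reordered to the table's sample order; every sample must be present."""
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples absent from metadata: {missing}")
        return SampleFrame(self.data.loc[list(table.sample_ids)].copy())


@dataclass
class TaxonomyTable:
    """Ranked lineage per ZOTU; missing ranks hold the 'Unassigned' sentinel."""

    data: pd.DataFrame
    ranks: tuple = field(default=TAXONOMY_RANKS)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "ZOTU id")
        present = [r for r in self.ranks if r in self.data.columns]
        if "family" not in present:
            raise ValidationError("taxonomy table must carry a 'family' rank column")
        self.data = self.data[present].copy()
        for col in present:
            vals = self.data[col].astype(str)
            self.data[col] = vals.where(~vals.isin(["", "nan", "None"]), MISSING_RANK)

    def family_of(self, zotu_ids) -> pd.Series:
        fam = self.data["family"].reindex(zotu_ids)
        return fam.fillna(MISSING_RANK)


# ---------------------------------------------------------------------------
# Readers / writers (plain TSV, UTF-8, LF)
# ---------------------------------------------------------------------------

def read_count_table(path) -> CountTable:
    """Read a taxa-by-sample TSV: first column ZOTU id, header row of sample ids."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample id")  # pandas would silently mangle dups
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no data rows")
    _check_unique(df.columns, "sample id")
    id_col = df.columns[0]
    ids = df[id_col]
    _check_unique(ids, "ZOTU id")
    body = df.drop(columns=[id_col])
    parsed = {}
    for col in body.columns:
        try:
            parsed[col] = pd.to_numeric(body[col], downcast=None)
        except ValueError as exc:
            raise ValidationError(f"non-numeric count in sample column {col!r}: {exc}")
        if not np.allclose(parsed[col], np.round(parsed[col]), atol=0):
            row = ids[parsed[col] != np.round(parsed[col])].iloc[0]
            raise ValidationError(f"non-integer count at ZOTU {row!r}, sample {col!r}")
    out = pd.DataFrame({c: s.to_numpy() for c, s in parsed.items()},
                       index=pd.Index(ids.to_numpy(), name=id_col)).astype(np.int64)
    return CountTable(out)


def write_count_table(table: CountTable, path) -> None:
    df = table.data.copy()
    df.index.name = df.index.name or "#ZOTU_ID"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def read_sample_frame(path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", header=0)
    for col in REQUIRED_METADATA:
        if col not in df.columns:
            raise ValidationError(f"missing required metadata column {col!r}")
    df = df.set_index("sample_id")
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path) -> None:
    df = frame.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def read_taxonomy_table(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    df = df.set_index(df.columns[0])
    return TaxonomyTable(df)


def write_taxonomy_table(taxonomy: TaxonomyTable, path) -> None:
    df = taxonomy.data.copy()
    df.index.name = "zotu_id"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def to_relative(table: CountTable) -> RelAbundanceTable:
    """Divide every sample column by its read total."""
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-total sample(s): {zero.index.tolist()}")
    rel = table.data / totals
    return RelAbundanceTable(rel.astype(float))


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Each sample gets an independent hypergeometric draw seeded by
    (seed, sample position), so reordering samples does not change any
    individual sample's draw.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    shallow = totals[totals < depth]
    if len(shallow):
        raise ValidationError(
            f"depth {depth} exceeds total reads of sample(s): {shallow.index.tolist()}"
        )
    out = np.empty_like(table.counts)
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
            continue
        rng = np.random.default_rng([int(seed), j])
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(pd.DataFrame(out, index=table.zotu_ids, columns=table.sample_ids))


def filter_taxa(table: CountTable, min_total: int = 0,
                min_prevalence: float = 0.0) -> CountTable:
    """Keep ZOTUs with total reads >= min_total AND detected in >= min_prevalence
    of samples. Row order is preserved; may return an empty table."""
    if min_total < 0 or min_prevalence < 0:
        raise ValidationError("filter thresholds must be non-negative")
    totals = table.data.sum(axis=1)
    prevalence = (table.data > 0).mean(axis=1)
    keep = (totals >= min_total) & (prevalence >= min_prevalence)
    kept = table.data.loc[keep]
    if kept.shape[0] == 0:
        import warnings

        warnings.warn("filter_taxa removed every ZOTU", stacklevel=2)
    return CountTable(kept.copy())


def nutrient_change(frame: SampleFrame, sign: str = "final-initial") -> SampleFrame:
    """Add per-nutrient change columns relative to the day-0 baseline of the
    same (group, replicate).

    ``sign='final-initial'`` reports X(t) - X(0); ``'initial-final'`` flips it.
    Day-0 rows get change 0 by construction. Missing nutrient cells propagate
    as missing.
    """
    if sign not in ("final-initial", "initial-final"):
        raise ValidationError(f"unknown sign convention {sign!r}")
    df = frame.data.copy()
    nutrient_cols = [c for c in df.columns if c in NUTRIENT_COLUMNS]
    if not nutrient_cols:
        raise ValidationError("no nutrient columns present")
    day0 = df[df["time"] == 0]
    baseline = day0.groupby(["group", "replicate"])[nutrient_cols].mean()
    keys = pd.MultiIndex.from_frame(df[["group", "replicate"]])
    missing = [k for k in keys.unique() if k not in baseline.index]
    if missing:
        raise ValidationError(f"no day-0 baseline for (group, replicate): {missing}")
    base = baseline.reindex(keys).to_numpy()
    for i, col in enumerate(nutrient_cols):
        delta = df[col].to_numpy(dtype=float) - base[:, i]
        if sign == "initial-final":
            delta = -delta
        df[f"{col}_change"] = delta
    return SampleFrame(df)
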