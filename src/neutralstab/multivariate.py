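"""Distance-based community statistics.

Alpha diversity, Bray-Curtis dissimilarity, principal coordinates analysis,
redundancy analysis and its distance-based variant, PERMANOVA with sequential
(Type I) sums of squares and interaction terms, ANOSIM, MRPP, the Mantel
test, one-way ANOVA with Tukey HSD and a compact letter display, and UPGMA
clustering with Newick output. All permutation p-values use the
(1 + #exceedances) / (1 + n_perm) estimator and are reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountTable, RelAbundanceTable, ValidationError


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with zero diagonal."""

    data: np.ndarray
    sample_ids: list

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("distance matrix must be square")
        if len(self.sample_ids) != d.shape[0]:
            raise ValidationError("sample_ids length must match matrix size")
        if np.abs(np.diag(d)).max(initial=0.0) != 0.0:
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if np.abs(d - d.T).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix must be symmetric")
        self.data = d
        self.sample_ids = list(self.sample_ids)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.data[iu]

    def permuted(self, order: np.ndarray) -> "DistanceMatrix":
        return DistanceMatrix(self.data[np.ix_(order, order)],
                              [self.sample_ids[i] for i in order])


def bray_curtis(table, scale: str = "relative") -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(u,v) = sum|u-v| / sum(u+v) between samples.

    ``scale='relative'`` normalises each sample to proportions first (robust
    to unequal sequencing depth); ``'counts'`` uses the values as given.
    """
    if isinstance(table, (CountTable, RelAbundanceTable)):
        df = table.data
    else:
        df = table
    if df.shape[1] < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    x = df.to_numpy(dtype=float)
    totals = x.sum(axis=0)
    if (totals == 0).any():
        bad = df.columns[totals == 0].tolist()
        raise ValidationError(f"zero-total sample(s): {bad}")
    if scale == "relative":
        x = x / totals
    elif scale != "counts":
        raise ValidationError(f"unknown abundance scale {scale!r}")
    n = x.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[:, i][:, None] - x[:, i + 1:]).sum(axis=0)
        tot = (x[:, i][:, None] + x[:, i + 1:]).sum(axis=0)
        out[i, i + 1:] = diff / tot
    out = out + out.T
    return DistanceMatrix(out, list(df.columns))


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

_ALPHA_METRICS = ("observed", "shannon", "simpson", "chao1", "pielou")


def alpha_diversity(table: CountTable, metrics=_ALPHA_METRICS) -> pd.DataFrame:
    """Per-sample alpha diversity.

    observed = richness; shannon = -sum p ln p (natural log); simpson =
    1 - sum p^2; chao1 = S + F1^2/(2 F2) (bias-uncorrected; the classic
    F1(F1-1)/2 fallback applies when no doubletons exist); pielou =
    shannon / ln(observed).
    """
    unknown = set(metrics) - set(_ALPHA_METRICS)
    if unknown:
        raise ValidationError(f"unknown alpha metric(s): {sorted(unknown)}")
    counts = table.counts
    rows = {}
    for j, sample in enumerate(table.sample_ids):
        c = counts[:, j]
        present = c[c > 0]
        s_obs = present.size
        p = present / present.sum()
        shannon = float(-(p * np.log(p)).sum()) if s_obs else 0.0
        f1 = int((present == 1).sum())
        f2 = int((present == 2).sum())
        if f2 > 0:
            chao1 = s_obs + f1 * f1 / (2.0 * f2)
        else:
            chao1 = s_obs + f1 * (f1 - 1) / 2.0
        row = {
            "observed": float(s_obs),
            "shannon": shannon,
            "simpson": float(1.0 - (p ** 2).sum()) if s_obs else 0.0,
            "chao1": float(chao1),
            "pielou": shannon / np.log(s_obs) if s_obs > 1 else np.nan,
        }
        rows[sample] = {m: row[m] for m in metrics}
    return pd.DataFrame.from_dict(rows, orient="index")[list(metrics)]


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray              # sorted non-increasing
    coordinates: pd.DataFrame            # samples x axes
    proportion_explained: np.ndarray
    constrained_eigenvalues: np.ndarray = field(
        default_factory=lambda: np.array([]))
    unconstrained_eigenvalues: np.ndarray = field(
        default_factory=lambda: np.array([]))
    biplot_scores: pd.DataFrame | None = None
    negative_eigenvalues: np.ndarray = field(
        default_factory=lambda: np.array([]))

    @property
    def constrained_proportion(self) -> float:
        tot = self.constrained_eigenvalues.sum() + \
            self.unconstrained_eigenvalues.sum()
        if tot <= 0:
            return 0.0
        return float(self.constrained_eigenvalues.sum() / tot)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, correction: str | None = None) -> OrdinationResult:
    """Principal coordinates analysis (classical MDS) of a dissimilarity matrix.

    Negative eigenvalues (from non-Euclidean dissimilarities) are reported;
    ``correction='lingoes'`` adds the constant that makes them vanish.
    Proportions are relative to the positive inertia.
    """
    d = dm.data
    if correction == "lingoes":
        g = _gower_center(d)
        eig = np.linalg.eigvalsh(g)
        c = max(0.0, -eig.min())
        if c > 0:
            off = ~np.eye(dm.n, dtype=bool)
            d = np.sqrt(d ** 2 + 2 * c * off)
    elif correction is not None:
        raise ValidationError(f"unknown correction {correction!r}")
    g = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, np.abs(eigvals).max(initial=1.0))
    pos = eigvals > tol
    neg = eigvals < -tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    pos_sum = eigvals[pos].sum()
    return OrdinationResult(
        eigenvalues=eigvals[pos],
        coordinates=pd.DataFrame(coords, index=dm.sample_ids, columns=axes),
        proportion_explained=eigvals[pos] / pos_sum if pos_sum > 0
        else np.zeros(int(pos.sum())),
        negative_eigenvalues=eigvals[neg],
    )


@dataclass
class PermutationTestResult:
    statistic_name: str
    statistic: float
    n_perm: int
    p_value: float
    seed: int
    extras: dict = field(default_factory=dict)


def _perm_p(observed: float, permuted: np.ndarray, greater: bool = True) -> float:
    if greater:
        b = int(np.sum(permuted >= observed))
    else:
        b = int(np.sum(permuted <= observed))
    return (1.0 + b) / (1.0 + permuted.size)


def _check_collinear(x: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # report an aliased set via the QR diagonal
        q, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = diag.max(initial=0) * max(x.shape) * np.finfo(float).eps
        bad = [names[i] for i in range(x.shape[1])
               if i < diag.size and diag[i] <= tol] or list(names)
        raise ValidationError(f"collinear covariates: {bad}")


def rda(abundance: pd.DataFrame, constraints: pd.DataFrame,
        n_perm: int = 999, seed: int = 0):
    """Redundancy analysis: PCA of the fitted values of abundance ~ constraints.

    ``abundance`` is samples x taxa (already transformed as desired);
    ``constraints`` samples x numeric covariates. Eigenvalues are variances
    (divisor n-1). Overall significance by permutation of the response rows.
    Returns (OrdinationResult, PermutationTestResult).
    """
    y = abundance.to_numpy(dtype=float)
    x = constraints.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("constraints contain missing values")
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValidationError("abundance and constraints disagree on samples")
    if n <= x.shape[1]:
        raise ValidationError("need more samples than covariates")
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    _check_collinear(xc, list(constraints.columns))
    q, _ = np.linalg.qr(xc)

    def fit_stats(ycur):
        yhat = q @ (q.T @ ycur)
        ss_fit = float(np.sum(yhat ** 2))
        ss_res = float(np.sum((ycur - yhat) ** 2))
        return yhat, ss_fit, ss_res

    yhat, ss_fit, ss_res = fit_stats(yc)
    rank_x = xc.shape[1]
    df_res = n - rank_x - 1
    f_obs = (ss_fit / rank_x) / (ss_res / df_res) if ss_res > 0 else np.inf

    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    lam_c = s ** 2 / (n - 1)
    keep_c = lam_c > 1e-12 * max(1.0, lam_c.max(initial=1.0))
    lam_c = lam_c[keep_c]
    v_c = vt[keep_c].T
    resid = yc - yhat
    _, s_r, _ = np.linalg.svd(resid, full_matrices=False)
    lam_u = s_r ** 2 / (n - 1)
    lam_u = lam_u[lam_u > 1e-12 * max(1.0, lam_u.max(initial=1.0))]

    coords = yc @ v_c  # site scores (weighted-average style) on constrained axes
    axes = [f"RDA{i + 1}" for i in range(coords.shape[1])]
    coords_df = pd.DataFrame(coords, index=abundance.index, columns=axes)
    lc = yhat @ v_c  # linear-constraint scores, used for biplot correlations
    with np.errstate(invalid="ignore", divide="ignore"):
        biplot = pd.DataFrame(
            [[_safe_corr(xc[:, i], lc[:, j]) for j in range(lc.shape[1])]
             for i in range(xc.shape[1])],
            index=constraints.columns, columns=axes,
        )
    total = lam_c.sum() + lam_u.sum()
    ord_res = OrdinationResult(
        eigenvalues=np.concatenate([lam_c, lam_u]),
        coordinates=coords_df,
        proportion_explained=np.concatenate([lam_c, lam_u]) / total
        if total > 0 else np.concatenate([lam_c, lam_u]),
        constrained_eigenvalues=lam_c,
        unconstrained_eigenvalues=lam_u,
        biplot_scores=biplot,
    )
    rng = np.random.default_rng([int(seed), 11])
    perms = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(n)
        _, ss_f, ss_r = fit_stats(yc[order])
        perms[b] = (ss_f / rank_x) / (ss_r / df_res) if ss_r > 0 else np.inf
    test = PermutationTestResult(
        statistic_name="pseudo-F", statistic=float(f_obs), n_perm=n_perm,
        p_value=_perm_p(f_obs, perms), seed=seed,
        extras={"ss_constrained": ss_fit, "ss_residual": ss_res},
    )
    return ord_res, test


def _safe_corr(a, b):
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def dbrda(dm: DistanceMatrix, constraints: pd.DataFrame, n_perm: int = 999,
          seed: int = 0, inertia_threshold: float = 0.999):
    """Distance-based RDA: PCoA axes (covering >= 99.9% of positive inertia)
    regressed on the constraints. With Euclidean input this reproduces plain
    RDA on the raw data."""
    ord0 = pcoa(dm)
    cum = np.cumsum(ord0.proportion_explained)
    n_axes = int(np.searchsorted(cum, inertia_threshold) + 1)
    n_axes = min(n_axes, ord0.coordinates.shape[1])
    coords = ord0.coordinates.iloc[:, :n_axes]
    return rda(coords, constraints.loc[coords.index], n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaTable:
    table: pd.DataFrame  # index term (+ Residual, Total)
    n_perm: int
    seed: int


def _term_design(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy-coded (drop-first) design columns for a main effect or
    ':'-separated interaction; every variable is treated as categorical."""
    parts = term.split(":")
    blocks = []
    for v in parts:
        if v not in meta.columns:
            raise ValidationError(f"unknown design variable {v!r}")
        d = pd.get_dummies(meta[v].astype(str), drop_first=True, dtype=float)
        blocks.append(d.to_numpy())
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(out.shape[0], -1)
    return out


def permanova(dm: DistanceMatrix, meta: pd.DataFrame, terms: list[str],
              n_perm: int = 999, seed: int = 0,
              permutations=None) -> PermanovaTable:
    """Distance-based multivariate ANOVA with sequential (Type I) SS.

    ``terms`` are applied in the given order; interactions use 'a:b' syntax
    and every variable is treated as a categorical factor. p-values come
    from free permutation of sample labels (rows/columns of the distance
    matrix). ``permutations`` may supply explicit permutation index arrays
    instead of random draws.
    """
    if isinstance(meta, pd.DataFrame):
        meta = meta.loc[dm.sample_ids]
    n = dm.n
    g = _gower_center(dm.data)
    designs = []
    x_cum = np.ones((n, 1))
    rank_prev = 1
    dfs = []
    for term in terms:
        cols = _term_design(meta, term)
        x_cum = np.hstack([x_cum, cols])
        rank = np.linalg.matrix_rank(x_cum)
        df_term = rank - rank_prev
        if df_term == 0:
            raise ValidationError(f"term {term!r} is aliased with earlier terms")
        u, s, _ = np.linalg.svd(x_cum, full_matrices=False)
        designs.append(u[:, s > s.max() * max(x_cum.shape) * np.finfo(float).eps])
        dfs.append(df_term)
        rank_prev = rank
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValidationError("saturated design: no residual degrees of freedom")

    def decompose(gm):
        ss_total = float(np.trace(gm))
        tr_prev = 0.0  # tr(H_0 G) vanishes: G is double-centered
        ss_terms = []
        for q in designs:
            h_tr = float(np.einsum("ij,ij->", q, gm @ q))
            ss_terms.append(h_tr - tr_prev)
            tr_prev = h_tr
        ss_res = ss_total - tr_prev
        return np.array(ss_terms), ss_res, ss_total

    ss_terms, ss_res, ss_total = decompose(g)
    f_obs = (ss_terms / np.array(dfs)) / (ss_res / df_res)

    if permutations is None:
        rng = np.random.default_rng([int(seed), 12])
        permutations = [rng.permutation(n) for _ in range(n_perm)]
    else:
        permutations = [np.asarray(p) for p in permutations]
        n_perm = len(permutations)
    exceed = np.zeros(len(terms))
    tie_tol = 1e-12 * (1.0 + np.abs(f_obs))  # count exact ties despite float noise
    for order in permutations:
        gp = g[np.ix_(order, order)]
        ss_t, ss_r, _ = decompose(gp)
        f_p = (ss_t / np.array(dfs)) / (ss_r / df_res)
        exceed += f_p >= f_obs - tie_tol
    p_vals = (1.0 + exceed) / (1.0 + len(permutations))

    rows = []
    for i, term in enumerate(terms):
        rows.append({"term": term, "df": dfs[i], "SS": ss_terms[i],
                     "R2": ss_terms[i] / ss_total, "F": f_obs[i],
                     "p": p_vals[i]})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return PermanovaTable(pd.DataFrame(rows).set_index("term"),
                          n_perm=len(permutations), seed=seed)


# ---------------------------------------------------------------------------
# ANOSIM / MRPP / Mantel
# ---------------------------------------------------------------------------

def _grouping_array(grouping, sample_ids) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        return grouping.loc[list(sample_ids)].to_numpy()
    return np.asarray(grouping)


def anosim(dm: DistanceMatrix, grouping, n_perm: int = 999,
           seed: int = 0) -> PermutationTestResult:
    """Analysis of similarities: R = (mean between rank - mean within rank) / (M/2)."""
    labels = _grouping_array(grouping, dm.sample_ids)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs at least 2 samples")
    n = dm.n
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dm.data[iu])
    m = ranks.size

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = r_stat(labels)
    rng = np.random.default_rng([int(seed), 13])
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = r_stat(labels[rng.permutation(n)])
    return PermutationTestResult("ANOSIM R", float(observed), n_perm,
                                 _perm_p(observed, perms), seed)


def mrpp(dm: DistanceMatrix, grouping, n_perm: int = 999,
         seed: int = 0) -> PermutationTestResult:
    """Multi-response permutation procedure.

    delta = sum_g (n_g/n) * mean within-group distance; the chance-corrected
    agreement A = 1 - delta / mean(permuted deltas).
    """
    labels = _grouping_array(grouping, dm.sample_ids)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValidationError("MRPP needs at least 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs at least 2 samples")
    n = dm.n
    d = dm.data

    def delta(lab):
        val = 0.0
        for gname, ng in zip(uniq, counts):
            idx = np.flatnonzero(lab == gname)
            sub = d[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            val += (ng / n) * sub[iu].mean()
        return val

    observed = delta(labels)
    rng = np.random.default_rng([int(seed), 14])
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = delta(labels[rng.permutation(n)])
    a_stat = 1.0 - observed / perms.mean()
    return PermutationTestResult(
        "MRPP delta", float(observed), n_perm,
        _perm_p(observed, perms, greater=False), seed,
        extras={"A": float(a_stat)},
    )


def mantel(dm1: DistanceMatrix, dm2: DistanceMatrix,
           method: str = "spearman", n_perm: int = 999,
           seed: int = 0) -> PermutationTestResult:
    """Mantel correlation between two distance matrices over the same samples.

    Spearman by default (average ranks on ties); p from jointly permuting
    the rows/columns of the second matrix, one-sided for positive
    association.
    """
    if list(dm1.sample_ids) != list(dm2.sample_ids):
        raise ValidationError("distance matrices must share sample ids in order")
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method {method!r}")
    n = dm1.n
    iu = np.triu_indices(n, k=1)
    v1 = dm1.data[iu]

    def corr(mat):
        v2 = mat[iu]
        if method == "spearman":
            a, b = stats.rankdata(v1), stats.rankdata(v2)
        else:
            a, b = v1, v2
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    observed = corr(dm2.data)
    rng = np.random.default_rng([int(seed), 15])
    perms = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(n)
        perms[b] = corr(dm2.data[np.ix_(order, order)])
    return PermutationTestResult(f"Mantel r ({method})", observed, n_perm,
                                 _perm_p(observed, perms), seed)


# ---------------------------------------------------------------------------
# ANOVA + Tukey + compact letter display
# ---------------------------------------------------------------------------

@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame        # pairwise: group1, group2, p_adj
    letters: dict              # group -> letter string
    group_means: pd.Series


def compact_letter_display(groups: list, significant: set) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant`` holds frozensets {g1, g2} of significantly different
    pairs; groups sharing a letter are never significantly different.
    """
    letter_sets: list[set] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, other)) not in significant for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb duplicate subsets
    keep = []
    for s in letter_sets:
        if not any(s < t for t in letter_sets if s is not t):
            if s not in keep:
                keep.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, s in enumerate(keep):
        for g in groups:
            if g in s:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def anova_tukey(values: np.ndarray, groups: np.ndarray,
                alpha: float = 0.05) -> AnovaTukeyResult:
    """Classical one-way ANOVA followed by Tukey HSD on all pairs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(dict.fromkeys(groups))  # order of first appearance
    if len(uniq) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) < 2 for s in samples):
        raise ValidationError("every group needs at least 2 values")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValidationError("zero within-group variance in every group")
    f_stat, p_val = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    rows = []
    significant = set()
    for i, j in combinations(range(len(uniq)), 2):
        p_adj = float(hsd.pvalue[i, j])
        rows.append({"group1": uniq[i], "group2": uniq[j], "p_adj": p_adj})
        if p_adj < alpha:
            significant.add(frozenset((uniq[i], uniq[j])))
    letters = compact_letter_display(uniq, significant)
    means = pd.Series({g: float(np.mean(values[groups == g])) for g in uniq})
    return AnovaTukeyResult(float(f_stat), float(p_val),
                            pd.DataFrame(rows), letters, means)


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------

def hclust_average(dm: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) agglomeration; returns a Newick string.

    Ties in the minimum inter-cluster distance are broken by the
    lexicographically smallest pair of cluster representatives (each
    cluster represented by its smallest member id), so the result does not
    depend on input order. Branch lengths place each merge at height d/2
    (ultrametric).
    """
    n = dm.n
    ids = list(dm.sample_ids)
    active = {i: ([ids[i]], ids[i], 0.0, ids[i]) for i in range(n)}
    # members, newick, height, representative(min id)
    dist = {frozenset((i, j)): dm.data[i, j]
            for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    next_id = n
    while len(active) > 1:
        best = None
        for pair, d in dist.items():
            i, j = sorted(pair)
            key = tuple(sorted((active[i][3], active[j][3])))
            cand = (d, key, i, j)
            if best is None or cand < best:
                best = cand
        d, _, i, j = best
        h = d / 2.0
        mi, ni, hi, ri = active[i]
        mj, nj, hj, rj = active[j]
        first, second = ((ni, hi, ri), (nj, hj, rj))
        if rj < ri:
            first, second = second, first
        newick = (f"({first[0]}:{h - first[1]:.10g},"
                  f"{second[0]}:{h - second[1]:.10g})")
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((new, k))] = (
                sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        dist.pop(frozenset((i, j)))
        sizes[new] = sizes[i] + sizes[j]
        active[new] = (mi + mj, newick, h, min(ri, rj))
        del active[i], active[j], sizes[i], sizes[j]
    (_, newick, _, _), = active.values()
    return newick + ";"
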