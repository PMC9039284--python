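"""Growth-rate-dependent transcriptome statistics.

Counts -> RPKM -> expression filtering -> differential-expression calling
between dilution rates within one gas mix -> Ward clustering of expression
profiles -> Fisher-exact functional enrichment -> selection of
"tight-control" genes whose expression slope versus the growth rate is the
same on both gases.

The statistical engine is deliberately simple and fully specified:
library-size CPM normalisation, Welch t-tests on log2(CPM + 0.5) and
Benjamini-Hochberg FDR control. A differentially expressed gene (DEG) is
one with fold-change > 1.5 and q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ExpressionMatrix",
    "rpkm",
    "cpm",
    "filter_expressed",
    "bh_fdr",
    "deg_call",
    "overlap_counts",
    "cluster_profiles",
    "enrichment",
    "tight_control_selection",
    "within_gas_comparisons",
]

LOG_OFFSET_CPM = 0.5   # pseudo-count on the CPM scale before log2


class TranscriptomicsError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene x sample counts with lengths and sample metadata.

    ``sample_meta`` must carry columns gas, mu and replicate indexed by (or
    containing) sample_id covering every count column.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise TranscriptomicsError("counts must be non-negative")
        if (self.gene_lengths <= 0).any():
            raise TranscriptomicsError("gene lengths must be positive")
        meta = self.sample_meta
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id")
            self.sample_meta = meta
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise TranscriptomicsError(
                f"sample metadata missing for {sorted(missing)[:3]}...")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def rpkm(self) -> pd.DataFrame:
        return rpkm(self.counts, self.gene_lengths, self.library_sizes)

    def log2cpm(self) -> pd.DataFrame:
        return np.log2(cpm(self.counts, self.library_sizes) + LOG_OFFSET_CPM)

    def samples_for(self, gas: str, mu: float, atol: float = 1e-6) -> list[str]:
        meta = self.sample_meta
        mask = (meta["gas"] == gas) & (np.abs(meta["mu"] - mu) <= atol)
        cols = [s for s in self.counts.columns if mask.get(s, False)]
        if not cols:
            raise TranscriptomicsError(f"no samples for gas={gas}, mu={mu}")
        return cols


# --------------------------------------------------------------------------
# normalisation and filtering
# --------------------------------------------------------------------------

def cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None
        ) -> pd.DataFrame:
    lib = counts.sum(axis=0) if library_sizes is None else library_sizes
    if (lib <= 0).any():
        raise TranscriptomicsError("zero library size")
    return counts * 1e6 / lib


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    lib = counts.sum(axis=0) if library_sizes is None else library_sizes
    if (np.asarray(lib) <= 0).any():
        raise TranscriptomicsError("zero library size")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise TranscriptomicsError("missing or non-positive gene length")
    return counts.mul(1e9, axis=0).div(lib, axis=1).div(lengths, axis=0)


def filter_expressed(rpkm_matrix: pd.DataFrame, threshold: float = 10.0,
                     min_samples: int = 2) -> pd.Index:
    """Genes with RPKM strictly above ``threshold`` in >= ``min_samples`` samples."""
    keep = (rpkm_matrix > threshold).sum(axis=1) >= min_samples
    return rpkm_matrix.index[keep]


# --------------------------------------------------------------------------
# differential expression
# --------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise TranscriptomicsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def within_gas_comparisons(mus) -> list[tuple[float, float]]:
    """All pairwise (higher, lower) mu comparisons within one gas."""
    levels = sorted(set(mus))
    return [(b, a) for a, b in combinations(levels, 2)]


def deg_call(matrix: ExpressionMatrix, comparison: tuple[str, float, float],
             fc_threshold: float = 1.5, q_threshold: float = 0.05,
             expressed: pd.Index | None = None) -> pd.DataFrame:
    """Call DEGs for one within-gas growth-rate comparison.

    ``comparison`` is (gas, mu_a, mu_b); the log2 fold change is mu_a
    relative to mu_b (conventionally higher vs lower growth rate). Only
    within-gas comparisons are allowed — comparing gas mixes at the same mu
    is outside the study design and raises an error. The per-gene test is
    Welch's t on log2(CPM + 0.5); q-values are Benjamini-Hochberg across
    the tested (expression-filtered) genes.
    """
    if len(comparison) == 4:
        raise TranscriptomicsError(
            "cross-gas comparisons are not part of the design: compare mu "
            "levels within one gas mixture")
    gas, mu_a, mu_b = comparison
    cols_a = matrix.samples_for(gas, mu_a)
    cols_b = matrix.samples_for(gas, mu_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise TranscriptomicsError("need >= 2 replicates on each side")
    log2 = matrix.log2cpm()
    if expressed is None:
        expressed = filter_expressed(matrix.rpkm())
    log2 = log2.loc[expressed]
    a = log2[cols_a].to_numpy()
    b = log2[cols_b].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_fdr(p)
    table = pd.DataFrame({"log2_fc": log2fc, "p_value": p, "q_value": q},
                         index=log2.index)
    table["is_deg"] = ((np.abs(table["log2_fc"]) > np.log2(fc_threshold))
                       & (table["q_value"] < q_threshold))
    table.attrs["comparison"] = f"{gas}:{mu_a:g}_vs_{mu_b:g}"
    return table


def overlap_counts(deg_sets: dict[str, set]) -> dict[str, int]:
    """Exact Venn-region cardinalities for 2-3 named DEG sets."""
    names = list(deg_sets)
    if not 2 <= len(names) <= 3:
        raise TranscriptomicsError("overlap counts support 2 or 3 sets")
    sets = {n: set(s) for n, s in deg_sets.items()}
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    for mask in range(1, 2 ** len(names)):
        inside = [names[i] for i in range(len(names)) if mask >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set(universe)
        for n in inside:
            region &= sets[n]
        for n in outside:
            region -= sets[n]
        regions["&".join(inside)] = len(region)
    return regions


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def cluster_profiles(profiles: pd.DataFrame, max_clusters: int = 12
                     ) -> tuple[pd.Series, int, np.ndarray]:
    """Ward (D2) hierarchical clustering of row-z-scored expression profiles.

    Rows with zero variance are excluded (with a warning) before z-scoring.
    The cluster count is chosen at the largest relative drop between
    consecutive dendrogram merge heights (ties break toward fewer
    clusters); identical profiles collapse to a single cluster. Returns
    (assignments indexed like the kept rows, chosen k, linkage matrix).
    """
    if len(profiles) < 2:
        raise TranscriptomicsError("need at least two profiles to cluster")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        import warnings
        warnings.warn(f"excluding {int((~keep).sum())} constant profiles "
                      "before z-scoring", stacklevel=2)
    X = X[keep]
    index = profiles.index[keep]
    if len(X) < 2:
        raise TranscriptomicsError("fewer than two variable profiles")
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0,
                                                    keepdims=True)
    L = linkage(Z, method="ward")
    heights = L[:, 2]
    if heights[-1] <= 1e-12:       # all profiles identical after z-scoring
        return pd.Series(1, index=index, name="cluster"), 1, L
    # descending heights: D[j] is the merge taking j+2 clusters to j+1
    D = heights[::-1]
    kmax = min(max_clusters, len(X))
    best_k, best_drop = 2, -np.inf
    for k in range(2, kmax + 1):
        prev, nxt = D[k - 2], D[k - 1] if k - 1 < len(D) else 0.0
        if prev <= 1e-12:
            continue
        drop = (prev - nxt) / prev
        if drop > best_drop + 1e-12:   # strict: ties keep the smaller k
            best_drop, best_k = drop, k
    labels = fcluster(L, t=best_k, criterion="maxclust")
    return pd.Series(labels, index=index, name="cluster"), best_k, L


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------

def enrichment(gene_set, annotation: pd.DataFrame, universe,
               q_threshold: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher exact over-representation per annotation term.

    ``annotation`` has columns gene_id and term_id (a COG table works the
    same way with letters as terms). For each term annotating at least one
    universe gene the 2x2 table (in-set/term membership) is tested for
    enrichment; q-values are Benjamini-Hochberg across tested terms.
    """
    universe = set(universe)
    if not universe:
        raise TranscriptomicsError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise TranscriptomicsError("gene set must be a subset of the universe")
    ann = annotation[annotation["gene_id"].isin(universe)]
    term_col = ("term_id" if "term_id" in ann.columns
                else [c for c in ann.columns if c != "gene_id"][0])
    rows = []
    n_set = len(gene_set)
    n_uni = len(universe)
    for term, grp in ann.groupby(term_col):
        members = set(grp["gene_id"])
        a = len(gene_set & members)
        b = n_set - a
        c = len(members) - a
        d = n_uni - n_set - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"term_id": term, "in_set": a, "term_size": len(members),
                     "odds_ratio": odds, "p_value": p})
    if not rows:
        return pd.DataFrame(columns=["term_id", "in_set", "term_size",
                                     "odds_ratio", "p_value", "q_value",
                                     "significant"])
    out = pd.DataFrame(rows)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < q_threshold
    return out.sort_values("p_value", ignore_index=True)


# --------------------------------------------------------------------------
# tight-control (slope-equality) gene selection
# --------------------------------------------------------------------------

def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Slope, its standard error and residual dof of an OLS line."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    resid = y - (ym + slope * (x - xm))
    dof = n - 2
    s2 = float((resid ** 2).sum()) / dof if dof > 0 else np.nan
    se = np.sqrt(s2 / sxx)
    return slope, se, dof


def tight_control_selection(matrix: ExpressionMatrix,
                            deg_tables: dict[tuple[str, float, float],
                                             pd.DataFrame],
                            alpha: float = 0.05,
                            require_equal_slopes: bool = True
                            ) -> pd.DataFrame:
    """Genes whose expression tracks the growth rate identically on both gases.

    Step 1 keeps genes that are DEGs with a consistent direction in both
    consecutive growth-rate comparisons on both gases (monotone up or down
    with increasing mu everywhere). Step 2 fits, per gas, an OLS slope of
    log2(CPM + 0.5) against mu. Step 3 compares the two slopes with a
    two-sample t statistic (difference over pooled standard error).

    With ``require_equal_slopes`` (the default) a gene is retained when the
    equality of slopes is *not* rejected (p >= alpha), i.e. the expression
    trend has the same magnitude on both gases; the literal opposite
    reading (retain p < alpha) is available by setting it to False.
    """
    gases = sorted(matrix.sample_meta["gas"].unique())
    if len(gases) != 2:
        raise TranscriptomicsError("tight-control selection needs two gases")
    for gas in gases:
        mus = sorted(matrix.sample_meta.loc[
            matrix.sample_meta["gas"] == gas, "mu"].unique())
        if len(mus) < 3:
            raise TranscriptomicsError(
                f"gas {gas} has fewer than three mu levels")

    # consecutive comparisons per gas, keyed as in deg_tables
    def consecutive(gas):
        mus = sorted(matrix.sample_meta.loc[
            matrix.sample_meta["gas"] == gas, "mu"].unique())
        return [(gas, mus[i + 1], mus[i]) for i in range(len(mus) - 1)]

    needed = [cmp for gas in gases for cmp in consecutive(gas)]
    missing = [c for c in needed if c not in deg_tables]
    if missing:
        raise TranscriptomicsError(f"missing DEG tables for {missing}")

    candidates: pd.Index | None = None
    signs: pd.Series | None = None
    for cmp_key in needed:
        tab = deg_tables[cmp_key]
        degs = tab.index[tab["is_deg"]]
        sgn = np.sign(tab.loc[degs, "log2_fc"])
        if candidates is None:
            candidates, signs = degs, sgn
        else:
            common = candidates.intersection(degs)
            same = common[(signs.loc[common] == sgn.loc[common])]
            candidates, signs = same, signs.loc[same]
    candidates = candidates if candidates is not None else pd.Index([])

    log2 = matrix.log2cpm()
    meta = matrix.sample_meta
    rows = []
    for gene in candidates:
        per_gas = []
        for gas in gases:
            cols = [s for s in log2.columns if meta.loc[s, "gas"] == gas]
            x = meta.loc[cols, "mu"].to_numpy(float)
            y = log2.loc[gene, cols].to_numpy(float)
            per_gas.append(_ols_slope(x, y))
        (b1, se1, df1), (b2, se2, df2) = per_gas
        t = (b1 - b2) / np.hypot(se1, se2)
        p = 2.0 * stats.t.sf(abs(t), df=df1 + df2)
        rows.append({"gene_id": gene, f"slope_{gases[0]}": b1,
                     f"slope_{gases[1]}": b2, "t_stat": t, "p_value": p,
                     "direction": "up" if signs.loc[gene] > 0 else "down"})
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(columns=["gene_id", f"slope_{gases[0]}",
                                    f"slope_{gases[1]}", "t_stat", "p_value",
                                    "direction", "retained"])
        return out.set_index("gene_id")
    out = out.set_index("gene_id")
    if require_equal_slopes:
        out["retained"] = out["p_value"] >= alpha
    else:
        out["retained"] = out["p_value"] < alpha
    return out
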