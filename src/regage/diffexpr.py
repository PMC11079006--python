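"""Two-condition differential expression with batch covariates.

Counts are normalized by median-of-ratios size factors, log2-transformed with
a pseudocount, and fit gene-wise by ordinary least squares on a
condition + batch design. Residual variances are shrunk toward a common prior
by empirical-Bayes moderation (a scaled-F prior fit by moment matching on
log s^2), giving a moderated t statistic on augmented degrees of freedom.
Significance follows the aged-vs-young convention: direction "up" means
higher in the aged condition.

The single-cell stages apply the strict quality filters (mitochondrial
fraction > max, detected genes < min) and a rank-sum DE test with an
expression floor, standing in for a hurdle-model test while keeping the
published thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import ExpressionMatrix

log = logging.getLogger("regage.diffexpr")

PSEUDOCOUNT = 0.5  # on size-factor-normalized counts, before log2
SC_EPS = 1e-9  # fold-change stabilizer for single-cell group means


@dataclass
class DEResult:
    """Per-gene differential-expression table (aged vs young).

    ``direction`` is "up" iff q < alpha and log2fc > lfc_min, "down" iff
    q < alpha and log2fc < -lfc_min, else "ns".
    """

    table: pd.DataFrame  # index gene_id; log2fc, se, statistic, df_total, p, q, direction
    alpha: float
    lfc_min: float

    def genes(self, direction: str) -> set[str]:
        return set(self.table.index[self.table["direction"] == direction])

    @property
    def up(self) -> set[str]:
        return self.genes("up")

    @property
    def down(self) -> set[str]:
        return self.genes("down")

    def significant(self) -> set[str]:
        return self.up | self.down

    def direction_of(self, gene: str) -> str:
        if gene not in self.table.index:
            return "ns"
        return str(self.table.loc[gene, "direction"])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read(cls, path, alpha: float = 0.01, lfc_min: float = 1.0) -> "DEResult":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"), alpha, lfc_min)


@dataclass
class ModerationFit:
    """Empirical-Bayes variance moderation: prior df d0, prior variance s0_sq,
    and per-gene posterior variances (d0*s0_sq + df*s_sq)/(d0 + df)."""

    d0: float  # may be inf
    s0_sq: float
    posterior_s_sq: np.ndarray


@dataclass
class IntersectionResult:
    shared_genes: set[str]
    concordant_genes: set[str]
    discordant_genes: set[str]
    concordance_fraction: float
    directions_a: dict[str, str] = field(default_factory=dict)
    directions_b: dict[str, str] = field(default_factory=dict)
    empty_flag: bool = False


# ---------------------------------------------------------------------------
# Normalization and model fitting
# ---------------------------------------------------------------------------


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean pseudo-sample.

    Genes with a zero count in any sample are excluded from the reference.
    """
    if counts.unit != "count":
        raise ValueError("size factors are defined on raw counts")
    arr = counts.values.to_numpy(dtype=float)
    if arr.shape[1] == 1:
        return pd.Series([1.0], index=counts.sample_ids)
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "use a pseudo-reference fallback (not enabled by default)"
        )
    logref = np.log(arr[eligible]).mean(axis=1)  # geometric mean per gene
    ratios = np.log(arr[eligible]) - logref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.sample_ids)


def _design_matrix(meta: pd.DataFrame, conditions: tuple[str, str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + aged indicator + batch dummies (first batch as reference)."""
    young, aged = conditions
    cond = meta["condition"]
    unknown = set(cond) - {young, aged}
    if unknown:
        raise ValueError(f"unexpected condition label(s): {sorted(unknown)}")
    cols = [np.ones(len(meta)), (cond == aged).to_numpy(float)]
    names = ["intercept", f"{aged}_vs_{young}"]
    if "batch" in meta.columns and meta["batch"].nunique() > 1:
        batches = sorted(meta["batch"].unique())
        for b in batches[1:]:
            cols.append((meta["batch"] == b).to_numpy(float))
            names.append(f"batch_{b}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (batch confounded with condition?): columns {names}"
        )
    return X, names


def fit_gene_models(
    mat: ExpressionMatrix,
    conditions: tuple[str, str] = ("young", "aged"),
    normalize: bool = True,
) -> pd.DataFrame:
    """Gene-wise OLS of (log) expression on condition + batch.

    Counts are transformed to log2(count/size_factor + pseudocount); tpm to
    log2(tpm + pseudocount); log-intensities are used as-is. Returns per-gene
    coef (aged-vs-young contrast), se_unit (contrast standard error at unit
    residual sd), s_sq (residual variance) and df.
    """
    meta = mat.sample_meta.loc[mat.sample_ids]
    X, names = _design_matrix(meta, conditions)
    n, p = X.shape
    if n <= p:
        raise ValueError("zero residual df: as many coefficients as samples")

    if mat.unit == "count" and normalize:
        sf = size_factors(mat)
        y = np.log2(mat.values.to_numpy(float) / sf.to_numpy()[None, :] + PSEUDOCOUNT)
    elif mat.unit == "count":
        y = np.log2(mat.values.to_numpy(float) + PSEUDOCOUNT)
    elif mat.unit == "tpm":
        y = np.log2(mat.values.to_numpy(float) + PSEUDOCOUNT)
    else:  # log_intensity: already on a log scale
        y = mat.values.to_numpy(float)

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = y @ X @ xtx_inv.T  # genes x p
    resid = y - beta @ X.T
    df = n - p
    s_sq = (resid**2).sum(axis=1) / df
    c = names.index(f"{conditions[1]}_vs_{conditions[0]}")
    se_unit = float(np.sqrt(xtx_inv[c, c]))
    return pd.DataFrame(
        {
            "coef": beta[:, c],
            "se_unit": se_unit,
            "s_sq": s_sq,
            "df": float(df),
        },
        index=mat.gene_ids,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration; x > 0."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < tol:
            return float(y)
    raise RuntimeError("trigamma inversion did not converge")


def moderate_variances(s_sq: np.ndarray, df: np.ndarray) -> ModerationFit:
    """Fit a scaled-F prior to gene variances by moment matching on log s^2.

    Matches the first two moments of e_g = log(s_g^2) - digamma(df/2) +
    log(df/2) to the prior, inverting the trigamma function for the prior
    degrees of freedom d0. Zero (or negative) excess spread estimates
    d0 = infinity: all posterior variances collapse to the common mean.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    if (s_sq <= 0).any():
        s_sq = np.maximum(s_sq, 1e-12)
    if len(s_sq) < 2:
        raise ValueError("need >= 2 genes to moderate variances")

    e = np.log(s_sq) - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    n = len(e)
    e_var = ((e - e_mean) ** 2).sum() / (n - 1)
    excess = e_var - special.polygamma(1, df / 2).mean()

    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.mean(s_sq))
        posterior = np.full_like(s_sq, s0_sq)
        return ModerationFit(d0, s0_sq, posterior)

    try:
        d0 = 2.0 * _trigamma_inverse(float(excess))
    except RuntimeError:
        log.warning("trigamma inversion non-convergent; falling back to d0=inf")
        d0 = np.inf
        s0_sq = float(np.mean(s_sq))
        return ModerationFit(d0, s0_sq, np.full_like(s_sq, s0_sq))

    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    posterior = (d0 * s0_sq + df * s_sq) / (d0 + df)
    return ModerationFit(float(d0), s0_sq, posterior)


def posterior_variance(fit: ModerationFit, s_sq: np.ndarray, df: np.ndarray) -> np.ndarray:
    """(d0*s0^2 + df*s^2)/(d0 + df); the s^2 limit when d0 = 0, the common
    prior when d0 = infinity."""
    if fit.d0 == 0:
        return np.asarray(s_sq, float)
    if np.isinf(fit.d0):
        return np.full(len(np.atleast_1d(s_sq)), fit.s0_sq)
    return (fit.d0 * fit.s0_sq + df * s_sq) / (fit.d0 + df)


# ---------------------------------------------------------------------------
# Multiple testing and the DE decision
# ---------------------------------------------------------------------------


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _directions(log2fc: np.ndarray, q: np.ndarray, alpha: float, lfc_min: float) -> np.ndarray:
    direction = np.full(len(log2fc), "ns", dtype=object)
    direction[(q < alpha) & (log2fc > lfc_min)] = "up"
    direction[(q < alpha) & (log2fc < -lfc_min)] = "down"
    return direction


def test_de(
    models: pd.DataFrame,
    moderation: ModerationFit | None = None,
    alpha: float = 0.01,
    lfc_min: float = 1.0,
    abundance: pd.DataFrame | None = None,
) -> DEResult:
    """Moderated (or ordinary) t-test per gene, BH-adjusted, with direction calls.

    ``models`` comes from :func:`fit_gene_models`. With ``moderation`` None an
    ordinary t-test on the residual df is used (the d0 = 0 limit).
    """
    s_sq = models["s_sq"].to_numpy()
    df = models["df"].to_numpy()
    if moderation is None:
        moderation = ModerationFit(0.0, 0.0, s_sq.copy())
    post = posterior_variance(moderation, s_sq, df)
    se = np.sqrt(post) * models["se_unit"].to_numpy()
    t = models["coef"].to_numpy() / se
    if np.isinf(moderation.d0):
        p = 2 * stats.norm.sf(np.abs(t))
        df_total = np.full(len(t), np.inf)
    else:
        df_total = df + moderation.d0
        p = 2 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    log2fc = models["coef"].to_numpy()
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "statistic": t,
            "df_total": df_total,
            "p": p,
            "q": q,
            "direction": _directions(log2fc, q, alpha, lfc_min),
        },
        index=models.index,
    )
    if abundance is not None:
        for cond in abundance.columns:
            table[f"median_{cond}"] = abundance[cond]
    n_sig = int((table["direction"] != "ns").sum())
    log.info("test_de: %d/%d genes significant (alpha=%g, lfc_min=%g)",
             n_sig, len(table), alpha, lfc_min)
    return DEResult(table, alpha, lfc_min)


def run_de(
    mat: ExpressionMatrix,
    conditions: tuple[str, str] = ("young", "aged"),
    alpha: float = 0.01,
    lfc_min: float = 1.0,
    moderation: bool = True,
) -> DEResult:
    """Convenience wrapper: fit, moderate, test."""
    models = fit_gene_models(mat, conditions)
    fit = moderate_variances(models["s_sq"].to_numpy(), models["df"].to_numpy()) if moderation else None
    return test_de(models, fit, alpha=alpha, lfc_min=lfc_min)


def condition_medians(mat: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene median abundance within each condition (columns = conditions)."""
    cond = mat.conditions()
    out = {}
    for c in sorted(cond.unique()):
        cols = [s for s, cc in cond.items() if cc == c]
        out[c] = mat.values[cols].median(axis=1)
    return pd.DataFrame(out, index=mat.gene_ids)


def abundance_filter(
    de: DEResult, mat: ExpressionMatrix, min_median: float = 1.0
) -> DEResult:
    """Keep genes whose median abundance reaches ``min_median`` in >= 1 group.

    The boundary is inclusive: a gene at exactly the floor in one condition is
    retained.
    """
    med = condition_medians(mat)
    med = med.loc[[g for g in de.table.index if g in med.index]]
    keep = (med >= min_median).any(axis=1)
    kept = de.table.loc[keep.index[keep]]
    log.info("abundance_filter: %d -> %d genes (min_median=%g)",
             len(de.table), len(kept), min_median)
    return DEResult(kept, de.alpha, de.lfc_min)


def intersect_concordant(de_a: DEResult, de_b: DEResult) -> IntersectionResult:
    """Intersect two comparisons on significant genes; score sign concordance."""
    sig_a = {g: de_a.direction_of(g) for g in de_a.significant()}
    sig_b = {g: de_b.direction_of(g) for g in de_b.significant()}
    shared = set(sig_a) & set(sig_b)
    concordant = {g for g in shared if sig_a[g] == sig_b[g]}
    discordant = shared - concordant
    if not shared:
        log.warning("intersect_concordant: no shared significant genes")
        return IntersectionResult(set(), set(), set(), 1.0, sig_a, sig_b, empty_flag=True)
    frac = len(concordant) / len(shared)
    return IntersectionResult(shared, concordant, discordant, frac, sig_a, sig_b)


# ---------------------------------------------------------------------------
# Single-cell stages
# ---------------------------------------------------------------------------


def sc_filter_cells(
    cells: ExpressionMatrix,
    max_mito_pct: float = 15.0,
    min_genes: int = 500,
    mito_prefix: str = "MT-",
) -> ExpressionMatrix:
    """Drop low-quality cells: mito fraction strictly above ``max_mito_pct``
    percent OR detected genes strictly below ``min_genes``.

    A cell at exactly the mito ceiling and exactly the gene floor is kept.
    """
    arr = cells.values.to_numpy(float)
    mito_mask = np.array([g.startswith(mito_prefix) for g in cells.gene_ids])
    detected = (arr > 0).sum(axis=0)
    if not mito_mask.any():
        log.warning("sc_filter_cells: no gene matches prefix %r; mito filter skipped", mito_prefix)
        mito_pct = np.zeros(arr.shape[1])
    else:
        totals = arr.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_pct = np.where(totals > 0, 100.0 * arr[mito_mask].sum(axis=0) / totals, 0.0)
    keep = ~((mito_pct > max_mito_pct) | (detected < min_genes))
    kept_ids = [s for s, k in zip(cells.sample_ids, keep) if k]
    log.info("sc_filter_cells: %d -> %d cells (mito>%g%%: %d, genes<%d: %d)",
             len(keep), int(keep.sum()), max_mito_pct, int((mito_pct > max_mito_pct).sum()),
             min_genes, int((detected < min_genes).sum()))
    return cells.subset_samples(kept_ids)


def sc_normalize(cells: ExpressionMatrix, scale: float = 1e4) -> pd.DataFrame:
    """Depth-normalize counts per cell to ``scale`` total (no log)."""
    arr = cells.values.to_numpy(float)
    depth = arr.sum(axis=0)
    depth = np.where(depth > 0, depth, 1.0)
    return pd.DataFrame(arr / depth * scale, index=cells.gene_ids, columns=cells.sample_ids)


def sc_de(
    cells: ExpressionMatrix,
    groups: tuple[str, str],
    alpha: float = 0.05,
    lfc_min: float = 0.25,
    min_pct: float = 0.10,
) -> DEResult:
    """Rank-sum differential expression between two cell groups.

    Genes must be detected in >= ``min_pct`` of cells in at least one group.
    log2fc = log2((mean_b + eps)/(mean_a + eps)) on depth-normalized
    expression, with groups (a, b) = (reference, test).
    """
    ref, test = groups
    cond = cells.conditions()
    ids_a = [s for s, c in cond.items() if c == ref]
    ids_b = [s for s, c in cond.items() if c == test]
    if len(ids_a) < 3 or len(ids_b) < 3:
        raise ValueError("each group needs >= 3 cells")

    norm = sc_normalize(cells)
    a = norm[ids_a].to_numpy()
    b = norm[ids_b].to_numpy()
    pct_a = (a > 0).mean(axis=1)
    pct_b = (b > 0).mean(axis=1)
    expressed = (pct_a >= min_pct) | (pct_b >= min_pct)
    genes = [g for g, e in zip(cells.gene_ids, expressed) if e]
    log.info("sc_de: %d/%d genes pass the %g%% expression floor",
             len(genes), len(expressed), 100 * min_pct)
    a = np.log1p(a[expressed])
    b = np.log1p(b[expressed])

    method = "exact" if min(a.shape[1], b.shape[1]) <= 10 else "asymptotic"
    pvals = np.empty(len(genes))
    stats_ = np.empty(len(genes))
    for i in range(len(genes)):
        if np.all(a[i] == a[i][0]) and np.all(b[i] == b[i][0]) and a[i][0] == b[i][0]:
            pvals[i], stats_[i] = 1.0, a.shape[1] * b.shape[1] / 2.0
            continue
        m = method
        if m == "exact" and (len(np.unique(np.concatenate([a[i], b[i]]))) < len(a[i]) + len(b[i])):
            m = "asymptotic"  # ties: mid-ranks with normal approximation
        res = stats.mannwhitneyu(b[i], a[i], alternative="two-sided", method=m)
        stats_[i], pvals[i] = res.statistic, res.pvalue

    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    log2fc = np.log2((mean_b + SC_EPS) / (mean_a + SC_EPS))
    q = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": np.nan,
            "statistic": stats_,
            "df_total": np.nan,
            "p": pvals,
            "q": q,
            "direction": _directions(log2fc, q, alpha, lfc_min),
            "pct_ref": pct_a[expressed],
            "pct_test": pct_b[expressed],
        },
        index=genes,
    )
    return DEResult(table, alpha, lfc_min)
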