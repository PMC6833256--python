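"""Four simplified count-based differential expression procedures.

All methods consume a two-group :class:`~coregnet.simdata.CountMatrix` and
produce a :class:`DEResult` with one raw and one BH-adjusted p-value per gene.

* ``deseq_like``  — median-of-ratios size factors, mean-dispersion trend,
  conditional NB exact test on group count sums.
* ``edger_like``  — total-count scaling, empirical-Bayes shrunken gene-wise
  dispersions, same exact test.
* ``vst_like``    — variance-stabilizing transform of normalized counts,
  moderated t.
* ``voom_like``   — log-cpm with mean-variance precision weights,
  weighted moderated t.

NB convention: mean ``mu``, variance ``mu + alpha * mu**2``; the dispersion
trend is ``alpha(mu) = a1 + a0 / mu``, i.e. ``w(q) = (1 + a0) q + a1 q**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from coregnet.simdata import CountMatrix

__all__ = [
    "DispersionModel",
    "TransformedMatrix",
    "DEResult",
    "DEGeneSet",
    "size_factors",
    "estimate_dispersion",
    "nb_exact_test",
    "run_deseq_like",
    "run_edger_like",
    "vst_transform",
    "voom_transform",
    "run_vst_like",
    "run_voom_like",
    "moderated_t",
    "bh_adjust",
    "significant_genes",
]

_DISP_FLOOR = 1e-8
_D0_CAP = 1e6  # stands in for an infinite prior df


@dataclass
class DispersionModel:
    """Fitted mean-dispersion structure of a count matrix."""

    a0: float
    a1: float
    common_dispersion: float
    per_gene_dispersion: pd.Series  # EB-shrunken gene-wise estimates
    gene_wise: pd.Series = field(repr=False, default=None)  # raw MoM estimates

    def trend(self, mu):
        """Trend dispersion ``a1 + a0/mu`` evaluated at mean ``mu``."""
        mu = np.maximum(np.asarray(mu, dtype=float), 1e-8)
        return self.a1 + self.a0 / mu


@dataclass
class TransformedMatrix:
    """Variance-stabilized or log-cpm expression values (genes x samples)."""

    values: np.ndarray
    transform_name: str  # "vst" or "logcpm"
    gene_ids: list[str]
    sample_ids: list[str]
    group_labels: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.transform_name not in ("vst", "logcpm"):
            raise ValueError(f"unknown transform {self.transform_name!r}")
        if (self.weights is not None) != (self.transform_name == "logcpm"):
            raise ValueError("weights present iff transform is logcpm")


@dataclass
class DEResult:
    """Per-gene test results of one method."""

    method_name: str
    table: pd.DataFrame  # columns: gene_id, log2fc, p_value, adj_p_value

    def __post_init__(self) -> None:
        t = self.table
        if np.any(t["adj_p_value"].to_numpy() < t["p_value"].to_numpy() - 1e-12):
            raise ValueError("adjusted p-values must not undercut raw p-values")


@dataclass
class DEGeneSet:
    method_name: str
    genes: set[str]
    alpha: float


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------

def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    For every gene with all-positive counts, each sample's count is divided
    by the gene's geometric mean across samples; the size factor is the
    median of those ratios over genes.
    """
    k = counts.counts
    positive = np.all(k > 0, axis=1)
    if not np.any(positive):
        raise ValueError(
            "size factors undefined: no all-positive gene in the count matrix"
        )
    logk = np.log(k[positive].astype(float))
    log_gm = logk.mean(axis=1, keepdims=True)
    return np.median(np.exp(logk - log_gm), axis=0)


def _group_stats(z: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray):
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    mean_a = z[:, mask_a].mean(axis=1)
    mean_b = z[:, mask_b].mean(axis=1)
    ss = ((z[:, mask_a] - mean_a[:, None]) ** 2).sum(axis=1) + (
        (z[:, mask_b] - mean_b[:, None]) ** 2
    ).sum(axis=1)
    return mean_a, mean_b, ss, na, nb


def _conditional_loglik(y: np.ndarray, mask: np.ndarray, alpha: float) -> float:
    """NB log-likelihood of one group's counts conditioned on their total.

    Valid for exchangeable samples (counts pre-normalized to a common
    library scale); the group mean cancels out, leaving alpha only.
    """
    r = 1.0 / alpha
    yg = y[:, mask]
    n = yg.shape[1]
    tot = yg.sum(axis=1)
    return float(
        np.sum(special.gammaln(yg + r))
        + np.sum(special.gammaln(n * r) - special.gammaln(tot + n * r))
        - yg.shape[0] * n * special.gammaln(r)
    )


def estimate_dispersion(
    counts: CountMatrix, sf: np.ndarray, prior_df: float = 10.0
) -> DispersionModel:
    """Estimate gene-wise, common, shrunken and trend dispersions.

    Gene-wise estimates are method-of-moments on size-factor-normalized
    counts (floored at 1e-8). The common dispersion maximizes the pooled
    conditional likelihood over a log-spaced grid. Shrunken values combine
    gene-wise and common estimates with ``prior_df`` pseudo-observations.
    The trend ``alpha(mu) = a1 + a0/mu`` is fit by non-negative least
    squares on mean-binned gene-wise estimates.
    """
    mask_a, mask_b = counts.group_masks()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("dispersion estimation needs at least two samples per group")
    z = counts.counts / np.asarray(sf)[None, :]
    mean_a, mean_b, ss, na, nb = _group_stats(z, mask_a, mask_b)
    df = na + nb - 2
    mu = z.mean(axis=1)
    var_pooled = ss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var_pooled - mu) / np.where(mu > 0, mu**2, 1.0)
    alpha_mom = np.where(mu > 0, np.maximum(alpha_mom, _DISP_FLOOR), _DISP_FLOOR)

    # common dispersion: pooled conditional likelihood, coarse grid + refine
    y = np.rint(z)
    expressed = y.sum(axis=1) > 0
    ysub = y[expressed]
    if ysub.shape[0] > 2000:  # likelihood shape is stable; subsample for speed
        step = ysub.shape[0] // 2000
        ysub = ysub[::step]

    def neg_cl(log_alpha: float) -> float:
        a = float(np.exp(log_alpha))
        return -(
            _conditional_loglik(ysub, mask_a, a) + _conditional_loglik(ysub, mask_b, a)
        )

    grid = np.log(np.geomspace(1e-6, 10.0, 40))
    vals = [neg_cl(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_cl, bounds=(lo, hi), method="bounded")
    common = float(np.exp(res.x))

    shrunk = (df * alpha_mom + prior_df * common) / (df + prior_df)

    a0, a1 = _fit_trend(mu, alpha_mom)
    genes = counts.gene_ids
    return DispersionModel(
        a0=a0,
        a1=a1,
        common_dispersion=common,
        per_gene_dispersion=pd.Series(shrunk, index=genes),
        gene_wise=pd.Series(alpha_mom, index=genes),
    )


def _fit_trend(mu: np.ndarray, alpha: np.ndarray, n_bins: int = 20) -> tuple[float, float]:
    ok = mu > 0
    mu, alpha = mu[ok], alpha[ok]
    order = np.argsort(mu)
    mu, alpha = mu[order], alpha[order]
    bins = np.array_split(np.arange(len(mu)), min(n_bins, max(len(mu) // 5, 1)))
    bm = np.array([mu[b].mean() for b in bins if len(b)])
    ba = np.array([alpha[b].mean() for b in bins if len(b)])
    design = np.column_stack([1.0 / bm, np.ones_like(bm)])
    coef, _ = optimize.nnls(design, ba)
    return float(coef[0]), float(coef[1])


# ---------------------------------------------------------------------------
# conditional NB exact test
# ---------------------------------------------------------------------------

def _group_sum_logpmf(a: np.ndarray, n: int, mu0: float, dispersion: float) -> np.ndarray:
    """log pmf of a sum of ``n`` iid NB(mu0, dispersion) counts at values a."""
    m = n * mu0
    if dispersion <= 1e-12:
        return stats.poisson.logpmf(a, m)
    r = n / dispersion  # sum of n NB(mu0, alpha) is NB with size n/alpha
    p = r / (r + m)
    return stats.nbinom.logpmf(a, r, p)


def nb_exact_test(
    k_a: int, k_b: int, n_a: int, n_b: int, dispersion: float
) -> float:
    """Conditional exact p-value for a pair of group count sums.

    Given the overall sum ``k_s = k_a + k_b``, every split ``(a, b)`` with
    ``a + b = k_s`` is weighted by the product of the two group-sum NB
    probability masses; the p-value is the total conditional probability of
    splits no more likely than the observed one. ``dispersion <= 0`` uses
    the Poisson limit.
    """
    if k_a < 0 or k_b < 0:
        raise ValueError("counts must be non-negative")
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups must be non-empty")
    ks = int(k_a) + int(k_b)
    if ks == 0:
        return 1.0
    mu0 = ks / (n_a + n_b)

    if ks <= 4096:
        a = np.arange(ks + 1)
    else:  # enumerate only where mass is non-negligible, always incl. observed
        qa_lo, qa_hi = _sum_quantiles(n_a, mu0, dispersion)
        qb_lo, qb_hi = _sum_quantiles(n_b, mu0, dispersion)
        lo = int(min(qa_lo, ks - qb_hi, k_a))
        hi = int(max(qa_hi, ks - qb_lo, k_a))
        a = np.arange(max(lo, 0), min(hi, ks) + 1)

    logp = _group_sum_logpmf(a, n_a, mu0, dispersion) + _group_sum_logpmf(
        ks - a, n_b, mu0, dispersion
    )
    total = special.logsumexp(logp)
    obs = logp[a == k_a][0]
    keep = logp <= obs + 1e-9  # tolerate float ties (symmetric splits)
    p = float(np.exp(special.logsumexp(logp[keep]) - total))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def _sum_quantiles(n: int, mu0: float, dispersion: float) -> tuple[float, float]:
    m = n * mu0
    if dispersion <= 1e-12:
        lo = stats.poisson.ppf(1e-14, m)
        hi = stats.poisson.isf(1e-14, m)
    else:
        r = n / dispersion
        p = r / (r + m)
        lo = stats.nbinom.ppf(1e-14, r, p)
        hi = stats.nbinom.isf(1e-14, r, p)
    spread = max(hi - lo, 10.0)
    return lo - 0.1 * spread, hi + 0.1 * spread


# ---------------------------------------------------------------------------
# exact-test methods
# ---------------------------------------------------------------------------

def _exact_test_pipeline(
    counts: CountMatrix,
    sf: np.ndarray,
    dispersion_per_gene: np.ndarray,
    method_name: str,
) -> DEResult:
    """Shared core of the two exact-test methods: normalize, sum, test, BH."""
    mask_a, mask_b = counts.group_masks()
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    z = counts.counts / np.asarray(sf)[None, :]
    y = np.rint(z).astype(np.int64)
    ka = y[:, mask_a].sum(axis=1)
    kb = y[:, mask_b].sum(axis=1)

    pvals = np.ones(counts.n_genes)
    for i in range(counts.n_genes):
        if ka[i] + kb[i] > 0:
            pvals[i] = nb_exact_test(int(ka[i]), int(kb[i]), na, nb, float(dispersion_per_gene[i]))

    mean_a = ka / na
    mean_b = kb / nb
    log2fc = np.where(
        ka + kb > 0, np.log2((mean_b + 0.5) / (mean_a + 0.5)), 0.0
    )
    adj = bh_adjust(pvals)
    return DEResult(
        method_name=method_name,
        table=pd.DataFrame(
            {
                "gene_id": counts.gene_ids,
                "log2fc": log2fc,
                "p_value": pvals,
                "adj_p_value": adj,
            }
        ),
    )


def run_deseq_like(
    counts: CountMatrix,
    sf: np.ndarray | None = None,
    dispersion: np.ndarray | None = None,
) -> DEResult:
    """Median-of-ratios normalization, trend dispersion, conditional exact test.

    ``sf`` / ``dispersion`` may be supplied to pin the normalization or the
    per-gene dispersions (used for cross-method identity checks).
    """
    if sf is None:
        sf = size_factors(counts)
    if dispersion is None:
        model = estimate_dispersion(counts, sf)
        mu = (counts.counts / np.asarray(sf)[None, :]).mean(axis=1)
        dispersion = model.trend(mu)
    return _exact_test_pipeline(counts, sf, np.asarray(dispersion), "deseq_like")


def run_edger_like(
    counts: CountMatrix,
    sf: np.ndarray | None = None,
    dispersion: np.ndarray | None = None,
    prior_df: float = 10.0,
) -> DEResult:
    """Total-count scaling, EB-shrunken gene-wise dispersions, exact test."""
    if sf is None:
        lib = counts.counts.sum(axis=0).astype(float)
        if np.any(lib <= 0):
            raise ValueError("every sample needs a positive library size")
        sf = lib / np.exp(np.mean(np.log(lib)))
    if dispersion is None:
        model = estimate_dispersion(counts, sf, prior_df=prior_df)
        dispersion = model.per_gene_dispersion.to_numpy()
    return _exact_test_pipeline(counts, sf, np.asarray(dispersion), "edger_like")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def vst_transform(
    counts: CountMatrix, model: DispersionModel, sf: np.ndarray | None = None
) -> TransformedMatrix:
    """Variance-stabilizing transform for the fitted mean-variance trend.

    With ``w(q) = (1 + a0) q + a1 q**2`` the antiderivative of ``1/sqrt(w)``
    has the closed form ``(2/sqrt(a1)) * asinh(sqrt(a1 q / (1 + a0)))``,
    reducing to ``2 sqrt(q / (1 + a0))`` when a1 = 0.
    """
    c = 1.0 + model.a0
    if c <= 0 or model.a1 < 0:
        raise ValueError("fitted variance function is not monotone increasing")
    if sf is None:
        sf = size_factors(counts)
    q = counts.counts / np.asarray(sf)[None, :]
    if model.a1 > 0:
        vals = 2.0 / np.sqrt(model.a1) * np.arcsinh(np.sqrt(model.a1 * q / c))
    else:
        vals = 2.0 * np.sqrt(q / c)
    return TransformedMatrix(
        values=vals,
        transform_name="vst",
        gene_ids=counts.gene_ids,
        sample_ids=counts.sample_ids,
        group_labels=list(counts.group_labels),
    )


def voom_transform(counts: CountMatrix, n_bins: int = 20) -> TransformedMatrix:
    """log-cpm values with precision weights from a binned sqrt-SD trend.

    log-cpm uses the ``(count + 0.5) / (libsize + 1)`` pseudocounts. The
    sqrt of each gene's residual SD (two-group model) is related to its
    average log2 count by a 20-bin median trend with linear interpolation
    and flat extrapolation; each observation's weight is the predicted
    sqrt-SD (at that observation's fitted log2 count) to the power -4.
    """
    if counts.n_genes < 10:
        raise ValueError("too few genes to fit the mean-variance trend (need >= 10)")
    mask_a, mask_b = counts.group_masks()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need at least two samples per group")
    lib = counts.counts.sum(axis=0).astype(float)
    logcpm = np.log2((counts.counts + 0.5) / (lib + 1.0)[None, :] * 1e6)

    mean_a, mean_b, ss, na, nb = _group_stats(logcpm, mask_a, mask_b)
    sd = np.sqrt(ss / (na + nb - 2))
    sqrt_sd = np.sqrt(sd)

    # trend on the average log2-count scale
    log2lib = np.log2(lib + 1.0)
    sx = logcpm.mean(axis=1) + log2lib.mean() - np.log2(1e6)
    order = np.argsort(sx, kind="stable")
    bins = np.array_split(order, min(n_bins, max(counts.n_genes // 2, 1)))
    bx = np.array([np.median(sx[b]) for b in bins if len(b)])
    by = np.array([np.median(sqrt_sd[b]) for b in bins if len(b)])

    fitted = np.where(mask_a[None, :], mean_a[:, None], mean_b[:, None])
    fitted_count = fitted + log2lib[None, :] - np.log2(1e6)
    pred = np.interp(fitted_count, bx, by)  # flat beyond the outer bins
    pred = np.maximum(pred, 1e-3)
    weights = pred**-4.0
    return TransformedMatrix(
        values=logcpm,
        transform_name="logcpm",
        gene_ids=counts.gene_ids,
        sample_ids=counts.sample_ids,
        group_labels=list(counts.group_labels),
        weights=weights,
    )


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def _fit_fdist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled F: returns (d0, s0_sq)."""
    ok = s2 > 0
    if ok.sum() < 2:
        return _D0_CAP, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(z, ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = min(2.0 * _trigamma_inverse(float(evar)), _D0_CAP)
    else:
        d0 = _D0_CAP
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(values: TransformedMatrix, d0: float | None = None) -> DEResult:
    """Two-group (weighted) linear model with empirical-Bayes variance shrinkage.

    Posterior variance ``(d0*s0^2 + d*s^2)/(d0 + d)``; moderated t has
    ``d0 + d`` degrees of freedom. ``d0=0`` recovers the ordinary t-test,
    ``d0=inf`` replaces every gene variance by the common prior ``s0^2``.
    """
    labels = np.asarray(values.group_labels)
    uniq = sorted(set(values.group_labels))
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    mask_a = labels == uniq[0]
    mask_b = labels == uniq[1]
    x = values.values
    w = values.weights if values.weights is not None else np.ones_like(x)

    wa = w[:, mask_a]
    wb = w[:, mask_b]
    swa = wa.sum(axis=1)
    swb = wb.sum(axis=1)
    mean_a = (wa * x[:, mask_a]).sum(axis=1) / swa
    mean_b = (wb * x[:, mask_b]).sum(axis=1) / swb
    resid = np.where(mask_a[None, :], x - mean_a[:, None], x - mean_b[:, None])
    ss = (w * resid**2).sum(axis=1)
    df = x.shape[1] - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    s2 = ss / df
    u = np.sqrt(1.0 / swa + 1.0 / swb)

    if d0 is None:
        d0_fit, s0_sq = _fit_fdist(s2, df)
    elif np.isinf(d0) or d0 >= _D0_CAP:
        d0_fit, s0_sq = np.inf, _fit_fdist(s2, df)[1]
    else:
        d0_fit, s0_sq = float(d0), _fit_fdist(s2, df)[1]

    if np.isinf(d0_fit):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0_fit * s0_sq + df * s2) / (d0_fit + df)
        df_total = d0_fit + df
    s2_post = np.maximum(s2_post, 1e-300)

    effect = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = effect / (u * np.sqrt(s2_post))
    tstat = np.where(np.isfinite(tstat), tstat, 0.0)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    pvals = np.clip(pvals, np.nextafter(0.0, 1.0), 1.0)
    adj = bh_adjust(pvals)
    name = "vst_like" if values.transform_name == "vst" else "voom_like"
    return DEResult(
        method_name=name,
        table=pd.DataFrame(
            {
                "gene_id": values.gene_ids,
                "log2fc": effect,
                "p_value": pvals,
                "adj_p_value": adj,
            }
        ),
    )


def run_vst_like(counts: CountMatrix) -> DEResult:
    """VST of normalized counts followed by the moderated t-test.

    The reported log2fc is recomputed on the normalized-count scale (the
    VST scale is not log2).
    """
    sf = size_factors(counts)
    model = estimate_dispersion(counts, sf)
    tm = vst_transform(counts, model, sf=sf)
    res = moderated_t(tm)
    mask_a, mask_b = counts.group_masks()
    z = counts.counts / sf[None, :]
    lfc = np.log2((z[:, mask_b].mean(axis=1) + 0.5) / (z[:, mask_a].mean(axis=1) + 0.5))
    res.table["log2fc"] = lfc
    return res


def run_voom_like(counts: CountMatrix) -> DEResult:
    """log-cpm + precision weights followed by the weighted moderated t-test."""
    return moderated_t(voom_transform(counts))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def significant_genes(res: DEResult, alpha: float = 0.05) -> DEGeneSet:
    """Genes with adjusted p strictly below ``alpha``."""
    t = res.table
    genes = set(t.loc[t["adj_p_value"].to_numpy() < alpha, "gene_id"])
    return DEGeneSet(method_name=res.method_name, genes=genes, alpha=alpha)
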