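"""Count-matrix processing and per-gene differential expression.

The workflow mirrors standard bulk RNA-seq practice: drop uninformative
genes, compute TMM (trimmed mean of M-values) scaling factors, transform to
log2 counts-per-million, and fit per-gene linear models on the log-CPM with
the treatment indicator as the coefficient of interest and any supplied
covariates (cell line, batch, ...) as fixed effects.  Residual variances are
shrunk by an empirical-Bayes scaled-inverse-chi-squared prior and the
moderated t-statistic is referenced to a t distribution with augmented
degrees of freedom.  Ordinary least squares on log-CPM (rather than
precision-weighted least squares) is a deliberate simplification: the
downstream products are t-statistic rank lists and FDR/logFC threshold
sets, which depend on relative ordering that both approaches preserve.

Repeated-measures designs (multiple biopsies per patient) are handled by
:func:`fit_random_intercept`, a Gaussian random-intercept model fit by REML
with the likelihood profiled down to the single variance ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "DEResult",
    "RankList",
    "MixedLMResult",
    "filter_low_info_genes",
    "tmm_factors",
    "log_cpm",
    "fit_de",
    "bh_fdr",
    "rank_by_t",
    "fit_random_intercept",
]


@dataclass
class CountMatrix:
    """Genes x samples nonnegative integer counts plus sample metadata.

    ``counts`` is a DataFrame indexed by gene id with sample-id columns;
    ``meta`` is indexed by sample id and row-aligned with the columns.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("gene ids not unique")
        if not self.counts.columns.is_unique:
            raise ValueError("sample ids not unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if len(self.meta):
            self.meta = self.meta.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass
class NormalizedMatrix:
    """log2-CPM values with the TMM factors and library sizes that made them."""

    logcpm: pd.DataFrame
    tmm_factor: pd.Series
    lib_size: pd.Series
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one contrast.

    ``table`` columns: logFC (log2), t_stat, p_value, fdr, mean_expr.
    """

    table: pd.DataFrame
    contrast: str
    df_prior: float = np.nan
    s2_prior: float = np.nan

    def significant(self, fdr_max: float = 0.05, abs_logfc_min: float = 0.5,
                    direction: str | None = None) -> pd.Index:
        """Genes passing strict FDR and |logFC| thresholds.

        direction "up" keeps logFC > abs_logfc_min, "down" keeps
        logFC < -abs_logfc_min, None keeps either.
        """
        t = self.table
        sig = t["fdr"] < fdr_max
        if direction == "up":
            sig &= t["logFC"] > abs_logfc_min
        elif direction == "down":
            sig &= t["logFC"] < -abs_logfc_min
        else:
            sig &= t["logFC"].abs() > abs_logfc_min
        return t.index[sig]


@dataclass
class RankList:
    """Genes ordered by descending t-statistic (ties: gene id ascending)."""

    gene_ids: list[str]
    t_stats: np.ndarray

    @classmethod
    def from_stats(cls, t_by_gene: pd.Series) -> "RankList":
        order = sorted(t_by_gene.index, key=lambda g: (-t_by_gene[g], g))
        return cls(gene_ids=list(order),
                   t_stats=t_by_gene.loc[order].to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.gene_ids)


def filter_low_info_genes(cm: CountMatrix) -> CountMatrix:
    """Drop genes with zero interquartile range or total count <= 1.

    The IQR uses linearly interpolated quartiles (Q3 - Q1).  Constant genes
    and all-but-empty genes carry no usable contrast information.
    """
    x = cm.counts.to_numpy(dtype=float)
    q1, q3 = np.percentile(x, [25, 75], axis=1)
    keep = ((q3 - q1) > 0) & (x.sum(axis=1) > 1)
    return CountMatrix(cm.counts.loc[keep], cm.meta)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float = 0.3, trim_a: float = 0.05) -> float:
    """Robinson-Oshlack TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos], ref[pos]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * (np.log2(o / lib_obs) + np.log2(r / lib_ref))
    # inverse asymptotic variance of M (delta method on binomial counts)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None) -> pd.Series:
    """TMM normalization factors, rescaled to multiply to one.

    M-values (log count-proportion ratios vs the reference sample) are
    trimmed 30% on M and 5% on A and averaged with inverse-variance weights.
    The reference defaults to the sample whose upper-quartile count
    proportion is closest to the mean of those, as in edgeR.
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    x = cm.counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = cm.samples[lib == 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    if ref_sample is None:
        f75 = np.array([np.percentile(x[:, j] / lib[j], 75) for j in range(x.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = int(cm.samples.get_loc(ref_sample))
    factors = np.array([
        _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx])
        for j in range(x.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.samples, name="tmm_factor")


def log_cpm(cm: CountMatrix, factors: pd.Series | None = None,
            prior_count: float = 0.5) -> NormalizedMatrix:
    """log2 counts-per-million on TMM-scaled library sizes.

    value = log2( (count + prior) / (lib*factor + 2*prior) * 1e6 ).
    """
    if factors is None:
        factors = tmm_factors(cm)
    lib = cm.counts.sum(axis=0).astype(float)
    eff = lib * factors.loc[cm.samples]
    vals = np.log2(
        (cm.counts.to_numpy(dtype=float) + prior_count)
        / (eff.to_numpy() + 2 * prior_count)[None, :]
        * 1e6
    )
    return NormalizedMatrix(
        logcpm=pd.DataFrame(vals, index=cm.genes, columns=cm.samples),
        tmm_factor=factors.loc[cm.samples],
        lib_size=lib,
        meta=cm.meta,
    )


def _moment_match_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """(d0, s0^2) of the scaled-inverse-chi2 variance prior by moments.

    Under the hierarchical model s^2/s0^2 ~ F(d, d0), so
    Var(s^2)/E(s^2)^2 = 2(d + d0 - 2)/(d (d0 - 4)); invert for d0.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    m1 = float(np.mean(s2))
    if len(s2) < 3 or m1 <= 0:
        return np.inf, m1 if m1 > 0 else 1.0
    r = float(np.var(s2, ddof=1)) / m1**2
    denom = r * d - 2.0
    if denom <= 0:  # less spread than pure chi2 noise: fully pooled prior
        return np.inf, m1
    d0 = (2.0 * d - 4.0 + 4.0 * r * d) / denom
    if d0 <= 4.0:
        d0 = max(d0, 1e-3)
        s0_sq = m1 * max(d0 - 2.0, 1e-3) / d0 if d0 > 2 else np.median(s2)
        return d0, float(s0_sq)
    return d0, m1 * (d0 - 2.0) / d0


def fit_de(nm: NormalizedMatrix, design: pd.DataFrame,
           coef: str = "treatment", contrast: str = "",
           moderate: bool = True) -> DEResult:
    """Per-gene linear model on log-CPM with empirical-Bayes moderation.

    ``design`` is a samples x covariates numeric frame (no intercept column
    needed; one is added).  The coefficient named ``coef`` becomes the log2
    fold change.  Residual variances are shrunk toward a common prior fitted
    by method of moments, and the moderated t uses d0 + d degrees of
    freedom.  ``moderate=False`` gives the ordinary t-test.
    """
    design = design.loc[nm.logcpm.columns]
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    colnames = ["(intercept)", *design.columns]
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"{n} samples cannot identify {p} coefficients "
            f"(columns: {colnames})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"design not full rank (rank {rank} < {p} columns)")
    j = colnames.index(coef)
    Y = nm.logcpm.to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (XtX_inv @ X.T).T          # genes x p
    resid = Y - beta @ X.T
    d = n - p
    s2 = (resid**2).sum(axis=1) / d
    if moderate:
        d0, s0_sq = _moment_match_prior(s2, d)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = 1e6  # effectively normal reference
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d0 + d
    else:
        d0, s0_sq = 0.0, np.nan
        s2_post, df_total = s2, d
    se = np.sqrt(s2_post * XtX_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, j] / se
    # zero-residual genes: a numerically-zero effect is a zero t, not 0/0
    degenerate = se < 1e-12
    t[degenerate & (np.abs(beta[:, j]) < 1e-8)] = 0.0
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {
            "logFC": beta[:, j],
            "t_stat": t,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
            "mean_expr": Y.mean(axis=1),
        },
        index=nm.logcpm.index,
    )
    return DEResult(table=table, contrast=contrast or coef,
                    df_prior=float(d0), s2_prior=float(s0_sq))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def rank_by_t(de: DEResult) -> RankList:
    """Rank list by descending t-statistic; ties broken by gene id."""
    return RankList.from_stats(de.table["t_stat"])


# ---------------------------------------------------------------------------
# random-intercept mixed model


@dataclass
class MixedLMResult:
    """Random-intercept fit for one response.

    ``model`` records which path produced the estimates: "mixed" for the
    REML fit, "ols" for the single-observation-per-group fallback.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2_group: float
    sigma2_resid: float
    reml_loglik: float
    df_resid: int
    model: str
    coef: str

    @property
    def slope(self) -> float:
        return float(self.params[self.coef])

    @property
    def slope_se(self) -> float:
        return float(self.bse[self.coef])

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"coef": self.params, "se": self.bse,
             "t": self.tvalues, "p": self.pvalues}
        )
        out.attrs["sigma2_group"] = self.sigma2_group
        out.attrs["sigma2_resid"] = self.sigma2_resid
        out.attrs["model"] = self.model
        return out


def _reml_profile(lam: float, y: np.ndarray, X: np.ndarray,
                  group_slices: list[np.ndarray]) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profiled restricted log-likelihood at variance ratio lam.

    V0 = I + lam * Z Z' is block diagonal; per group of size m,
    V0^-1 = I - lam/(1+lam*m) J and |V0| = 1 + lam*m.  Returns
    (restricted loglik, beta_hat, (X'V0^-1 X)^-1, sigma2_hat).
    """
    n, p = X.shape
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for idx in group_slices:
        m = len(idx)
        Xg, yg = X[idx], y[idx]
        shrink = lam / (1.0 + lam * m)
        xs, ys = Xg.sum(axis=0), yg.sum()
        XtVX += Xg.T @ Xg - shrink * np.outer(xs, xs)
        XtVy += Xg.T @ yg - shrink * xs * ys
        ytVy += yg @ yg - shrink * ys * ys
        logdet += np.log1p(lam * m)
    XtVX_inv = np.linalg.inv(XtVX)
    beta = XtVX_inv @ XtVy
    rss = ytVy - XtVy @ beta
    rss = max(rss, 1e-300)
    sigma2 = rss / (n - p)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    ll = -0.5 * (
        (n - p) * np.log(sigma2) + logdet + logdet_xvx + (n - p)
    )
    return ll, beta, XtVX_inv, sigma2


def fit_random_intercept(
    y: np.ndarray | pd.Series,
    x: pd.DataFrame | np.ndarray,
    group: np.ndarray | pd.Series,
    coef: str | None = None,
) -> MixedLMResult:
    """Gaussian random-intercept model fit by profiled REML.

    y_ij = x_ij' beta + b_i + e_ij with b_i ~ N(0, sigma_g^2) and
    e_ij ~ N(0, sigma^2).  The restricted likelihood is profiled down to the
    variance ratio lam = sigma_g^2 / sigma^2 and maximised in one dimension.
    Wald test on ``coef`` (default: the first covariate column).  If every
    group has a single observation the random intercept is unidentifiable
    and the fit falls back to OLS with a warning.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(x, pd.DataFrame):
        xnames = list(x.columns)
        Xcov = x.to_numpy(dtype=float)
    else:
        Xcov = np.atleast_2d(np.asarray(x, dtype=float))
        if Xcov.shape[0] != len(y):
            Xcov = Xcov.T
        xnames = [f"x{i}" for i in range(Xcov.shape[1])]
    coef = coef or xnames[0]
    names = ["(intercept)", *xnames]
    X = np.column_stack([np.ones(len(y)), Xcov])
    group = pd.Series(np.asarray(group))
    codes, uniques = pd.factorize(group)
    if len(uniques) < 2:
        raise ValueError("need at least two groups")
    group_slices = [np.flatnonzero(codes == g) for g in range(len(uniques))]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"{n} observations cannot fit {p} coefficients")

    singleton = all(len(s) == 1 for s in group_slices)
    if singleton:
        warnings.warn(
            "one observation per group: random intercept unidentifiable, "
            "falling back to OLS",
            stacklevel=2,
        )
        lam_hat = 0.0
        model = "ols"
        ll, beta, XtVX_inv, sigma2 = _reml_profile(0.0, y, X, group_slices)
    else:
        def neg_ll(log_lam: float) -> float:
            return -_reml_profile(np.exp(log_lam), y, X, group_slices)[0]

        res = optimize.minimize_scalar(
            neg_ll, bounds=(-12.0, 12.0), method="bounded",
            options={"xatol": 1e-10},
        )
        lam_hat = float(np.exp(res.x))
        ll0 = _reml_profile(0.0, y, X, group_slices)[0]
        if ll0 >= -res.fun:  # boundary solution: no between-group variance
            lam_hat = 0.0
        ll, beta, XtVX_inv, sigma2 = _reml_profile(lam_hat, y, X, group_slices)
        model = "mixed"

    se = np.sqrt(sigma2 * np.diag(XtVX_inv))
    t = beta / se
    df = n - p
    pv = 2.0 * stats.t.sf(np.abs(t), df)
    return MixedLMResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        tvalues=pd.Series(t, index=names),
        pvalues=pd.Series(pv, index=names),
        sigma2_group=lam_hat * sigma2,
        sigma2_resid=sigma2,
        reml_loglik=float(ll),
        df_resid=df,
        model=model,
        coef=coef,
    )
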