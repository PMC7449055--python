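"""Marker-by-marker association of splicing/expression phenotypes with dosages.

Each marker is tested with ordinary least squares ``y ~ intercept + covariates
+ dosage`` (dosage additive, one coefficient per alternative-allele copy) and
a two-sided t-test on the dosage coefficient.  An optional grouped random
intercept is fitted by restricted maximum likelihood over a single variance
ratio, as a light-weight stand-in for pedigree-based relatedness models.
Conditional scans append a focal marker's dosage to the covariates; LD between
markers is summarised as the squared Pearson correlation of dosages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from junctionqtl.io_core import GenotypeMatrix


@dataclass
class MarkerFit:
    beta: float
    se: float
    p_value: float
    var_explained_pct: float
    n: int
    reason: str | None = None  # set when the fit is missing (e.g. "monomorphic")
    sigma2_group: float | None = None
    sigma2_resid: float | None = None

    @property
    def missing(self) -> bool:
        return self.reason is not None


def _design(X, n) -> np.ndarray:
    """Intercept + covariate design; raises on rank deficiency."""
    if X is None:
        M = np.ones((n, 1))
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        M = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        cols: list[np.ndarray] = []
        for j in range(M.shape[1]):
            trial = np.column_stack(cols + [M[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(j)
            else:
                cols.append(M[:, j])
        raise ValueError(f"rank-deficient covariate design; collinear columns {bad}")
    return M


def _ols(y: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    return beta, float(resid @ resid)


def fit_marker_model(
    y,
    g,
    X=None,
    random_group=None,
) -> MarkerFit:
    """Test one marker: ``y ~ intercept + X + g`` with a t-test on ``g``.

    Samples with missing ``y`` or ``g`` are dropped pairwise.  The reported
    ``var_explained_pct`` is 100 x (SSE_reduced - SSE_full) / SSE_reduced,
    i.e. the share of covariate-adjusted phenotypic variance removed by the
    marker.  With ``random_group`` labels, a single grouped random intercept
    is fitted by REML over the variance ratio and the marker is tested in
    the resulting GLS fit (a ratio optimised to 0 reduces exactly to OLS).
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    y, g = y[keep], g[keep]
    Xk = None
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != keep.size:
            X = X.T
        Xk = X[keep]
    n = y.size
    if n == 0 or np.nanstd(g) == 0:
        return MarkerFit(math.nan, math.nan, math.nan, math.nan, n, reason="monomorphic")
    M0 = _design(Xk, n)
    if random_group is not None:
        groups = np.asarray(list(random_group))[keep]
        return _reml_marker(y, g, M0, groups)
    M1 = np.column_stack([M0, g])
    _, sse0 = _ols(y, M0)
    beta1, sse1 = _ols(y, M1)
    df = n - M1.shape[1]
    if df <= 0:
        return MarkerFit(math.nan, math.nan, math.nan, math.nan, n, reason="insufficient df")
    sigma2 = sse1 / df
    try:
        XtX_inv = np.linalg.inv(M1.T @ M1)
    except np.linalg.LinAlgError:
        return MarkerFit(math.nan, math.nan, math.nan, math.nan, n, reason="collinear")
    se = math.sqrt(sigma2 * XtX_inv[-1, -1])
    beta = float(beta1[-1])
    if se == 0:
        p = 0.0 if beta != 0 else 1.0
    else:
        p = 2.0 * stats.t.sf(abs(beta / se), df)
    ve = 100.0 * (sse0 - sse1) / sse0 if sse0 > 0 else math.nan
    return MarkerFit(beta, se, max(p, 5e-324), ve, n)


def _reml_marker(y: np.ndarray, g: np.ndarray, M0: np.ndarray, groups) -> MarkerFit:
    """Grouped random-intercept model fitted by REML over lam = s2_u/s2_e."""
    M1 = np.column_stack([M0, g])
    codes, _ = pd.factorize(pd.Series(groups))
    Z = np.zeros((y.size, codes.max() + 1))
    Z[np.arange(y.size), codes] = 1.0
    ZZt = Z @ Z.T
    n, p = M1.shape

    def gls(lam: float):
        V = np.eye(n) + lam * ZZt
        Vi = np.linalg.inv(V)
        A = M1.T @ Vi @ M1
        b = np.linalg.solve(A, M1.T @ Vi @ y)
        r = y - M1 @ b
        s2 = float(r @ Vi @ r) / (n - p)
        return V, Vi, A, b, s2

    def neg_reml(log_lam: float) -> float:
        lam = math.exp(log_lam)
        V, Vi, A, b, s2 = gls(lam)
        sign, logdetV = np.linalg.slogdet(V)
        _, logdetA = np.linalg.slogdet(A)
        return 0.5 * ((n - p) * math.log(s2) + logdetV + logdetA)

    # profile over log lambda; include the lam -> 0 boundary explicitly
    res = optimize.minimize_scalar(neg_reml, bounds=(-12.0, 6.0), method="bounded")
    lam = math.exp(res.x)
    if neg_reml(-12.0) <= res.fun + 1e-10:
        lam = 0.0
    V, Vi, A, b, s2 = gls(lam)
    cov = np.linalg.inv(A) * s2
    beta = float(b[-1])
    se = math.sqrt(cov[-1, -1])
    df = n - p
    pval = 2.0 * stats.t.sf(abs(beta / se), df) if se > 0 else (0.0 if beta else 1.0)
    # variance explained on the covariate-adjusted scale, as in the OLS path
    M0b = np.linalg.solve(M0.T @ Vi @ M0, M0.T @ Vi @ y)
    r0 = y - M0 @ M0b
    sse0 = float(r0 @ Vi @ r0)
    r1 = y - M1 @ b
    sse1 = float(r1 @ Vi @ r1)
    ve = 100.0 * (sse0 - sse1) / sse0 if sse0 > 0 else math.nan
    return MarkerFit(
        beta, se, max(pval, 5e-324), ve, n,
        sigma2_group=lam * s2, sigma2_resid=s2,
    )


def scan(
    y,
    genotypes: GenotypeMatrix,
    covariates=None,
    condition_on: str | None = None,
    focal: str | None = None,
    sample_ids=None,
) -> pd.DataFrame:
    """Associate one phenotype with every marker of a genotype matrix.

    ``y`` may be a pandas Series indexed by sample id or an array aligned to
    ``genotypes.sample_ids`` (or to ``sample_ids``).  ``condition_on``
    appends that marker's dosage to the covariates (the marker itself is
    then reported as missing with reason "conditioned").  ``focal`` adds an
    ``r2_with_focal`` LD column.  Returns one row per marker with columns
    marker, chrom, pos, beta, se, p, var_explained_pct, n, rank, and the
    optional LD column; ranking is ascending p with ties broken by position
    then marker id.
    """
    if isinstance(y, pd.Series):
        common = [s for s in genotypes.sample_ids if s in y.index]
        if not common:
            raise ValueError("no samples shared between phenotype and genotypes")
        idx = [genotypes.sample_ids.index(s) for s in common]
        yv = y.loc[common].to_numpy(dtype=float)
        G = genotypes.dosage[idx]
        if covariates is not None:
            covariates = (
                covariates.loc[common].to_numpy(dtype=float)
                if isinstance(covariates, pd.DataFrame)
                else np.asarray(covariates, dtype=float)[idx]
            )
    else:
        yv = np.asarray(y, dtype=float)
        G = genotypes.dosage
        if covariates is not None:
            covariates = np.asarray(covariates, dtype=float)
    X = covariates
    cond_idx = None
    if condition_on is not None:
        cond_idx = genotypes.marker_index(condition_on)
        gc = G[:, cond_idx]
        X = gc[:, None] if X is None else np.column_stack([np.atleast_2d(X.T).T, gc])

    keep = ~np.isnan(yv)
    clean = keep.all() and not np.isnan(G).any()
    rows = []
    if clean:
        # vectorised Frisch-Waugh path: residualise y and every dosage column
        # against the covariate design, then test each marker in one pass
        M0 = _design(X, yv.size)
        Q, _ = np.linalg.qr(M0)
        yt = yv - Q @ (Q.T @ yv)
        Gt = G - Q @ (Q.T @ G)
        gss = (Gt * Gt).sum(axis=0)
        yss = float(yt @ yt)
        df = yv.size - M0.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (Gt.T @ yt) / gss
            sse_full = yss - beta**2 * gss
            se = np.sqrt(sse_full / df / gss)
            tstat = beta / se
            pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
            ve = 100.0 * (beta**2 * gss) / yss
        gvar = G.var(axis=0)
        mono = gvar == 0
        # dosage fully absorbed by the covariates (e.g. perfect LD with the
        # conditioned marker): no testable residual variation
        collinear = ~mono & (gss < 1e-9 * gvar * yv.size)
        for j, (mid, chrom, pos, ref, alt) in enumerate(genotypes.markers):
            if cond_idx is not None and j == cond_idx:
                rows.append((mid, chrom, pos, math.nan, math.nan, math.nan, math.nan, 0, "conditioned"))
            elif collinear[j]:
                rows.append((mid, chrom, pos, math.nan, math.nan, math.nan, math.nan, yv.size, "collinear"))
            elif mono[j] or df <= 0:
                rows.append((mid, chrom, pos, math.nan, math.nan, math.nan, math.nan, yv.size, "monomorphic"))
            else:
                rows.append(
                    (mid, chrom, pos, float(beta[j]), float(se[j]),
                     max(float(pvals[j]), 5e-324), float(ve[j]), yv.size, None)
                )
    else:
        for j, (mid, chrom, pos, ref, alt) in enumerate(genotypes.markers):
            if cond_idx is not None and j == cond_idx:
                rows.append((mid, chrom, pos, math.nan, math.nan, math.nan, math.nan, 0, "conditioned"))
                continue
            fit = fit_marker_model(yv, G[:, j], X)
            rows.append((mid, chrom, pos, fit.beta, fit.se, fit.p_value, fit.var_explained_pct, fit.n, fit.reason))
    out = pd.DataFrame(
        rows, columns=["marker", "chrom", "pos", "beta", "se", "p", "var_explained_pct", "n", "reason"]
    )
    out = rank_markers(out)
    if focal is not None:
        gf = genotypes.dosages_of(focal)
        out["r2_with_focal"] = [ld_r2(gf, G[:, j]) for j in range(G.shape[1])]
    return out


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise-complete).

    NaN when fewer than 3 complete pairs remain or either marker is
    monomorphic; invariant to swapping ref/alt coding (g -> 2 - g).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    keep = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[keep], g2[keep]
    if g1.size < 3 or g1.std() == 0 or g2.std() == 0:
        return math.nan
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test of a phenotype across genotype classes.

    Returns (H, p) with tie correction; all-tied input gives (0, 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(list(groups))
    samples = [values[groups == gclass] for gclass in pd.unique(groups)]
    samples = [s for s in samples if s.size > 0]
    if len(samples) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if np.all(values == values[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), float(p)


def genotype_class_summary(pheno, dosage) -> pd.DataFrame:
    """Per genotype class (dosage 0/1/2): n, mean, SE of the mean, median.

    Empty classes are omitted.  NaN phenotypes are dropped within class.
    """
    pheno = np.asarray(pheno, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    rows = []
    for d in (0, 1, 2):
        vals = pheno[(dosage == d) & ~np.isnan(pheno)]
        if vals.size == 0:
            continue
        se = vals.std(ddof=1) / math.sqrt(vals.size) if vals.size > 1 else math.nan
        rows.append((d, vals.size, vals.mean(), se, float(np.median(vals))))
    return pd.DataFrame(rows, columns=["dosage", "n", "mean", "se", "median"])


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1): {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1: {n_tests}")
    return alpha / n_tests


def rank_markers(results: pd.DataFrame) -> pd.DataFrame:
    """Add a 1-based ``rank`` column: ascending p, ties broken by genomic
    position then marker id; missing results (NaN p) are unranked."""
    out = results.copy()
    valid = out["p"].notna()
    order = out[valid].sort_values(["p", "pos", "marker"]).index
    out["rank"] = pd.Series(pd.NA, index=out.index, dtype="Int64")
    out.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return out
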