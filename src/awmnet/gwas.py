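"""Genomic relationship matrix, REML variance components, and
mixed-linear-model association.

The association model for each SNP k and trait is

    y = 1*mu + s_k * a_k + u + e,   u ~ N(0, G * sigma_u^2)

where G is the genomic relationship matrix of Yang et al. built from
all (post-QC) SNPs. Variance components are estimated once per trait
under the null model (no SNP term) and reused for every SNP test — the
convention of GCTA's ``--mlma`` — so each per-SNP test is a generalized
least squares fit in the eigenbasis of G, O(n) per SNP after a single
rotation of the phenotype and genotypes. Wald p-values use the normal
approximation. Phenotypes are assumed pre-adjusted for systematic
environmental effects; an optional covariate matrix is accepted for
generality.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from awmnet.datatypes import (
    GenotypeMatrix,
    Grm,
    GwasResult,
    TraitTable,
    ValidationError,
    VarianceEstimate,
)

_LAMBDA_LOG_RANGE = (-12.0, 12.0)  # search window for log variance ratio
_BRENT_TOL = 1e-8
_MIN_RECORDS = 50  # traits with fewer non-missing records are skipped


def compute_grm(g: GenotypeMatrix) -> Grm:
    """Yang et al. genomic relationship matrix.

    Off-diagonal:  A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2p_i(1-p_i))
    Diagonal:      A_jj = 1 + (1/m) sum_i (x_j^2 - (1+2p_i)x_j + 2p_i^2) / (2p_i(1-p_i))

    with p_i the sample A1-allele frequency. Missing dosages are
    mean-imputed per SNP (never persisted back to the genotypes).
    """
    x = np.array(g.dosages, dtype=float)
    n, m = x.shape
    if n < 2 or m < 1:
        raise ValidationError("GRM needs >= 2 samples and >= 1 SNP")
    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("monomorphic SNP encountered while building the GRM")
    # mean-impute missing dosages
    nan_r, nan_c = np.nonzero(np.isnan(x))
    if len(nan_r):
        x[nan_r, nan_c] = 2.0 * p[nan_c]

    denom = 2.0 * p * (1.0 - p)
    w = (x - 2.0 * p) / np.sqrt(denom)
    a = (w @ w.T) / m
    diag = 1.0 + np.sum((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom, axis=1) / m
    np.fill_diagonal(a, diag)
    return Grm(values=a, m_snps=m, sample_ids=list(g.sample_ids))


class GrmEigen:
    """Eigendecomposition of a GRM, cached for REML and the MLMA scan."""

    def __init__(self, grm: Grm):
        vals, vecs = np.linalg.eigh(grm.values)
        # the Yang estimator is not guaranteed PSD at finite m (small
        # subsets especially); REML instead keeps V = s_u^2*D + s_e^2*I
        # positive during optimization. Eigenvalues more negative than
        # the mean diagonal mean the input is not a relationship matrix.
        mean_diag = float(np.mean(np.diag(grm.values)))
        if vals.min() < -10.0 * max(mean_diag, 1.0):
            raise ValidationError(
                f"GRM is not positive semi-definite (min eigenvalue {vals.min():.3g})"
            )
        self.values = vals
        self.vectors = vecs
        self.grm = grm

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return self.vectors.T @ v


def _reml_neg2_profile(
    log_lambda: float, d: np.ndarray, ystar: np.ndarray, xstar: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """-2 * restricted log-likelihood profiled over sigma_e^2.

    Model in the eigenbasis: Var(y*) = sigma_e^2 * (lambda*D + I) with
    lambda = sigma_u^2 / sigma_e^2. Returns (-2lR, sigma_e^2_hat, beta).
    """
    lam = np.exp(log_lambda)
    v = lam * d + 1.0
    if np.any(v <= 0):  # infeasible for GRMs with negative eigenvalues
        return np.inf, np.nan, None
    w = 1.0 / v
    n, p = xstar.shape
    xtwx = xstar.T @ (w[:, None] * xstar)
    xtwy = xstar.T @ (w * ystar)
    beta = np.linalg.solve(xtwx, xtwy)
    r = ystar - xstar @ beta
    rss = float(r @ (w * r))
    sigma_e2 = rss / (n - p)
    logdet_v = float(np.sum(np.log(v)))
    sign, logdet_x = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf, sigma_e2, beta
    neg2 = (n - p) * np.log(sigma_e2) + logdet_v + logdet_x + (n - p)
    return neg2, sigma_e2, beta


def _reml_neg2_at(
    sigma_u2: float, sigma_e2: float, d, ystar, xstar
) -> float:
    """-2 restricted log-likelihood at explicit variance components."""
    v = sigma_u2 * d + sigma_e2
    if np.any(v <= 0):
        return np.inf
    w = 1.0 / v
    xtwx = xstar.T @ (w[:, None] * xstar)
    beta = np.linalg.solve(xtwx, xstar.T @ (w * ystar))
    r = ystar - xstar @ beta
    sign, logdet_x = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    return float(np.sum(np.log(v)) + logdet_x + r @ (w * r))


def reml_null(
    y: np.ndarray,
    grm: Grm | GrmEigen,
    covariates: np.ndarray | None = None,
    compute_se: bool = True,
) -> VarianceEstimate:
    """REML estimates of (sigma_u^2, sigma_e^2) for y = Xb + u + e.

    Maximizes the restricted likelihood via the eigendecomposition of G
    and a 1-D Brent search over log(lambda), lambda = sigma_u^2/sigma_e^2.
    Standard errors come from the numerically differentiated observed
    information in (sigma_u^2, sigma_e^2); the h^2 SE uses the delta
    method. A flat profile (identity-like GRM) is flagged rather than
    silently reported.
    """
    eig = grm if isinstance(grm, GrmEigen) else GrmEigen(grm)
    y = np.asarray(y, float)
    n = len(y)
    if n != eig.grm.n:
        raise ValidationError("phenotype length does not match GRM dimension")
    if np.nanstd(y) == 0:
        raise ValidationError("phenotype is constant")
    x = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    ystar = eig.rotate(y)
    xstar = eig.rotate(x)
    d = eig.values

    obj = lambda ll: _reml_neg2_profile(ll, d, ystar, xstar)[0]
    lo, hi = _LAMBDA_LOG_RANGE
    dmin = float(d.min())
    if dmin < 0:  # keep lambda*d + 1 strictly positive
        hi = min(hi, float(np.log(0.999 / -dmin)))
    res = optimize.minimize_scalar(
        obj, bounds=(lo, hi), method="bounded",
        options={"xatol": _BRENT_TOL},
    )
    ll_hat = float(res.x)
    neg2_hat, sigma_e2, _ = _reml_neg2_profile(ll_hat, d, ystar, xstar)
    lam = np.exp(ll_hat)
    sigma_u2 = lam * sigma_e2

    # flat-likelihood check: identity-like GRM leaves lambda unidentified
    span = max(
        abs(obj(_LAMBDA_LOG_RANGE[0]) - neg2_hat),
        abs(obj(_LAMBDA_LOG_RANGE[1]) - neg2_hat),
    )
    flat = bool(span < 1e-6) or float(np.ptp(d)) < 1e-10
    converged = bool(res.success) and not flat

    # truncate near-boundary estimates to a clean zero
    if lam < 1.5 * np.exp(_LAMBDA_LOG_RANGE[0]):
        sigma_u2 = 0.0
    total = sigma_u2 + sigma_e2
    h2 = sigma_u2 / total if total > 0 else 0.0

    se_u = se_e = se_h2 = np.nan
    if compute_se and not flat:
        se_u, se_e, se_h2 = _reml_standard_errors(
            sigma_u2, sigma_e2, d, ystar, xstar
        )
    return VarianceEstimate(
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        h2=float(min(max(h2, 0.0), 1.0)),
        se_sigma_u2=float(se_u),
        se_sigma_e2=float(se_e),
        se_h2=float(se_h2),
        loglik=-0.5 * float(neg2_hat),
        converged=converged,
        n=n,
        m_snps=eig.grm.m_snps,
        flat_likelihood=flat,
    )


def _reml_standard_errors(su, se, d, ystar, xstar):
    """SEs from a central-difference observed information matrix."""
    total = su + se
    h = np.array([max(su, 1e-3 * total), max(se, 1e-3 * total)]) * 1e-3
    f = lambda a, b: _reml_neg2_at(a, b, d, ystar, xstar)
    hess = np.empty((2, 2))
    pts = [(su, se)]

    def d2(i, j):
        ei = np.array([h[0], 0.0]) if i == 0 else np.array([0.0, h[1]])
        ej = np.array([h[0], 0.0]) if j == 0 else np.array([0.0, h[1]])
        p0 = np.array([su, se])
        if i == j:
            return (f(*(p0 + ei)) - 2 * f(*p0) + f(*(p0 - ei))) / h[i] ** 2
        return (
            f(*(p0 + ei + ej)) - f(*(p0 + ei - ej))
            - f(*(p0 - ei + ej)) + f(*(p0 - ei - ej))
        ) / (4 * h[i] * h[j])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(2):
            for j in range(i, 2):
                hess[i, j] = hess[j, i] = d2(i, j)
        info = 0.5 * hess  # -2lR -> information is half the Hessian
        try:
            cov = np.linalg.inv(info)
            var_u, var_e = max(cov[0, 0], 0.0), max(cov[1, 1], 0.0)
            # delta method for h2 = su / (su + se)
            gdot = np.array([se, -su]) / total**2
            var_h2 = max(float(gdot @ cov @ gdot), 0.0)
            return np.sqrt(var_u), np.sqrt(var_e), np.sqrt(var_h2)
        except np.linalg.LinAlgError:
            return np.nan, np.nan, np.nan


def mlma_scan(
    y: np.ndarray,
    g: GenotypeMatrix,
    grm: Grm | GrmEigen,
    vc: VarianceEstimate,
    trait_name: str = "trait",
) -> GwasResult:
    """Per-SNP GLS association with fixed variance components.

    For each SNP s (intercept projected out in the V-metric,
    V = G*sigma_u^2 + I*sigma_e^2):

        a_hat = s'V^-1 y~ / s'V^-1 s~,   SE = (s~'V^-1 s~)^(-1/2)

    computed in the GRM eigenbasis. SNPs with zero dosage variance are
    emitted with NaN statistics and a reason.
    """
    eig = grm if isinstance(grm, GrmEigen) else GrmEigen(grm)
    y = np.asarray(y, float)
    n, m = g.dosages.shape
    if n != eig.grm.n:
        raise ValidationError("genotype/GRM sample dimension mismatch")
    v = vc.sigma_u2 * eig.values + vc.sigma_e2
    w = 1.0 / v

    x = np.array(g.dosages, dtype=float)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
    nan_r, nan_c = np.nonzero(np.isnan(x))
    if len(nan_r):
        x[nan_r, nan_c] = 2.0 * p[nan_c]

    ystar = eig.rotate(y)
    one_star = eig.rotate(np.ones(n))
    sstar = eig.vectors.T @ x  # n x m rotated genotypes

    # project the intercept out of y and every SNP in the V-metric
    denom1 = float(one_star @ (w * one_star))
    y_t = ystar - one_star * (float(one_star @ (w * ystar)) / denom1)
    proj = (one_star * w) @ sstar / denom1
    s_t = sstar - np.outer(one_star, proj)

    stv_s = np.einsum("ij,ij->j", s_t, w[:, None] * s_t)
    stv_y = s_t.T @ (w * y_t)
    zero_var = x.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.where(zero_var, np.nan, stv_y / stv_s)
        se = np.where(zero_var, np.nan, 1.0 / np.sqrt(stv_s))
        z = effect / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.where(np.isnan(z), np.nan, np.clip(pvals, np.nextafter(0, 1), 1.0))

    table = pd.DataFrame(
        {
            "trait": trait_name,
            "snp": g.snp_info.index,
            "chrom": g.snp_info["chrom"].values,
            "pos": g.snp_info["pos"].values,
            "effect": effect,
            "se": se,
            "z": z,
            "p": pvals,
            "n": n,
            "reason": np.where(zero_var, "zero_variance", ""),
        }
    )
    return GwasResult(table.reset_index(drop=True))


def mlma_loco_scan(
    y: np.ndarray,
    g: GenotypeMatrix,
    trait_name: str = "trait",
) -> GwasResult:
    """Leave-one-chromosome-out MLMA: each chromosome's SNPs are tested
    against a GRM built from all *other* chromosomes (variance
    components re-estimated per left-out chromosome). Off by default in
    the pipeline; provided for users who want the candidate SNP's
    chromosome excluded from the polygenic term."""
    chroms = pd.unique(g.snp_info["chrom"])
    if len(chroms) < 2:
        raise ValidationError("LOCO needs SNPs on >= 2 chromosomes")
    tables = []
    for chrom in chroms:
        on = (g.snp_info["chrom"] == chrom).to_numpy()
        g_test = GenotypeMatrix(
            g.dosages[:, on], g.snp_info.loc[on].copy(), list(g.sample_ids)
        )
        g_rest = GenotypeMatrix(
            g.dosages[:, ~on], g.snp_info.loc[~on].copy(), list(g.sample_ids)
        )
        eig = GrmEigen(compute_grm(g_rest))
        vc = reml_null(y, eig, compute_se=False)
        tables.append(mlma_scan(y, g_test, eig, vc, trait_name=trait_name).table)
    table = pd.concat(tables, ignore_index=True)
    # restore panel SNP order
    order = {s: i for i, s in enumerate(g.snp_info.index)}
    table = table.sort_values("snp", key=lambda s: s.map(order), kind="stable")
    return GwasResult(table.reset_index(drop=True))


def run_all_gwas(
    traits: TraitTable,
    g: GenotypeMatrix,
    grm: Grm | GrmEigen | None = None,
    min_records: int = _MIN_RECORDS,
    loco: bool = False,
) -> tuple[GwasResult, dict[str, VarianceEstimate]]:
    """One null REML fit plus one MLMA scan per trait.

    Traits with fewer than ``min_records`` non-missing records are
    skipped with a warning. Missing phenotypes are dropped pairwise:
    each trait is analyzed on its own complete-record subset, so
    per-trait sample sizes may differ. With ``loco=True`` each
    chromosome is tested against a GRM of the remaining chromosomes.
    """
    if list(traits.sample_ids) != list(g.sample_ids):
        raise ValidationError("trait table and genotypes have different samples")
    if loco:
        tables, vcs = [], {}
        for j, name in enumerate(traits.trait_names):
            y = traits.values[:, j]
            ok = np.isfinite(y)
            if ok.sum() < min_records:
                warnings.warn(
                    f"trait {name}: only {int(ok.sum())} records "
                    f"(<{min_records}), skipped"
                )
                continue
            idx = np.nonzero(ok)[0]
            sub_g = g if ok.all() else g.subset_samples(idx)
            res = mlma_loco_scan(y[idx], sub_g, trait_name=name)
            tables.append(res.table)
        if not tables:
            raise ValidationError("no trait had enough records for GWAS")
        return GwasResult(pd.concat(tables, ignore_index=True)), {}
    if grm is None:
        grm = compute_grm(g)
    eig = grm if isinstance(grm, GrmEigen) else GrmEigen(grm)

    tables = []
    vcs: dict[str, VarianceEstimate] = {}
    for j, name in enumerate(traits.trait_names):
        y = traits.values[:, j]
        ok = np.isfinite(y)
        if ok.sum() < min_records:
            warnings.warn(
                f"trait {name}: only {int(ok.sum())} records (<{min_records}), skipped"
            )
            continue
        if ok.all():
            sub_g, sub_eig, ysub = g, eig, y
        else:
            idx = np.nonzero(ok)[0]
            sub_g = g.subset_samples(idx)
            sub_eig = GrmEigen(
                Grm(
                    eig.grm.values[np.ix_(idx, idx)],
                    eig.grm.m_snps,
                    [g.sample_ids[i] for i in idx],
                )
            )
            ysub = y[idx]
        vc = reml_null(ysub, sub_eig, compute_se=False)
        vcs[name] = vc
        res = mlma_scan(ysub, sub_g, sub_eig, vc, trait_name=name)
        tables.append(res.table)
    if not tables:
        raise ValidationError("no trait had enough records for GWAS")
    return GwasResult(pd.concat(tables, ignore_index=True)), vcs


def zscore_effects(res: GwasResult) -> pd.DataFrame:
    """Column-standardize additive effects: per trait, (a - mean)/sd
    over all SNPs in the result (sample standard deviation)."""
    eff = res.pivot("effect")
    if eff.shape[0] < 2:
        raise ValidationError("z-scoring needs >= 2 SNPs per trait")
    sd = eff.std(axis=0, ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValidationError(f"constant effect column for trait(s): {zero}")
    return (eff - eff.mean(axis=0)) / sd


def write_grm(grm: Grm, prefix: str | os.PathLike) -> None:
    """GCTA binary-compatible triplet (grm.bin/grm.N.bin/grm.id) + TSV."""
    prefix = Path(prefix)
    n = grm.n
    iu = np.tril_indices(n)
    # GCTA stores the lower triangle row-wise as float32
    vals = grm.values[iu].astype("<f4")
    with open(f"{prefix}.grm.bin", "wb") as fh:
        fh.write(vals.tobytes())
    with open(f"{prefix}.grm.N.bin", "wb") as fh:
        fh.write(np.full(len(vals), grm.m_snps, dtype="<f4").tobytes())
    with open(f"{prefix}.grm.id", "w") as fh:
        for sid in grm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")
    pd.DataFrame(grm.values, index=grm.sample_ids, columns=grm.sample_ids).to_csv(
        f"{prefix}.grm.tsv", sep="\t", float_format="%.8g"
    )
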