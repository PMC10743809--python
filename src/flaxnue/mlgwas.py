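"""Multi-locus mixed-model GWAS.

A two-stage algorithm standing in for an ensemble of multi-locus
random-SNP-effect mixed linear models:

1. a kinship-adjusted single-marker screen — REML variance components are
   fitted once on the null model (EMMA-style spectral decomposition of the
   genomic relationship matrix, 1-D optimization of the variance ratio) and
   reused for every marker (P3D), giving a generalized-least-squares Wald
   p-value per marker;
2. markers passing a screening p-threshold enter forward selection under the
   extended BIC into one multi-marker linear model; each retained marker is
   scored by a single-term-deletion likelihood-ratio test, converted to a LOD
   score (LRT / (2 ln 10)).  Only markers with LOD above the retention
   threshold (3.0 by default) become QTNs.

Config variants (screening threshold x EBIC gamma) play the role of the model
ensemble: per-variant QTN sets are unioned with provenance tags, keeping the
max-LOD record for duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

LOG10_FACTOR = 2.0 * np.log(10.0)

#: default ensemble of config variants (tag, stage-1 p threshold, EBIC gamma)
DEFAULT_VARIANTS: list[tuple[str, float, float]] = [
    ("mlA", 0.01, 0.5),
    ("mlB", 0.005, 1.0),
    ("mlC", 0.05, 0.5),
]


@dataclass
class VarianceComponents:
    """REML variance components of y = Xb + g + e, g ~ (0, sigma_g2 * G)."""

    sigma_g2: float
    sigma_e2: float
    loglik: float
    unidentifiable: bool = False
    g_diag_mean: float = 1.0  # mean diagonal of G (≈2 for a fully inbred panel)

    @property
    def delta(self) -> float:
        return self.sigma_e2 / self.sigma_g2 if self.sigma_g2 > 0 else np.inf

    @property
    def h2(self) -> float:
        """Genetic fraction of phenotypic variance for a typical individual:
        sigma_g2 scaled by the mean diagonal of G."""
        vg = self.sigma_g2 * self.g_diag_mean
        tot = vg + self.sigma_e2
        return vg / tot if tot > 0 else 0.0


def _spectral(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the relationship matrix, with PSD check."""
    G = np.asarray(G, dtype=float)
    S, U = np.linalg.eigh(0.5 * (G + G.T))
    if S.min() < -1e-6 * max(1.0, S.max()):
        raise ValueError(f"relationship matrix is not PSD (min eigenvalue {S.min():.3g})")
    return np.clip(S, 0.0, None), U


def fit_null_vc(
    y: np.ndarray,
    G: np.ndarray | pd.DataFrame,
    X: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML fit of the single-random-effect null model.

    Deterministic: the restricted likelihood is profiled over the variance
    ratio delta = sigma_e2/sigma_g2 on the spectral axis of G and optimized in
    one dimension (log-scale bounded search).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    S, U = eig if eig is not None else _spectral(np.asarray(G, dtype=float))
    ys = U.T @ y
    Xs = U.T @ X

    g_diag = float(np.mean(S))  # trace/n equals the mean diagonal of G
    if np.ptp(S) < 1e-10 * max(1.0, S.max()):
        # G proportional to identity: the split sigma_g2/sigma_e2 is not
        # identifiable; report the whole variance as residual, flagged.
        beta, rss = _ols(X, y)
        return VarianceComponents(0.0, rss / (n - p), np.nan, unidentifiable=True,
                                  g_diag_mean=g_diag)

    def neg_reml(log_delta: float) -> float:
        return -_reml_loglik(ys, Xs, S, np.exp(log_delta))[0]

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg_reml(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(neg_reml, bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
                          options={"xatol": 1e-6})
    delta = float(np.exp(res.x))
    ll, sigma_g2 = _reml_loglik(ys, Xs, S, delta)
    sigma_e2 = sigma_g2 * delta
    # collapse boundary solutions
    if delta > 1e10:
        sigma_e2, sigma_g2 = sigma_g2 * delta, 0.0
    return VarianceComponents(sigma_g2, sigma_e2, ll, g_diag_mean=g_diag)


def _reml_loglik(ys: np.ndarray, Xs: np.ndarray, S: np.ndarray, delta: float) -> tuple[float, float]:
    """Restricted log-likelihood and profiled sigma_g2 at a given delta."""
    n, p = Xs.shape
    v = S + delta
    w = 1.0 / v
    XtWX = Xs.T @ (Xs * w[:, None])
    XtWy = Xs.T @ (ys * w)
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    quad = float(np.sum(r * r * w))
    sigma_g2 = quad / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    _, logdet_xx = np.linalg.slogdet(Xs.T @ Xs)
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma_g2) + 1.0)
        + np.sum(np.log(v))
        + logdet_xwx
        - logdet_xx
    )
    return float(ll), float(sigma_g2)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(res[0]) if res.size else float(np.sum((y - X @ beta) ** 2))
    return beta, rss


# ------------------------------------------------------------------- stage 1

def scan_stage1(
    y: np.ndarray,
    geno: GenotypeMatrix,
    G: np.ndarray | pd.DataFrame | None = None,
    X: np.ndarray | None = None,
    vc: VarianceComponents | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Kinship-adjusted single-marker screen (P3D GLS Wald test).

    The null variance components are reused for every marker; covariates are
    projected out under the null covariance and each marker is tested by a
    1-df Wald chi-square.  Monomorphic markers and markers collinear with the
    covariates get a missing p-value.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if eig is None:
        S, U = _spectral(np.asarray(G, dtype=float))
    else:
        S, U = eig
    if vc is None:
        vc = fit_null_vc(y, G, X, eig=(S, U))
    w = 1.0 / (vc.sigma_g2 * S + vc.sigma_e2)  # absolute precisions
    sw = np.sqrt(w)
    ys = (U.T @ y) * sw
    Xs = (U.T @ X) * sw[:, None]
    M = geno.impute_mean().dosages
    Ms = (U.T @ M) * sw[:, None]
    # project covariates out
    Q, _ = np.linalg.qr(Xs)
    ry = ys - Q @ (Q.T @ ys)
    RM = Ms - Q @ (Q.T @ Ms)
    xx = np.einsum("ij,ij->j", RM, RM)
    xy = RM.T @ ry
    mono = geno.impute_mean().dosages.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xy / xx
        wald = beta * xy  # beta^2 * xx, in absolute precision units
    bad = mono | (xx <= 1e-8 * n)
    pvals = stats.chi2.sf(wald, df=1)
    pvals[bad] = np.nan
    beta[bad] = np.nan
    return pd.DataFrame({
        "marker": geno.marker_ids,
        "chrom": geno.chrom,
        "pos": geno.pos,
        "beta": beta,
        "score": wald,
        "p": pvals,
    })


# ------------------------------------------------------------------- stage 2

def multilocus_refine(
    y: np.ndarray,
    geno: GenotypeMatrix,
    candidates: np.ndarray,
    X: np.ndarray | None = None,
    ebic_gamma: float = 0.5,
    lod_min: float = 3.0,
    m_total: int | None = None,
    trait: str = "",
    model_tag: str = "",
) -> pd.DataFrame:
    """Fit screened candidates jointly by EBIC forward selection.

    Selected markers are scored by single-term-deletion likelihood-ratio
    tests: LOD = LRT / (2 ln 10), p from a 1-df chi-square, effect = the joint
    per-dosage coefficient and R2 = 100 * Var(x beta) / Var(y).  Only markers
    with LOD > ``lod_min`` are returned.  An empty candidate set is valid and
    yields an empty table.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    candidates = np.asarray(candidates, dtype=int)
    cols = ["marker", "chrom", "pos", "trait", "effect", "LOD", "p", "R2", "models"]
    if candidates.size == 0:
        return pd.DataFrame(columns=cols)
    M = geno.impute_mean().dosages
    m_total = m_total or geno.n_markers
    penalty = np.log(n) + 2.0 * ebic_gamma * np.log(m_total)

    selected: list[int] = []
    design = X
    _, rss_cur = _ols(design, y)
    ebic_cur = n * np.log(rss_cur / n)
    remaining = list(candidates)
    while remaining:
        best = None
        for j in remaining:
            cand_design = np.column_stack([design, M[:, j]])
            if np.linalg.matrix_rank(cand_design) < cand_design.shape[1]:
                continue  # collinear with current model
            _, rss = _ols(cand_design, y)
            if rss <= 0:
                rss = 1e-300
            ebic = n * np.log(rss / n) + (len(selected) + 1) * penalty
            if best is None or ebic < best[0]:
                best = (ebic, j, rss)
        if best is None or best[0] >= ebic_cur - 1e-9:
            break
        ebic_cur, j_sel, rss_cur = best
        selected.append(j_sel)
        design = np.column_stack([design, M[:, j_sel]])
        remaining = [j for j in remaining if j != j_sel]

    if not selected:
        return pd.DataFrame(columns=cols)

    beta_full, rss_full = _ols(design, y)
    if rss_full <= 0:
        rss_full = 1e-300
    var_y = float(np.var(y))
    rows = []
    p_cov = X.shape[1]
    for k, j in enumerate(selected):
        keep = [c for c in range(design.shape[1]) if c != p_cov + k]
        _, rss_red = _ols(design[:, keep], y)
        lrt = max(0.0, n * np.log(rss_red / rss_full))
        lod = lrt / LOG10_FACTOR
        pval = float(stats.chi2.sf(lrt, df=1))
        eff = float(beta_full[p_cov + k])
        r2 = 100.0 * float(np.var(M[:, j] * eff)) / var_y if var_y > 0 else np.nan
        if lod > lod_min:
            rows.append((geno.marker_ids[j], geno.chrom[j], int(geno.pos[j]), trait,
                         eff, lod, pval, r2, model_tag))
    return pd.DataFrame(rows, columns=cols)


# ----------------------------------------------------------------- ensemble

def run_mlgwas(
    traits: pd.DataFrame,
    geno: GenotypeMatrix,
    G: np.ndarray | pd.DataFrame,
    variants: list[tuple[str, float, float]] | None = None,
    X: np.ndarray | None = None,
    lod_min: float = 3.0,
) -> pd.DataFrame:
    """Scan every trait column under every config variant and union the QTNs.

    ``traits`` is an accession x trait table aligned with ``geno.accessions``.
    Duplicate marker x trait records are collapsed keeping the max-LOD one;
    the ``models`` column lists every variant that found the QTN.
    """
    variants = variants or DEFAULT_VARIANTS
    Gm = np.asarray(G, dtype=float)
    eig = _spectral(Gm)
    all_qtns: list[pd.DataFrame] = []
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=float)
        if np.var(y[~np.isnan(y)]) == 0 or np.isnan(y).all():
            log.info("run_mlgwas: trait %s has zero variance, skipped", trait)
            continue
        if np.isnan(y).any():
            raise ValueError(f"trait {trait} contains missing values")
        vc = fit_null_vc(y, Gm, X, eig=eig)
        scan = scan_stage1(y, geno, Gm, X, vc=vc, eig=eig)
        for tag, stage1_p, gamma in variants:
            cand = np.flatnonzero(scan["p"].to_numpy() < stage1_p)
            qtns = multilocus_refine(y, geno, cand, X, ebic_gamma=gamma,
                                     lod_min=lod_min, trait=trait, model_tag=tag)
            if len(qtns):
                all_qtns.append(qtns)
    if not all_qtns:
        return pd.DataFrame(columns=["marker", "chrom", "pos", "trait", "effect",
                                     "LOD", "p", "R2", "models"])
    cat = pd.concat(all_qtns, ignore_index=True)
    # union with provenance: per marker x trait keep the max-LOD record and
    # list every variant that found it
    tags = (cat.groupby(["marker", "trait"])["models"]
            .agg(lambda s: ",".join(sorted(set(s)))).reset_index())
    best = (cat.sort_values("LOD", ascending=False)
            .drop_duplicates(["marker", "trait"]).drop(columns="models"))
    out = best.merge(tags, on=["marker", "trait"]).reset_index(drop=True)
    return out[["marker", "chrom", "pos", "trait", "effect", "LOD", "p", "R2", "models"]]
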