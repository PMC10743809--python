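"""Differential expression and QTL-window colocalization.

Counts are normalized by median-of-ratios size factors; per gene, a negative
binomial generalized linear model (log link, group indicator, log size factor
offset) with a moment-estimated dispersion is fitted and the group coefficient
tested by Wald.  Benjamini-Hochberg controls the FDR across tested genes; a
gene is called differentially expressed when |log2FC| >= 1 and FDR < 0.05.
The contrast is N+ relative to the N- baseline within one genotype, so a
positive log2FC means higher expression under optimum nitrate.

Colocalization intersects gene intervals (1-based, closed) with +/-100 kb
windows around each QTL's representative position, clipped at the chromosome
start, and summarizes how many QTL windows harbor DEGs.

The per-gene moment dispersion (no empirical-Bayes shrinkage) is a deliberate
simplification that is adequate at four replicates for planted fold changes
of |log2FC| >= 1; see the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qtl import QTLRecord

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The size factor of a sample is the median, over genes positive in every
    sample, of the ratio of its count to the gene's geometric mean.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene is positive in all samples; supply a pseudo-reference")
    log_geo = np.mean(np.log(mat[all_pos]), axis=1)
    sf = np.exp(np.median(np.log(mat[all_pos]) - log_geo[:, None], axis=0))
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    normalized = counts / sf
    return size_factors, normalized


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-contrast differential-expression table plus call thresholds."""

    table: pd.DataFrame  # gene_id, contrast, base_mean, log2FC, p, fdr, significant
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05


def de_test(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    genotype: str,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> DEResult:
    """N+ vs N- differential expression within one genotype.

    Wald test on the treatment coefficient of a per-gene NB GLM; log2FC > 0
    means up-regulated under N+.  All-zero genes are excluded (logged).
    """
    sheet = sample_sheet.copy()
    sheet["treatment"] = sheet["treatment"].astype(str).str.replace("−", "-", regex=False)
    sel = sheet[sheet["genotype"] == genotype]
    if sel.empty:
        raise ValueError(f"no samples for genotype {genotype!r}")
    for tr in ("N+", "N-"):
        if (sel["treatment"] == tr).sum() < 2:
            raise ValueError(f"need >= 2 replicates under {tr} for genotype {genotype}")
    sub = counts[sel["sample"].tolist()]
    sf, _ = normalize_counts(counts)
    sf = sf[sel["sample"]].to_numpy()
    group = (sel["treatment"] == "N+").to_numpy(dtype=float)  # N- is baseline
    X = sm.add_constant(group)
    offset = np.log(sf)

    nonzero = sub.sum(axis=1) > 0
    n_drop = int((~nonzero).sum())
    if n_drop:
        log.info("de_test[%s]: excluded %d all-zero genes", genotype, n_drop)
    rows = []
    norm = sub.to_numpy(dtype=float) / sf
    for gi, gene in enumerate(sub.index):
        if not nonzero.iloc[gi]:
            continue
        y = sub.iloc[gi].to_numpy(dtype=float)
        alpha = _moment_dispersion(norm[gi], group)
        try:
            fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                         offset=offset).fit()
            coef = fit.params[1]
            se = fit.bse[1]
        except Exception:
            rows.append((gene, np.nan, np.nan, np.nan))
            continue
        wald_p = float(stats.chi2.sf((coef / se) ** 2, df=1)) if se > 0 else np.nan
        rows.append((gene, float(norm[gi].mean()), coef / np.log(2.0), wald_p))
    tab = pd.DataFrame(rows, columns=["gene_id", "base_mean", "log2FC", "p"])
    tested = tab["p"].notna()
    tab["fdr"] = np.nan
    tab.loc[tested, "fdr"] = bh_fdr(tab.loc[tested, "p"].to_numpy())
    tab["significant"] = (tab["log2FC"].abs() >= lfc_threshold) & (tab["fdr"] < fdr_threshold)
    tab.insert(1, "contrast", f"{genotype}:N+_vs_N-")
    return DEResult(tab, lfc_threshold, fdr_threshold)


def _moment_dispersion(norm_y: np.ndarray, group: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled across the two groups, floored."""
    est = []
    for gval in (0.0, 1.0):
        v = norm_y[group == gval]
        m = v.mean()
        if m > 0 and len(v) > 1:
            est.append((v.var(ddof=1) - m) / m**2)
    if not est:
        return DISPERSION_FLOOR
    return float(max(DISPERSION_FLOOR, np.mean(est)))


def de_both_genotypes(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Run the contrast independently for each genotype and stack the tables."""
    parts = []
    for g in sample_sheet["genotype"].unique():
        parts.append(de_test(counts, sample_sheet, g, lfc_threshold, fdr_threshold).table)
    return pd.concat(parts, ignore_index=True)


# -------------------------------------------------------------- colocalization

@dataclass
class QTLWindowHit:
    qtl_id: str
    chrom: str
    window_start: int
    window_end: int
    genes: list[str] = field(default_factory=list)
    degs: list[str] = field(default_factory=list)


def colocalize(
    qtls: list[QTLRecord],
    annotation: pd.DataFrame,
    degs: pd.DataFrame,
    half_window: int = 100_000,
) -> tuple[list[QTLWindowHit], dict]:
    """Intersect +/-``half_window`` QTL windows with genes and DEGs.

    Windows are centred on the representative QTN position and clipped at the
    chromosome start (coordinates stay >= 1); interval intersection is on
    1-based closed intervals.  Returns the per-QTL hits and a summary with the
    number of QTLs harboring >= 1 DEG, the fraction of distinct DEGs falling
    inside any window, and the mean +/- SD of DEG counts per hit QTL.
    """
    ann_chroms = set(annotation["chrom"].unique())
    qtl_chroms = set(q.chrom for q in qtls)
    unmatched = qtl_chroms - ann_chroms
    if unmatched:
        raise ValueError(f"QTL chromosomes missing from annotation: {sorted(unmatched)}")
    deg_sig = degs[degs["significant"]] if "significant" in degs.columns else degs
    deg_ids = set(deg_sig["gene_id"].unique())
    hits: list[QTLWindowHit] = []
    for q in qtls:
        start = max(1, q.rep_pos - half_window)
        end = q.rep_pos + half_window
        sub = annotation[(annotation["chrom"] == q.chrom)
                         & (annotation["end"] >= start)
                         & (annotation["start"] <= end)]
        genes = sub["gene_id"].tolist()
        dg = sorted(set(genes) & deg_ids)
        hits.append(QTLWindowHit(q.qtl_id, q.chrom, start, end, genes, dg))
    hit_counts = [len(h.degs) for h in hits if h.degs]
    distinct_in_windows = set().union(*[set(h.degs) for h in hits]) if hits else set()
    summary = {
        "n_qtl": len(qtls),
        "n_qtl_with_deg": len(hit_counts),
        "n_deg_total": len(deg_ids),
        "n_deg_in_windows": len(distinct_in_windows),
        "frac_deg_in_windows": (len(distinct_in_windows) / len(deg_ids)) if deg_ids else np.nan,
        "mean_deg_per_hit_qtl": float(np.mean(hit_counts)) if hit_counts else 0.0,
        "sd_deg_per_hit_qtl": float(np.std(hit_counts, ddof=1)) if len(hit_counts) > 1 else 0.0,
        "sum_deg_over_qtls": int(np.sum(hit_counts)) if hit_counts else 0,
    }
    return hits, summary
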