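"""Linkage disequilibrium and relatedness machinery.

r-squared is the squared Pearson correlation of unphased dosage vectors — for
a panel of inbred lines this coincides with haplotype-frequency r²; the decay
profile fits the Hill & Weir (1988) expectation of r² against distance, with a
binned-median interpolation fallback.  Kinship comes in two flavors: simple
identity-by-state sharing and the VanRaden genomic relationship matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)


# ------------------------------------------------------------------ pairwise r2

def pairwise_r2(geno: GenotypeMatrix, window: int = 50) -> pd.DataFrame:
    """Sliding-window pairwise r² (squared dosage correlation).

    For each marker, r² is computed against the next ``window`` markers on the
    same chromosome.  Monomorphic markers are skipped (count logged).  Returns
    a table with columns chrom, pos_i, pos_j, dist, r2.
    """
    g = geno.impute_mean()
    rows = []
    n_mono = 0
    for chrom in g.chromosomes():
        idx = g.markers_on(chrom)
        if len(idx) < 2:
            continue
        D = g.dosages[:, idx]
        pos = g.pos[idx]
        sd = D.std(axis=0)
        Dc = D - D.mean(axis=0)
        m = len(idx)
        for i in range(m - 1):
            if sd[i] == 0:
                n_mono += 1
                continue
            j_hi = min(m, i + 1 + window)
            js = np.arange(i + 1, j_hi)
            js = js[sd[js] > 0]
            if len(js) == 0:
                continue
            r = (Dc[:, js].T @ Dc[:, i]) / (len(D) * sd[i] * sd[js])
            for j, rv in zip(js, r):
                rows.append((chrom, int(pos[i]), int(pos[j]), int(pos[j] - pos[i]), float(rv**2)))
    if n_mono:
        log.info("pairwise_r2: skipped %d monomorphic index markers", n_mono)
    return pd.DataFrame(rows, columns=["chrom", "pos_i", "pos_j", "dist", "r2"])


# ------------------------------------------------------------------ decay fit

def _hill_weir(dist: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Expected r² under the Hill-Weir (1988) drift-recombination model with
    sample-size correction; C = rho * distance."""
    C = rho * dist
    term1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    term2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return term1 * term2


@dataclass
class LDDecayProfile:
    """Fitted LD-decay curve for one scope (genome-wide or one chromosome)."""

    scope: str
    rho: float | None  # Hill-Weir per-bp recombination-scale parameter
    n: int  # sample size used in the expectation
    max_dist: float
    method: str = "hill-weir"  # or "binned-median"
    bin_mid: np.ndarray | None = None
    bin_r2: np.ndarray | None = None

    def expected_r2(self, dist: np.ndarray) -> np.ndarray:
        dist = np.asarray(dist, dtype=float)
        if self.method == "hill-weir":
            return _hill_weir(dist, self.rho, self.n)
        return np.interp(dist, self.bin_mid, self.bin_r2)

    def decay_distance(self, threshold: float) -> float:
        """Smallest distance at which the fitted curve falls to ``threshold``.

        Right-censored at the maximum observed distance: if the curve never
        reaches the threshold, returns ``inf`` (no decay within range).
        """
        lo, hi = 1.0, float(self.max_dist)
        if self.expected_r2(np.array([lo]))[0] <= threshold:
            return lo
        if self.expected_r2(np.array([hi]))[0] > threshold:
            return float("inf")
        return float(brentq(lambda d: self.expected_r2(np.array([d]))[0] - threshold, lo, hi))


def fit_ld_decay(
    pairs: pd.DataFrame,
    scope: str = "genome",
    n: int | None = None,
    method: str = "hill-weir",
) -> LDDecayProfile:
    """Fit an LD-decay profile to an r²-vs-distance cloud.

    ``n`` is the number of accessions behind the r² values (enters the
    Hill-Weir finite-sample term; defaults to 100 when unknown, which only
    shifts the asymptote slightly).  A non-converging nonlinear fit falls back
    to binned-median interpolation and flags the profile accordingly.
    """
    if scope != "genome":
        pairs = pairs[pairs["chrom"] == scope]
    if len(pairs) < 50:
        raise ValueError(f"need >= 50 LD pairs in scope {scope!r}, got {len(pairs)}")
    d = pairs["dist"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    n = n or 100
    max_dist = float(d.max())

    def binned() -> LDDecayProfile:
        edges = np.quantile(d, np.linspace(0, 1, 21))
        edges = np.unique(edges)
        mids, meds = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (d >= lo) & (d <= hi)
            if sel.sum() >= 5:
                mids.append(0.5 * (lo + hi))
                meds.append(np.median(r2[sel]))
        # enforce monotone non-increasing medians for a well-defined threshold
        meds = np.minimum.accumulate(np.asarray(meds, dtype=float))
        return LDDecayProfile(scope=scope, rho=None, n=n, max_dist=max_dist,
                              method="binned-median",
                              bin_mid=np.asarray(mids), bin_r2=meds)

    if method == "binned-median":
        return binned()
    try:
        popt, _ = curve_fit(
            lambda x, rho: _hill_weir(x, rho, n),
            d, r2, p0=[1.0 / max(1.0, np.median(d))],
            bounds=(1e-12, np.inf), maxfev=10000,
        )
        return LDDecayProfile(scope=scope, rho=float(popt[0]), n=n, max_dist=max_dist)
    except Exception:  # non-convergence: fall back, flagged via method field
        log.warning("Hill-Weir fit failed for scope %s; using binned-median fallback", scope)
        return binned()


def decay_profiles_by_chromosome(
    pairs: pd.DataFrame, n: int | None = None, min_pairs: int = 50
) -> dict[str, LDDecayProfile]:
    """Per-chromosome decay profiles plus a genome-wide fallback under key
    ``"genome"``; chromosomes with too few pairs use the genome-wide fit."""
    out = {"genome": fit_ld_decay(pairs, "genome", n=n)}
    for chrom in pairs["chrom"].unique():
        sub = pairs[pairs["chrom"] == chrom]
        if len(sub) >= min_pairs:
            out[str(chrom)] = fit_ld_decay(pairs, str(chrom), n=n)
    return out


# --------------------------------------------------------------------- kinship

def ibs_kinship(geno: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state sharing: mean over markers of 1 - |d_i - d_j| / 2."""
    D = geno.impute_mean().dosages
    n, m = D.shape
    # |d_i - d_j| summed over markers, via the identity on pairwise L1 distance
    K = np.empty((n, n))
    for i in range(n):
        K[i] = 1.0 - np.abs(D - D[i]).sum(axis=1) / (2.0 * m)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return pd.DataFrame(K, index=geno.accessions, columns=geno.accessions)


def vanraden_grm(geno: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden genomic relationship matrix G = ZZ' / (2 * sum p(1-p)).

    Z is the dosage matrix centered at twice the allele frequency; monomorphic
    markers are excluded (count logged).
    """
    g = geno.impute_mean()
    p = g.allele_freq()
    poly = (p > 0) & (p < 1)
    if (~poly).sum():
        log.info("vanraden_grm: excluded %d monomorphic markers", int((~poly).sum()))
    if poly.sum() == 0:
        raise ValueError("no polymorphic markers for GRM")
    Z = g.dosages[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (Z @ Z.T) / denom
    return pd.DataFrame(G, index=g.accessions, columns=g.accessions)
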