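"""QTN validation and LD-based QTL construction.

QTNs from the multi-locus scan are validated with a two-sided Mann-Whitney U
test on the two homozygous allele classes (heterozygotes excluded by default,
an inbred-panel assumption); validated QTNs are merged per chromosome into QTL
blocks by single-linkage clustering with link distance 0.75 x the
chromosome-specific distance at which LD decays to r² = 0.3.  Each block is
represented by its maximum-R² member (ties to the smallest position) and named
``{chrom}_{representative position}``.  QTLs explaining more than 10% of the
phenotypic variance are flagged major; blocks whose members associate with at
least two traits are flagged pleiotropic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .popgen import LDDecayProfile

log = logging.getLogger(__name__)


# -------------------------------------------------------------- allele tests

@dataclass
class AlleleEffectTest:
    marker: str
    trait: str
    n1: int
    n2: int
    u_stat: float
    p: float
    favorable_dosage: int | None  # dosage (0 or 2) of the class with larger mean
    testable: bool = True
    reason: str = ""


def allele_effect_test(
    trait_values: np.ndarray,
    dosages: np.ndarray,
    marker: str = "",
    trait: str = "",
    min_class: int = 2,
    pool_hets: bool = False,
) -> AlleleEffectTest:
    """Two-sided Mann-Whitney U test of the two homozygous allele classes.

    Exact p-value when the smaller class has <= 8 members and there are no
    ties; normal approximation with tie and continuity corrections otherwise.
    Heterozygotes are excluded (or pooled with the minor homozygous class when
    ``pool_hets``).  A class with fewer than ``min_class`` members makes the
    QTN untestable and it is removed upstream with a reason code.
    """
    y = np.asarray(trait_values, dtype=float)
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(d)
    y, d = y[ok], d[ok]
    g0 = y[d == 0]
    g2 = y[d == 2]
    if pool_hets and np.any(d == 1):
        minor = 0 if len(g0) <= len(g2) else 2
        if minor == 0:
            g0 = np.concatenate([g0, y[d == 1]])
        else:
            g2 = np.concatenate([g2, y[d == 1]])
    n1, n2 = len(g0), len(g2)
    if min(n1, n2) < min_class:
        return AlleleEffectTest(marker, trait, n1, n2, np.nan, np.nan, None,
                                testable=False, reason="class_too_small")
    if np.ptp(np.concatenate([g0, g2])) == 0:
        # all values identical: no evidence either way
        return AlleleEffectTest(marker, trait, n1, n2, n1 * n2 / 2.0, 1.0, None)
    has_ties = len(np.unique(np.concatenate([g0, g2]))) < n1 + n2
    method = "exact" if (min(n1, n2) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g0, g2, alternative="two-sided", method=method,
                             use_continuity=True)
    fav = 0 if g0.mean() > g2.mean() else 2
    return AlleleEffectTest(marker, trait, n1, n2, float(res.statistic),
                            float(min(1.0, res.pvalue)), fav)


def validate_qtns(
    qtns: pd.DataFrame,
    traits: pd.DataFrame,
    geno: GenotypeMatrix,
    alpha: float = 0.05,
    pool_hets: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the allele-effect filter over a QTN table.

    Returns (validated QTNs with favorable-allele labels, full test table).
    QTNs whose allele classes are untestable or whose p >= alpha are removed,
    mirroring the false-positive filter of the association pipeline.
    """
    tests = []
    for rec in qtns.itertuples():
        d = geno.dosages[:, geno.marker_index(rec.marker)]
        y = traits[rec.trait].to_numpy(dtype=float)
        t = allele_effect_test(y, d, rec.marker, rec.trait, pool_hets=pool_hets)
        tests.append(t)
    test_df = pd.DataFrame([vars(t) for t in tests])
    keep = test_df["testable"] & (test_df["p"] < alpha)
    validated = qtns.loc[keep.to_numpy()].copy()
    validated["favorable_dosage"] = test_df.loc[keep.to_numpy(), "favorable_dosage"].to_numpy()
    n_rm = len(qtns) - len(validated)
    log.info("validate_qtns: %d QTNs in, %d removed, %d validated",
             len(qtns), n_rm, len(validated))
    return validated.reset_index(drop=True), test_df


# ------------------------------------------------------------------ merging

@dataclass
class QTLRecord:
    qtl_id: str
    chrom: str
    rep_marker: str
    rep_pos: int
    rep_r2: float
    members: list[str] = field(default_factory=list)
    traits: list[str] = field(default_factory=list)
    trait_r2: dict[str, float] = field(default_factory=dict)
    major: bool = False
    pleiotropic: bool = False


def merge_qtns(
    qtns: pd.DataFrame,
    decay: dict[str, LDDecayProfile],
    factor: float = 0.75,
    r2_threshold: float = 0.3,
) -> list[QTLRecord]:
    """Single-linkage clustering of validated QTNs into QTL blocks.

    Link distance per chromosome is ``factor`` x the distance at which the
    chromosome's fitted LD curve decays to ``r2_threshold`` (genome-wide
    profile as fallback).  Clustering is across traits; the representative QTN
    is the max-R² member with ties broken by smallest position.
    """
    if len(qtns) == 0:
        return []
    out: list[QTLRecord] = []
    for chrom, sub in qtns.groupby("chrom", sort=True):
        prof = decay.get(str(chrom), decay.get("genome"))
        if prof is None:
            raise ValueError(f"no LD-decay profile for chromosome {chrom} and no genome-wide fallback")
        d_link = prof.decay_distance(r2_threshold)
        if not np.isfinite(d_link):
            d_link = prof.max_dist
        d_link *= factor
        # de-duplicate markers (same marker may carry several traits)
        sub = sub.sort_values(["pos", "marker"]).reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        uniq_pos = np.unique(pos)
        breaks = np.flatnonzero(np.diff(uniq_pos) > d_link)
        cluster_edges = np.concatenate([[0], breaks + 1, [len(uniq_pos)]])
        for lo, hi in zip(cluster_edges[:-1], cluster_edges[1:]):
            lo_pos, hi_pos = uniq_pos[lo], uniq_pos[hi - 1]
            members = sub[(pos >= lo_pos) & (pos <= hi_pos)]
            # representative: max R2, ties -> smallest position
            rep = members.sort_values(["R2", "pos"], ascending=[False, True]).iloc[0]
            marker_list = sorted(members["marker"].unique())
            trait_list = sorted(members["trait"].unique())
            trait_r2 = members.groupby("trait")["R2"].max().to_dict()
            out.append(QTLRecord(
                qtl_id=f"{chrom}_{int(rep['pos'])}",
                chrom=str(chrom),
                rep_marker=str(rep["marker"]),
                rep_pos=int(rep["pos"]),
                rep_r2=float(rep["R2"]),
                members=marker_list,
                traits=trait_list,
                trait_r2={k: float(v) for k, v in trait_r2.items()},
            ))
    return out


def classify_qtls(qtls: list[QTLRecord], major_r2: float = 10.0) -> list[QTLRecord]:
    """Flag major (representative R² strictly above ``major_r2`` percent) and
    pleiotropic (>= 2 distinct associated traits) QTLs in place."""
    for q in qtls:
        q.major = q.rep_r2 > major_r2
        q.pleiotropic = len(q.traits) >= 2
    return qtls


def qtls_to_frame(qtls: list[QTLRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "qtl_id": q.qtl_id, "chrom": q.chrom, "rep_marker": q.rep_marker,
        "rep_pos": q.rep_pos, "rep_R2": q.rep_r2, "n_members": len(q.members),
        "traits": ";".join(q.traits), "major": q.major, "pleiotropic": q.pleiotropic,
        "members": ";".join(q.members),
    } for q in qtls])


# --------------------------------------------------------------- regression

def qtl_regression(y: np.ndarray, qtl_dosages: np.ndarray) -> tuple[float, float]:
    """OLS of a trait on its representative-QTN dosage columns.

    Returns (R², adjusted R²); raises when predictors are not fewer than
    n - 1 (prune markers first).
    """
    y = np.asarray(y, dtype=float).ravel()
    Xq = np.atleast_2d(np.asarray(qtl_dosages, dtype=float))
    if Xq.shape[0] != len(y):
        Xq = Xq.T
    n, p = Xq.shape
    if p >= n - 1:
        raise ValueError(f"{p} predictors for {n} observations: prune markers (need p < n - 1)")
    X = np.column_stack([np.ones(n), Xq])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2, adj


# --------------------------------------------------------- favorable alleles

def count_favorable_alleles(
    traits: pd.DataFrame,
    qtls: list[QTLRecord],
    validated_qtns: pd.DataFrame,
    geno: GenotypeMatrix,
    trait: str,
    decile: float = 0.10,
) -> pd.DataFrame:
    """Per-accession favorable-QTL counts for one trait, with decile groups.

    An accession scores a QTL when it is homozygous for the allele class with
    the larger trait mean at the representative QTN; heterozygous calls count
    as non-favorable (logged).  Decile membership uses round(decile * n).
    """
    fav = validated_qtns.set_index(["marker", "trait"])["favorable_dosage"]
    counts = np.zeros(geno.n_accessions, dtype=int)
    n_het = 0
    n_qtl_trait = 0
    for q in qtls:
        if trait not in q.traits:
            continue
        key = (q.rep_marker, trait)
        if key not in fav.index:
            # representative found for another trait; use any member for this trait
            members_for_trait = [(m, trait) for m in q.members if (m, trait) in fav.index]
            if not members_for_trait:
                continue
            key = members_for_trait[0]
        n_qtl_trait += 1
        d = geno.dosages[:, geno.marker_index(key[0])]
        n_het += int(np.sum(d == 1))
        counts += (d == fav.loc[key]).astype(int)
    if n_het:
        log.info("count_favorable_alleles: %d heterozygous calls counted non-favorable", n_het)
    vals = traits[trait]
    df = pd.DataFrame({
        "accession": list(geno.accessions),
        "trait_value": vals.reindex(geno.accessions).to_numpy(),
        "favorable_count": counts,
        "n_qtl": n_qtl_trait,
    })
    k = int(round(decile * len(df)))
    order = df["trait_value"].rank(method="first", ascending=False)
    df["decile_group"] = np.where(order <= k, "top",
                                  np.where(order > len(df) - k, "bottom", "mid"))
    return df
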