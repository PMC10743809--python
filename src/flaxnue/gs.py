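"""GWAS-assisted genomic selection.

Five marker sets are compared for predicting the nitrogen-use-efficiency
stress tolerance index (NUE_STI):

* M1 — a seeded random sample of genome-wide markers;
* M2 — representative QTNs of QTLs associated with any trait measured under
  nitrogen deficiency;
* M3 — representative QTNs of QTLs associated with the target trait itself;
* M4 — representative QTNs of QTLs for traits significantly positively
  correlated with the target (the target is in its own group, so M3 ⊆ M4);
* M5 — M4 restricted to QTLs whose ±100 kb window harbors at least one DEG.

Markers are coded +1 for the favorable homozygote, -1 for the alternative
homozygote (0 for a heterozygote, an extension for residual heterozygosity).
GBLUP uses the realized relationship G = WW'/m with REML variance components
(deterministic, equivalent in expectation to the Bayesian engine it stands in
for) and repeated k-fold cross-validation; accuracy is the Pearson
correlation between predicted genetic values and observed phenotypes in the
held-out fold.  Marker sets are compared by one-way ANOVA with Tukey HSD and
a compact letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .mlgwas import fit_null_vc
from .qtl import QTLRecord

log = logging.getLogger(__name__)

SET_IDS = ["M1", "M2", "M3", "M4", "M5"]


@dataclass
class MarkerSet:
    set_id: str
    markers: list[str]
    rule: str = ""


def build_marker_sets(
    geno: GenotypeMatrix,
    qtls: list[QTLRecord],
    trait_corr_r: pd.DataFrame,
    trait_corr_p: pd.DataFrame,
    coloc_hits: list | None,
    target: str = "NUE_STI",
    m1_size: int = 1000,
    seed: int = 0,
    correlation_gate: str = "p<0.05",
) -> dict[str, MarkerSet]:
    """Construct the five marker sets from the QTL pipeline outputs.

    ``correlation_gate`` controls whether M4's "positively correlated" means
    r > 0 with p < 0.05 (default) or any r > 0 ("none").  Raises when a set
    comes out empty, naming it.
    """
    rng = np.random.default_rng(seed)
    m1_size = min(m1_size, geno.n_markers)
    m1 = [geno.marker_ids[i] for i in sorted(rng.choice(geno.n_markers, size=m1_size, replace=False))]

    def reps(selector) -> list[str]:
        return sorted({q.rep_marker for q in qtls if selector(q)})

    m2 = reps(lambda q: any(t.endswith("_N-") for t in q.traits))
    m3 = reps(lambda q: target in q.traits)
    if target not in trait_corr_r.columns:
        raise ValueError(f"target trait {target!r} absent from the correlation matrix")
    r_col = trait_corr_r[target]
    p_col = trait_corr_p[target]
    if correlation_gate == "none":
        pos = set(r_col[r_col > 0].index)
    else:
        pos = set(r_col[(r_col > 0) & (p_col < 0.05)].index)
    pos.add(target)
    m4 = reps(lambda q: any(t in pos for t in q.traits))
    deg_qtls = {h.qtl_id for h in coloc_hits if h.degs} if coloc_hits else set()
    m5 = reps(lambda q: any(t in pos for t in q.traits) and q.qtl_id in deg_qtls)
    sets = {
        "M1": MarkerSet("M1", m1, f"random genome-wide sample (n={len(m1)})"),
        "M2": MarkerSet("M2", m2, "QTL representatives for traits under N-"),
        "M3": MarkerSet("M3", m3, f"QTL representatives for {target}"),
        "M4": MarkerSet("M4", m4, f"QTL representatives for traits positively correlated with {target}"),
        "M5": MarkerSet("M5", m5, "M4 restricted to QTLs whose window harbors a DEG"),
    }
    for sid, ms in sets.items():
        if not ms.markers:
            raise ValueError(f"marker set {sid} is empty ({ms.rule})")
    return sets


def encode_markers(
    geno: GenotypeMatrix,
    markers: list[str],
    favorable: dict[str, int] | None = None,
    allow_frequency_fallback: bool = False,
) -> pd.DataFrame:
    """Code an accession x marker matrix as +1/-1 (favorable/alternative
    homozygote), 0 for heterozygotes.

    ``favorable`` maps marker id -> favorable homozygous dosage (0 or 2) from
    the allele-effect tests.  Markers without an entry raise, unless
    ``allow_frequency_fallback`` (used for the random genome-wide set, where
    no allele test exists): the alternate allele is then treated as favorable
    with a warning — GBLUP predictions are invariant to this sign choice.
    """
    favorable = favorable or {}
    cols = {}
    n_fallback = 0
    d = geno.impute_mean()
    for m in markers:
        x = d.dosages[:, d.marker_index(m)]
        if m in favorable and favorable[m] is not None:
            sign = 1.0 if favorable[m] == 2 else -1.0
        elif allow_frequency_fallback:
            sign = 1.0
            n_fallback += 1
        else:
            raise ValueError(f"marker {m} has no allele-effect test; cannot define the favorable allele")
        cols[m] = sign * (x - 1.0)
    if n_fallback:
        log.warning("encode_markers: %d markers coded by frequency fallback (no allele test)", n_fallback)
    return pd.DataFrame(cols, index=geno.accessions)


@dataclass
class CVResult:
    table: pd.DataFrame  # set_id, repeat, fold, r, n_test
    seed: int
    n_constant_folds: int = 0


def gblup_cv(
    y: np.ndarray | pd.Series,
    coded: pd.DataFrame,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    set_id: str = "",
) -> CVResult:
    """Repeated k-fold GBLUP cross-validation.

    Per repeat, accessions are randomly partitioned into ``k`` folds; the
    relationship matrix G = WW'/m uses all accessions, variance components
    are REML-fitted on the training block, and held-out genetic values are
    ĝ_test = G_ts (G_tt + δ̂ I)⁻¹ (y_train − μ̂) with the GLS intercept μ̂.
    Folds with constant observed y yield no accuracy (flagged and counted).
    Deterministic under ``seed``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} accessions for {k}-fold CV")
    if np.isnan(y).any():
        raise ValueError("phenotype contains missing values")
    W = coded.to_numpy(dtype=float)
    m = W.shape[1]
    G = W @ W.T / m
    rng = np.random.default_rng(seed)
    rows = []
    n_const = 0
    for rep in range(1, repeats + 1):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fi, test in enumerate(folds, start=1):
            train = np.setdiff1d(perm, test)
            G_tt = G[np.ix_(train, train)]
            G_st = G[np.ix_(test, train)]
            y_tr = y[train]
            vc = fit_null_vc(y_tr, G_tt)
            delta = vc.delta if np.isfinite(vc.delta) else 1e12
            A = G_tt + delta * np.eye(len(train))
            try:
                Ainv_1 = np.linalg.solve(A, np.ones(len(train)))
                mu = float(Ainv_1 @ y_tr / Ainv_1.sum())
                g_hat = G_st @ np.linalg.solve(A, y_tr - mu)
            except np.linalg.LinAlgError:
                log.warning("gblup_cv: singular training system, adding ridge jitter")
                A = A + 1e-8 * np.eye(len(train))
                Ainv_1 = np.linalg.solve(A, np.ones(len(train)))
                mu = float(Ainv_1 @ y_tr / Ainv_1.sum())
                g_hat = G_st @ np.linalg.solve(A, y_tr - mu)
            y_te = y[test]
            if np.std(y_te) == 0 or np.std(g_hat) == 0:
                n_const += 1
                r = np.nan
            else:
                r = float(np.corrcoef(g_hat, y_te)[0, 1])
            rows.append((set_id, rep, fi, r, len(test)))
    tab = pd.DataFrame(rows, columns=["set_id", "repeat", "fold", "r", "n_test"])
    if n_const:
        log.info("gblup_cv[%s]: %d folds with undefined accuracy excluded from means", set_id, n_const)
    return CVResult(tab, seed, n_const)


def run_gs_comparison(
    y: np.ndarray | pd.Series,
    geno: GenotypeMatrix,
    marker_sets: dict[str, MarkerSet],
    favorable: dict[str, int],
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate every marker set on the same fold sequence."""
    parts = []
    for sid in sorted(marker_sets):
        ms = marker_sets[sid]
        coded = encode_markers(geno, ms.markers, favorable,
                               allow_frequency_fallback=(sid == "M1"))
        parts.append(gblup_cv(y, coded, k=k, repeats=repeats, seed=seed, set_id=sid).table)
    return pd.concat(parts, ignore_index=True)


# ------------------------------------------------------------------ comparison

def compare_sets(cv: pd.DataFrame) -> dict:
    """One-way ANOVA over marker sets, Tukey HSD and compact letters.

    Returns a dict with keys ``anova`` (F, p, dfs), ``tukey`` (pairwise
    table), ``letters`` (set -> letter string; sets sharing a letter are not
    significantly different at 0.05) and ``means`` (per-set mean/SD/count).
    Degenerate zero-within-variance input is flagged and handled without the
    studentized-range machinery.
    """
    cv = cv.dropna(subset=["r"])
    sets = sorted(cv["set_id"].unique())
    if len(sets) < 2:
        raise ValueError("need at least 2 marker sets to compare")
    groups = [cv.loc[cv["set_id"] == s, "r"].to_numpy() for s in sets]
    sizes = {s: len(g) for s, g in zip(sets, groups)}
    means = pd.DataFrame({
        "set_id": sets,
        "mean_r": [g.mean() for g in groups],
        "sd_r": [g.std(ddof=1) if len(g) > 1 else 0.0 for g in groups],
        "n": [len(g) for g in groups],
    }).set_index("set_id")
    within_var = np.sum([np.sum((g - g.mean()) ** 2) for g in groups])
    degenerate = within_var <= 0
    if degenerate:
        log.warning("compare_sets: zero within-group variance; degenerate comparison")
        pairs = []
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                same = np.isclose(groups[i].mean(), groups[j].mean())
                pairs.append((sets[i], sets[j], 0.0, 1.0 if same else 0.0))
        tukey = pd.DataFrame(pairs, columns=["set_a", "set_b", "meandiff", "p_adj"])
        tukey["meandiff"] = [means.loc[b, "mean_r"] - means.loc[a, "mean_r"]
                             for a, b in zip(tukey["set_a"], tukey["set_b"])]
        anova = {"F": np.inf if len(set(means["mean_r"].round(12))) > 1 else 0.0,
                 "p": np.nan, "df_between": len(sets) - 1,
                 "df_within": int(sum(sizes.values())) - len(sets), "degenerate": True}
    else:
        F, p = stats.f_oneway(*groups)
        anova = {"F": float(F), "p": float(p), "df_between": len(sets) - 1,
                 "df_within": int(sum(sizes.values())) - len(sets), "degenerate": False}
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        th = pairwise_tukeyhsd(cv["r"].to_numpy(), cv["set_id"].to_numpy(), alpha=0.05)
        tukey = pd.DataFrame(th.summary().data[1:], columns=th.summary().data[0])
        tukey = tukey.rename(columns={"group1": "set_a", "group2": "set_b",
                                      "p-adj": "p_adj"})[["set_a", "set_b", "meandiff", "p_adj"]]
        tukey["p_adj"] = tukey["p_adj"].astype(float)
        tukey["meandiff"] = tukey["meandiff"].astype(float)
    letters = _compact_letters(sets, means["mean_r"], tukey)
    return {"anova": anova, "tukey": tukey, "letters": letters, "means": means.reset_index()}


def _compact_letters(sets: list[str], means: pd.Series, tukey: pd.DataFrame,
                     alpha: float = 0.05) -> dict[str, str]:
    """Greedy compact letter display: sets sharing a letter are not
    significantly different."""
    ns_pairs = set()
    for rec in tukey.itertuples():
        if rec.p_adj >= alpha:
            ns_pairs.add(frozenset((rec.set_a, rec.set_b)))

    def compatible(s: str, grp: set[str]) -> bool:
        return all(frozenset((s, t)) in ns_pairs for t in grp)

    order = sorted(sets, key=lambda s: -means[s])
    groups: list[set[str]] = []
    for s in order:
        placed = False
        for grp in groups:
            if compatible(s, grp):
                grp.add(s)
                placed = True
        if not placed:
            groups.append({s})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {s: "" for s in sets}
    for gi, grp in enumerate(groups):
        for s in grp:
            out[s] += alphabet[gi % len(alphabet)]
    return {s: "".join(sorted(v)) for s, v in out.items()}
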