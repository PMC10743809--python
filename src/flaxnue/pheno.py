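"""Derivation of the 21 nitrogen-use-efficiency seedling traits.

From replicate-level measurements of root traits (TRL, RV, RT), biomass
compartments (PDW, SDW, RDW) and shoot/root nitrogen content under an optimum
(N+) and a deficient (N-) nitrate treatment, this module produces:

* per-accession best linear unbiased estimates (for a balanced completely
  randomized design these are the replicate means; unbalanced designs use a
  two-factor fixed-effect least-squares fit),
* the 21-trait table: six base traits per treatment, five stability indices
  (100 x trait_N- / trait_N+), NUE under each treatment
  (NUE = PDW / plant N content, with plant N = shoot N + root N), the NUE
  stability index, and the Fernandez stress tolerance index
  NUE_STI = (Yp * Ys) / Ybar_p^2 with Yp = NUE_N+, Ys = NUE_N-,
* Table-style summaries (mean, SD, range, CV%), two-factor effect tests and
  Pearson trait correlations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

TREATMENTS = ["N+", "N-"]

#: the 21 derived trait columns, in fixed order
TRAIT_COLUMNS = [
    "TRL_N+", "TRL_N-", "RV_N+", "RV_N-", "RT_N+", "RT_N-",
    "PDW_N+", "PDW_N-", "SDW_N+", "SDW_N-", "R/S_N+", "R/S_N-",
    "TRL_Index", "RV_Index", "RT_Index", "PDW_Index", "SDW_Index",
    "NUE_N+", "NUE_N-", "NUE_Index", "NUE_STI",
]

_INDEX_BASES = ["TRL", "RV", "RT", "PDW", "SDW"]


def _normalize_treatment(t: pd.Series) -> pd.Series:
    """Accept both the ASCII hyphen and the typographic minus in labels."""
    return t.astype(str).str.replace("−", "-", regex=False)


def compute_blues(raw: pd.DataFrame) -> pd.DataFrame:
    """Accession x (trait, treatment) best linear unbiased estimates.

    For a balanced completely randomized design this is the arithmetic
    replicate mean.  With unbalanced replication the estimate is the
    least-squares accession mean from a two-factor (accession + replicate)
    fixed-effect fit, averaged over replicate levels.  Raises if any
    accession x treatment x trait cell is empty.
    """
    raw = raw.copy()
    raw["treatment"] = _normalize_treatment(raw["treatment"])
    accs = sorted(raw["accession"].unique())
    out = {}
    for (trait, treat), sub in raw.groupby(["trait", "treatment"]):
        counts = sub.groupby("accession")["value"].size().reindex(accs)
        if counts.isna().any():
            missing = counts[counts.isna()].index.tolist()
            raise ValueError(
                f"empty cell(s) for trait {trait!r} under {treat!r}: {missing[:5]}"
            )
        if counts.nunique() == 1 and sub.groupby("accession")["replicate"].apply(
                frozenset).nunique() == 1:
            est = sub.groupby("accession")["value"].mean()
        else:
            est = _lsq_cell_means(sub)
        out[f"{trait}_{treat}"] = est.reindex(accs)
    df = pd.DataFrame(out, index=pd.Index(accs, name="accession"))
    return df


def _lsq_cell_means(sub: pd.DataFrame) -> pd.Series:
    """Least-squares accession means from y ~ accession + replicate."""
    acc = pd.Categorical(sub["accession"])
    rep = pd.Categorical(sub["replicate"])
    A = pd.get_dummies(acc, dtype=float).to_numpy()
    R = pd.get_dummies(rep, drop_first=True, dtype=float).to_numpy()
    X = np.column_stack([A, R]) if R.size else A
    y = sub["value"].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    alpha = coef[: A.shape[1]]
    rep_eff = np.concatenate([[0.0], coef[A.shape[1]:]])
    blue = alpha + rep_eff.mean()
    return pd.Series(blue, index=list(acc.categories))


def derive_traits(blues: pd.DataFrame) -> pd.DataFrame:
    """Build the 21-trait table from accession x treatment base-trait means.

    Requires columns ``{trait}_{treatment}`` for TRL, RV, RT, PDW, SDW, RDW,
    shootN and rootN.  Accessions with a zero denominator (trait_N+ = 0 for an
    index, or zero plant N content) are excluded with a logged count.
    """
    needed = [f"{t}_{tr}" for t in ("TRL", "RV", "RT", "PDW", "SDW", "RDW", "shootN", "rootN")
              for tr in TREATMENTS]
    missing = [c for c in needed if c not in blues.columns]
    if missing:
        raise ValueError(f"missing base-trait columns: {missing}")
    b = blues.copy()
    plant_n = {tr: b[f"shootN_{tr}"] + b[f"rootN_{tr}"] for tr in TREATMENTS}
    bad = pd.Series(False, index=b.index)
    for x in _INDEX_BASES:
        bad |= b[f"{x}_N+"] == 0
    for tr in TREATMENTS:
        bad |= plant_n[tr] <= 0
        bad |= b[f"SDW_{tr}"] == 0
    if bad.any():
        log.warning("derive_traits: excluded %d accession(s) with zero denominators", int(bad.sum()))
        b = b[~bad]
        plant_n = {tr: plant_n[tr][~bad] for tr in TREATMENTS}

    out = pd.DataFrame(index=b.index)
    for x in ("TRL", "RV", "RT", "PDW", "SDW"):
        for tr in TREATMENTS:
            out[f"{x}_{tr}"] = b[f"{x}_{tr}"]
    for tr in TREATMENTS:
        out[f"R/S_{tr}"] = b[f"RDW_{tr}"] / b[f"SDW_{tr}"]
    for x in _INDEX_BASES:
        out[f"{x}_Index"] = 100.0 * b[f"{x}_N-"] / b[f"{x}_N+"]
    for tr in TREATMENTS:
        out[f"NUE_{tr}"] = b[f"PDW_{tr}"] / plant_n[tr]
    out["NUE_Index"] = 100.0 * out["NUE_N-"] / out["NUE_N+"]
    out["NUE_STI"] = out["NUE_N+"] * out["NUE_N-"] / out["NUE_N+"].mean() ** 2
    return out[TRAIT_COLUMNS]


def summarize_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-trait mean, sample SD, range and CV% (missing when the mean is 0)."""
    if len(traits) < 2:
        raise ValueError("need at least 2 accessions to summarize")
    mean = traits.mean()
    sd = traits.std(ddof=1)
    cv = 100.0 * sd / mean
    cv[mean == 0] = np.nan
    return pd.DataFrame({
        "mean": mean,
        "sd": sd,
        "min": traits.min(),
        "max": traits.max(),
        "cv_pct": cv,
    })


def test_effects(raw: pd.DataFrame) -> pd.DataFrame:
    """Two-factor effect tests (treatment, genotype, interaction) per trait.

    Fixed-effects two-way analysis of variance on replicate-level data.  A
    balanced design uses the classical sums-of-squares decomposition; an
    unbalanced one falls back to a type-II ANOVA via statsmodels.  Without
    replication the interaction is not estimable and its p-value is missing.
    """
    raw = raw.copy()
    raw["treatment"] = _normalize_treatment(raw["treatment"])
    rows = {}
    for trait, sub in raw.groupby("trait"):
        tab = sub.pivot_table(index="accession", columns=["treatment", "replicate"],
                              values="value")
        n_cells = sub.groupby(["accession", "treatment"])["value"].size()
        balanced = n_cells.nunique() == 1 and not tab.isna().any().any()
        if balanced:
            rows[trait] = _balanced_two_way(sub)
        else:
            rows[trait] = _anova_type2(sub)
    return pd.DataFrame(rows).T.rename_axis("trait")


def _balanced_two_way(sub: pd.DataFrame) -> pd.Series:
    y = sub["value"].to_numpy(dtype=float)
    a = pd.Categorical(sub["treatment"])
    b = pd.Categorical(sub["accession"])
    I, J = len(a.categories), len(b.categories)
    r = len(sub) // (I * J)
    grand = y.mean()
    mean_a = sub.groupby("treatment")["value"].mean().to_numpy()
    mean_b = sub.groupby("accession")["value"].mean().to_numpy()
    mean_ab = sub.groupby(["treatment", "accession"])["value"].mean().unstack().to_numpy()
    ss_a = J * r * np.sum((mean_a - grand) ** 2)
    ss_b = I * r * np.sum((mean_b - grand) ** 2)
    ss_ab = r * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_e = ss_tot - ss_a - ss_b - ss_ab
    df_a, df_b, df_ab = I - 1, J - 1, (I - 1) * (J - 1)
    df_e = I * J * (r - 1)
    if df_e == 0:  # no replication: interaction absorbed into error
        ms_e = ss_ab / df_ab if df_ab > 0 else np.nan
        p_a = stats.f.sf(ss_a / df_a / ms_e, df_a, df_ab)
        p_b = stats.f.sf(ss_b / df_b / ms_e, df_b, df_ab)
        return pd.Series({"p_treatment": p_a, "p_genotype": p_b, "p_interaction": np.nan})
    ms_e = ss_e / df_e
    if ms_e <= 0:
        return pd.Series({"p_treatment": np.nan, "p_genotype": np.nan, "p_interaction": np.nan})
    p_a = stats.f.sf(ss_a / df_a / ms_e, df_a, df_e)
    p_b = stats.f.sf(ss_b / df_b / ms_e, df_b, df_e)
    p_ab = stats.f.sf(ss_ab / df_ab / ms_e, df_ab, df_e)
    return pd.Series({"p_treatment": p_a, "p_genotype": p_b, "p_interaction": p_ab})


def _anova_type2(sub: pd.DataFrame) -> pd.Series:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = sub.rename(columns={"value": "y"}).copy()
    d["treatment"] = d["treatment"].astype("category")
    d["accession"] = d["accession"].astype("category")
    has_rep = d.groupby(["accession", "treatment"], observed=True)["y"].size().max() > 1
    formula = "y ~ C(treatment) * C(accession)" if has_rep else "y ~ C(treatment) + C(accession)"
    fit = smf.ols(formula, data=d).fit()
    an = sm.stats.anova_lm(fit, typ=2)
    get = lambda k: float(an.loc[k, "PR(>F)"]) if k in an.index else np.nan
    return pd.Series({
        "p_treatment": get("C(treatment)"),
        "p_genotype": get("C(accession)"),
        "p_interaction": get("C(treatment):C(accession)"),
    })


def correlate_traits(traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation and p-value matrices over pairwise-complete pairs.

    Zero-variance traits yield missing correlations for their pairs.
    """
    cols = list(traits.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            x, y = traits[cols[i]], traits[cols[j]]
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(x[ok], y[ok])
            r.iloc[i, j] = r.iloc[j, i] = rv
            p.iloc[i, j] = p.iloc[j, i] = pv
    return r, p
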