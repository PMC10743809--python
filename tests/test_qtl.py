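"""Allele-effect validation, QTL merging, classification and favorable alleles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flaxnue import qtl
from flaxnue.genotypes import GenotypeMatrix
from flaxnue.popgen import LDDecayProfile


def _flat_decay(dist_at_03: float, max_dist: float = 1e9) -> dict:
    """Profile whose decay_distance(0.3) is exactly `dist_at_03`."""
    prof = LDDecayProfile(scope="genome", rho=None, n=100, max_dist=max_dist,
                          method="binned-median",
                          bin_mid=np.array([0.0, dist_at_03, max_dist]),
                          bin_r2=np.array([1.0, 0.3, 0.0]))
    return {"genome": prof}


def _enumerated_mw_p(a, b):
    """Full-enumeration two-sided Mann-Whitney p-value (tie-aware)."""
    pool = list(a) + list(b)
    n1 = len(a)

    def u_stat(ga, gb):
        return sum((x < y) + 0.5 * (x == y) for x in ga for y in gb)

    mu = n1 * len(b) / 2.0
    obs = abs(u_stat(a, b) - mu)
    devs = []
    for idx in combinations(range(len(pool)), n1):
        ga = [pool[i] for i in idx]
        gb = [pool[i] for i in range(len(pool)) if i not in idx]
        devs.append(abs(u_stat(ga, gb) - mu))
    return float(np.mean(np.asarray(devs) >= obs - 1e-12))


# ------------------------------------------------------------- allele tests

def test_mw_exact_p_one_third():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    d = np.array([0.0, 0.0, 2.0, 2.0])
    t = qtl.allele_effect_test(y, d)
    assert t.p == pytest.approx(1.0 / 3.0, abs=1e-12)
    assert t.favorable_dosage == 2


@pytest.mark.parametrize("n1,n2", [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4)])
def test_mw_exact_matches_full_enumeration(n1, n2, rng):
    """Exact p agrees with brute-force enumeration for all sizes <= (4,4)."""
    for _ in range(5):
        a = list(np.round(rng.standard_normal(n1), 3))
        b = list(np.round(rng.standard_normal(n2), 3))
        y = np.array(a + b)
        d = np.array([0.0] * n1 + [2.0] * n2)
        t = qtl.allele_effect_test(y, d)
        assert t.p == pytest.approx(_enumerated_mw_p(a, b), abs=1e-10)


def test_mw_all_ties_p_one():
    y = np.array([5.0] * 6)
    d = np.array([0.0, 0.0, 0.0, 2.0, 2.0, 2.0])
    t = qtl.allele_effect_test(y, d)
    assert t.p == 1.0


def test_mw_small_class_untestable():
    y = np.arange(6, dtype=float)
    d = np.array([0.0, 2.0, 2.0, 2.0, 2.0, 2.0])
    t = qtl.allele_effect_test(y, d)
    assert not t.testable and t.reason == "class_too_small"


def test_mw_type1_rate(rng):
    rej = 0
    n_runs = 2000
    for _ in range(n_runs):
        y = rng.standard_normal(60)
        d = np.array([0.0] * 30 + [2.0] * 30)
        if qtl.allele_effect_test(y, d).p < 0.05:
            rej += 1
    assert 0.035 <= rej / n_runs <= 0.065


# ------------------------------------------------------------------ merging

def _qtn_frame(rows):
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "trait",
                                       "effect", "LOD", "p", "R2", "models"])


def test_merge_distance_rule():
    decay = _flat_decay(10_000 / 0.75)  # link distance exactly 10 kb
    close = _qtn_frame([("m1", "Lu1", 10_000, "t", 1, 4, 1e-5, 5, "a"),
                        ("m2", "Lu1", 12_000, "t", 1, 4, 1e-5, 6, "a")])
    apart = _qtn_frame([("m1", "Lu1", 10_000, "t", 1, 4, 1e-5, 5, "a"),
                        ("m2", "Lu1", 25_000, "t", 1, 4, 1e-5, 6, "a")])
    assert len(qtl.merge_qtns(close, decay)) == 1
    assert len(qtl.merge_qtns(apart, decay)) == 2


def test_merge_chain_linkage_and_representative():
    decay = _flat_decay(10_000 / 0.75)
    q = _qtn_frame([("m1", "Lu1", 1, "t", 1, 4, 1e-5, 5.0, "a"),
                    ("m2", "Lu1", 9_001, "t", 1, 4, 1e-5, 9.0, "a"),
                    ("m3", "Lu1", 18_001, "t", 1, 4, 1e-5, 2.0, "a")])
    out = qtl.merge_qtns(q, decay)
    assert len(out) == 1
    assert out[0].rep_marker == "m2"
    assert out[0].qtl_id == "Lu1_9001"
    assert out[0].rep_r2 == max(m for m in (5.0, 9.0, 2.0))


def test_merge_constructed_cluster_count(rng):
    """Positions constructed with gaps strictly below or above the link
    distance reproduce the planned cluster count exactly."""
    link = 10_000.0
    decay = _flat_decay(link / 0.75)
    pos, truth = [], 0
    cur = 1000
    for _ in range(120):
        if rng.random() < 0.4:  # new cluster
            cur += int(link * rng.uniform(1.5, 3.0))
            truth += 1
        else:
            cur += int(link * rng.uniform(0.1, 0.9))
        pos.append(cur)
    truth += 0 if truth else 1
    rows = [(f"m{i}", "Lu1", p, "t", 1, 4, 1e-5, float(rng.uniform(1, 20)), "a")
            for i, p in enumerate(pos)]
    out = qtl.merge_qtns(_qtn_frame(rows), decay)
    # recompute ground truth from the realized gaps
    gaps = np.diff(sorted(pos))
    expected = 1 + int(np.sum(gaps > link))
    assert len(out) == expected


def test_merge_invariant_to_input_order(rng):
    decay = _flat_decay(8_000 / 0.75)
    rows = [(f"m{i}", "Lu1", int(p), "t", 1, 4, 1e-5, float(r), "a")
            for i, (p, r) in enumerate(zip(rng.choice(10**6, 50, replace=False),
                                           rng.uniform(1, 30, 50)))]
    q = _qtn_frame(rows)
    a = qtl.qtls_to_frame(qtl.merge_qtns(q, decay))
    b = qtl.qtls_to_frame(qtl.merge_qtns(q.sample(frac=1, random_state=0), decay))
    pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))


def test_no_qtn_in_two_qtls(rng):
    decay = _flat_decay(5_000 / 0.75)
    rows = [(f"m{i}", "Lu1", int(p), f"t{i % 3}", 1, 4, 1e-5, 5.0, "a")
            for i, p in enumerate(sorted(rng.choice(10**6, 60, replace=False)))]
    out = qtl.merge_qtns(_qtn_frame(rows), decay)
    members = [m for q_ in out for m in q_.members]
    assert len(members) == len(set(members))


def test_merge_missing_decay_raises():
    q = _qtn_frame([("m1", "Lu1", 100, "t", 1, 4, 1e-5, 5, "a")])
    with pytest.raises(ValueError, match="decay"):
        qtl.merge_qtns(q, {})


# ----------------------------------------------------------- classification

def test_classification_boundaries():
    recs = [
        qtl.QTLRecord("Lu1_1", "Lu1", "m1", 1, rep_r2=10.0, members=["m1"], traits=["a"]),
        qtl.QTLRecord("Lu1_2", "Lu1", "m2", 2, rep_r2=10.01, members=["m2"], traits=["a"]),
        qtl.QTLRecord("Lu1_3", "Lu1", "m3", 3, rep_r2=4.0, members=["m3"],
                      traits=["NUE_N-", "RV_N-"]),
    ]
    out = qtl.classify_qtls(recs)
    assert not out[0].major          # strictly greater than 10
    assert out[1].major
    assert out[2].pleiotropic
    assert not out[0].pleiotropic


# -------------------------------------------------------------- regression

def test_regression_perfect_predictor(rng):
    y = rng.standard_normal(50)
    r2, adj = qtl.qtl_regression(y, y.reshape(-1, 1))
    assert r2 == pytest.approx(1.0) and adj == pytest.approx(1.0)


def test_regression_adjusted_formula():
    """n=100, p=1, R2=0.5 -> adjR2 = 1 - 0.5*99/98."""
    rng = np.random.default_rng(12)
    n = 100
    x = rng.standard_normal(n)
    # construct y with R2 exactly 0.5 against x
    e = rng.standard_normal(n)
    x_c = x - x.mean()
    e_c = e - e.mean()
    e_c -= x_c * (x_c @ e_c) / (x_c @ x_c)  # orthogonalize in centered space
    y = x_c / x_c.std() + e_c / e_c.std()
    r2, adj = qtl.qtl_regression(y, x.reshape(-1, 1))
    assert r2 == pytest.approx(0.5, abs=1e-9)
    assert adj == pytest.approx(1 - 0.5 * 99 / 98, abs=1e-9)


def test_regression_too_many_predictors(rng):
    with pytest.raises(ValueError, match="prune"):
        qtl.qtl_regression(rng.standard_normal(10), rng.standard_normal((10, 9)))


def test_regression_recovers_planted_band(medium_geno):
    """~10 planted QTLs totalling ~60% genetic variance: fitted adjR2 lands in
    a broad recovery band."""
    from flaxnue import pheno, synth
    rng = np.random.default_rng(9)
    var_d = medium_geno.dosages.var(axis=0)
    idx = rng.choice(np.flatnonzero(var_d > 0.3), 10, replace=False)
    sd_tab = synth.DEFAULT_TRAIT_SCALE[("TRL", "N+")][1]
    adjs = []
    for seed in range(5):
        qtls = [synth.PlantedQTL(medium_geno.marker_ids[i], "TRL",
                                 float(np.sqrt(0.06 * sd_tab**2 / var_d[i])))
                for i in idx]
        plan = synth.QTLPlan(qtls=qtls, h2={t: 0.65 for t in synth.BASE_TRAITS})
        raw = synth.simulate_phenotypes(medium_geno, plan, n_reps=3, seed=800 + seed)
        y = pheno.compute_blues(raw)["TRL_N+"].to_numpy()
        _, adj = qtl.qtl_regression(y, medium_geno.dosages[:, idx])
        adjs.append(adj)
    assert 0.4 <= np.mean(adjs) <= 0.75


# ------------------------------------------------------- favorable alleles

def _mini_setup(rng, n=40, n_qtl=10):
    d = rng.choice([0.0, 2.0], size=(n, n_qtl))
    geno = GenotypeMatrix(d, [f"A{i}" for i in range(n)],
                          np.repeat("Lu1", n_qtl),
                          np.arange(1, n_qtl + 1) * 200_000)
    y = d.sum(axis=1) + 0.5 * rng.standard_normal(n)  # allele 2 always favorable
    traits = pd.DataFrame({"T": y}, index=geno.accessions)
    qtns = pd.DataFrame({
        "marker": geno.marker_ids, "chrom": "Lu1", "pos": geno.pos, "trait": "T",
        "effect": 1.0, "LOD": 5.0, "p": 1e-6, "R2": 5.0, "models": "a",
        "favorable_dosage": 2,
    })
    recs = [qtl.QTLRecord(f"Lu1_{p}", "Lu1", m, int(p), 5.0, [m], ["T"])
            for m, p in zip(geno.marker_ids, geno.pos)]
    return geno, traits, qtns, recs


def test_favorable_count_all_favorable(rng):
    geno, traits, qtns, recs = _mini_setup(rng)
    best = int(np.argmax(geno.dosages.sum(axis=1)))
    df = qtl.count_favorable_alleles(traits, recs, qtns, geno, "T")
    expected = int((geno.dosages[best] == 2).sum())
    assert df.loc[df.accession == geno.accessions[best], "favorable_count"].iloc[0] == expected


def test_decile_size_round_rule():
    """123 accessions -> decile groups of round(0.1 * 123) = 12."""
    rng = np.random.default_rng(1)
    geno, traits, qtns, recs = _mini_setup(rng, n=123)
    df = qtl.count_favorable_alleles(traits, recs, qtns, geno, "T")
    assert (df.decile_group == "top").sum() == 12
    assert (df.decile_group == "bottom").sum() == 12


def test_favorable_count_correlates_with_trait(rng):
    geno, traits, qtns, recs = _mini_setup(rng, n=300)
    df = qtl.count_favorable_alleles(traits, recs, qtns, geno, "T")
    rho, p = sps.spearmanr(df.favorable_count, df.trait_value)
    assert rho > 0 and p < 0.05
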