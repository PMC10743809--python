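"""Generator properties: frequency control, structure, LD, additivity, counts."""

import numpy as np
import pandas as pd
import pytest

from flaxnue import popgen, synth
from flaxnue.synth import CountsPlan, GenomeSpec, PlantedQTL, QTLPlan


def test_genotypes_deterministic_and_maf_controlled():
    spec = GenomeSpec(n_chromosomes=2, n_markers_per_chrom=150, n_accessions=80, seed=5)
    g1 = synth.simulate_genotypes(spec)
    g2 = synth.simulate_genotypes(spec)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    maf = g1.maf()
    assert (maf >= spec.maf_range[0]).all() and (maf <= spec.maf_range[1]).all()
    assert set(np.unique(g1.dosages)) <= {0.0, 2.0}  # fully inbred default


def test_forced_frequency_single_marker():
    spec = GenomeSpec(n_chromosomes=1, n_markers_per_chrom=40, n_accessions=400,
                      maf_range=(0.45, 0.5), n_subpops=1, fst=0.0, seed=3,
                      ld_block_len_bp=1.0)
    g = synth.simulate_genotypes(spec)
    assert np.all(np.abs(g.allele_freq() - 0.5) <= 0.05 + 1e-9)


def test_zero_fst_no_subpopulation_divergence(rng):
    spec = GenomeSpec(n_chromosomes=1, n_markers_per_chrom=220, n_accessions=200,
                      fst=0.0, n_subpops=2, seed=11, ld_block_len_bp=1.0)
    g = synth.simulate_genotypes(spec)
    sub = np.asarray(g.subpop)
    labels = np.unique(sub)
    f1 = g.dosages[sub == labels[0]].mean(axis=0) / 2
    f2 = g.dosages[sub == labels[1]].mean(axis=0) / 2
    obs = np.mean(np.abs(f1 - f2))
    perms = []
    for _ in range(200):
        p = rng.permutation(sub)
        perms.append(np.mean(np.abs(
            g.dosages[p == labels[0]].mean(axis=0) / 2
            - g.dosages[p == labels[1]].mean(axis=0) / 2)))
    p_val = np.mean(np.asarray(perms) >= obs)
    assert p_val > 0.05


def test_ld_block_structure_decays_with_distance():
    near, far = [], []
    for seed in range(3):
        spec = GenomeSpec(n_chromosomes=1, n_markers_per_chrom=250, n_accessions=150,
                          ld_block_len_bp=50_000, chrom_length_bp=5_000_000, seed=seed)
        g = synth.simulate_genotypes(spec)
        pairs = popgen.pairwise_r2(g, window=60)
        near.append(pairs.loc[pairs.dist < 10_000, "r2"].mean())
        far.append(pairs.loc[pairs.dist > 200_000, "r2"].mean())
    assert np.mean(near) > np.mean(far)


def test_mean_binned_r2_monotone_on_expectation():
    """Binned mean r2 decreases with distance, averaged over seeds."""
    bins = [0, 25_000, 100_000, 400_000, 2_000_000]
    acc = np.zeros(len(bins) - 1)
    n_seeds = 10
    for seed in range(n_seeds):
        spec = GenomeSpec(n_chromosomes=1, n_markers_per_chrom=120, n_accessions=100,
                          ld_block_len_bp=60_000, chrom_length_bp=4_000_000, seed=100 + seed)
        g = synth.simulate_genotypes(spec)
        pairs = popgen.pairwise_r2(g, window=119)
        binned = pairs.groupby(pd.cut(pairs.dist, bins, labels=False), observed=True)["r2"].mean()
        acc += binned.reindex(range(len(bins) - 1)).fillna(0).to_numpy()
    acc /= n_seeds
    # strict decrease through the LD range; beyond it r2 sits at the 1/n
    # sampling baseline, so allow a hair of slack on the last bin
    assert acc[0] > acc[1] > acc[2]
    assert acc[3] <= acc[2] + 5e-4


def test_no_marker_survives_filter_raises():
    # 10 inbred accessions quantize allele frequencies to multiples of 0.1,
    # so no marker can land inside (0.41, 0.44)
    spec = GenomeSpec(n_chromosomes=1, n_markers_per_chrom=10, n_accessions=10,
                      maf_range=(0.41, 0.44), seed=2)
    with pytest.raises(ValueError, match="MAF"):
        synth.simulate_genotypes(spec)


# ----------------------------------------------------------------- phenotypes

def test_additive_coding_exact_difference(small_geno):
    marker = small_geno.marker_ids[0]
    plan = QTLPlan(
        qtls=[PlantedQTL(marker, "TRL", 1.0)],
        h2={t: 1.0 for t in synth.BASE_TRAITS},
        polygenic_sd={t: 0.0 for t in synth.BASE_TRAITS},
    )
    raw = synth.simulate_phenotypes(small_geno, plan, n_reps=2, seed=4)
    sub = raw[(raw.trait == "TRL") & (raw.treatment == "N+") & (raw.replicate == 1)]
    d = small_geno.dosages[:, 0]
    vals = sub.set_index("accession").loc[list(small_geno.accessions), "value"].to_numpy()
    m2 = vals[d == 2].mean()
    m0 = vals[d == 0].mean()
    assert m2 - m0 == pytest.approx(2.0, abs=1e-9)


def test_phenotypes_deterministic(small_geno):
    plan = synth.default_qtl_plan(small_geno, seed=2)
    a = synth.simulate_phenotypes(small_geno, plan, n_reps=3, seed=9)
    b = synth.simulate_phenotypes(small_geno, plan, n_reps=3, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_planted_genetic_correlation_recovered(medium_geno):
    """Genetic correlation 0.9 between two traits shows up in accession means."""
    corr = synth.default_trait_corr()
    corr.loc["TRL", "RV"] = corr.loc["RV", "TRL"] = 0.9
    # keep the matrix PSD by relaxing the other root-trait links
    for t in ("RT",):
        corr.loc["TRL", t] = corr.loc[t, "TRL"] = 0.5
        corr.loc["RV", t] = corr.loc[t, "RV"] = 0.5
    plan = QTLPlan(qtls=[], h2={t: 0.7 for t in synth.BASE_TRAITS}, trait_corr=corr)
    raw = synth.simulate_phenotypes(medium_geno, plan, n_reps=3, seed=21)
    means = raw[raw.treatment == "N+"].groupby(["accession", "trait"])["value"].mean().unstack()
    r = np.corrcoef(means["TRL"], means["RV"])[0, 1]
    assert r >= 0.6


def test_treatment_direction_size_down_nue_up(small_geno):
    plan = synth.default_qtl_plan(small_geno, seed=2)
    raw = synth.simulate_phenotypes(small_geno, plan, n_reps=3, seed=5)
    m = raw.groupby(["trait", "treatment"])["value"].mean().unstack()
    for t in ("TRL", "RV", "RT", "PDW", "SDW"):
        assert m.loc[t, "N-"] < m.loc[t, "N+"]
    # NUE = PDW / (shootN + rootN): higher under deficiency
    wide = raw.pivot_table(index=["accession", "treatment", "replicate"],
                           columns="trait", values="value")
    nue = wide["PDW"] / (wide["shootN"] + wide["rootN"])
    nue_m = nue.groupby(level="treatment").mean()
    assert nue_m["N-"] > nue_m["N+"]


def test_non_psd_correlation_raises(small_geno):
    corr = synth.default_trait_corr()
    corr.iloc[0, 1] = corr.iloc[1, 0] = 1.5
    with pytest.raises(ValueError, match="symmetric|semi-definite|diagonal"):
        QTLPlan(qtls=[], trait_corr=corr)


# --------------------------------------------------------------------- counts

def test_counts_null_generator_group_means_close():
    plan = CountsPlan(n_genes=300, dispersion=0.0, deg_spec=[],
                      size_factor_range=(1.0, 1.0), baseline_log_mean=np.log(500),
                      baseline_log_sd=0.0)
    mat, sheet = synth.simulate_counts(plan, seed=6)
    grp = sheet.groupby(["genotype", "treatment"])["sample"].apply(list)
    means = {k: mat[v].mean(axis=1).mean() for k, v in grp.items()}
    vals = np.array(list(means.values()))
    # Poisson error on 300 genes x 4 reps at mean 500: ~ +/- 2
    assert np.ptp(vals) < 4 * np.sqrt(500 / (300 * 4)) * 4


def test_counts_planted_log2fc_ratio_in_band():
    ratios = []
    for seed in range(10):
        plan = CountsPlan(n_genes=50, dispersion=0.1,
                          deg_spec=[("LuSyn00001", "LN", 2.0)],
                          baseline_log_mean=np.log(200), baseline_log_sd=0.0)
        mat, sheet = synth.simulate_counts(plan, seed=seed)
        from flaxnue.expr import normalize_counts
        sf, norm = normalize_counts(mat)
        ln = sheet[sheet.genotype == "LN"]
        nm = norm.loc["LuSyn00001", ln[ln.treatment == "N-"]["sample"]].mean()
        np_ = norm.loc["LuSyn00001", ln[ln.treatment == "N+"]["sample"]].mean()
        ratios.append(nm / np_)
    assert 2.5 <= np.mean(ratios) <= 6.5


def test_counts_byte_identical_under_seed():
    plan = CountsPlan(n_genes=100, deg_spec=[("LuSyn00005", "HN", 1.5)])
    m1, s1 = synth.simulate_counts(plan, seed=42)
    m2, s2 = synth.simulate_counts(plan, seed=42)
    assert m1.to_csv() == m2.to_csv()
    assert s1.to_csv() == s2.to_csv()


# ----------------------------------------------------------------- annotation

def test_annotation_tiles_within_bounds():
    spec = GenomeSpec(n_chromosomes=1, chrom_length_bp=1_000_000, seed=0)
    ann = synth.make_annotation(spec, n_genes=10, gene_len_bp=1000)
    assert len(ann) == 10
    assert (ann.start >= 1).all() and (ann.end <= 1_000_000).all()
    assert (ann.end - ann.start + 1 == 1000).all()
    s = ann.sort_values("start")
    assert (s.start.to_numpy()[1:] > s.end.to_numpy()[:-1]).all()  # non-overlap


def test_annotation_too_many_genes_raises():
    spec = GenomeSpec(n_chromosomes=1, chrom_length_bp=10_000, seed=0)
    with pytest.raises(ValueError, match="do not fit"):
        synth.make_annotation(spec, n_genes=100, gene_len_bp=1000)


def test_annotation_gff3_round_trip(tmp_path):
    from flaxnue.workflow_io import read_annotation_gff3

    spec = GenomeSpec(n_chromosomes=2, chrom_length_bp=500_000, seed=0)
    ann = synth.make_annotation(spec, n_genes=8, gene_len_bp=900)
    path = tmp_path / "genes.gff3"
    synth.annotation_to_gff3(ann, path)
    back = read_annotation_gff3(path)
    merged = ann.merge(back, on="gene_id", suffixes=("", "_rt"))
    assert (merged.start == merged.start_rt).all()
    assert (merged.end == merged.end_rt).all()
    assert (merged.chrom == merged.chrom_rt).all()
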