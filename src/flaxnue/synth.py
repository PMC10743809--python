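"""Synthetic cohort generator: genotypes, seedling phenotypes, annotation, counts.

Everything downstream of this module (trait derivation, GWAS, QTL construction,
differential expression, genomic selection) is exercised on data produced here.
The generator emulates a diversity panel of mostly-inbred flax accessions
genotyped genome-wide, phenotyped for root/biomass/nitrogen traits under an
optimum-nitrate (N+) and a nitrogen-deficient (N-) treatment, plus a small
RNA-seq experiment contrasting a high-NUE and a low-NUE accession.

Design highlights
-----------------
* LD arises from a latent Gaussian autoregressive haplotype process: each
  gamete carries a latent field whose correlation decays as
  exp(-distance / ld_block_len_bp) along the chromosome and is thresholded at
  the (subpopulation) allele frequency, which yields block-structured LD with
  a directly tunable decay length.
* Population structure follows the Balding-Nichols model: subpopulation allele
  frequencies are Beta-distributed around an ancestral frequency with a single
  differentiation parameter (Fst).
* Phenotypes are additive: planted marker effects (trait units per dosage)
  plus a marker-derived polygenic term correlated across traits, plus an
  i.i.d. replicate residual scaled so the accession-mean heritability equals
  the planned h².
* Counts are negative binomial with gene-specific baselines, per-sample
  library-size factors, and planted fold changes applied to the N- samples of
  one genotype.

All simulators are pure functions of (inputs, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

#: traits carried by the genetic model, in fixed order; NUE is a latent
#: ratio trait (plant dry weight over plant N content) from which the shoot
#: and root nitrogen contents are derived
BASE_TRAITS = ["TRL", "RV", "RT", "SDW", "RDW", "NUE"]
#: traits emitted in the raw replicate-level table (PDW = SDW + RDW)
RAW_TRAITS = ["TRL", "RV", "RT", "PDW", "SDW", "RDW", "shootN", "rootN"]
TREATMENTS = ["N+", "N-"]

# Default per-trait (mean, SD) under each treatment.  Root and biomass values
# mirror the magnitudes reported for the flax seedling diversity panel
# (e.g. TRL ~469 cm under N+, ~407 cm under N-); latent NUE averages ~25.6
# under N+ and ~28.3 under N-, i.e. use efficiency rises under deficiency
# while size traits shrink.
DEFAULT_TRAIT_SCALE: dict[tuple[str, str], tuple[float, float]] = {
    ("TRL", "N+"): (469.2, 137.7), ("TRL", "N-"): (407.2, 156.8),
    ("RV", "N+"): (0.464, 0.181), ("RV", "N-"): (0.389, 0.188),
    ("RT", "N+"): (533.7, 120.7), ("RT", "N-"): (447.8, 125.1),
    ("SDW", "N+"): (77.1, 41.3), ("SDW", "N-"): (59.9, 38.5),
    ("RDW", "N+"): (28.6, 11.0), ("RDW", "N-"): (26.5, 12.5),
    ("NUE", "N+"): (25.6, 7.2), ("NUE", "N-"): (28.3, 7.8),
}

#: shoot share of plant N content (rest in roots), with small per-plant noise
SHOOT_N_SHARE = 0.75


def default_trait_corr() -> pd.DataFrame:
    """Default genetic correlation matrix over the base traits.

    Root traits are strongly inter-correlated, biomass compartments likewise;
    nitrogen contents track biomass moderately and roots weakly.
    """
    t = BASE_TRAITS
    c = pd.DataFrame(np.eye(len(t)), index=t, columns=t)

    def set_(a, b, r):
        c.loc[a, b] = r
        c.loc[b, a] = r

    set_("TRL", "RV", 0.75)
    set_("TRL", "RT", 0.70)
    set_("RV", "RT", 0.70)
    set_("SDW", "RDW", 0.85)
    for root in ("TRL", "RV", "RT"):
        for bio in ("SDW", "RDW"):
            set_(root, bio, 0.40)
        # roots help N capture: positive genetic link to use efficiency
        set_(root, "NUE", 0.35)
    set_("NUE", "SDW", 0.05)
    set_("NUE", "RDW", 0.05)
    return c


# --------------------------------------------------------------------- specs

@dataclass
class GenomeSpec:
    """Genome and panel layout for the genotype simulator."""

    n_chromosomes: int = 15
    chrom_length_bp: int = 20_000_000
    n_markers_per_chrom: int = 400
    ld_block_len_bp: float = 100_000.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 2
    fst: float = 0.10
    n_accessions: int = 123
    inbreeding: float = 1.0
    missing_rate: float = 0.0
    call_rate_min: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if not (0.0 <= self.inbreeding <= 1.0):
            raise ValueError("inbreeding must lie in [0, 1]")
        if self.ld_block_len_bp <= 0:
            raise ValueError("ld_block_len_bp must be positive")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"Lu{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class PlantedQTL:
    """One planted additive marker effect.

    ``trait`` is a base trait name or the convenience alias "PDW" (effect split
    between SDW and RDW in proportion to their means).  ``effect`` is in trait
    units per alternate-allele dosage.  ``treatments`` restricts the effect to
    one or both treatments.
    """

    marker: str
    trait: str
    effect: float
    treatments: tuple[str, ...] = ("N+", "N-")


@dataclass
class QTLPlan:
    """Planted genetic architecture for the phenotype simulator."""

    qtls: list[PlantedQTL] = field(default_factory=list)
    h2: dict[str, float] = field(default_factory=lambda: {t: 0.6 for t in BASE_TRAITS})
    trait_corr: pd.DataFrame = field(default_factory=default_trait_corr)
    trait_scale: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_SCALE)
    )
    polygenic_sd: dict[str, float] | None = None  # None: derived from h2 and scale

    def __post_init__(self) -> None:
        for t, h in self.h2.items():
            if not (0.0 < h <= 1.0):
                raise ValueError(f"h2[{t!r}] must lie in (0, 1]")
        c = np.asarray(self.trait_corr, dtype=float)
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("trait correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("trait correlation matrix must have unit diagonal")
        if np.min(np.linalg.eigvalsh(c)) < -1e-8:
            raise ValueError("trait correlation matrix is not positive semi-definite")
        for q in self.qtls:
            base = q.trait
            if base != "PDW" and base not in BASE_TRAITS:
                raise ValueError(f"planted trait {base!r} is not a base trait")

    def expanded_effects(self) -> list[PlantedQTL]:
        """Resolve the "PDW" alias into SDW/RDW effects."""
        out: list[PlantedQTL] = []
        for q in self.qtls:
            if q.trait == "PDW":
                tot = {
                    tr: DEFAULT_TRAIT_SCALE[("SDW", tr)][0] + DEFAULT_TRAIT_SCALE[("RDW", tr)][0]
                    for tr in TREATMENTS
                }
                w_sdw = DEFAULT_TRAIT_SCALE[("SDW", "N+")][0] / tot["N+"]
                out.append(PlantedQTL(q.marker, "SDW", q.effect * w_sdw, q.treatments))
                out.append(PlantedQTL(q.marker, "RDW", q.effect * (1 - w_sdw), q.treatments))
            else:
                out.append(q)
        return out


@dataclass
class CountsPlan:
    """Design for the RNA-seq count simulator (genes x 16 samples)."""

    n_genes: int = 2000
    n_replicates: int = 4
    dispersion: float = 0.1
    deg_spec: list[tuple[str, str, float]] = field(default_factory=list)  # (gene, genotype, log2FC on N-)
    placement: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    baseline_log_mean: float = np.log(150.0)
    baseline_log_sd: float = 1.0
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    genotypes: tuple[str, str] = ("HN", "LN")

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        for g, geno, _ in self.deg_spec:
            if geno not in self.genotypes:
                raise ValueError(f"deg_spec genotype {geno!r} not in {self.genotypes}")


# ----------------------------------------------------------------- genotypes

def simulate_genotypes(spec: GenomeSpec) -> GenotypeMatrix:
    """Simulate a filtered diploid dosage panel with block LD and structure.

    Each gamete carries a latent Gaussian field that is first-order
    autoregressive along the chromosome (correlation exp(-gap/ld_block_len_bp)
    between adjacent markers) and is thresholded at the subpopulation allele
    frequency, so nearby markers sit on shared latent blocks and pairwise r²
    decays roughly as exp(-2 d / ld_block_len_bp).  Subpopulation frequencies
    follow Balding-Nichols around a shared ancestral frequency.  Missing calls
    (if any) are injected before the call-rate and MAF filters, mirroring a
    real variant-filtering path.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(spec.seed)
    n_acc = spec.n_accessions
    # accession -> subpopulation, round-robin for balance
    subpop = np.arange(n_acc) % spec.n_subpops
    # fully correlated pair of gametes with probability `inbreeding`
    selfed = rng.random(n_acc) < spec.inbreeding
    chrom_all, pos_all, dos_all = [], [], []
    for cname in spec.chromosome_names:
        m = spec.n_markers_per_chrom
        pos = np.sort(rng.choice(np.arange(1, spec.chrom_length_bp + 1), size=m, replace=False))
        anc = rng.uniform(spec.maf_range[0], 1.0 - spec.maf_range[0], size=m)
        # Balding-Nichols subpopulation frequencies
        freqs = np.empty((spec.n_subpops, m))
        if spec.fst > 0:
            a = anc * (1.0 - spec.fst) / spec.fst
            b = (1.0 - anc) * (1.0 - spec.fst) / spec.fst
            for s in range(spec.n_subpops):
                freqs[s] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        else:
            freqs[:] = anc
        thresholds = norm.ppf(freqs)  # latent z < threshold -> alternate allele

        def draw_gametes(k: int) -> np.ndarray:
            """k latent AR(1) haplotype fields of length m."""
            z = np.empty((k, m))
            z[:, 0] = rng.standard_normal(k)
            ar = np.exp(-np.diff(pos) / spec.ld_block_len_bp)
            noise = rng.standard_normal((k, m - 1))
            for j in range(1, m):
                a_j = ar[j - 1]
                z[:, j] = a_j * z[:, j - 1] + np.sqrt(1.0 - a_j**2) * noise[:, j - 1]
            return z

        z1 = draw_gametes(n_acc)
        z2 = draw_gametes(n_acc)
        z2[selfed] = z1[selfed]
        tau = thresholds[subpop, :]
        dos = (z1 < tau).astype(float) + (z2 < tau).astype(float)
        chrom_all.append(np.repeat(cname, m))
        pos_all.append(pos)
        dos_all.append(dos)

    dosages = np.concatenate(dos_all, axis=1)
    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages[mask] = np.nan
    geno = GenotypeMatrix(
        dosages=dosages,
        accessions=[f"ACC{i + 1:04d}" for i in range(n_acc)],
        chrom=np.concatenate(chrom_all),
        pos=np.concatenate(pos_all),
        subpop=np.array([f"C{s + 1}" for s in subpop], dtype=object),
    )
    try:
        return geno.filter(call_rate=spec.call_rate_min if spec.missing_rate > 0 else 0.0,
                           maf_range=spec.maf_range)
    except ValueError as e:
        raise ValueError(f"genotype simulation produced {geno.n_markers} markers but {e}") from e


# ---------------------------------------------------------------- phenotypes

def _polygenic_scores(geno: GenotypeMatrix, corr: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Marker-derived polygenic scores, one standardized column per base trait,
    correlated across traits via the Cholesky factor of the plan correlation."""
    Z = geno.impute_mean().dosages
    sd = Z.std(axis=0)
    ok = sd > 0
    Zs = (Z[:, ok] - Z[:, ok].mean(axis=0)) / sd[ok]
    L = np.linalg.cholesky(np.asarray(corr, dtype=float) + 1e-10 * np.eye(len(corr)))
    B = rng.standard_normal((Zs.shape[1], len(corr))) @ L.T
    scores = Zs @ B
    scores -= scores.mean(axis=0)
    s = scores.std(axis=0)
    s[s == 0] = 1.0
    return scores / s


def simulate_phenotypes(
    geno: GenotypeMatrix,
    plan: QTLPlan,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-level phenotypes under both treatments (long format).

    Per accession a, treatment t and trait:
    ``value = mu + sum_q beta_q * dosage_aq + polygenic_a * s + residual``,
    where the residual SD is set so the heritability of accession means over
    ``n_reps`` replicates equals ``plan.h2`` for that trait.  PDW is emitted
    as SDW + RDW per replicate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    dimp = geno.impute_mean().dosages
    n = geno.n_accessions
    effects = plan.expanded_effects()
    for q in effects:
        geno.marker_index(q.marker)  # raises on unknown marker
    poly = _polygenic_scores(geno, plan.trait_corr, rng)
    L = np.linalg.cholesky(np.asarray(plan.trait_corr, dtype=float)
                           + 1e-10 * np.eye(len(BASE_TRAITS)))

    by_key: dict[tuple[str, str], np.ndarray] = {}
    for treat in TREATMENTS:
        genetic = np.empty((n, len(BASE_TRAITS)))
        mus = np.empty(len(BASE_TRAITS))
        sigma_rep = np.empty(len(BASE_TRAITS))
        for trait_i, trait in enumerate(BASE_TRAITS):
            h2 = plan.h2.get(trait, 0.6)
            mu, sd_tab = plan.trait_scale[(trait, treat)]
            mus[trait_i] = mu
            qtl_part = np.zeros(n)
            for q in effects:
                if q.trait == trait and treat in q.treatments:
                    qtl_part += q.effect * dimp[:, geno.marker_index(q.marker)]
            qtl_part -= qtl_part.mean()
            if plan.polygenic_sd is not None:
                psd = plan.polygenic_sd.get(trait, 0.0) * sd_tab / plan.trait_scale[(trait, "N+")][1]
            else:
                psd = float(np.sqrt(max(0.0, h2 * sd_tab**2 - qtl_part.var())))
            g = qtl_part + psd * poly[:, trait_i]
            genetic[:, trait_i] = g
            var_g = g.var()
            if var_g > 0:
                sigma_rep[trait_i] = np.sqrt(n_reps * var_g * (1.0 - h2) / h2)
            else:  # no genetic signal at all: pure-noise trait at the table scale
                sigma_rep[trait_i] = sd_tab
        # replicate residuals share the trait correlation (same plant measured)
        for rep in range(n_reps):
            eps = rng.standard_normal((n, len(BASE_TRAITS))) @ L.T
            vals = mus + genetic + eps * sigma_rep
            key = (treat, rep + 1)
            by_key[key] = vals

    rows = []
    t_idx = {t: i for i, t in enumerate(BASE_TRAITS)}
    for treat in TREATMENTS:
        for rep in range(1, n_reps + 1):
            vals = by_key[(treat, rep)]
            # measurements are positive; rectify the rare low tail at a small
            # fraction of the treatment mean
            for trait in BASE_TRAITS:
                floor = 0.08 * plan.trait_scale[(trait, treat)][0]
                vals[:, t_idx[trait]] = np.maximum(vals[:, t_idx[trait]], floor)
            pdw = vals[:, t_idx["SDW"]] + vals[:, t_idx["RDW"]]
            # N contents derive from the latent efficiency: plantN = PDW / NUE,
            # split between shoot and root with small per-plant noise
            plant_n = pdw / vals[:, t_idx["NUE"]]
            share = np.clip(SHOOT_N_SHARE + 0.02 * rng.standard_normal(n), 0.5, 0.95)
            emitted = {
                "TRL": vals[:, t_idx["TRL"]], "RV": vals[:, t_idx["RV"]],
                "RT": vals[:, t_idx["RT"]], "PDW": pdw,
                "SDW": vals[:, t_idx["SDW"]], "RDW": vals[:, t_idx["RDW"]],
                "shootN": share * plant_n, "rootN": (1.0 - share) * plant_n,
            }
            for trait in RAW_TRAITS:
                v = emitted[trait]
                for a_i, acc in enumerate(geno.accessions):
                    rows.append((acc, treat, rep, trait, v[a_i]))
    out = pd.DataFrame(rows, columns=["accession", "treatment", "replicate", "trait", "value"])
    return out.reset_index(drop=True)


def default_qtl_plan(geno: GenotypeMatrix, seed: int = 0, n_sti_qtl: int = 16) -> QTLPlan:
    """Standard planted architecture for the panel.

    An oligogenic set of ``n_sti_qtl`` markers drives nitrogen use efficiency
    under both treatments (and hence NUE_STI), with per-QTL variance explained
    spanning roughly 1-12% and ~55% in total; each root/biomass trait
    additionally carries a handful of its own QTLs, partly shared between
    correlated traits to create pleiotropic loci.
    """
    rng = np.random.default_rng(seed)
    dimp = geno.impute_mean().dosages
    var_d = dimp.var(axis=0)
    usable = np.flatnonzero(var_d > 0)

    def pick(k):
        return rng.choice(usable, size=k, replace=False)

    def beta_for(midx, pve, trait):
        sd_tab = DEFAULT_TRAIT_SCALE[(trait, "N+")][1]
        b = np.sqrt(pve * sd_tab**2 / var_d[midx])
        return b * rng.choice([-1.0, 1.0])

    qtls: list[PlantedQTL] = []
    # oligogenic nitrogen-use-efficiency architecture under both treatments
    sti_markers = pick(n_sti_qtl)
    pves = np.concatenate([
        rng.uniform(0.06, 0.12, size=max(1, n_sti_qtl // 4)),
        rng.uniform(0.01, 0.04, size=n_sti_qtl - max(1, n_sti_qtl // 4)),
    ])
    pves *= 0.55 / pves.sum()  # total planted PVE on NUE ~55%
    for midx, pve in zip(sti_markers, pves):
        qtls.append(PlantedQTL(geno.marker_ids[midx], "NUE",
                               beta_for(midx, pve, "NUE"), ("N+", "N-")))
    # root traits share a block of pleiotropic markers
    shared = pick(4)
    for trait in ("TRL", "RV", "RT"):
        own = pick(3)
        for midx in np.concatenate([shared, own]):
            pve = rng.uniform(0.02, 0.08)
            qtls.append(PlantedQTL(geno.marker_ids[midx], trait, beta_for(midx, pve, trait),
                                   tuple(TREATMENTS) if rng.random() < 0.6 else ("N-",)))
    for trait in ("SDW", "RDW"):
        for midx in pick(3):
            pve = rng.uniform(0.02, 0.06)
            qtls.append(PlantedQTL(geno.marker_ids[midx], trait, beta_for(midx, pve, trait)))
    return QTLPlan(qtls=qtls, h2={t: 0.6 for t in BASE_TRAITS})


# -------------------------------------------------------------- annotation

def make_annotation(spec: GenomeSpec, n_genes: int, gene_len_bp: int = 2000) -> pd.DataFrame:
    """Tile non-overlapping genes uniformly over the genome (1-based inclusive).

    Genes are distributed over chromosomes proportionally to length; raises if
    the requested genes do not fit.
    """
    per_chrom = int(np.ceil(n_genes / spec.n_chromosomes))
    rows = []
    gid = 0
    for cname in spec.chromosome_names:
        k = min(per_chrom, n_genes - gid)
        if k <= 0:
            break
        stride = spec.chrom_length_bp // k
        if stride < gene_len_bp:
            raise ValueError(
                f"{n_genes} genes of {gene_len_bp} bp do not fit in the genome "
                f"({spec.n_chromosomes} x {spec.chrom_length_bp} bp)"
            )
        for j in range(k):
            start = j * stride + (stride - gene_len_bp) // 2 + 1
            end = start + gene_len_bp - 1
            gid += 1
            rows.append((f"LuSyn{gid:05d}", cname, start, end, "+"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def annotation_to_gff3(annotation: pd.DataFrame, path) -> None:
    """Write the gene table as a minimal valid GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in annotation.iterrows():
            attrs = f"ID={r.gene_id};Name={r.gene_id}"
            fh.write(
                f"{r.chrom}\tflaxnue\tgene\t{int(r.start)}\t{int(r.end)}\t.\t{r.strand}\t.\t{attrs}\n"
            )


# ------------------------------------------------------------------- counts

def simulate_counts(plan: CountsPlan, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix (genes x samples) and its sample sheet.

    Baseline means are log-normal per gene; each sample has a library-size
    factor; planted fold changes multiply the N- samples of the specified
    genotype by 2**log2FC.  Counts are NB with Var = mu + dispersion * mu^2
    (Poisson when dispersion is ~0).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    genes = (list(plan.placement.keys()) if plan.placement
             else [f"LuSyn{i + 1:05d}" for i in range(plan.n_genes)])
    if plan.placement and len(genes) < plan.n_genes:
        genes = genes + [f"gene_extra{i:05d}" for i in range(plan.n_genes - len(genes))]
    genes = genes[: plan.n_genes]

    samples, meta = [], []
    for g in plan.genotypes:
        for tr in TREATMENTS:
            for r in range(1, plan.n_replicates + 1):
                tag = "Np" if tr == "N+" else "Nm"
                samples.append(f"{g}.{tag}.{r}")
                meta.append((f"{g}.{tag}.{r}", g, tr, r))
    sheet = pd.DataFrame(meta, columns=["sample", "genotype", "treatment", "replicate"])

    base = rng.lognormal(plan.baseline_log_mean, plan.baseline_log_sd, size=len(genes))
    sf = rng.uniform(*plan.size_factor_range, size=len(samples))
    lfc = pd.DataFrame(0.0, index=genes, columns=plan.genotypes)
    for gene, geno, l2 in plan.deg_spec:
        if gene in lfc.index:
            lfc.loc[gene, geno] += l2
    mu = np.empty((len(genes), len(samples)))
    for j, (_, g, tr, _) in enumerate(meta):
        fold = np.where(tr == "N-", 2.0 ** lfc[g].to_numpy(), 1.0)
        mu[:, j] = base * sf[j] * fold
    if plan.dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        r_nb = 1.0 / plan.dispersion
        p_nb = r_nb / (r_nb + mu)
        counts = rng.negative_binomial(r_nb, p_nb)
    mat = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    return mat, sheet


def default_counts_plan(
    annotation: pd.DataFrame,
    qtl_positions: list[tuple[str, int]],
    seed: int = 0,
    n_genes: int | None = None,
    n_deg_in_windows: int = 30,
    n_deg_elsewhere: int = 60,
    half_window: int = 100_000,
) -> CountsPlan:
    """Counts plan with DEGs planted inside +/-100 kb windows of chosen loci.

    ``qtl_positions`` are (chrom, bp) anchors, typically the planted QTL
    markers of the phenotype plan, so that colocalization has signal to find.
    Remaining DEGs are scattered outside every window; planted |log2FC| is
    drawn from [1.2, 2.5] with random sign, mostly on the LN genotype (the
    low-NUE accession shows the bulk of the transcriptional response).
    """
    rng = np.random.default_rng(seed)
    ann = annotation.reset_index(drop=True)
    placement = {r.gene_id: (r.chrom, int(r.start), int(r.end)) for r in ann.itertuples()}
    in_win = np.zeros(len(ann), dtype=bool)
    for chrom, bp in qtl_positions:
        hit = (ann["chrom"] == chrom) & (ann["end"] >= bp - half_window) & (ann["start"] <= bp + half_window)
        in_win |= hit.to_numpy()
    inside = ann.index[in_win].to_numpy()
    outside = ann.index[~in_win].to_numpy()
    deg_spec: list[tuple[str, str, float]] = []

    def draw(idx_pool, k):
        k = min(k, len(idx_pool))
        return rng.choice(idx_pool, size=k, replace=False)

    for i in draw(inside, n_deg_in_windows):
        g = ann.loc[i, "gene_id"]
        l2 = rng.uniform(1.2, 2.5) * rng.choice([-1.0, 1.0])
        deg_spec.append((g, "LN" if rng.random() < 0.8 else "HN", float(l2)))
    for i in draw(outside, n_deg_elsewhere):
        g = ann.loc[i, "gene_id"]
        l2 = rng.uniform(1.2, 2.5) * rng.choice([-1.0, 1.0])
        deg_spec.append((g, "LN" if rng.random() < 0.8 else "HN", float(l2)))
    return CountsPlan(
        n_genes=n_genes or len(ann),
        deg_spec=deg_spec,
        placement=placement,
    )
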