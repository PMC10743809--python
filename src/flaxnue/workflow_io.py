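"""Run configuration, file formats and the end-to-end pipeline orchestrator.

Formats: genotypes as VCF 4.2 (GT field, one sample column per accession) or
CSV with a chrom/pos sidecar; phenotypes as long-format CSV; annotation as
GFF3; counts as TSV with a sample-sheet CSV.  All coordinates are 1-based
inclusive (VCF/GFF3 convention).  ``run_pipeline`` chains the stages in
dependency order and writes a provenance manifest with the config hash, seed
and per-stage record counts, since the analysis narrative hinges on the
QTN -> validated QTN -> QTL count transitions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expr, gs, mlgwas, pheno, popgen, qtl, synth
from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

STAGES = ["simulate", "derive", "ld", "gwas", "qtl", "de", "coloc", "gs"]


@dataclass
class RunConfig:
    """Thresholds and sizes for a full pipeline run (YAML-loadable)."""

    out_dir: str | None = None
    seed: int = 0
    # filtering / association thresholds
    maf: float = 0.05
    call_rate: float = 0.95
    lod_min: float = 3.0
    mw_alpha: float = 0.05
    merge_factor: float = 0.75
    merge_r2: float = 0.3
    window_bp: int = 100_000
    de_lfc: float = 1.0
    de_fdr: float = 0.05
    ld_window: int = 50
    # genomic selection block
    gs_k: int = 5
    gs_repeats: int = 100
    gs_target: str = "NUE_STI"
    m1_size: int = 1000
    # synthetic-data block
    n_accessions: int = 123
    n_chromosomes: int = 15
    chrom_length_bp: int = 20_000_000
    n_markers_per_chrom: int = 400
    ld_block_len_bp: float = 100_000.0
    fst: float = 0.10
    n_subpops: int = 2
    n_reps: int = 3
    n_genes: int = 2000
    # optional input paths (used instead of simulation when set)
    genotype_path: str | None = None
    genotype_format: str = "vcf"
    phenotype_path: str | None = None
    annotation_path: str | None = None
    counts_path: str | None = None
    sample_sheet_path: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.maf <= 0.5):
            raise ValueError("maf must lie in [0, 0.5]")
        for name in ("mw_alpha", "de_fdr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.lod_min < 0 or self.merge_factor <= 0 or self.window_bp < 0:
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analytic settings (the output location is excluded so
        reruns into different directories stay byte-identical)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def genome_spec(self) -> synth.GenomeSpec:
        return synth.GenomeSpec(
            n_chromosomes=self.n_chromosomes,
            chrom_length_bp=self.chrom_length_bp,
            n_markers_per_chrom=self.n_markers_per_chrom,
            ld_block_len_bp=self.ld_block_len_bp,
            maf_range=(self.maf, 0.5),
            n_subpops=self.n_subpops,
            fst=self.fst,
            n_accessions=self.n_accessions,
            seed=self.seed,
        )


# ------------------------------------------------------------------ genotypes

def write_genotypes_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with a GT field per accession (0/0, 0/1, 1/1, ./.)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(geno.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.accessions) + "\n")
        for j in range(geno.n_markers):
            calls = [gt_map.get(geno.dosages[i, j], "./.") for i in range(geno.n_accessions)]
            fh.write(f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.marker_ids[j]}\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_genotypes_vcf(path, call_rate: float = 0.0,
                       maf_range: tuple[float, float] = (0.0, 0.5)) -> GenotypeMatrix:
    """Read a VCF via cyvcf2 into a dosage matrix, then apply call-rate and
    MAF filters (logged).  Non-diploid GT records raise."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    chroms, poss, ids, rows = [], [], [], []
    for ln, v in enumerate(vcf, start=1):
        dos = np.empty(len(accessions))
        for i, call in enumerate(v.genotypes):
            alleles = call[:-1]
            if len(alleles) != 2:
                raise ValueError(f"non-diploid GT at record {ln} ({v.CHROM}:{v.POS})")
            if alleles[0] < 0 or alleles[1] < 0:
                dos[i] = np.nan
            else:
                dos[i] = alleles[0] + alleles[1]
        chroms.append(v.CHROM)
        poss.append(v.POS)
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        rows.append(dos)
    geno = GenotypeMatrix(
        dosages=np.array(rows).T,
        accessions=accessions,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        marker_ids=ids,
    )
    if call_rate > 0 or maf_range[0] > 0:
        geno = geno.filter(call_rate=call_rate, maf_range=maf_range)
    return geno


def write_genotypes_csv(geno: GenotypeMatrix, path, map_path) -> None:
    """Accession x marker dosage CSV plus a chrom/pos sidecar."""
    geno.to_dataframe().to_csv(path, index_label="accession")
    pd.DataFrame({"marker": geno.marker_ids, "chrom": geno.chrom, "pos": geno.pos}
                 ).to_csv(map_path, index=False)


def read_genotypes_csv(path, map_path, call_rate: float = 0.0,
                       maf_range: tuple[float, float] = (0.0, 0.5)) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    mp = pd.read_csv(map_path).set_index("marker").loc[df.columns]
    geno = GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        accessions=[str(a) for a in df.index],
        chrom=mp["chrom"].to_numpy(dtype=object),
        pos=mp["pos"].to_numpy(dtype=np.int64),
        marker_ids=list(df.columns),
    )
    if call_rate > 0 or maf_range[0] > 0:
        geno = geno.filter(call_rate=call_rate, maf_range=maf_range)
    return geno


def read_annotation_gff3(path) -> pd.DataFrame:
    """Read gene records from GFF3 (via gffutils) into the gene table."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand or "+"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# ------------------------------------------------------------------- pipeline

@dataclass
class PipelineResult:
    config: RunConfig
    geno: GenotypeMatrix | None = None
    raw_phenotypes: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None
    sample_sheet: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None
    trait_summary: pd.DataFrame | None = None
    trait_corr_r: pd.DataFrame | None = None
    trait_corr_p: pd.DataFrame | None = None
    ld_pairs: pd.DataFrame | None = None
    decay: dict | None = None
    grm: pd.DataFrame | None = None
    qtns: pd.DataFrame | None = None
    validated_qtns: pd.DataFrame | None = None
    allele_tests: pd.DataFrame | None = None
    qtls: list | None = None
    degs: pd.DataFrame | None = None
    coloc_hits: list | None = None
    coloc_summary: dict | None = None
    marker_sets: dict | None = None
    cv_results: pd.DataFrame | None = None
    gs_comparison: dict | None = None
    manifest: dict = field(default_factory=dict)
    plan: synth.QTLPlan | None = None


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> PipelineResult:
    """Execute the requested stages in dependency order.

    Stages: simulate, derive, ld, gwas, qtl, de, coloc, gs.  Later stages pull
    in their prerequisites automatically; a manifest records the config hash,
    seed and per-stage record counts.
    """
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    # close over dependencies
    deps = {
        "derive": ["simulate"], "ld": ["simulate"], "gwas": ["simulate", "derive", "ld"],
        "qtl": ["gwas"], "de": ["simulate"], "coloc": ["qtl", "de"],
        "gs": ["qtl", "coloc"],
    }
    needed = set(stages)
    changed = True
    while changed:
        changed = False
        for s in list(needed):
            for d in deps.get(s, []):
                if d not in needed:
                    needed.add(d)
                    changed = True
    ordered = [s for s in STAGES if s in needed]

    res = PipelineResult(config=config)
    man = {"config_hash": config.config_hash(), "seed": config.seed, "stages": ordered,
           "counts": {}}

    for stage in ordered:
        _STAGE_FN[stage](res, config, man)

    res.manifest = man
    if config.out_dir:
        _write_outputs(res, Path(config.out_dir))
    return res


def _stage_simulate(res: PipelineResult, cfg: RunConfig, man: dict) -> None:
    if cfg.genotype_path:
        if cfg.genotype_format == "vcf":
            res.geno = read_genotypes_vcf(cfg.genotype_path, cfg.call_rate, (cfg.maf, 0.5))
        else:
            map_path = str(cfg.genotype_path).replace(".csv", ".map.csv")
            res.geno = read_genotypes_csv(cfg.genotype_path, map_path, cfg.call_rate, (cfg.maf, 0.5))
    else:
        res.geno = synth.simulate_genotypes(cfg.genome_spec())
    if cfg.phenotype_path:
        res.raw_phenotypes = pd.read_csv(cfg.phenotype_path)
    else:
        res.plan = synth.default_qtl_plan(res.geno, seed=cfg.seed + 1)
        res.raw_phenotypes = synth.simulate_phenotypes(res.geno, res.plan,
                                                       n_reps=cfg.n_reps, seed=cfg.seed + 2)
    if cfg.annotation_path:
        res.annotation = read_annotation_gff3(cfg.annotation_path)
    else:
        res.annotation = synth.make_annotation(cfg.genome_spec(), cfg.n_genes)
    if cfg.counts_path and cfg.sample_sheet_path:
        res.counts = pd.read_csv(cfg.counts_path, sep="\t", index_col=0)
        res.sample_sheet = pd.read_csv(cfg.sample_sheet_path)
    else:
        anchors = []
        if res.plan is not None:
            for q in res.plan.expanded_effects():
                idx = res.geno.marker_index(q.marker)
                anchors.append((str(res.geno.chrom[idx]), int(res.geno.pos[idx])))
        cplan = synth.default_counts_plan(res.annotation, anchors, seed=cfg.seed + 3,
                                          half_window=cfg.window_bp)
        res.counts, res.sample_sheet = synth.simulate_counts(cplan, seed=cfg.seed + 4)
    man["counts"]["n_accessions"] = res.geno.n_accessions
    man["counts"]["n_markers"] = res.geno.n_markers
    man["counts"]["n_genes"] = len(res.annotation)


def _stage_derive(res: PipelineResult, cfg: RunConfig, man: dict) -> None:
    blues = pheno.compute_blues(res.raw_phenotypes)
    res.traits = pheno.derive_traits(blues)
    res.trait_summary = pheno.summarize_traits(res.traits)
    res.trait_corr_r, res.trait_corr_p = pheno.correlate_traits(res.traits)
    man["counts"]["n_traits"] = res.traits.shape[1]


def _stage_ld(res: PipelineResult, cfg: RunConfig, man: dict) -> None:
    res.ld_pairs = popgen.pairwise_r2(res.geno, window=cfg.ld_window)
    res.decay = popgen.decay_profiles_by_chromosome(res.ld_pairs, n=res.geno.n_accessions)
    res.grm = popgen.vanraden_grm(res.geno)
    man["counts"]["n_ld_pairs"] = len(res.ld_pairs)


def _stage_gwas(res: PipelineResult, cfg: RunConfig, man: dict) -> None:
    traits = res.traits.loc[res.geno.accessions]
    res.qtns = mlgwas.run_mlgwas(traits, res.geno, res.grm.to_numpy(), lod_min=cfg.lod_min)
    man["counts"]["n_qtn_detected"] = int(res.qtns[["marker", "trait"]].drop_duplicates().shape[0])


def _stage_qtl(res: PipelineResult, cfg: RunConfig, man: dict) -> None:
    traits = res.traits.loc[res.geno.accessions]
    res.validated_qtns, res.allele_tests = qtl.validate_qtns(
        res.qtns, traits, res.geno, alpha=cfg.mw_alpha)
    qtls = qtl.merge_qtns(res.validated_qtns, res.decay,
                          factor=cfg.merge_factor, r2_threshold=cfg.merge_r2)
    res.qtls = qtl.classify_qtls(qtls)
    man["counts"]["n_qtn_validated"] = int(res.validated_qtns[["marker", "trait"]]
                                           .drop_duplicates().shape[0])
    man["counts"]["n_qtl"] = len(res.qtls)
    man["counts"]["n_major_qtl"] = int(sum(q.major for q in res.qtls))
    man["counts"]["n_pleiotropic_qtl"] = int(sum(q.pleiotropic for q in res.qtls))


def _stage_de(res: PipelineResult, cfg: RunConfig, man: dict) -> None:
    res.degs = expr.de_both_genotypes(res.counts, res.sample_sheet,
                                      lfc_threshold=cfg.de_lfc, fdr_threshold=cfg.de_fdr)
    man["counts"]["n_deg"] = int(res.degs.loc[res.degs["significant"], "gene_id"].nunique())


def _stage_coloc(res: PipelineResult, cfg: RunConfig, man: dict) -> None:
    res.coloc_hits, res.coloc_summary = expr.colocalize(
        res.qtls, res.annotation, res.degs, half_window=cfg.window_bp)
    man["counts"]["n_qtl_with_deg"] = res.coloc_summary["n_qtl_with_deg"]
    man["counts"]["n_deg_in_windows"] = res.coloc_summary["n_deg_in_windows"]


def _stage_gs(res: PipelineResult, cfg: RunConfig, man: dict) -> None:
    res.marker_sets = gs.build_marker_sets(
        res.geno, res.qtls, res.trait_corr_r, res.trait_corr_p, res.coloc_hits,
        target=cfg.gs_target, m1_size=cfg.m1_size, seed=cfg.seed + 5)
    favorable = (res.validated_qtns.dropna(subset=["favorable_dosage"])
                 .drop_duplicates("marker").set_index("marker")["favorable_dosage"]
                 .astype(int).to_dict())
    y = res.traits.loc[res.geno.accessions, cfg.gs_target]
    res.cv_results = gs.run_gs_comparison(y, res.geno, res.marker_sets, favorable,
                                          k=cfg.gs_k, repeats=cfg.gs_repeats,
                                          seed=cfg.seed + 6)
    res.gs_comparison = gs.compare_sets(res.cv_results)
    man["counts"]["marker_set_sizes"] = {k: len(v.markers) for k, v in res.marker_sets.items()}
    man["counts"]["gs_mean_r"] = {
        r.set_id: round(float(r.mean_r), 6)
        for r in res.gs_comparison["means"].itertuples()}


_STAGE_FN = {
    "simulate": _stage_simulate, "derive": _stage_derive, "ld": _stage_ld,
    "gwas": _stage_gwas, "qtl": _stage_qtl, "de": _stage_de,
    "coloc": _stage_coloc, "gs": _stage_gs,
}


def _write_outputs(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    h = res.config.config_hash()

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash={h}\n")
            df.to_csv(fh, sep="\t", **kw)

    if res.geno is not None:
        write_genotypes_vcf(res.geno, out / "genotypes.vcf")
    if res.raw_phenotypes is not None:
        res.raw_phenotypes.to_csv(out / "phenotypes_raw.csv", index=False)
    if res.annotation is not None:
        synth.annotation_to_gff3(res.annotation, out / "annotation.gff3")
    if res.counts is not None:
        res.counts.to_csv(out / "counts.tsv", sep="\t")
        res.sample_sheet.to_csv(out / "sample_sheet.csv", index=False)
    if res.traits is not None:
        save(res.traits, "traits.tsv", index_label="accession")
        save(res.trait_summary, "trait_summary.tsv", index_label="trait")
    if res.ld_pairs is not None:
        save(res.ld_pairs, "ld_pairs.tsv", index=False)
        decay_rows = []
        for scope, prof in (res.decay or {}).items():
            for thr in (0.1, 0.3):
                decay_rows.append((scope, thr, prof.decay_distance(thr), prof.method))
        save(pd.DataFrame(decay_rows, columns=["scope", "threshold", "distance_bp", "method"]),
             "ld_decay.tsv", index=False)
    if res.qtns is not None:
        save(res.qtns, "qtns.tsv", index=False)
    if res.validated_qtns is not None:
        save(res.validated_qtns, "qtns_validated.tsv", index=False)
        save(res.allele_tests, "allele_tests.tsv", index=False)
    if res.qtls is not None:
        save(qtl.qtls_to_frame(res.qtls), "qtls.tsv", index=False)
    if res.degs is not None:
        save(res.degs, "degs.tsv", index=False)
    if res.coloc_summary is not None:
        (out / "coloc_summary.json").write_text(json.dumps(res.coloc_summary, indent=2))
    if res.cv_results is not None:
        save(res.cv_results, "gs_cv.tsv", index=False)
        comp = res.gs_comparison
        means = comp["means"].copy()
        means["letter"] = means["set_id"].map(comp["letters"])
        save(means, "gs_comparison.tsv", index=False)
    (out / "manifest.json").write_text(json.dumps(res.manifest, indent=2, sort_keys=True))
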