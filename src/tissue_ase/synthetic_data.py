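"""Ground-truth simulator for multi-tissue, multi-replicate allele counts.

The generator emulates the data-generating structure of a single-donor
multi-tissue ASE study: a panel of heterozygous coding SNPs (controls,
deleterious nonsynonymous, and stop-gain variants) measured by three
assays — deep targeted sequencing (mmPCR-like, two technical replicates
per tissue, depth decoupled from expression), RNA-seq (depth tied to a
per-gene expression level, so lowly expressed genes are underpowered),
and exome DNA from two tissues (allelic ratio ~0.5 regardless of
expression).

Each site carries a true cross-tissue ASE class: balanced everywhere
(no ASE), imbalanced the same way in every tissue (shared ASE),
tissue-dependent imbalance (variable ASE), or monoallelic. Stop-gain
(nonsense) sites override their RNA allele fraction with a
nonsense-mediated-decay mean that is lower for rare alleles than for
common ones, while their DNA fraction stays 0.5. Reference-mapping bias
is applied as an odds multiplier beta on the reference allele at read
sampling time: observed P(ref read) = beta*(1-mu) / (beta*(1-mu) + mu),
so a truly balanced site (mu = 0.5) shows ref fraction beta/(beta+1).
Replicate noise is beta-binomial with intra-class correlation rho,
optionally inflated for designated high-noise tissues (emulating
degraded-RNA tissues such as post-mortem pancreas).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cross_tissue import ASEClass
from .io_formats import (AlleleCountRecord, Assay, HetSite, VariantClass,
                         write_count_table, write_sites_table)

logger = logging.getLogger("tissue_ase")

_DEFAULT_TISSUES = ("cerebellum", "frontal_lobe", "pancreas", "stomach",
                    "small_intestine", "colon", "heart", "liver")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults define the study conditions.

    Class proportions mirror the observed predominance of balanced sites
    (~70% no ASE, ~21% shared, ~5% variable) plus a small monoallelic
    set; variant classes mirror a targeted panel of controls,
    deleterious nsSNPs and nonsense variants in roughly 62/23/15
    proportion. Depths: the targeted assay draws ~2000 reads per site
    per replicate regardless of expression; RNA-seq depth follows a
    log-normal per-gene expression level (median ~`rna_depth_mean`
    x e^{-sigma^2/2}) so many measurements fall below the depth filters;
    exome DNA averages ~80x. ``ref_bias_factor`` >= 1 is the mapping-bias
    odds multiplier on the reference allele; ``overdispersion_rho`` is
    the beta-binomial intra-class correlation of replicate noise.
    """

    n_sites: int = 500
    tissue_ids: tuple[str, ...] = _DEFAULT_TISSUES
    dna_sample_ids: tuple[str, ...] = ("frontal_lobe", "small_intestine")
    replicates_per_tissue: int = 2
    class_proportions: dict[str, float] = field(default_factory=lambda: {
        "no_ase": 0.70, "shared_ase": 0.21, "variable_ase": 0.05,
        "monoallelic": 0.04,
    })
    variant_class_proportions: dict[str, float] = field(default_factory=lambda: {
        "control": 0.62, "deleterious_nsSNP": 0.23, "nonsense": 0.15,
    })
    rare_fraction_nonsense: float = 0.5
    nmd_alt_mean_rare: float = 0.15
    nmd_alt_mean_common: float = 0.30
    shared_ase_alt_mean: float = 0.20
    within_class_tissue_sd: float = 0.03
    variable_ase_tissue_sd: float = 0.30
    ref_bias_factor: float = 1.05
    overdispersion_rho: float = 0.005
    high_noise_tissues: tuple[str, ...] = ()
    high_noise_rho: float = 0.05
    mmpcr_depth_mean: float = 2000.0
    mmpcr_depth_shape: float = 10.0
    rna_depth_mean: float = 30.0
    rna_lognormal_sigma: float = 1.0
    dna_depth_mean: float = 80.0
    other_base_fraction: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or not self.tissue_ids:
            raise ValueError("need at least one site and one tissue")
        for name, props in (("class_proportions", self.class_proportions),
                            ("variant_class_proportions", self.variant_class_proportions)):
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for m in (self.nmd_alt_mean_rare, self.nmd_alt_mean_common,
                  self.shared_ase_alt_mean):
            if not 0.0 < m < 1.0:
                raise ValueError("allele-fraction means must lie in (0,1)")
        if self.ref_bias_factor < 1.0:
            raise ValueError("ref_bias_factor must be >= 1")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho outside [0,1)")
        unknown = set(self.dna_sample_ids) - set(self.tissue_ids)
        if unknown:
            raise ValueError(f"dna_sample_ids not among tissue_ids: {sorted(unknown)}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth: one row per site, and one per (site, tissue).

    ``sites`` columns: site_id, true_class, expected_label,
    variant_class, maf, is_private, is_rare. ``per_tissue`` columns:
    site_id, tissue_id, mu (true RNA alternate-allele fraction),
    theta (observed alternate-read probability after mapping bias),
    mu_dna, theta_dna.
    """

    sites: pd.DataFrame
    per_tissue: pd.DataFrame


@dataclass(frozen=True)
class SimDataset:
    sites: list[HetSite]
    records: list[AlleleCountRecord]
    truth: SimTruth

    def records_for(self, assay: Assay) -> list[AlleleCountRecord]:
        return [r for r in self.records if r.assay == assay]


#: profile label the classifier should recover for each true class
_EXPECTED_LABEL = {
    "no_ase": ASEClass.NO_ASE,
    "shared_ase": ASEClass.SHARED_ASE,
    "variable_ase": ASEClass.VARIABLE_ASE,
    # monoallelic sites sit at an extreme mean with tiny dispersion, which
    # the three-way classifier labels shared; detect_monoallelic finds them
    "monoallelic": ASEClass.SHARED_ASE,
}


def biased_alt_probability(mu: np.ndarray | float, beta: float) -> np.ndarray | float:
    """Observed alternate-read probability after reference-mapping bias.

    The bias multiplies the reference allele's sampling odds by beta, so
    theta = mu / (beta*(1-mu) + mu); at mu = 0.5 the observed reference
    fraction is beta/(beta+1).
    """
    return mu / (beta * (1.0 - mu) + mu)


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, theta: np.ndarray,
                   rho: np.ndarray) -> np.ndarray:
    """Draw counts ~ BetaBinomial(n, theta, rho); rho = 0 is pure binomial."""
    n = np.asarray(n)
    theta = np.broadcast_to(theta, n.shape).astype(float)
    rho = np.broadcast_to(rho, n.shape).astype(float)
    p = theta.copy()
    od = rho > 0
    if od.any():
        a = theta[od] * (1.0 - rho[od]) / rho[od]
        b = (1.0 - theta[od]) * (1.0 - rho[od]) / rho[od]
        p[od] = rng.beta(a, b)
    return rng.binomial(n, p)


def simulate_dataset(config: SimConfig | None = None) -> SimDataset:
    """Generate sites, counts for all three assays, and the ground truth.

    Deterministic given ``config.seed``: the same config always yields
    the identical dataset.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    tissues = list(cfg.tissue_ids)
    n_t = len(tissues)

    class_names = list(cfg.class_proportions)
    classes = rng.choice(class_names, size=n, p=[cfg.class_proportions[c] for c in class_names])
    vc_names = list(cfg.variant_class_proportions)
    vclasses = rng.choice(vc_names, size=n,
                          p=[cfg.variant_class_proportions[c] for c in vc_names])

    # --- site table ---------------------------------------------------
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    maf = np.full(n, np.nan)
    is_private = np.zeros(n, dtype=bool)
    for i in range(n):
        vc = vclasses[i]
        if vc == "control":
            maf[i] = rng.uniform(0.06, 0.5)
        elif vc == "deleterious_nsSNP":
            is_private[i] = True  # panel mirrors rare/private deleterious picks
        else:  # nonsense: rare (private) or common by configured fraction
            if rng.random() < cfg.rare_fraction_nonsense:
                is_private[i] = True
            else:
                maf[i] = rng.uniform(0.06, 0.5)

    sites = [
        HetSite(
            site_id=f"site{i:05d}", chrom="chr1", pos=1000 * (i + 1),
            ref_base=str(_BASES[ref_idx[i]]), alt_base=str(_BASES[alt_idx[i]]),
            gene_id=f"GENE{i:05d}",
            variant_class=VariantClass(vclasses[i]),
            maf=None if np.isnan(maf[i]) else float(maf[i]),
            is_private=bool(is_private[i]),
            is_intragenic=True,
        )
        for i in range(n)
    ]

    # --- true per-tissue alternate-allele fractions -------------------
    mu = np.empty((n, n_t))
    true_class = classes.astype(object).copy()
    for i in range(n):
        c = classes[i]
        if c == "no_ase":
            mu[i] = 0.5
        elif c == "shared_ase":
            base = cfg.shared_ase_alt_mean if rng.random() < 0.5 \
                else 1.0 - cfg.shared_ase_alt_mean
            mu[i] = base + rng.normal(0.0, cfg.within_class_tissue_sd, n_t)
        elif c == "variable_ase":
            mu[i] = rng.normal(0.5, cfg.variable_ase_tissue_sd, n_t)
        else:  # monoallelic: one allele everywhere
            mu[i] = 0.99 if rng.random() < 0.5 else 0.01
        if vclasses[i] == "nonsense":
            # NMD depletes the alternate (stop-gain) allele in RNA
            nmd = cfg.nmd_alt_mean_rare if sites[i].is_rare else cfg.nmd_alt_mean_common
            mu[i] = nmd + rng.normal(0.0, cfg.within_class_tissue_sd, n_t)
            true_class[i] = "shared_ase"
    mu = np.clip(mu, 0.02, 0.98)

    beta = cfg.ref_bias_factor
    theta = biased_alt_probability(mu, beta)
    mu_dna = np.full((n, len(cfg.dna_sample_ids)), 0.5)
    theta_dna = biased_alt_probability(mu_dna, beta)

    rho_by_tissue = np.array([
        cfg.high_noise_rho if t in cfg.high_noise_tissues else cfg.overdispersion_rho
        for t in tissues
    ])

    records: list[AlleleCountRecord] = []

    def emit(assay: Assay, tissue: str, rep: str, depth: np.ndarray,
             th: np.ndarray, rho: float) -> None:
        depth = np.asarray(depth, dtype=np.int64)
        other = rng.binomial(depth, cfg.other_base_fraction)
        bi = depth - other
        alt = _beta_binomial(rng, bi, th, np.full(bi.shape, rho))
        ref = bi - alt
        for i in range(n):
            if depth[i] == 0:
                continue
            records.append(AlleleCountRecord(
                site_id=sites[i].site_id, tissue_id=tissue, replicate_id=rep,
                assay=assay, ref_count=int(ref[i]), alt_count=int(alt[i]),
                other_count=int(other[i]),
            ))

    # targeted deep assay: depth decoupled from expression, 2 replicates
    k = cfg.mmpcr_depth_shape
    for j, tissue in enumerate(tissues):
        for r in range(cfg.replicates_per_tissue):
            depth = rng.negative_binomial(k, k / (k + cfg.mmpcr_depth_mean), n)
            emit(Assay.MMPCR, tissue, f"rep{r + 1}", depth, theta[:, j],
                 rho_by_tissue[j])

    # RNA-seq: depth follows per-gene expression, decoupled per tissue
    sigma = cfg.rna_lognormal_sigma
    for j, tissue in enumerate(tissues):
        expr = rng.lognormal(np.log(cfg.rna_depth_mean) - sigma ** 2 / 2, sigma, n)
        depth = rng.poisson(expr)
        emit(Assay.RNA_SEQ, tissue, "rep1", depth, theta[:, j], rho_by_tissue[j])

    # exome DNA from the two DNA tissues: balanced apart from mapping bias
    for j, tissue in enumerate(cfg.dna_sample_ids):
        depth = rng.poisson(cfg.dna_depth_mean, n)
        emit(Assay.EXOME_DNA, tissue, "rep1", depth, theta_dna[:, j],
             cfg.overdispersion_rho)

    sites_df = pd.DataFrame({
        "site_id": [s.site_id for s in sites],
        "true_class": true_class,
        "expected_label": [_EXPECTED_LABEL[c].value for c in true_class],
        "variant_class": vclasses,
        "maf": maf,
        "is_private": is_private,
        "is_rare": [s.is_rare for s in sites],
    })
    per_tissue = pd.DataFrame({
        "site_id": np.repeat([s.site_id for s in sites], n_t),
        "tissue_id": np.tile(tissues, n),
        "mu": mu.ravel(),
        "theta": theta.ravel(),
    })
    logger.info("simulate_dataset: %d sites, %d tissues, %d count records "
                "(seed %d)", n, n_t, len(records), cfg.seed)
    return SimDataset(sites=sites, records=records,
                      truth=SimTruth(sites=sites_df, per_tissue=per_tissue))


def smoke_config(seed: int = 7) -> SimConfig:
    """A tiny configuration that exercises every pipeline stage quickly."""
    return SimConfig(
        n_sites=50,
        tissue_ids=("frontal_lobe", "small_intestine", "colon", "liver"),
        dna_sample_ids=("frontal_lobe", "small_intestine"),
        seed=seed,
    )


def _write_vcf(sites: Sequence[HetSite], path: Path,
               dna_samples: Sequence[str]) -> None:
    """Plain-text VCF v4.2 with 0/1 genotypes for each DNA sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chr1,length=250000000>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dna_samples) + "\n")
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
            gts = "\t".join(["0/1"] * len(dna_samples))
            fh.write(f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref_base}\t"
                     f"{s.alt_base}\t.\tPASS\t.\tGT\t{gts}\n")


def _write_annotation(sites: Sequence[HetSite], path: Path) -> None:
    pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "ref": [s.ref_base for s in sites],
        "alt": [s.alt_base for s in sites],
        "gene_id": [s.gene_id for s in sites],
        "variant_class": [s.variant_class.value for s in sites],
        "maf": [s.maf if s.maf is not None else "" for s in sites],
        "is_private": [s.is_private for s in sites],
        "is_intragenic": [s.is_intragenic for s in sites],
    }).to_csv(path, sep="\t", index=False)


def _write_genes_bed(sites: Sequence[HetSite], path: Path, pad: int = 200) -> None:
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos)):
            if s.is_intragenic:
                fh.write(f"{s.chrom}\t{s.pos - 1 - pad}\t{s.pos + pad}\t"
                         f"{s.gene_id or '.'}\n")


def end_to_end_fixture(config: SimConfig | None = None,
                       out_dir: str | Path = "fixtures") -> dict[str, Path]:
    """Write a complete on-disk fixture readable by the io layer.

    Produces a sites VCF (with DNA-sample genotype columns), an
    annotation TSV, a sites TSV, one count TSV per assay, a gene BED
    and the two truth TSVs. Regeneration with the same config is
    byte-identical.
    """
    cfg = config or smoke_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(cfg)
    paths = {
        "vcf": out / "sites.vcf",
        "annotation": out / "sites_annotation.tsv",
        "sites": out / "sites.tsv",
        "genes_bed": out / "genes.bed",
        "truth_sites": out / "truth_sites.tsv",
        "truth_per_tissue": out / "truth_per_tissue.tsv",
    }
    _write_vcf(data.sites, paths["vcf"], cfg.dna_sample_ids)
    _write_annotation(data.sites, paths["annotation"])
    write_sites_table(data.sites, paths["sites"])
    _write_genes_bed(data.sites, paths["genes_bed"])
    data.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    data.truth.per_tissue.to_csv(paths["truth_per_tissue"], sep="\t", index=False,
                                 float_format="%.6g")
    for assay in Assay:
        p = out / f"counts_{assay.value}.tsv"
        write_count_table(data.records_for(assay), p)
        paths[f"counts_{assay.value}"] = p
    logger.info("end_to_end_fixture: wrote %d files to %s", len(paths), out)
    return paths
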