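# tissue-ase

Allele-specific expression (ASE) analysis across multiple tissues of one
individual: per-site binomial ASE calling with an empirical
reference-mapping-bias correction, a QC filter cascade, cross-tissue
classification of sites into no/shared/variable ASE, monoallelic-expression
detection, technical-replicate concordance, and cohort-level contrasts such
as the nonsense-mediated-decay (NMD) signal of stop-gain alleles.

## The problem

At a heterozygous coding SNP, RNA reads can be assigned to the two alleles,
and the **allelic ratio** `alt / (ref + alt)` measures their relative
expression. An imbalanced ratio can modify the effective dose of a
deleterious allele — a stop-gain allele degraded by NMD, or a damaging
missense allele that happens to sit on the lowly expressed haplotype — and
this imbalance can differ between tissues. The package answers, for a panel
of heterozygous sites measured in many tissues (by RNA-seq and by deep
targeted mmPCR-style sequencing with technical replicates):

1. **Is each site imbalanced in each tissue?** A two-sided exact binomial
   test of `ref ~ Binomial(n, p̂)`, where `p̂` is the *empirical* probability
   that a read carries the reference allele, estimated over all
   depth-passing sites in the sample. Aligning to the reference genome
   favours reference-carrying reads, so `p̂ > 0.5`; testing against `p̂`
   instead of 0.5 absorbs that mapping bias. The p-value is the
   minimum-likelihood two-sided construction: the summed probability of all
   outcomes no more likely than the observed one.
2. **Which QC filters does the measurement survive?** Base quality ≥ 10 at
   counting time; each allele ≥ 5 reads and total ≥ 20; ≤ 5% of reads on a
   third or fourth base (bi-allelic expression); intragenic location.
   Significance cutoffs are 0.05 for RNA-seq and 0.01 for the deep targeted
   assay.
3. **How does the imbalance behave across tissues?** Each site's
   QC-passing ratios are summarised by their mean m and population standard
   deviation σ: **no ASE** if 0.35 ≤ m ≤ 0.65 and σ < 0.2; **shared ASE**
   if m < 0.35 or m > 0.65, σ < 0.2, and at least one tissue significant at
   0.01; **variable ASE** if σ > 0.2 with at least one significant tissue.
   Sites at a ratio extreme (≥ 0.95 toward one allele) in ≥ 5 testable
   tissues are flagged monoallelic.
4. **Are the calls reproducible, and what do cohort contrasts show?**
   Replicate concordance (Pearson r of ratios, label agreement over cutoff
   grids), Welch t-tests of group ratios (nonsense vs control, rare vs
   common), a DNA-allelic-ratio guard against genotyping/mappability
   artifacts, and Fisher exact enrichment of deleteriousness by ASE class.

A ground-truth simulator (`tissue_ase.synthetic_data`) generates
multi-tissue, multi-replicate beta-binomial counts with configurable
mapping bias, overdispersion, depth regimes, ASE classes and NMD effects,
so every stage is testable without sequencing data.

## Worked example

```python
from tissue_ase import (Assay, SimConfig, simulate_dataset, merge_replicates,
                        estimate_reference_bias, call_ase, build_profiles)

data = simulate_dataset(SimConfig(seed=11))          # 500 sites x 8 tissues
records = merge_replicates(data.records_for(Assay.MMPCR))
bias = estimate_reference_bias(records)              # per tissue x assay
print(round(bias.p_ref[("liver", "mmpcr")], 3))      # 0.549

calls = call_ase(records, data.sites, bias)
profiles = build_profiles(calls)
from collections import Counter
print(Counter(p.class_label.value for p in profiles))
# Counter({'no_ase': 318, 'shared_ase': 166, 'variable_ase': 16})
```

The estimated reference-read probability 0.549 reflects the simulated
mapping bias (odds factor 1.05 ⇒ 0.512 at balanced sites) plus the pull of
the one-directional NMD sites; the class counts recover the configured mix
(70% no ASE; shared ASE collects the configured shared, monoallelic and
NMD-affected nonsense sites; ~5% variable). Compared against the generator's
truth labels, 99.6% of sites are classified correctly at this seed.

The same chain is available from the shell:

```bash
tissue-ase simulate --out-dir fx
tissue-ase test --counts fx/counts_mmpcr.tsv --sites fx/sites.tsv \
    --assay mmpcr --out calls.tsv
tissue-ase classify --ase calls.tsv --out profiles.tsv
tissue-ase enrich --profiles profiles.tsv --sites fx/sites.tsv \
    --classes shared_ase,no_ase --flag deleterious
```

## Layout

- `src/tissue_ase/io_formats.py` — VCF/mpileup/TSV/BED readers and writers,
  data model (`HetSite`, `AlleleCountRecord`)
- `src/tissue_ase/ase_core.py` — bias estimation, exact binomial test,
  QC cascade (`call_ase`)
- `src/tissue_ase/cross_tissue.py` — profiles, classification, monoallelic
  detection, correlations, ratio ranges
- `src/tissue_ase/cohort_stats.py` — group t-tests, DNA-bias filter,
  frequency strata, Fisher enrichment
- `src/tissue_ase/replicates.py` — merging, concordance, cutoff sweep
- `src/tissue_ase/synthetic_data.py` — generator and on-disk fixtures
- `src/tissue_ase/cli.py` — `tissue-ase` subcommands
- `docs/methods.md` — model, parameters, and design notes
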