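"""Cohort-level contrasts: variant-class and frequency-stratum comparisons
of allelic ratios, DNA-bias filtering of nonsense sites, and enrichment of
deleteriousness across ASE classes.

The central biological contrast is nonsense-mediated decay (NMD): a
premature stop codon marks its transcript for degradation, so at a
heterozygous stop-gain site the nonsense allele contributes fewer RNA
reads and the allelic ratio drops below 0.5. Comparing rare against
common nonsense alleles asks whether rare stop-gains show the stronger
decay signal. DNA allelic ratios from exome sequencing guard against
genotyping or mappability artifacts masquerading as decay.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .ase_core import ASECall
from .cross_tissue import ASEClass, TissueASEProfile
from .io_formats import HetSite, VariantClass

logger = logging.getLogger("tissue_ase")


@dataclass(frozen=True)
class GroupComparison:
    """A two-group comparison of allelic ratios within one tissue."""

    tissue_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_ratio_a: float | None
    mean_ratio_b: float | None
    t_statistic: float | None
    p_value: float | None


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 Fisher test of a boolean flag across two ASE classes.

    ``table`` rows are the two classes, columns are (flagged,
    unflagged). ``odds_ratio`` is the sample odds ratio ad/bc; when a
    zero cell makes it undefined, 0.5 is added to every cell and
    ``haldane_corrected`` is set.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    class_a: str
    class_b: str
    haldane_corrected: bool = False


def dna_bias_filter(
    sites: Sequence[HetSite],
    dna_calls: Sequence[ASECall],
    min_dna_alt_ratio: float = 0.2,
) -> list[HetSite]:
    """Drop nonsense sites whose DNA alt ratio is low in every DNA sample.

    A stop-gain site whose exome-DNA alternate-allele ratio sits below
    the threshold in ALL DNA samples with QC-passing calls is more
    plausibly a genotyping or mappability artifact than a decayed
    transcript, and is removed. Non-nonsense sites pass through; a
    nonsense site with no usable DNA call anywhere is retained with a
    warning.
    """
    by_site: dict[str, list[float]] = {}
    for c in dna_calls:
        if c.qc_pass and c.allelic_ratio is not None:
            by_site.setdefault(c.site_id, []).append(c.allelic_ratio)
    kept = []
    for s in sites:
        if s.variant_class != VariantClass.NONSENSE:
            kept.append(s)
            continue
        ratios = by_site.get(s.site_id)
        if not ratios:
            warnings.warn(f"nonsense site {s.site_id} has no usable DNA call; retained")
            kept.append(s)
            continue
        if all(r < min_dna_alt_ratio for r in ratios):
            logger.info("dna_bias_filter: removed %s (DNA alt ratios %s)",
                        s.site_id, [round(r, 3) for r in ratios])
            continue
        kept.append(s)
    return kept


def stratify_by_frequency(
    sites: Sequence[HetSite],
    maf_cutoff: float = 0.05,
) -> dict[str, list[HetSite]]:
    """Partition sites into rare and common by minor allele frequency.

    Common means MAF strictly above the cutoff; rare means MAF at or
    below it, or private (absent from reference panels). A site with no
    MAF and no private flag is treated as rare with a warning.
    """
    rare, common = [], []
    for s in sites:
        if s.maf is None:
            if not s.is_private:
                warnings.warn(f"site {s.site_id} has no MAF and is not flagged "
                              "private; treated as rare")
            rare.append(s)
        elif s.maf > maf_cutoff:
            common.append(s)
        else:
            rare.append(s)
    return {"rare": rare, "common": common}


def _welch_or_pooled(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    ase_calls: Sequence[ASECall],
    sites: Sequence[HetSite] | Mapping[str, HetSite],
    grouping: str | Callable[[HetSite], str] = "variant_class",
    pairs: Sequence[tuple[str, str]] | None = None,
    per_tissue: bool = True,
    equal_var: bool = False,
    maf_cutoff: float = 0.05,
) -> list[GroupComparison]:
    """Two-sample t-tests on allelic ratios between site groups.

    ``grouping`` is ``"variant_class"`` (control / deleterious_nsSNP /
    nonsense), ``"rarity"`` (rare / common, applied within nonsense
    sites' MAF annotations), or any callable HetSite -> label. Only
    QC-passing calls enter. The default test is Welch's (unequal
    variance); ``equal_var=True`` gives the pooled variant. Groups with
    fewer than 2 calls are reported with a missing statistic and
    p-value.
    """
    site_map = sites if isinstance(sites, Mapping) else {s.site_id: s for s in sites}
    if callable(grouping):
        label_of = grouping
    elif grouping == "variant_class":
        label_of = lambda s: s.variant_class.value  # noqa: E731
    elif grouping == "rarity":
        label_of = lambda s: "rare" if s.is_rare or (s.maf is not None and s.maf <= maf_cutoff) else "common"  # noqa: E731
    else:
        raise ValueError(f"unknown grouping key {grouping!r}")

    # tissue -> label -> ratios
    by_tissue: dict[str, dict[str, list[float]]] = {}
    for c in ase_calls:
        if not c.qc_pass or c.allelic_ratio is None:
            continue
        site = site_map.get(c.site_id)
        if site is None:
            raise KeyError(f"call references unknown site {c.site_id!r}")
        tissue = c.tissue_id if per_tissue else "all"
        by_tissue.setdefault(tissue, {}).setdefault(label_of(site), []).append(
            c.allelic_ratio)

    results: list[GroupComparison] = []
    for tissue in sorted(by_tissue):
        groups = by_tissue[tissue]
        labels = sorted(groups)
        todo = pairs if pairs is not None else [
            (a, b) for i, a in enumerate(labels) for b in labels[i + 1:]
        ]
        for a_lab, b_lab in todo:
            a = np.asarray(groups.get(a_lab, []), dtype=float)
            b = np.asarray(groups.get(b_lab, []), dtype=float)
            if len(a) >= 2 and len(b) >= 2:
                t, p = _welch_or_pooled(a, b, equal_var)
            else:
                t = p = None
            results.append(GroupComparison(
                tissue_id=tissue, group_a=a_lab, group_b=b_lab,
                n_a=len(a), n_b=len(b),
                mean_ratio_a=float(a.mean()) if len(a) else None,
                mean_ratio_b=float(b.mean()) if len(b) else None,
                t_statistic=t, p_value=p,
            ))
    return results


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float, bool]:
    """Two-sided Fisher exact test on a 2x2 table of counts.

    Returns (odds_ratio, p_value, haldane_corrected). The p-value is the
    standard hypergeometric construction: the sum of probabilities of
    all tables with the observed margins that are no more probable than
    the observed one. The odds ratio is ad/bc from the raw counts, with
    a 0.5 Haldane-Anscombe correction applied only when a zero cell
    leaves it undefined.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = b * c == 0  # ad/bc undefined only on division by zero
    if corrected:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a2 * d2) / (b2 * c2)
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p), corrected


def fisher_enrichment(
    profiles: Sequence[TissueASEProfile],
    sites: Sequence[HetSite] | Mapping[str, HetSite],
    class_a: ASEClass | str,
    class_b: ASEClass | str,
    flag: str | Callable[[HetSite], bool] = "deleterious",
) -> EnrichmentResult:
    """Fisher test: is a site flag enriched in one ASE class vs another?

    ``flag`` defaults to "deleterious" (variant class is
    deleterious_nsSNP or nonsense); any callable HetSite -> bool works.
    The 2x2 table is [[flagged_a, unflagged_a], [flagged_b,
    unflagged_b]].
    """
    class_a, class_b = ASEClass(class_a), ASEClass(class_b)
    site_map = sites if isinstance(sites, Mapping) else {s.site_id: s for s in sites}
    if callable(flag):
        flag_of = flag
    elif flag == "deleterious":
        flag_of = lambda s: s.variant_class != VariantClass.CONTROL  # noqa: E731
    elif flag == "rare":
        flag_of = lambda s: s.is_rare  # noqa: E731
    else:
        raise ValueError(f"unknown flag {flag!r}")

    counts = {class_a: [0, 0], class_b: [0, 0]}
    for prof in profiles:
        if prof.class_label not in counts:
            continue
        site = site_map.get(prof.site_id)
        if site is None:
            raise KeyError(f"profile references unknown site {prof.site_id!r}")
        counts[prof.class_label][0 if flag_of(site) else 1] += 1
    if sum(counts[class_a]) == 0 or sum(counts[class_b]) == 0:
        raise ValueError(f"empty ASE class among {class_a.value}, {class_b.value}")
    table = (tuple(counts[class_a]), tuple(counts[class_b]))
    odds, p, corrected = fisher_exact_2x2(table)
    return EnrichmentResult(table=table, odds_ratio=odds, p_value=p,
                            class_a=class_a.value, class_b=class_b.value,
                            haldane_corrected=corrected)
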