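"""Technical-replicate handling: merging, concordance, and the
classification-reproducibility sweep.

Two technical replicates per tissue allow three checks on the deep
targeted assay: merged counts for maximum power (read counts are
additive, so testing the merged counts equals testing the summed
counts), effect-size concordance between replicates (Pearson r of
allelic ratios, and |Δratio| stratified by read depth), and a sweep that
re-runs the cross-tissue classification independently from each
replicate over a grid of cutoffs to find where the class labels become
reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .ase_core import ASECall
from .cross_tissue import ASEClass, ClassParams, build_profiles
from .io_formats import AlleleCountRecord

logger = logging.getLogger("tissue_ase")

#: depth bins (on the smaller of the two replicate depths) for |delta ratio|
DEFAULT_DEPTH_BINS: tuple[tuple[float, float], ...] = (
    (20, 100), (100, 200), (200, 500), (500, 2000), (2000, float("inf")),
)


def merge_replicates(records: Sequence[AlleleCountRecord]) -> list[AlleleCountRecord]:
    """Sum replicate counts per (site, tissue, assay); output rep id "merged".

    Read totals are conserved: the summed output counts equal the summed
    input counts for every key.
    """
    merged: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for r in records:
        key = (r.site_id, r.tissue_id, r.assay)
        if key not in merged:
            merged[key] = [0, 0, 0]
            order.append(key)
        merged[key][0] += r.ref_count
        merged[key][1] += r.alt_count
        merged[key][2] += r.other_count
    return [
        AlleleCountRecord(site_id=k[0], tissue_id=k[1], replicate_id="merged",
                          assay=k[2], ref_count=merged[k][0],
                          alt_count=merged[k][1], other_count=merged[k][2])
        for k in order
    ]


@dataclass(frozen=True)
class ConcordanceReport:
    """Effect-size agreement between two technical replicates in one tissue."""

    tissue_id: str
    pearson_r: float | None
    mean_abs_delta: Mapping[tuple[float, float], float | None]
    n_sites: int


def replicate_concordance(
    calls_rep1: Sequence[ASECall],
    calls_rep2: Sequence[ASECall],
    depth_bins: Sequence[tuple[float, float]] = DEFAULT_DEPTH_BINS,
) -> list[ConcordanceReport]:
    """Per-tissue Pearson r of allelic ratios between replicates.

    Calls are matched on (site, tissue); only pairs QC-passing in both
    replicates count. |Δratio| is summarised per depth bin, binning each
    pair by the smaller of the two replicate read totals. Tissues with
    fewer than 3 shared sites get a missing r and a warning.
    """
    def index(calls):
        return {(c.site_id, c.tissue_id): c for c in calls
                if c.qc_pass and c.allelic_ratio is not None}

    idx1, idx2 = index(calls_rep1), index(calls_rep2)
    shared = sorted(set(idx1) & set(idx2))
    by_tissue: dict[str, list[tuple[float, float, int]]] = {}
    for key in shared:
        c1, c2 = idx1[key], idx2[key]
        by_tissue.setdefault(key[1], []).append(
            (c1.allelic_ratio, c2.allelic_ratio,
             min(c1.ref_count + c1.alt_count, c2.ref_count + c2.alt_count))
        )
    reports = []
    for tissue in sorted(by_tissue):
        rows = by_tissue[tissue]
        r1 = np.array([x[0] for x in rows])
        r2 = np.array([x[1] for x in rows])
        depth = np.array([x[2] for x in rows])
        if len(rows) >= 3 and r1.std() > 0 and r2.std() > 0:
            r = float(np.corrcoef(r1, r2)[0, 1])
        else:
            r = None
            if len(rows) < 3:
                warnings.warn(f"tissue {tissue!r}: only {len(rows)} shared sites; "
                              "replicate correlation not computed")
        deltas = {}
        for lo, hi in depth_bins:
            mask = (depth >= lo) & (depth < hi)
            deltas[(lo, hi)] = float(np.abs(r1[mask] - r2[mask]).mean()) if mask.any() else None
        reports.append(ConcordanceReport(tissue_id=tissue, pearson_r=r,
                                         mean_abs_delta=deltas, n_sites=len(rows)))
    return reports


@dataclass(frozen=True)
class SweepResult:
    """Replicate label agreement at one grid point of the cutoff sweep."""

    ratio_cutoffs: tuple[float, float]
    dispersion_cutoff: float
    excluded_tissues: tuple[str, ...]
    concordance_3class: float
    concordance_2class: float
    n_sites: int


def _binary(label: ASEClass) -> str:
    return "ase" if label in (ASEClass.SHARED_ASE, ASEClass.VARIABLE_ASE) else "non_ase"


def classification_sweep(
    calls_rep1: Sequence[ASECall],
    calls_rep2: Sequence[ASECall],
    grid: Sequence[tuple[tuple[float, float], float]],
    exclusions: Sequence[Sequence[str]] = ((),),
    base_params: ClassParams | None = None,
) -> list[SweepResult]:
    """Label agreement between replicate-wise classifications over a grid.

    For each (ratio cutoff pair, dispersion cutoff) grid point and each
    tissue-exclusion subset, both replicates' calls are classified
    independently with the full rule set; concordance_3class is the
    fraction of sites (profiled from both replicates) with identical
    labels, and concordance_2class the same after coarsening to ASE
    (shared + variable) vs non-ASE. Coarsening can only merge labels, so
    the binary concordance is never below the 3-class one.
    """
    if not grid:
        raise ValueError("empty sweep grid")
    base = base_params or ClassParams()
    results = []
    for excluded in exclusions:
        excluded = tuple(excluded)
        keep1 = [c for c in calls_rep1 if c.tissue_id not in excluded]
        keep2 = [c for c in calls_rep2 if c.tissue_id not in excluded]
        for (lo, hi), disp in grid:
            params = replace(base, ratio_lo=lo, ratio_hi=hi, dispersion_max=disp)
            prof1 = {p.site_id: p for p in build_profiles(keep1, params.min_tissues, params)}
            prof2 = {p.site_id: p for p in build_profiles(keep2, params.min_tissues, params)}
            shared = sorted(set(prof1) & set(prof2))
            if shared:
                same3 = sum(prof1[s].class_label == prof2[s].class_label for s in shared)
                same2 = sum(_binary(prof1[s].class_label) == _binary(prof2[s].class_label)
                            for s in shared)
                c3, c2 = same3 / len(shared), same2 / len(shared)
            else:
                c3 = c2 = float("nan")
            results.append(SweepResult(
                ratio_cutoffs=(lo, hi), dispersion_cutoff=disp,
                excluded_tissues=excluded,
                concordance_3class=c3, concordance_2class=c2,
                n_sites=len(shared),
            ))
    return results
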