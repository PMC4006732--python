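"""Cross-tissue aggregation: ASE profiles, classification, monoallelic
detection, correlation structure and ratio-range summaries.

A site measured in several tissues is summarised by the mean and the
dispersion (population standard deviation) of its allelic ratios. Sites
fall into three classes: balanced everywhere (no ASE), imbalanced the
same way everywhere (shared ASE), or imbalanced differently across
tissues (variable ASE). Because a high-coverage binomial test flags even
trivial deviations from balance, classification combines effect size
(the ratio geometry) with significance rather than relying on p-values
alone.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ase_core import ASECall

logger = logging.getLogger("tissue_ase")


class ASEClass(str, enum.Enum):
    NO_ASE = "no_ase"
    SHARED_ASE = "shared_ase"
    VARIABLE_ASE = "variable_ase"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassParams:
    """Cutoffs of the three-way classification.

    The balanced band is mean ratio in [ratio_lo, ratio_hi] = [0.35,
    0.65]; the dispersion cutoff 0.2 is on the standard deviation of
    ratios across tissues (an SD: the variance of a [0,1]-bounded ratio
    cannot exceed 0.25, so a 0.2 cutoff on a variance would be nearly
    vacuous, and the replicate-concordance sweep range 0.05-0.3 only
    makes sense on the SD scale). Shared/variable calls additionally
    require at least ``min_significant_tissues`` tissues significant at
    ``alpha``.
    """

    ratio_lo: float = 0.35
    ratio_hi: float = 0.65
    dispersion_max: float = 0.2
    alpha: float = 0.01
    min_tissues: int = 3
    min_significant_tissues: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio_lo < 0.5 < self.ratio_hi < 1.0:
            raise ValueError("require 0 < ratio_lo < 0.5 < ratio_hi < 1")
        if self.dispersion_max <= 0:
            raise ValueError("dispersion_max must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha outside (0,1)")


@dataclass(frozen=True)
class TissueASEProfile:
    """Cross-tissue view of one site, over its QC-passing tissues."""

    site_id: str
    ratios: Mapping[str, float]
    p_values: Mapping[str, float]
    mean_ratio: float
    ratio_dispersion: float
    class_label: ASEClass = ASEClass.UNCLASSIFIED

    @property
    def n_tissues(self) -> int:
        return len(self.ratios)

    def n_significant(self, alpha: float) -> int:
        return sum(1 for p in self.p_values.values() if p is not None and p < alpha)


def build_profiles(
    ase_calls: Sequence[ASECall],
    min_tissues: int = 3,
    class_params: ClassParams | None = None,
) -> list[TissueASEProfile]:
    """Aggregate QC-passing calls into one profile per site and classify.

    Expects replicate-merged calls from a single assay; two calls for the
    same (site, tissue) raise. The dispersion is the population standard
    deviation of ratios across tissues (the tissue panel is the whole
    object of study, not a sample from one). Profiles seen in fewer than
    ``min_tissues`` tissues stay unclassified.
    """
    cp = class_params or ClassParams(min_tissues=min_tissues)
    by_site: dict[str, dict[str, ASECall]] = {}
    for c in ase_calls:
        if not c.qc_pass or c.allelic_ratio is None:
            continue
        tissues = by_site.setdefault(c.site_id, {})
        if c.tissue_id in tissues:
            raise ValueError(
                f"duplicate tissue {c.tissue_id!r} for site {c.site_id!r}; "
                "merge replicates before profiling"
            )
        tissues[c.tissue_id] = c
    profiles = []
    for site_id, calls in by_site.items():
        ratios = {t: c.allelic_ratio for t, c in calls.items()}
        pvals = {t: c.p_value for t, c in calls.items()}
        vals = np.array(list(ratios.values()))
        prof = TissueASEProfile(
            site_id=site_id, ratios=ratios, p_values=pvals,
            mean_ratio=float(vals.mean()),
            ratio_dispersion=float(vals.std(ddof=0)),
        )
        label = classify_profile(prof, cp) if prof.n_tissues >= cp.min_tissues \
            else ASEClass.UNCLASSIFIED
        profiles.append(TissueASEProfile(
            site_id=prof.site_id, ratios=prof.ratios, p_values=prof.p_values,
            mean_ratio=prof.mean_ratio, ratio_dispersion=prof.ratio_dispersion,
            class_label=label,
        ))
    logger.info("build_profiles: %d profiles from %d calls", len(profiles),
                len(ase_calls))
    return profiles


def classify_profile(profile: TissueASEProfile, params: ClassParams | None = None) -> ASEClass:
    """Assign no/shared/variable ASE from the ratio geometry + significance.

    No ASE: mean within the balanced band and dispersion below the
    cutoff. Shared ASE: mean outside the band, dispersion below the
    cutoff, and enough significant tissues. Variable ASE: dispersion
    above the cutoff and enough significant tissues. Cutoffs are strict
    inequalities; exact ties fall to UNCLASSIFIED.
    """
    p = params or ClassParams()
    if profile.n_tissues < p.min_tissues:
        return ASEClass.UNCLASSIFIED
    m, sd = profile.mean_ratio, profile.ratio_dispersion
    n_sig = profile.n_significant(p.alpha)
    if p.ratio_lo <= m <= p.ratio_hi and sd < p.dispersion_max:
        return ASEClass.NO_ASE
    if (m < p.ratio_lo or m > p.ratio_hi) and sd < p.dispersion_max \
            and n_sig >= p.min_significant_tissues:
        return ASEClass.SHARED_ASE
    if sd > p.dispersion_max and n_sig >= p.min_significant_tissues:
        return ASEClass.VARIABLE_ASE
    return ASEClass.UNCLASSIFIED


@dataclass(frozen=True)
class MonoallelicCall:
    site_id: str
    expressed_allele: str  # "ref" or "alt"
    consistent: bool
    n_tissues: int


def detect_monoallelic(
    profiles: Sequence[TissueASEProfile],
    mono_threshold: float = 0.95,
    min_testable: int = 5,
) -> list[MonoallelicCall]:
    """Find sites expressing a single allele in every testable tissue.

    A site qualifies when it has at least ``min_testable`` QC-passing
    tissues and every allelic ratio is >= mono_threshold (alt allele
    expressed) or every ratio is <= 1 - mono_threshold (ref allele).
    Sites whose ratios span both tails are never reported, so a reported
    call is always consistent (same allele favoured everywhere).
    """
    if not 0.5 < mono_threshold <= 1.0:
        raise ValueError("mono_threshold must lie in (0.5, 1]")
    out = []
    for prof in profiles:
        if prof.n_tissues < min_testable:
            continue
        vals = np.array(list(prof.ratios.values()))
        if np.all(vals >= mono_threshold):
            out.append(MonoallelicCall(prof.site_id, "alt", True, prof.n_tissues))
        elif np.all(vals <= 1.0 - mono_threshold):
            out.append(MonoallelicCall(prof.site_id, "ref", True, prof.n_tissues))
    return out


def pairwise_correlations(
    matrix: pd.DataFrame,
    method: str = "spearman",
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise-complete tissue-by-tissue correlations + a clustering order.

    ``matrix`` has genes or sites as rows and tissues as columns.
    Correlations use pairwise-complete observations; a pair with fewer
    than 3 complete rows gets a missing correlation and a warning. The
    returned leaf order comes from average-linkage clustering on
    1 - correlation and is deterministic given the input.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr = matrix.corr(method=method, min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    n_pairs = matrix.notna().astype(int).T @ matrix.notna().astype(int)
    if ((n_pairs < 3) & ~np.eye(len(corr), dtype=bool)).to_numpy().any():
        warnings.warn("some tissue pairs have < 3 complete observations; "
                      "their correlations are missing")
    order = list(corr.columns)
    if len(corr) > 2 and not corr.isna().to_numpy().any():
        dist = 1.0 - corr.to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2  # enforce exact symmetry for squareform
        link = hierarchy.average(squareform(dist, checks=False))
        leaves = hierarchy.leaves_list(link)
        order = [corr.columns[i] for i in leaves]
    return corr, order


class FlipClass(str, enum.Enum):
    NONE = "none"
    MAJOR = "major"        # < 0.2 in one tissue, > 0.8 in another
    LARGE = "large"        # < 0.4 to > 0.8
    MODERATE = "moderate"  # < 0.2 to > 0.6


@dataclass(frozen=True)
class RatioRange:
    site_id: str
    min_ratio: float
    max_ratio: float
    flip_class: FlipClass


def ratio_range_summary(profiles: Sequence[TissueASEProfile]) -> list[RatioRange]:
    """Per-site min/max allelic ratio and direction-flip class.

    Only sites profiled in >= 3 tissues are summarised. Flip classes,
    most extreme first: major (ratio below 0.2 in some tissue and above
    0.8 in another), large (below 0.4 to above 0.8), moderate (below 0.2
    to above 0.6).
    """
    out = []
    for prof in profiles:
        if prof.n_tissues < 3:
            continue
        vals = np.array(list(prof.ratios.values()))
        lo, hi = float(vals.min()), float(vals.max())
        if lo < 0.2 and hi > 0.8:
            flip = FlipClass.MAJOR
        elif lo < 0.4 and hi > 0.8:
            flip = FlipClass.LARGE
        elif lo < 0.2 and hi > 0.6:
            flip = FlipClass.MODERATE
        else:
            flip = FlipClass.NONE
        out.append(RatioRange(prof.site_id, lo, hi, flip))
    return out
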