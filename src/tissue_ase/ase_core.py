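"""Reference-bias estimation, the per-site binomial ASE test, and QC filters.

The ASE test at a heterozygous site asks whether the observed split of
reads between the two alleles is compatible with a binomial draw whose
success probability is not 1/2 but the *empirical* probability p̂ that a
read carries the reference allele — estimated over all (depth-passing)
sites in the sample. Aligning reads to the reference genome favours
reference-carrying reads, so p̂ is typically slightly above 0.5; testing
against p̂ rather than 0.5 absorbs that mapping bias.

The p-value is the exact two-sided minimum-likelihood construction: the
sum of the probabilities of all outcomes no more likely than the one
observed. This is well defined for any p̂ (unlike doubling one tail) and
coincides with brute-force enumeration over outcomes.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import AlleleCountRecord, Assay, HetSite

logger = logging.getLogger("tissue_ase")

_P_CLAMP = 1e-6
# relative slack when comparing outcome likelihoods; absorbs floating-point
# noise at exact ties (e.g. the symmetric outcome under p = 0.5)
_REL_TOL = 1e-7


class FilterFlag(enum.Enum):
    """QC filters applied to a per-site per-tissue measurement."""

    BASE_QUALITY = "base_quality"
    ALLELE_DEPTH = "allele_depth"
    TOTAL_DEPTH = "total_depth"
    SIGNIFICANCE = "significance"
    BIALLELIC = "biallelic"
    INTRAGENIC = "intragenic"


#: flags that void a measurement entirely (significance is a call, not QC)
_QC_FLAGS = frozenset({FilterFlag.ALLELE_DEPTH, FilterFlag.TOTAL_DEPTH,
                       FilterFlag.BIALLELIC, FilterFlag.INTRAGENIC})


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the QC cascade.

    Defaults: per-allele read depth >= 5 and total (ref+alt) depth >= 20;
    significance cutoffs 0.05 for RNA-seq and 0.01 for the deep targeted
    (mmPCR) assay; at most 5% of reads on a third/fourth base; intragenic
    location required.
    """

    min_allele_depth: int = 5
    min_total_depth: int = 20
    alpha_rna: float = 0.05
    alpha_mmpcr: float = 0.01
    max_other_fraction: float = 0.05
    require_intragenic: bool = True

    def __post_init__(self) -> None:
        if self.min_allele_depth < 0 or self.min_total_depth < 0:
            raise ValueError("depth thresholds must be non-negative")
        for a in (self.alpha_rna, self.alpha_mmpcr):
            if not 0.0 < a < 1.0:
                raise ValueError(f"alpha {a} outside (0,1)")
        if not 0.0 <= self.max_other_fraction <= 1.0:
            raise ValueError("max_other_fraction outside [0,1]")

    def alpha(self, assay: Assay) -> float:
        if assay == Assay.MMPCR:
            return self.alpha_mmpcr
        return self.alpha_rna


@dataclass(frozen=True)
class BiasModel:
    """Empirical probability that a read carries the reference allele.

    ``scope`` is either ``"global"`` (one p̂ for all records) or
    ``"sample"`` (one p̂ per tissue × assay, reflecting per-sample
    mapping-ratio differences). ``p_ref`` maps scope keys to estimates;
    the global model uses the single key ``("*", "*")``.
    """

    scope: str
    p_ref: Mapping[tuple[str, str], float]

    def lookup(self, record: AlleleCountRecord) -> float:
        if self.scope == "global":
            return self.p_ref[("*", "*")]
        key = (record.tissue_id, record.assay.value)
        if key not in self.p_ref:
            raise KeyError(
                f"no bias estimate for sample {key}; "
                "estimate_reference_bias did not see this tissue/assay"
            )
        return self.p_ref[key]


def _passes_depth(r: AlleleCountRecord, fp: FilterParams) -> bool:
    return (min(r.ref_count, r.alt_count) >= fp.min_allele_depth
            and r.total >= fp.min_total_depth)


def estimate_reference_bias(
    records: Sequence[AlleleCountRecord],
    scope: str = "sample",
    filter_params: FilterParams | None = None,
) -> BiasModel:
    """Estimate p̂ = Σref / Σ(ref+alt) over depth-passing records.

    Only the depth filters gate the estimate (low-coverage records add
    noise; significance must not, or the estimate would be circular).
    Estimates are clamped to [1e-6, 1-1e-6].
    """
    if scope not in ("sample", "global"):
        raise ValueError(f"unknown bias scope {scope!r}")
    fp = filter_params or FilterParams()
    passing = [r for r in records if _passes_depth(r, fp)]
    if not passing:
        raise ValueError("insufficient data for bias estimation")
    groups: dict[tuple[str, str], list[AlleleCountRecord]] = {}
    for r in passing:
        key = ("*", "*") if scope == "global" else (r.tissue_id, r.assay.value)
        groups.setdefault(key, []).append(r)
    p_ref = {}
    for key, grp in groups.items():
        ref = sum(r.ref_count for r in grp)
        tot = sum(r.total for r in grp)
        p_ref[key] = float(np.clip(ref / tot, _P_CLAMP, 1.0 - _P_CLAMP))
    return BiasModel(scope=scope, p_ref=p_ref)


# ---------------------------------------------------------------------------
# Exact two-sided binomial test
# ---------------------------------------------------------------------------

def binom_pvalues_two_sided(k: np.ndarray, n: np.ndarray, p: float | np.ndarray) -> np.ndarray:
    """Vectorised exact two-sided binomial p-values (minimum-likelihood).

    For each observation, sums P(X = j) over every outcome j whose
    probability does not exceed that of the observed k (within a 1e-7
    relative tolerance for ties). Works by locating, on the far side of
    the distribution's mode, the boundary outcome via bisection on the
    monotone tail of the pmf.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    k, n = np.broadcast_arrays(k, n)
    p = np.broadcast_to(np.asarray(p, dtype=float), k.shape)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0,1)")
    if np.any(n < 1):
        raise ValueError("total count must be >= 1")
    if np.any((k < 0) | (k > n)):
        raise ValueError("observed count outside [0, n]")

    # canonicalise to p <= 0.5 so that mirrored inputs (k, p) and
    # (n - k, 1 - p) evaluate through the identical code path
    flip = p > 0.5
    k = np.where(flip, n - k, k)
    p = np.where(flip, 1.0 - p, p)

    d = stats.binom.pmf(k, n, p) * (1.0 + _REL_TOL)
    mode = np.floor((n + 1) * p).astype(np.int64)
    mode = np.minimum(mode, n)
    at_mode = stats.binom.pmf(mode, n, p) <= d
    out = np.empty(k.shape, dtype=float)
    out[at_mode] = 1.0  # observed is (at least as likely as) the mode

    left = ~at_mode & (k < mode)
    right = ~at_mode & (k > mode)

    # observed on the left tail: find smallest j > mode with pmf(j) <= d
    if left.any():
        kl, nl, pl, dl, ml = k[left], n[left], p[left], d[left], mode[left]
        lo = ml.copy()            # pmf(lo) > d
        hi = nl.copy()            # search in (mode, n]
        need = stats.binom.pmf(hi, nl, pl) > dl
        # if even pmf(n) > d the right tail contributes nothing
        j = np.where(need, nl + 1, hi)
        lo_b, hi_b = lo.copy(), hi.copy()
        active = ~need
        while True:
            gap = (hi_b - lo_b > 1) & active
            if not gap.any():
                break
            mid = (lo_b + hi_b) // 2
            pm = stats.binom.pmf(mid, nl, pl)
            go_right = gap & (pm > dl)
            lo_b = np.where(go_right, mid, lo_b)
            hi_b = np.where(gap & ~go_right, mid, hi_b)
        j = np.where(active, hi_b, j)
        pv = stats.binom.cdf(kl, nl, pl) + stats.binom.sf(j - 1, nl, pl)
        out[left] = pv

    # observed on the right tail: find largest j < mode with pmf(j) <= d
    if right.any():
        kr, nr, pr, dr, mr = k[right], n[right], p[right], d[right], mode[right]
        zero = np.zeros_like(mr)
        need = stats.binom.pmf(zero, nr, pr) > dr
        j = np.where(need, -1, zero)
        lo_b = zero.copy()        # pmf(lo) <= d (when active)
        hi_b = mr.copy()          # pmf(hi) > d
        active = ~need
        while True:
            gap = (hi_b - lo_b > 1) & active
            if not gap.any():
                break
            mid = (lo_b + hi_b) // 2
            pm = stats.binom.pmf(mid, nr, pr)
            le = gap & (pm <= dr)
            lo_b = np.where(le, mid, lo_b)
            hi_b = np.where(gap & ~le, mid, hi_b)
        j = np.where(active, lo_b, j)
        pv = stats.binom.sf(kr - 1, nr, pr) + np.where(
            j >= 0, stats.binom.cdf(np.maximum(j, 0), nr, pr), 0.0
        )
        out[right] = pv

    return np.minimum(out, 1.0)


def binomial_ase_test(ref_count: int, alt_count: int, p_ref_hat: float) -> float:
    """Exact two-sided p-value for ref_count ~ Binomial(ref+alt, p̂)."""
    n = ref_count + alt_count
    if n < 1:
        raise ValueError("ref_count + alt_count must be >= 1")
    return float(binom_pvalues_two_sided(np.array([ref_count]),
                                         np.array([n]), p_ref_hat)[0])


# ---------------------------------------------------------------------------
# The call
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ASECall:
    """One tested measurement: a site in a tissue under one assay.

    ``allelic_ratio`` is alt/(ref+alt); ``qc_pass`` means no structural
    QC flag (depth, bi-allelic, intragenic) fired; ``is_ase`` adds the
    assay-specific significance requirement on top of QC.
    """

    site_id: str
    tissue_id: str
    replicate_id: str
    assay: Assay
    ref_count: int
    alt_count: int
    other_count: int
    allelic_ratio: float | None
    p_value: float | None
    filter_flags: frozenset[FilterFlag] = frozenset()
    qc_pass: bool = False
    is_ase: bool = False

    def __post_init__(self) -> None:
        if self.allelic_ratio is not None and not 0.0 <= self.allelic_ratio <= 1.0:
            raise ValueError(f"{self.site_id}: allelic ratio outside [0,1]")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.site_id}: p-value outside [0,1]")


def call_ase(
    records: Sequence[AlleleCountRecord],
    sites: Sequence[HetSite] | Mapping[str, HetSite],
    bias_model: BiasModel,
    filter_params: FilterParams | None = None,
) -> list[ASECall]:
    """Run the binomial ASE test and the QC cascade over count records.

    Flags are evaluated in cascade order (base quality having been
    applied upstream when counting): allele depth, total depth,
    significance, bi-allelic expression, intragenic location. A record
    whose site_id is unknown raises.
    """
    fp = filter_params or FilterParams()
    site_map = sites if isinstance(sites, Mapping) else {s.site_id: s for s in sites}
    unknown = sorted({r.site_id for r in records} - set(site_map))
    if unknown:
        raise KeyError(f"records reference unknown sites: {unknown[:10]}")

    recs = list(records)
    if not recs:
        return []
    ref = np.array([r.ref_count for r in recs], dtype=np.int64)
    alt = np.array([r.alt_count for r in recs], dtype=np.int64)
    tot = ref + alt
    p_hat = np.array([bias_model.lookup(r) for r in recs], dtype=float)
    testable = tot >= 1
    pvals = np.full(len(recs), np.nan)
    if testable.any():
        pvals[testable] = binom_pvalues_two_sided(ref[testable], tot[testable],
                                                  p_hat[testable])

    calls: list[ASECall] = []
    for i, r in enumerate(recs):
        site = site_map[r.site_id]
        flags: set[FilterFlag] = set()
        if min(r.ref_count, r.alt_count) < fp.min_allele_depth:
            flags.add(FilterFlag.ALLELE_DEPTH)
        if r.total < fp.min_total_depth:
            flags.add(FilterFlag.TOTAL_DEPTH)
        grand = r.total + r.other_count
        if grand > 0 and r.other_count / grand > fp.max_other_fraction:
            flags.add(FilterFlag.BIALLELIC)
        if fp.require_intragenic and not site.is_intragenic:
            flags.add(FilterFlag.INTRAGENIC)
        p_value = float(pvals[i]) if testable[i] else None
        alpha = fp.alpha(r.assay)
        if p_value is None or p_value >= alpha:
            flags.add(FilterFlag.SIGNIFICANCE)
        qc = not (flags & _QC_FLAGS)
        calls.append(ASECall(
            site_id=r.site_id, tissue_id=r.tissue_id, replicate_id=r.replicate_id,
            assay=r.assay, ref_count=r.ref_count, alt_count=r.alt_count,
            other_count=r.other_count,
            allelic_ratio=float(alt[i] / tot[i]) if tot[i] > 0 else None,
            p_value=p_value,
            filter_flags=frozenset(flags),
            qc_pass=qc,
            is_ase=qc and p_value is not None and p_value < alpha,
        ))
    n_pass = sum(c.qc_pass for c in calls)
    logger.info("call_ase: %d records, %d qc-pass, %d ASE",
                len(calls), n_pass, sum(c.is_ase for c in calls))
    return calls
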