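"""Per-library minor-allele calling from strand-resolved base counts.

A library is a table of per-position counts of the four bases on each strand.
The caller emits at most one minor-allele call per position, governed by an
analysis threshold (AT) and interpretation threshold (IT) on the minor allele
fraction (both default 0.1%), a minimum minor-read count (default 10, with a
fall-back of 2 used only in the replicate-rescue step of the confirmation
cascade), a Phred-scaled genotype quality (GQ), and a Fisher-exact strand
bias (SB) score.  Only point substitutions are considered; indels and length
heteroplasmy are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_SITE_ERROR_RATE = 2e-4


class ParameterError(ValueError):
    pass


class InputError(ValueError):
    pass


class NoCoverage:
    """Sentinel for a position with zero depth (distinct from "no call")."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):  # pragma: no cover
        return "NO_COVERAGE"


NO_COVERAGE = NoCoverage()


@dataclass(frozen=True)
class SiteCounts:
    """Strand-resolved base counts at one rCRS position in one library."""

    position: int
    ref_base: str
    fwd: tuple[int, int, int, int]  # A, C, G, T on the forward strand
    rev: tuple[int, int, int, int]

    @property
    def depth(self) -> int:
        return sum(self.fwd) + sum(self.rev)

    def count(self, base: str) -> int:
        i = _BASE_INDEX[base]
        return self.fwd[i] + self.rev[i]


@dataclass(frozen=True)
class Thresholds:
    """Minor-allele calling thresholds.

    analysis_threshold (AT) and interpretation_threshold (IT) are MAF cut-offs
    for detection and reporting; both default to 0.1%.  ``min_read_count`` is
    the minor-read floor (10), lowered to ``fallback_read_count`` (2) only
    when a replicate is re-analysed for rescue.  ``gq_min`` (41) gates the
    confirmation cascade, not the per-library caller.
    """

    analysis_threshold: float = 0.001
    interpretation_threshold: float = 0.001
    min_read_count: int = 10
    fallback_read_count: int = 2
    gq_min: float = 41.0
    site_error_rate: float = DEFAULT_SITE_ERROR_RATE

    def __post_init__(self):
        if not (0 < self.analysis_threshold <= self.interpretation_threshold <= 0.5):
            raise ParameterError("need 0 < AT <= IT <= 0.5")
        if self.fallback_read_count > self.min_read_count:
            raise ParameterError("fallback_read_count must not exceed min_read_count")


@dataclass(frozen=True)
class VariantCall:
    """A per-library minor-allele call."""

    library_id: str
    position: int
    major_allele: str
    minor_allele: str
    maf: float
    depth: int
    minor_fwd: int
    minor_rev: int
    gq: float
    sb: float | None
    both_strands: bool = field(default=False)
    low_depth_rescued: bool = field(default=False)


def genotype_quality(site: SiteCounts, site_error_rate: float = DEFAULT_SITE_ERROR_RATE,
                     minor_base: str | None = None) -> float:
    """Phred-scaled likelihood ratio of heteroplasmy versus homoplasmy-plus-error.

    Compares a binomial model at the observed minor-allele fraction against a
    binomial error model at ``site_error_rate``, capped at 99.  A site with no
    minor reads has GQ 0 for heteroplasmy.  Monotone in the minor count at
    fixed depth.
    """
    if site_error_rate <= 0:
        raise ParameterError("site_error_rate must be positive")
    n = site.depth
    if n <= 0:
        raise ParameterError("genotype_quality requires depth > 0")
    if minor_base is None:
        ranked = sorted(BASES, key=lambda b: (-site.count(b), b))
        minor_base = ranked[1]
    k = site.count(minor_base)
    if k == 0 or k / n <= site_error_rate:
        # at or below the error expectation there is no heteroplasmy evidence
        return 0.0
    ll_het = stats.binom.logpmf(k, n, k / n)
    ll_err = stats.binom.logpmf(k, n, site_error_rate)
    gq = 10.0 / math.log(10.0) * (ll_het - ll_err)
    return float(min(max(gq, 0.0), 99.0))


def strand_bias(minor_fwd: int, minor_rev: int, major_fwd: int, major_rev: int) -> float | None:
    """Fisher-exact strand-bias score, -log10 of the two-sided p-value.

    Symmetric under relabelling of the strands.  Returns None for an all-zero
    table, where the score is undefined.
    """
    table = [[minor_fwd, minor_rev], [major_fwd, major_rev]]
    if sum(table[0]) + sum(table[1]) == 0:
        return None
    p = stats.fisher_exact(table)[1]
    return float(-math.log10(max(p, 1e-300)))


def _pick_major_minor(site: SiteCounts) -> tuple[str, str]:
    counts = {b: site.count(b) for b in BASES}
    top = max(counts.values())
    leaders = [b for b in BASES if counts[b] == top]
    if site.ref_base in leaders:
        major = site.ref_base  # 50/50 tie: the rCRS base is designated major
    else:
        major = leaders[0]
    rest = [b for b in BASES if b != major]
    rest.sort(key=lambda b: (-counts[b], b))  # ties broken by base order A<C<G<T
    return major, rest[0]


def call_site(site: SiteCounts, thresholds: Thresholds,
              min_read_count: int | None = None,
              library_id: str = "") -> VariantCall | None | NoCoverage:
    """Call the minor allele at a single position, or return None / NO_COVERAGE."""
    if site.depth == 0:
        return NO_COVERAGE
    min_count = thresholds.min_read_count if min_read_count is None else min_read_count
    major, minor = _pick_major_minor(site)
    i, j = _BASE_INDEX[minor], _BASE_INDEX[major]
    k = site.fwd[i] + site.rev[i]
    maf = k / site.depth
    if maf < thresholds.analysis_threshold or maf < thresholds.interpretation_threshold:
        return None
    if k < min_count:
        return None
    gq = genotype_quality(site, thresholds.site_error_rate, minor_base=minor)
    sb = strand_bias(site.fwd[i], site.rev[i], site.fwd[j], site.rev[j])
    return VariantCall(
        library_id=library_id, position=site.position, major_allele=major,
        minor_allele=minor, maf=maf, depth=site.depth,
        minor_fwd=site.fwd[i], minor_rev=site.rev[i], gq=gq, sb=sb,
        both_strands=site.fwd[i] > 0 and site.rev[i] > 0,
        low_depth_rescued=min_count < thresholds.min_read_count,
    )


def site_from_row(row) -> SiteCounts:
    return SiteCounts(
        position=int(row["pos"]), ref_base=str(row["ref"]),
        fwd=tuple(int(row[b + "_fwd"]) for b in BASES),
        rev=tuple(int(row[b + "_rev"]) for b in BASES),
    )


def call_library(counts: pd.DataFrame, thresholds: Thresholds,
                 library_id: str = "") -> list[VariantCall]:
    """Apply :func:`call_site` genome-wide to a per-library count table.

    The table must be sorted by position with one row per position.  The scan
    for candidate positions is vectorised; GQ and SB are computed only for
    the (rare) candidates.
    """
    if counts.empty:
        return []
    pos = counts["pos"].to_numpy()
    if np.any(np.diff(pos) <= 0):
        raise InputError("count table must be sorted by position without duplicates")
    fwd = counts[[b + "_fwd" for b in BASES]].to_numpy(dtype=np.int64)
    rev = counts[[b + "_rev" for b in BASES]].to_numpy(dtype=np.int64)
    tot = fwd + rev
    depth = tot.sum(axis=1)
    order = np.argsort(-tot, axis=1, kind="stable")
    top2 = np.take_along_axis(tot, order[:, 1:2], axis=1).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        maf2 = np.where(depth > 0, top2 / np.maximum(depth, 1), 0.0)
    floor = min(thresholds.fallback_read_count, thresholds.min_read_count)
    cand = (depth > 0) & (top2 >= floor) & (maf2 >= min(
        thresholds.analysis_threshold, thresholds.interpretation_threshold))
    calls = []
    idx = np.nonzero(cand)[0]
    for _, row in counts.iloc[idx].iterrows():
        call = call_site(site_from_row(row), thresholds, library_id=library_id)
        if isinstance(call, VariantCall):
            calls.append(call)
    return calls


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    cols = ["library_id", "position", "major_allele", "minor_allele", "maf", "depth",
            "minor_fwd", "minor_rev", "gq", "sb", "both_strands", "low_depth_rescued"]
    return pd.DataFrame([{c: getattr(v, c) for c in cols} for v in calls], columns=cols)
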