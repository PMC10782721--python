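"""The PHP confirmation cascade.

A candidate heteroplasmy is confirmed for a donor/tissue only if it is
completely reproducible: present with both-strand evidence in every
platform-A replicate library of the group (with a read-count-only rescue at
a fall-back of 2 reads for depth-limited replicates), above the genotype
quality gate in every replicate, and concordantly detected by the
independent platform-B run and by a second, independently coded analysis
path ("pipeline P2") that recomputes minor allele fractions from the raw
counts.  This is the error-suppression core of the workflow: stochastic
noise fails replicate reproducibility, systematic platform noise fails
cross-platform concordance, and code-path artefacts fail dual-pipeline
concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calling import (BASES, NO_COVERAGE, SiteCounts, Thresholds, VariantCall,
                      call_site, site_from_row)


class RescueRefused(ValueError):
    """Rescue requested for a site whose failure is not read-count-only."""


@dataclass(frozen=True)
class ConfirmedPHP:
    """A donor x tissue x position heteroplasmy and its evidence flags."""

    donor_id: str
    tissue: str
    position: int
    major_allele: str
    minor_allele: str
    replicate_mafs: tuple
    summary_maf: float | None
    all_replicates: bool
    both_strands_all: bool
    gq_pass_all: bool
    platformB_concordant: bool
    pipeline2_concordant: bool
    unevaluable: bool = False

    @property
    def confirmed(self) -> bool:
        return (self.all_replicates and self.both_strands_all and self.gq_pass_all
                and self.platformB_concordant and self.pipeline2_concordant
                and not self.unevaluable)


def rescue_low_depth(counts: pd.DataFrame, position: int,
                     thresholds: Thresholds, library_id: str = "") -> VariantCall:
    """Re-call one site with the fall-back read count.

    Rescue is read-count-only: a site that fails the MAF threshold or the
    both-strand rule is refused, mirroring re-analysis of a depth-limited
    replicate at a minimum read count of 2.
    """
    row = counts.loc[counts["pos"] == position]
    if row.empty:
        raise RescueRefused(f"no counts at position {position}")
    site = site_from_row(row.iloc[0])
    call = call_site(site, thresholds,
                     min_read_count=thresholds.fallback_read_count,
                     library_id=library_id)
    if call is NO_COVERAGE or call is None:
        raise RescueRefused("site fails the MAF threshold; rescue is read-count-only")
    if not call.both_strands:
        raise RescueRefused("minor allele on one strand only; rescue is read-count-only")
    return call


def _rescue_for_candidate(counts: pd.DataFrame, position: int, minor: str,
                          thresholds: Thresholds, library_id: str) -> VariantCall | None:
    try:
        call = rescue_low_depth(counts, position, thresholds, library_id)
    except RescueRefused:
        return None
    return call if call.minor_allele == minor else None


def confirm(calls_by_library: dict, manifest: pd.DataFrame,
            thresholds: Thresholds | None = None,
            counts_by_library: dict | None = None,
            require_platform_b: bool = True,
            require_pipeline2: bool = True) -> list[ConfirmedPHP]:
    """Run the full confirmation cascade.

    ``calls_by_library`` maps library_id to the platform-A/pipeline-P1 call
    list.  Candidates are grouped by donor x tissue x position x minor
    allele; each must be present (after read-count rescue where raw counts
    are supplied) with both-strand evidence and GQ above the gate in every
    platform-A library of the group, then match a call in the platform-B
    library set and in the independent pipeline-P2 re-analysis.  A group
    with no platform-B library is marked unevaluable rather than confirmed.
    """
    thresholds = thresholds or Thresholds()
    manifest = manifest.reset_index(drop=True)
    known = set(manifest.library_id)
    for lib in calls_by_library:
        if lib not in known:
            raise KeyError(f"library {lib!r} not in manifest")
    meta = manifest.set_index("library_id")
    a_libs: dict[tuple, list[str]] = {}
    b_libs: dict[tuple, list[str]] = {}
    for row in manifest.itertuples(index=False):
        group = (row.donor_id, row.tissue)
        (a_libs if row.platform == "A" else b_libs).setdefault(group, []).append(
            row.library_id)
    lookup = {
        lib: {(c.position, c.minor_allele): c for c in calls}
        for lib, calls in calls_by_library.items()
    }
    candidates: dict[tuple, VariantCall] = {}
    for lib, calls in calls_by_library.items():
        if meta.loc[lib, "platform"] != "A":
            continue
        g = (meta.loc[lib, "donor_id"], meta.loc[lib, "tissue"])
        for c in calls:
            candidates.setdefault((*g, c.position, c.minor_allele), c)

    results = []
    for (donor, tissue, pos, minor), first in sorted(candidates.items()):
        group = (donor, tissue)
        group_a = a_libs.get(group, [])
        per_lib: list[VariantCall | None] = []
        for lib in group_a:
            call = lookup.get(lib, {}).get((pos, minor))
            if call is None and counts_by_library is not None and lib in counts_by_library:
                call = _rescue_for_candidate(counts_by_library[lib], pos, minor,
                                             thresholds, lib)
            per_lib.append(call)
        present = [c for c in per_lib if c is not None]
        all_replicates = len(present) == len(group_a) and len(group_a) > 0
        both_strands_all = all_replicates and all(c.both_strands for c in present)
        gq_pass_all = all_replicates and all(c.gq > thresholds.gq_min for c in present)
        unevaluable = False
        if require_platform_b:
            group_b = b_libs.get(group, [])
            if not group_b:
                platform_b = False
                unevaluable = True
            else:
                platform_b = all((pos, minor) in lookup.get(lib, {}) for lib in group_b)
        else:
            platform_b = True
        if require_pipeline2 and counts_by_library is not None:
            p2 = pipeline2_present(counts_by_library, group_a, pos, minor, thresholds)
        else:
            p2 = not require_pipeline2 or all_replicates
        mafs = tuple(c.maf if c is not None else float("nan") for c in per_lib)
        t1 = [c.maf for lib, c in zip(group_a, per_lib)
              if c is not None and meta.loc[lib, "timepoint"] == 1]
        summary = sum(t1) / len(t1) if t1 else None
        results.append(ConfirmedPHP(
            donor_id=donor, tissue=tissue, position=pos,
            major_allele=first.major_allele, minor_allele=minor,
            replicate_mafs=mafs, summary_maf=summary,
            all_replicates=all_replicates, both_strands_all=both_strands_all,
            gq_pass_all=gq_pass_all, platformB_concordant=platform_b,
            pipeline2_concordant=bool(p2), unevaluable=unevaluable,
        ))
    return results


def confirmed_only(results: list[ConfirmedPHP]) -> list[ConfirmedPHP]:
    return [r for r in results if r.confirmed]


# --- pipeline P2: an independent second code path -------------------------
#
# Deliberately written without the calling module: MAFs are recomputed from
# the raw strand counts with plain loops, libraries are visited in the outer
# loop (the P1 path iterates candidates in the outer loop), and thresholds
# are re-applied from first principles.  Shared with P1 are only the numeric
# threshold values themselves.

def _p2_site_verdict(row, minor: str, thresholds: Thresholds) -> bool:
    fwd = {b: int(row[b + "_fwd"]) for b in BASES}
    rev = {b: int(row[b + "_rev"]) for b in BASES}
    total = {b: fwd[b] + rev[b] for b in BASES}
    depth = sum(total.values())
    if depth == 0:
        return False
    ranked = sorted(BASES, key=lambda b: (-total[b], b))
    major = row["ref"] if total[row["ref"]] == total[ranked[0]] else ranked[0]
    if minor == major:
        return False
    k = total[minor]
    top_minor = max(total[b] for b in BASES if b != major)
    if k < top_minor:  # some other base dominates the minor signal
        return False
    maf = k / depth
    if maf < thresholds.interpretation_threshold or maf < thresholds.analysis_threshold:
        return False
    if k < thresholds.fallback_read_count:
        return False
    if fwd[minor] == 0 or rev[minor] == 0:
        return False
    return True


def pipeline2_present(counts_by_library: dict, libraries: list[str], position: int,
                      minor: str, thresholds: Thresholds | None = None) -> bool:
    """Does the independent P2 path see the minor allele in every library?"""
    thresholds = thresholds or Thresholds()
    if not libraries:
        return False
    for lib in libraries:
        counts = counts_by_library.get(lib)
        if counts is None:
            return False
        row = counts.loc[counts["pos"] == position]
        if row.empty or not _p2_site_verdict(row.iloc[0], minor, thresholds):
            return False
    return True


def cross_set_concordance(set1, set2, match_on: tuple = ("position", "minor_allele")):
    """Symmetric set comparison of two PHP sets keyed by donor x tissue.

    Returns (concordant, only1, only2); concordant entries are (item1, item2)
    pairs so MAFs from both sides remain available for agreement diagnostics.
    """
    def key(item):
        return (item.donor_id, item.tissue) + tuple(getattr(item, f) for f in match_on)

    idx1 = {key(x): x for x in set1}
    idx2 = {key(x): x for x in set2}
    concordant = [(idx1[k], idx2[k]) for k in sorted(idx1.keys() & idx2.keys())]
    only1 = [idx1[k] for k in sorted(idx1.keys() - idx2.keys())]
    only2 = [idx2[k] for k in sorted(idx2.keys() - idx1.keys())]
    return concordant, only1, only2
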