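"""Cohort-level PHP landscape statistics.

Works on a table of PHP events -- one confirmed minor allele in one donor and
tissue, carrying a summary minor allele fraction (MAF).  Provides the
descriptive statistics of a replicate heteroplasmy study: event and position
counts by tissue, region distributions, MAF cut-off profiles, multi-person
hotspot tables, tissue specificity, minor-allele co-occurrence (linkage)
against a permutation null, longitudinal stability and blood:buccal MAF
ratios.  "Low-level" means MAF < 1% throughout; cut-off comparisons use >=
at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import reference

EVENT_COLUMNS = ["donor_id", "tissue", "position", "major_allele",
                 "minor_allele", "maf"]

LOW_LEVEL_MAF = 0.01
DEFAULT_CUTOFFS = (0.001, 0.005, 0.01, 0.03, 0.10)


class ParameterError(ValueError):
    pass


def events_from_confirmed(confirmed) -> pd.DataFrame:
    """Event table (one row per donor x tissue x position) from ConfirmedPHP."""
    rows = [{
        "donor_id": c.donor_id, "tissue": c.tissue, "position": c.position,
        "major_allele": c.major_allele, "minor_allele": c.minor_allele,
        "maf": c.summary_maf,
    } for c in confirmed if getattr(c, "confirmed", True)]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def aggregate_events(events: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Deduplicated event table plus the headline event/position counts.

    positions_total = positions_both + positions_buccal_only +
    positions_blood_only, and events_total = events_buccal + events_blood.
    """
    events = events.drop_duplicates(["donor_id", "tissue", "position"]).copy()
    by_pos = events.groupby("position")["tissue"].agg(set)
    counts = {
        "events_total": len(events),
        "events_buccal": int((events.tissue == "buccal").sum()),
        "events_blood": int((events.tissue == "blood").sum()),
        "positions_total": int(by_pos.size),
        "positions_both": int(sum(ts == {"buccal", "blood"} for ts in by_pos)),
        "positions_buccal_only": int(sum(ts == {"buccal"} for ts in by_pos)),
        "positions_blood_only": int(sum(ts == {"blood"} for ts in by_pos)),
    }
    return events, counts


def region_distribution(events: pd.DataFrame) -> pd.DataFrame:
    """Fraction of distinct positions and of events per region class.

    Both distributions sum to 1 over the region classes present.
    """
    ann = events["position"].map(lambda p: reference.locate(int(p)).region_class)
    by_event = ann.value_counts(normalize=True)
    by_position = (
        pd.Series(ann.values, index=events["position"].values)
        .groupby(level=0).first().value_counts(normalize=True)
    )
    out = pd.DataFrame({"fraction_positions": by_position,
                        "fraction_events": by_event}).fillna(0.0)
    out.index.name = "region_class"
    return out


def maf_cutoff_profile(events: pd.DataFrame,
                       cutoffs=DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Per-donor/tissue PHP counts at each MAF cut-off (>= at the boundary).

    Counts are non-increasing in the cut-off for every donor/tissue.  The
    cohort maximum per cut-off/tissue is carried in the ``cohort_max``
    column of the returned long-format table.
    """
    cutoffs = list(cutoffs)
    if any(not 0 < c <= 0.5 for c in cutoffs):
        raise ParameterError("cutoffs must lie in (0, 0.5]")
    if cutoffs != sorted(cutoffs):
        raise ParameterError("cutoffs must be ascending")
    rows = []
    groups = events.groupby(["donor_id", "tissue"])
    for cutoff in cutoffs:
        per_group = groups["maf"].apply(lambda m: int((m >= cutoff).sum()))
        for (donor, tissue), n in per_group.items():
            rows.append({"cutoff": cutoff, "donor_id": donor, "tissue": tissue,
                         "n_php": int(n)})
    out = pd.DataFrame(rows, columns=["cutoff", "donor_id", "tissue", "n_php"])
    if not out.empty:
        out["cohort_max"] = out.groupby(["cutoff", "tissue"])["n_php"].transform("max")
    else:
        out["cohort_max"] = pd.Series(dtype=int)
    return out


def hotspot_table(events: pd.DataFrame) -> pd.DataFrame:
    """Positions detected in more than one person, sorted by person count.

    Median/min/max MAF are pooled over all contributing events from both
    tissues; an even pool takes the midpoint of the central pair.
    """
    if events.empty:
        raise ParameterError("hotspot_table requires at least one event")
    rows = []
    for (pos, minor), grp in events.groupby(["position", "minor_allele"]):
        n_persons = grp.donor_id.nunique()
        if n_persons < 2:
            continue
        mafs = grp.maf.astype(float)
        rows.append({
            "position": int(pos),
            "locus": reference.locate(int(pos)).locus_name,
            "major_allele": grp.major_allele.iloc[0],
            "minor_allele": minor,
            "n_persons": int(n_persons),
            "total_php_count": int(len(grp)),
            "median_maf": float(mafs.median()),
            "min_maf": float(mafs.min()),
            "max_maf": float(mafs.max()),
        })
    out = pd.DataFrame(rows, columns=["position", "locus", "major_allele",
                                      "minor_allele", "n_persons", "total_php_count",
                                      "median_maf", "min_maf", "max_maf"])
    return out.sort_values(["n_persons", "total_php_count", "position"],
                           ascending=[False, False, True]).reset_index(drop=True)


def tissue_specificity(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each donor x position as both / buccal_only / blood_only.

    Returns (per donor x position classification, cross-donor preference
    table per position).  Tissue-exclusive rows carry ``low_level`` (MAF <
    1%), the regime where tissue specificity concentrates.
    """
    if events.empty:
        empty1 = pd.DataFrame(columns=["donor_id", "position", "minor_allele",
                                       "classification", "maf", "low_level"])
        empty2 = pd.DataFrame(columns=["position", "minor_allele", "n_both",
                                       "n_buccal_only", "n_blood_only"])
        return empty1, empty2
    rows = []
    for (donor, pos, minor), grp in events.groupby(
            ["donor_id", "position", "minor_allele"]):
        tissues = set(grp.tissue)
        if tissues == {"buccal", "blood"}:
            cls, maf = "both", float(grp.maf.mean())
        elif tissues == {"buccal"}:
            cls, maf = "buccal_only", float(grp.maf.iloc[0])
        else:
            cls, maf = "blood_only", float(grp.maf.iloc[0])
        rows.append({"donor_id": donor, "position": int(pos), "minor_allele": minor,
                     "classification": cls, "maf": maf,
                     "low_level": cls != "both" and maf < LOW_LEVEL_MAF})
    per_donor = pd.DataFrame(rows)
    pref = (per_donor.pivot_table(index=["position", "minor_allele"],
                                  columns="classification", values="donor_id",
                                  aggfunc="count", fill_value=0)
            .rename(columns={"both": "n_both", "buccal_only": "n_buccal_only",
                             "blood_only": "n_blood_only"})
            .reset_index())
    for col in ("n_both", "n_buccal_only", "n_blood_only"):
        if col not in pref:
            pref[col] = 0
    return per_donor, pref[["position", "minor_allele", "n_both",
                            "n_buccal_only", "n_blood_only"]]


def linkage_test(events: pd.DataFrame, n_permutations: int = 1000,
                 rng_seed: int = 0, donors: list | None = None) -> pd.DataFrame:
    """Minor-allele co-occurrence across donors within a tissue.

    For every pair of positions seen in a tissue, the observed statistic is
    the number of donors carrying both.  The null independently permutes
    each position's donor labels within the tissue (equivalently, redraws
    its donor set at fixed size), so the pairwise margins are preserved.
    Empirical p-values use the add-one rule p = (1 + #null >= obs) /
    (1 + n_permutations) and are Benjamini-Hochberg adjusted across pairs.
    """
    if n_permutations < 100:
        raise ParameterError("n_permutations must be at least 100")
    donors = sorted(donors if donors is not None else events.donor_id.unique())
    n_donors = len(donors)
    if n_donors < 2:
        return pd.DataFrame(columns=["tissue", "position1", "position2",
                                     "observed", "p_value", "q_value"])
    donor_idx = {d: i for i, d in enumerate(donors)}
    rng = np.random.default_rng(rng_seed)
    rows = []
    for tissue, grp in events.groupby("tissue"):
        positions = sorted(grp.position.unique())
        if len(positions) < 2:
            continue
        mat = np.zeros((len(positions), n_donors), dtype=bool)
        pos_idx = {p: i for i, p in enumerate(positions)}
        for r in grp.itertuples(index=False):
            mat[pos_idx[r.position], donor_idx[r.donor_id]] = True
        observed = (mat.astype(int) @ mat.T.astype(int))
        sizes = mat.sum(axis=1)
        exceed = np.zeros_like(observed)
        for _ in range(n_permutations):
            perm = np.zeros_like(mat)
            for i, k in enumerate(sizes):
                perm[i, rng.choice(n_donors, size=k, replace=False)] = True
            null = perm.astype(int) @ perm.T.astype(int)
            exceed += (null >= observed)
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                rows.append({
                    "tissue": tissue, "position1": positions[i],
                    "position2": positions[j],
                    "observed": int(observed[i, j]),
                    "p_value": (1 + exceed[i, j]) / (1 + n_permutations),
                })
    out = pd.DataFrame(rows, columns=["tissue", "position1", "position2",
                                      "observed", "p_value"])
    if not out.empty:
        out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def longitudinal_stability(observations: pd.DataFrame,
                           fallback_read_count: int = 2) -> pd.DataFrame:
    """Per donor/tissue/position stability over sampling time points.

    ``observations`` needs columns donor_id, tissue, position, timepoint,
    maf, minor_count, depth (maf 0 / minor_count 0 meaning undetected).
    A "lost" verdict requires detection at the first time point and zero
    minor reads later at a depth above the detectability floor -- the depth
    at which the first time point's MAF would still yield at least
    ``fallback_read_count`` expected minor reads -- so coverage dropouts are
    reported as unevaluable, never as losses.
    """
    rows = []
    for (donor, tissue, pos), grp in observations.groupby(
            ["donor_id", "tissue", "position"]):
        grp = grp.sort_values("timepoint")
        if grp.timepoint.nunique() < 2:
            status = "unevaluable"
        else:
            first = grp.iloc[0]
            later = grp.iloc[1:]
            if first.maf > 0:
                if (later.maf > 0).all():
                    status = "stable"
                else:
                    zero = later[later.minor_count == 0]
                    floor = fallback_read_count / first.maf
                    status = "lost" if (zero.depth >= floor).all() and len(zero) \
                        else "unevaluable"
            else:
                status = "gained" if (later.maf > 0).any() else "unevaluable"
        rows.append({"donor_id": donor, "tissue": tissue, "position": int(pos),
                     "status": status})
    return pd.DataFrame(rows, columns=["donor_id", "tissue", "position", "status"])


def blood_buccal_ratio(events: pd.DataFrame,
                       fold_threshold: float = 17.0) -> pd.DataFrame:
    """Blood:buccal MAF ratio for PHPs present in both tissues of a donor.

    A pair at or above ``fold_threshold`` is flagged as a potential
    leukocyte-contamination echo.  A zero buccal MAF yields an infinite
    ratio (flagged).
    """
    wide = (events.pivot_table(index=["donor_id", "position", "minor_allele"],
                               columns="tissue", values="maf", aggfunc="first")
            .dropna(subset=["buccal", "blood"], how="any")
            .reset_index())
    if wide.empty:
        return pd.DataFrame(columns=["donor_id", "position", "minor_allele",
                                     "buccal_maf", "blood_maf", "ratio", "flagged"])
    with np.errstate(divide="ignore"):
        ratio = np.where(wide["buccal"] > 0, wide["blood"] / wide["buccal"], np.inf)
    return pd.DataFrame({
        "donor_id": wide.donor_id, "position": wide.position.astype(int),
        "minor_allele": wide.minor_allele,
        "buccal_maf": wide["buccal"], "blood_maf": wide["blood"],
        "ratio": ratio, "flagged": ratio >= fold_threshold,
    })
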