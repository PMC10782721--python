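"""Synthetic replicate-pileup generator with known ground truth.

Emulates the statistical structure of a deep whole-mtDNA replicate study:
11 donors sampled in two tissues (buccal swab and blood), a mix of technical
(PCR / library) and biological (longitudinal time-point) replicates summing
to 159 libraries, two sequencing platforms with distinct error profiles, and
~7,700x mean coverage.  True point heteroplasmies (PHPs) are planted with
control-region hotspot enrichment and log-uniform minor allele fractions
down to 0.1%; everything else is per-position substitution noise.

The generator produces strand-resolved per-position count tables (the same
shape the caller consumes) plus a library manifest and a truth table, all
reproducibly derived from a single seed via per-library substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import reference
from .calling import BASES

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class ConfigError(ValueError):
    pass


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class TruthRecord:
    """A planted heteroplasmy in one donor/tissue."""

    donor_id: str
    tissue: str  # "buccal" | "blood"
    position: int
    major_allele: str
    minor_allele: str
    true_maf: float
    origin: str  # "germline_shared" | "somatic_tissue_specific"
    present_from_timepoint: int = 1


@dataclass
class ErrorProfile:
    """Per-substitution-type noise rates with heavy-tailed position multipliers.

    ``rates`` maps (ref, alt) to the mean per-strand substitution-error rate.
    ``multipliers`` is a (16569, 4) array of per-position, per-alt-base
    log-normal factors drawn once per platform, so that a small fraction of
    sites approach the 0.1% MAF threshold -- the regime the confirmation
    cascade has to defeat.
    """

    rates: dict
    multipliers: np.ndarray

    @classmethod
    def sample(cls, rng: np.random.Generator, mean_rate: float = 2e-4,
               sigma: float = 0.5) -> "ErrorProfile":
        rates = {}
        for ref in BASES:
            for alt in BASES:
                if alt == ref:
                    continue
                # transitions are the dominant error mode, as in real chemistry
                scale = 1.0 if alt == _TRANSITION[ref] else 0.25
                rates[(ref, alt)] = mean_rate * scale * rng.uniform(0.7, 1.3)
        mult = rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                             size=(reference.MT_LENGTH, 4))
        return cls(rates=rates, multipliers=mult)

    def rate_matrix(self, ref_idx: np.ndarray) -> np.ndarray:
        """(L, 4) per-position error rate for each alt base (0 on the ref base)."""
        base_rate = np.zeros((4, 4))
        for (r, a), v in self.rates.items():
            base_rate[_BASE_INDEX[r], _BASE_INDEX[a]] = v
        out = base_rate[ref_idx] * self.multipliers
        out[np.arange(len(ref_idx)), ref_idx] = 0.0
        return out


@dataclass
class CoverageModel:
    """Overdispersed per-position sequencing depth.

    Depth is gamma-Poisson (negative-binomial-like) around
    ``mean_depth * position multiplier``; the multipliers emulate uneven
    amplicon coverage, including a systematic dip flanking position 3586.
    """

    mean_depth: float = 7746.0
    dispersion: float = 20.0  # NB size parameter; larger = closer to Poisson
    multipliers: np.ndarray | None = None

    @classmethod
    def sample(cls, rng: np.random.Generator, mean_depth: float = 7746.0,
               dispersion: float = 20.0, dip_center: int = 3586,
               dip_halfwidth: int = 120, dip_factor: float = 0.35) -> "CoverageModel":
        mult = rng.lognormal(mean=-0.02, sigma=0.2, size=reference.MT_LENGTH)
        pos = np.arange(1, reference.MT_LENGTH + 1)
        dip = np.abs(pos - dip_center) <= dip_halfwidth
        mult[dip] *= dip_factor
        mult *= 1.0 / mult.mean()  # keep the genome-wide mean on target
        return cls(mean_depth=mean_depth, dispersion=dispersion, multipliers=mult)

    def sample_depths(self, rng: np.random.Generator) -> np.ndarray:
        mult = self.multipliers if self.multipliers is not None else 1.0
        lam = rng.gamma(self.dispersion, (self.mean_depth * mult) / self.dispersion,
                        size=reference.MT_LENGTH)
        return rng.poisson(lam)


@dataclass
class StudyConfig:
    """Design and noise parameters of a synthetic replicate study.

    The defaults emulate the study shape: 11 donors, two tissues, technical
    replicates for two donors, three longitudinal time points for nine, two
    platforms, 159 libraries, ~7,746x coverage, about six PHPs per sample
    with control-region hotspot enrichment and roughly one transversion per
    131 events.
    """

    n_donors: int = 11
    n_technical_donors: int = 2
    technical_plan: tuple = ((8, 8), (7, 6))  # (buccal, blood) libraries per technical donor
    n_timepoints: int = 3
    replicates_per_timepoint: int = 2
    platform_b_per_group: int = 1
    expected_phps_per_sample: float = 6.0
    germline_fraction: float = 0.45
    maf_floor: float = 0.001
    transversion_rate: float = 1.0 / 131.0
    hotspot_weight: float = 0.5
    tissue_jitter_sigma: float = 0.2
    mean_depth: float = 7746.0
    depth_dispersion: float = 20.0
    error_rate: float = 2e-4
    error_sigma: float = 0.5

    def __post_init__(self):
        if self.n_donors < 1 or self.n_technical_donors > self.n_donors:
            raise ConfigError("invalid donor plan")


@dataclass
class StudyResult:
    manifest: pd.DataFrame
    counts: dict  # library_id -> count DataFrame
    truth: pd.DataFrame
    config: StudyConfig


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: any library is reproducible in isolation."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def build_manifest(config: StudyConfig | None = None) -> pd.DataFrame:
    """The library manifest implied by the study plan (no simulation).

    With defaults: 2 technical donors contribute 16 + 13 libraries, nine
    longitudinal donors contribute 2 tissues x 3 time points x 2 replicates
    each, and every donor/tissue group has one platform-B library -- 159
    libraries in total.
    """
    config = config or StudyConfig()
    rows = []
    donors = [f"S{i:02d}" for i in range(1, config.n_donors + 1)]

    def add(donor, tissue, timepoint, kind, platform):
        rows.append({
            "library_id": f"{donor}-{tissue}-t{timepoint}-{platform}-{len(rows):03d}",
            "donor_id": donor, "tissue": tissue, "timepoint": timepoint,
            "replicate_kind": kind, "platform": platform, "pipeline": "P1",
        })

    for d, donor in enumerate(donors):
        technical = d < config.n_technical_donors
        for tissue_i, tissue in enumerate(("buccal", "blood")):
            if technical:
                n = config.technical_plan[d][tissue_i]
                for r in range(n):
                    add(donor, tissue, 1, "library" if r % 2 == 0 else "PCR", "A")
            else:
                for t in range(1, config.n_timepoints + 1):
                    for r in range(config.replicates_per_timepoint):
                        kind = ("library" if r == 0 else "PCR") if t == 1 else "biological"
                        add(donor, tissue, t, kind, "A")
            for _ in range(config.platform_b_per_group):
                add(donor, tissue, 1, "library", "B")
    manifest = pd.DataFrame(rows)
    if manifest.library_id.duplicated().any():
        raise ManifestError("duplicate library ids in manifest")
    return manifest


def sample_truth(config: StudyConfig, seed: int) -> list[TruthRecord]:
    """Draw the ground-truth PHP set for every donor/tissue.

    Positions come from a mixture of the control-region hotspot table
    (weighted by relative substitution rate) and the uniform genome; minor
    alleles are the transition partner of the rCRS base except for a small
    transversion fraction; minor allele fractions are log-uniform on
    [maf_floor, 0.5].  Germline-shared records appear in both tissues of a
    donor with independently jittered MAFs.
    """
    from .io import read_hotspot_fixture

    rng = _rng_for(seed, 0)
    hot = read_hotspot_fixture()
    hot_pos = hot.position.to_numpy()
    hot_w = hot.substitution_rate.to_numpy(dtype=float)
    hot_w = hot_w / hot_w.sum()
    seq = reference.rcrs_sequence()
    donors = [f"S{i:02d}" for i in range(1, config.n_donors + 1)]
    records: list[TruthRecord] = []

    def draw_position() -> int:
        if rng.random() < config.hotspot_weight:
            return int(rng.choice(hot_pos, p=hot_w))
        while True:
            p = int(rng.integers(1, reference.MT_LENGTH + 1))
            if seq[p - 1] != "N":
                return p

    def draw_alleles(pos: int) -> tuple[str, str]:
        major = seq[pos - 1]
        if rng.random() < config.transversion_rate:
            choices = [b for b in BASES if b != major and b != _TRANSITION[major]]
            return major, str(rng.choice(choices))
        return major, _TRANSITION[major]

    def draw_maf() -> float:
        lo, hi = np.log(config.maf_floor), np.log(0.5)
        return float(np.exp(rng.uniform(lo, hi)))

    g_mean = config.germline_fraction * config.expected_phps_per_sample
    s_mean = config.expected_phps_per_sample - g_mean
    for donor in donors:
        used: dict[str, set] = {"buccal": set(), "blood": set()}
        for _ in range(rng.poisson(g_mean)):
            pos = draw_position()
            if pos in used["buccal"] or pos in used["blood"]:
                continue
            major, minor = draw_alleles(pos)
            base = draw_maf()
            for tissue in ("buccal", "blood"):
                maf = min(0.5, base * float(rng.lognormal(0.0, config.tissue_jitter_sigma)))
                records.append(TruthRecord(donor, tissue, pos, major, minor,
                                           max(maf, config.maf_floor), "germline_shared"))
                used[tissue].add(pos)
        for tissue in ("buccal", "blood"):
            for _ in range(rng.poisson(s_mean)):
                pos = draw_position()
                if pos in used[tissue]:
                    continue
                major, minor = draw_alleles(pos)
                records.append(TruthRecord(donor, tissue, pos, major, minor,
                                           max(draw_maf(), config.maf_floor),
                                           "somatic_tissue_specific"))
                used[tissue].add(pos)
    return records


def truth_frame(records: list[TruthRecord]) -> pd.DataFrame:
    cols = ["donor_id", "tissue", "position", "major_allele", "minor_allele",
            "true_maf", "origin", "present_from_timepoint"]
    return pd.DataFrame([asdict(r) for r in records], columns=cols)


def simulate_library(truth: list[TruthRecord], error_profile: ErrorProfile,
                     coverage: CoverageModel, rng: np.random.Generator) -> pd.DataFrame:
    """One strand-resolved count table over the whole genome.

    Per position the depth is overdispersed around the coverage model; reads
    of the true minor allele are binomial at the true MAF; each alternative
    base receives binomial substitution noise on the residual depth; every
    count is split between strands Binomial(0.5).
    """
    L = reference.MT_LENGTH
    seq = reference.rcrs_sequence()
    ref_idx = np.frompyfunc(lambda c: _BASE_INDEX.get(c, 0), 1, 1)(
        np.array(list(seq))).astype(np.int64)
    depth = coverage.sample_depths(rng)
    depth[np.array(list(seq)) == "N"] = 0  # the 3107 placeholder has no real base
    counts = np.zeros((L, 4), dtype=np.int64)
    residual = depth.copy()
    for rec in truth:
        i = rec.position - 1
        k = rng.binomial(depth[i], min(rec.true_maf, 0.5))
        counts[i, _BASE_INDEX[rec.minor_allele]] += k
        residual[i] -= k
    rates = error_profile.rate_matrix(ref_idx)
    err = rng.binomial(np.repeat(residual[:, None], 4, axis=1),
                       np.minimum(rates, 0.25))
    counts += err
    residual = residual - err.sum(axis=1)
    counts[np.arange(L), ref_idx] += np.maximum(residual, 0)
    fwd = rng.binomial(counts, 0.5)
    rev = counts - fwd
    table = {"chrom": "chrM", "pos": np.arange(1, L + 1), "ref": list(seq)}
    for b in BASES:
        table[b + "_fwd"] = fwd[:, _BASE_INDEX[b]]
    for b in BASES:
        table[b + "_rev"] = rev[:, _BASE_INDEX[b]]
    df = pd.DataFrame(table)
    df["depth"] = fwd.sum(axis=1) + rev.sum(axis=1)
    return df


def simulate_study(config: StudyConfig | None = None, seed: int = 0,
                   truth: list[TruthRecord] | None = None) -> StudyResult:
    """Simulate the whole study: manifest, per-library count tables, truth."""
    config = config or StudyConfig()
    manifest = build_manifest(config)
    if truth is None:
        truth = sample_truth(config, seed)
    profiles = {p: ErrorProfile.sample(_rng_for(seed, 1, i), config.error_rate,
                                       config.error_sigma)
                for i, p in enumerate(("A", "B"))}
    coverage = CoverageModel.sample(_rng_for(seed, 2), config.mean_depth,
                                    config.depth_dispersion)
    by_group: dict[tuple, list[TruthRecord]] = {}
    for rec in truth:
        by_group.setdefault((rec.donor_id, rec.tissue), []).append(rec)
    counts = {}
    for i, row in enumerate(manifest.itertuples(index=False)):
        recs = [r for r in by_group.get((row.donor_id, row.tissue), [])
                if r.present_from_timepoint <= row.timepoint]
        counts[row.library_id] = simulate_library(
            recs, profiles[row.platform], coverage, _rng_for(seed, 3, i))
    return StudyResult(manifest=manifest, counts=counts,
                       truth=truth_frame(truth), config=config)
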