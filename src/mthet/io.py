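"""Readers/writers for the pipeline's tabular formats.

TSV is the native interchange format: strand-resolved count tables, library
manifests, call tables and confirmed-PHP tables, all with strict header
validation and 1-based rCRS coordinates in every user-facing file.  Calls
can additionally be exported as a minimal VCF for interoperability.  The
transcriptions of the two printed summary tables (control-region hotspots
and coding-region PHPs) ship as packaged fixtures and load through
:func:`read_hotspot_fixture` / :func:`read_coding_fixture`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from . import reference
from .calling import BASES, Thresholds, VariantCall

COUNT_COLUMNS = (
    ["chrom", "pos", "ref"]
    + [b + "_fwd" for b in BASES] + [b + "_rev" for b in BASES] + ["depth"]
)
MANIFEST_COLUMNS = ["library_id", "donor_id", "tissue", "timepoint",
                    "replicate_kind", "platform", "pipeline"]


class FormatError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def read_counts(path) -> pd.DataFrame:
    """Read a strand-resolved count table, validating schema and coordinates."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, COUNT_COLUMNS, path)
    for line0, row in enumerate(df.itertuples(index=False)):
        lineno = line0 + 2  # header is line 1
        if not 1 <= row.pos <= reference.MT_LENGTH:
            raise FormatError(f"{path}:{lineno}: position {row.pos} out of range")
        total = sum(getattr(row, b + "_fwd") + getattr(row, b + "_rev") for b in BASES)
        if total != row.depth:
            raise FormatError(
                f"{path}:{lineno}: depth {row.depth} != sum of strand counts {total}")
    if df.pos.duplicated().any():
        dup = int(df.pos[df.pos.duplicated()].iloc[0])
        raise FormatError(f"{path}: duplicate position {dup}")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COUNT_COLUMNS)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, MANIFEST_COLUMNS, path)
    if df.library_id.duplicated().any():
        raise FormatError(f"{path}: duplicate library_id")
    bad = set(df.tissue) - {"buccal", "blood"}
    if bad:
        raise FormatError(f"{path}: unknown tissue values {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)


def write_calls(calls: list[VariantCall], path) -> None:
    from .calling import calls_to_frame

    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    fields = [f.name for f in dataclasses.fields(VariantCall)]
    _require_columns(df, fields, path)
    out = []
    for row in df.itertuples(index=False):
        kw = {f: getattr(row, f) for f in fields}
        kw["sb"] = None if pd.isna(kw["sb"]) else float(kw["sb"])
        out.append(VariantCall(**kw))
    return out


def write_vcf(calls: list[VariantCall], path, sample: str = "sample") -> None:
    """Minimal VCF export: one record per call with AF/DP/SB/GQ in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=mthet",
        f"##contig=<ID=chrM,length={reference.MT_LENGTH}>",
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Minor allele fraction">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=SB,Number=1,Type=Float,Description="Strand bias, -log10 Fisher p">',
        '##INFO=<ID=GQ,Number=1,Type=Float,Description="Genotype quality, Phred">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in sorted(calls, key=lambda c: c.position):
        sb = "." if c.sb is None else f"{c.sb:.4g}"
        info = f"AF={c.maf:.6g};DP={c.depth};SB={sb};GQ={c.gq:.4g}"
        lines.append("\t".join([
            "chrM", str(c.position), ".", c.major_allele, c.minor_allele,
            ".", "PASS", info,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hotspot_fixture() -> pd.DataFrame:
    """Packaged transcription of the multi-person control-region hotspot table."""
    with resources.as_file(resources.files("mthet.data") / "cr_hotspots.tsv") as p:
        return pd.read_csv(p, sep="\t")


def read_coding_fixture() -> pd.DataFrame:
    """Packaged transcription of the coding-region PHP table (19 substitutions)."""
    with resources.as_file(resources.files("mthet.data") / "coding_phps.tsv") as p:
        return pd.read_csv(p, sep="\t")


@dataclasses.dataclass
class RunConfig:
    """Serializable run configuration (thresholds + simulation + seed)."""

    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)
    simulation: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"thresholds": dataclasses.asdict(self.thresholds),
                "simulation": dict(self.simulation), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(thresholds=Thresholds(**d.get("thresholds", {})),
                   simulation=dict(d.get("simulation", {})),
                   seed=int(d.get("seed", 0)))

    def dump(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
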