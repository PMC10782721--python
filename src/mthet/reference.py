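"""rCRS sequence, locus map and substitution annotation.

The human mitochondrial genome is annotated on the revised Cambridge
Reference Sequence (rCRS, NC_012920.1; 16,569 bp, 1-based coordinates, with
the historical placeholder ``N`` at position 3107).  The locus map ships as a
packaged BED-like table (0-based half-open internally; every user-facing
coordinate in this package is 1-based).  Positions are partitioned into the
non-coding control region (CR, 16024-16569 and 1-576, containing the
hypervariable segments HVS-I and HVS-II), protein-coding genes, rRNA genes,
tRNA genes and the few short non-coding spacers between them.

Substitutions are classified against the rCRS codon context using the
vertebrate mitochondrial genetic code; genes encoded on the light strand
(MT-ND6 and the light-strand tRNAs) are reverse-complemented before
translation.  Heteroplasmies are named in the ``m.<pos><major>><IUPAC>``
style, where the IUPAC ambiguity code stands for the major/minor base pair
(e.g. ``m.16093T>Y``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd
from Bio.Seq import Seq

MT_LENGTH = 16569

#: IUPAC ambiguity code for an unordered pair of bases.
IUPAC_PAIR = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class CoordinateError(ValueError):
    """Position outside 1..16569."""


class AlleleError(ValueError):
    """Allele is not one of A, C, G, T."""


class ReferenceMismatchWarning(UserWarning):
    """Strict-mode annotation where the stated major allele differs from rCRS."""


@dataclass(frozen=True)
class RegionAnnotation:
    """Locus context of a single rCRS position."""

    position: int
    region_class: str  # control_region | protein_coding | rRNA | tRNA | other_noncoding
    hvs: str  # "HVS-I" | "HVS-II" | "none"
    locus_name: str
    coding_strand: str  # "heavy" | "light" | "n/a"
    codon_number: int | None
    codon_offset: int | None


@dataclass(frozen=True)
class SubstitutionAnnotation:
    """Annotation of a single-base substitution at an rCRS position."""

    position: int
    major_allele: str
    minor_allele: str
    hgvs_name: str
    change_class: str  # transition | transversion
    coding_effect: str  # synonymous | non_synonymous | non_coding
    aa_change: str | None
    region: RegionAnnotation


@lru_cache(maxsize=1)
def rcrs_sequence() -> str:
    """The rCRS as an uppercase string (index 0 is position 1)."""
    text = (resources.files("mthet.data") / "rCRS.fasta").read_text()
    seq = "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))
    if len(seq) != MT_LENGTH:
        raise RuntimeError("packaged rCRS has unexpected length %d" % len(seq))
    return seq


def rcrs_base(position: int) -> str:
    """rCRS base at a 1-based position."""
    _check_position(position)
    return rcrs_sequence()[position - 1]


@lru_cache(maxsize=1)
def locus_table() -> pd.DataFrame:
    """Packaged locus map (columns name/start0/end0/strand/feature)."""
    with resources.as_file(resources.files("mthet.data") / "loci.tsv") as path:
        return pd.read_csv(path, sep="\t")


def _check_position(position: int) -> None:
    if not 1 <= int(position) <= MT_LENGTH:
        raise CoordinateError(f"rCRS position {position} outside 1..{MT_LENGTH}")


def _check_allele(base: str) -> str:
    base = str(base).upper()
    if base not in "ACGT" or len(base) != 1:
        raise AlleleError(f"invalid allele {base!r}")
    return base


@lru_cache(maxsize=None)
def _features_at(position: int) -> tuple:
    tab = locus_table()
    hit = tab[(tab.start0 < position) & (position <= tab.end0)]
    return tuple(hit.itertuples(index=False))


def in_control_region(position: int) -> bool:
    _check_position(position)
    return position >= 16024 or position <= 576


def locate(position: int) -> RegionAnnotation:
    """Deterministic locus annotation of one rCRS position.

    The control region takes precedence; outside it the first genic feature
    covering the position in locus-map order wins (this resolves the short
    overlaps between neighbouring genes, e.g. MT-ATP8/MT-ATP6).
    """
    _check_position(position)
    position = int(position)
    feats = _features_at(position)
    hvs = next((f.name for f in feats if f.feature == "hvs"), "none")
    hvs = {"HVS-I": "HVS-I", "HVS-II": "HVS-II"}.get(hvs, "none")
    if in_control_region(position):
        locus = {"HVS-I": "MT-HV1", "HVS-II": "MT-HV2"}.get(hvs, "CR")
        return RegionAnnotation(position, "control_region", hvs, locus, "n/a", None, None)
    genic = [f for f in feats if f.feature in ("protein_coding", "rRNA", "tRNA")]
    if not genic:
        return RegionAnnotation(position, "other_noncoding", "none", "non-coding", "n/a", None, None)
    f = genic[0]
    strand = "heavy" if f.strand == "H" else "light"
    codon_number = codon_offset = None
    if f.feature == "protein_coding":
        if strand == "heavy":
            idx = position - (f.start0 + 1)
        else:  # light-strand gene read 3'->5' in rCRS orientation
            idx = f.end0 - position
        codon_number = idx // 3 + 1
        codon_offset = idx % 3
    return RegionAnnotation(
        position, f.feature, "none", f.name, strand if f.feature == "protein_coding" else strand,
        codon_number, codon_offset,
    )


def is_transition(a: str, b: str) -> bool:
    pair = {a, b}
    return pair <= _PURINES or pair <= _PYRIMIDINES


def to_hgvs(position: int, major: str, minor: str) -> str:
    """Heteroplasmy name ``m.<pos><major>><IUPAC({major, minor})>``."""
    _check_position(position)
    major, minor = _check_allele(major), _check_allele(minor)
    if major == minor:
        raise AlleleError("major and minor allele must differ")
    code = IUPAC_PAIR[frozenset((major, minor))]
    return f"m.{position}{major}>{code}"


def _codon(seq: str, f, codon_number: int, strand: str) -> str:
    """rCRS codon (coding-strand orientation); incomplete terminal codons are
    completed with A, mirroring post-transcriptional polyadenylation."""
    if strand == "heavy":
        lo = f.start0 + 3 * (codon_number - 1)
        codon = seq[lo:lo + 3]
    else:
        hi = f.end0 - 3 * (codon_number - 1)
        codon = _revcomp(seq[max(hi - 3, f.start0):hi])
    return (codon + "AAA")[:3]


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=2))


def classify_substitution(
    position: int, major: str, minor: str, strict: bool = False
) -> SubstitutionAnnotation:
    """Classify a point substitution against the rCRS codon context.

    ``major``/``minor`` are the observed heavy-strand alleles.  For
    protein-coding positions the rCRS codon is translated twice, with the
    major and the minor allele substituted in, under the vertebrate
    mitochondrial code; light-strand genes are reverse-complemented first.
    With ``strict=True`` a major allele that does not match the packaged rCRS
    base raises a :class:`ReferenceMismatchWarning` (the sample's major allele
    may legitimately differ from the reference at polymorphic positions).
    """
    _check_position(position)
    major, minor = _check_allele(major), _check_allele(minor)
    if major == minor:
        raise AlleleError("major and minor allele must differ")
    ref = rcrs_base(position)
    if strict and major != ref:
        warnings.warn(
            f"major allele {major} at m.{position} does not match rCRS base {ref}",
            ReferenceMismatchWarning,
            stacklevel=2,
        )
    region = locate(position)
    change = "transition" if is_transition(major, minor) else "transversion"
    coding_effect, aa_change = "non_coding", None
    if region.region_class == "protein_coding":
        feats = [
            f for f in _features_at(position) if f.feature == "protein_coding"
        ]
        f = next(f for f in feats if f.name == region.locus_name)
        seq = rcrs_sequence()
        codon = _codon(seq, f, region.codon_number, region.coding_strand)
        off = region.codon_offset
        a, b = major, minor
        if region.coding_strand == "light":
            a, b = _COMPLEMENT[a], _COMPLEMENT[b]
        codon_major = codon[:off] + a + codon[off + 1:]
        codon_minor = codon[:off] + b + codon[off + 1:]
        aa_major, aa_minor = _translate(codon_major), _translate(codon_minor)
        if aa_major == aa_minor:
            coding_effect = "synonymous"
        else:
            coding_effect = "non_synonymous"
            aa_change = f"p.{aa_major}{region.codon_number}{aa_minor}"
    return SubstitutionAnnotation(
        position, major, minor, to_hgvs(position, major, minor),
        change, coding_effect, aa_change, region,
    )
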