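"""Locus-identifier grammar for the grapevine gene nomenclature.

A locus identifier is built from six elements, concatenated in order:

``<taxon><chromosome><object type><numeric code>[-<variant>][.<version>]``

e.g. ``Vitvi18g12230`` or ``Vitvi05t00480-tpa2.3``.  The taxon code is the
UniProt-style species abbreviation (``VITVI`` for *Vitis vinifera*; six-letter
``VIT``+catalogue codes such as ``VITVBR`` for other *Vitis* species), the
chromosome is rendered as two digits (00 = unanchored scaffold bin), the
object type is one of eleven lowercase tokens, the numeric code is five
digits, the optional hyphen-delimited variant discriminates alleles / splice
forms, and the optional dot-delimited version counts structural edits.

Identifiers are never reused; parsing and formatting round-trip exactly.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

__all__ = [
    "ObjectType",
    "LocusID",
    "LegacyLocusID",
    "LocusIDError",
    "TaxonCodeError",
    "ChromosomeRangeError",
    "NumericCodeError",
    "ObjectTypeError",
    "VariantError",
    "VersionError",
    "LegacyIDError",
    "Ordering",
    "parse_locus_id",
    "format_locus_id",
    "validate_locus_id",
    "parse_legacy_id",
    "compare_ids",
    "sort_ids",
]


class LocusIDError(ValueError):
    """Base class for all locus-identifier grammar errors."""


class TaxonCodeError(LocusIDError):
    """Taxon code is not a 5-6 letter species abbreviation."""


class ChromosomeRangeError(LocusIDError):
    """Chromosome is not a two-digit number in 00-19."""


class NumericCodeError(LocusIDError):
    """Numeric code is not exactly five digits in 00001-99999."""


class ObjectTypeError(LocusIDError):
    """Object-type token is not one of the eleven admissible codes."""


class VariantError(LocusIDError):
    """Sequence-variant suffix is malformed or not admissible."""


class VersionError(LocusIDError):
    """Version suffix is not a positive integer."""


class LegacyIDError(LocusIDError):
    """String does not match the legacy 12X-v1 identifier shape."""


class ObjectType(enum.Enum):
    """Molecular-entity code: the third element of a locus identifier.

    Splice-variant digits are admissible only on ``t`` (transcript) and
    ``p`` (protein) objects.
    """

    GENE = "g"
    TRANSCRIPT = "t"
    PROTEIN = "p"
    NON_CODING = "nc"
    TRNA = "tr"
    TRANSPOSABLE_ELEMENT = "te"
    RRNA = "rr"
    MIRNA = "mi"
    PSEUDOGENE = "ps"
    SIRNA = "si"
    SNRNA = "sn"

    @property
    def allows_splice_variant(self) -> bool:
        return self in (ObjectType.TRANSCRIPT, ObjectType.PROTEIN)

    @classmethod
    def from_token(cls, token: str) -> "ObjectType":
        try:
            return cls(token)
        except ValueError:
            raise ObjectTypeError(
                f"unknown object-type token {token!r}; expected one of "
                f"{sorted(m.value for m in cls)}"
            ) from None


OBJECT_TYPE_DESCRIPTIONS = {
    ObjectType.GENE: "gene",
    ObjectType.TRANSCRIPT: "protein coding transcript",
    ObjectType.PROTEIN: "protein",
    ObjectType.NON_CODING: "non-coding",
    ObjectType.TRNA: "transfer RNA",
    ObjectType.TRANSPOSABLE_ELEMENT: "transposable element",
    ObjectType.RRNA: "ribosomal RNA",
    ObjectType.MIRNA: "microRNA",
    ObjectType.PSEUDOGENE: "pseudogene",
    ObjectType.SIRNA: "small interfering RNA",
    ObjectType.SNRNA: "small nuclear RNA",
}

MAX_CHROMOSOME = 19
MAX_NUMERIC_CODE = 99999

# variant token: optional lowercase letters (cultivar and/or allele code)
# followed by an optional run of splice-form digits; never empty
_VARIANT_RE = re.compile(r"^(?P<letters>[a-z]*)(?P<digits>[0-9]*)$")

# overall shape: letters, two digits, 1-2 lowercase letters, five digits,
# then optional -variant and .version suffixes
_ID_RE = re.compile(
    r"^(?P<taxon>[A-Za-z]+?)"
    r"(?P<chrom>\d{2})"
    r"(?P<otype>[a-z]{1,2})"
    r"(?P<code>\d{5})"
    r"(?P<rest>(?:-[^.]*)?(?:\..*)?)$"
)

_LEGACY_RE = re.compile(r"^VIT(?P<chrom>\d{2})s(?P<scaf>\d{4})g(?P<gene>\d{5})$", re.I)


@dataclass(frozen=True, order=False)
class LocusID:
    """Structured form of the six-element grapevine locus identifier.

    An absent ``version`` means "the most recent version"; it is stored as
    ``None``, never defaulted to 1, so round-trips are exact.
    """

    taxon: str
    chromosome: int
    object_type: ObjectType
    numeric_code: int
    variant: Optional[str] = None
    version: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon", self.taxon.upper())

    @property
    def base(self) -> "LocusID":
        """The identifier with variant and version stripped (the locus itself)."""
        if self.variant is None and self.version is None:
            return self
        return LocusID(self.taxon, self.chromosome, self.object_type, self.numeric_code)

    def sort_key(self) -> Tuple:
        return (
            self.taxon,
            self.chromosome,
            self.numeric_code,
            self.object_type.value,
            self.variant or "",
            self.version or 0,
        )

    def __str__(self) -> str:
        return format_locus_id(self)


@dataclass(frozen=True)
class LegacyLocusID:
    """A 12X-v1 style identifier (``VIT06s0009g01380``): chromosome,
    scaffold index and gene index.  Kept only so historical names can be
    parsed and stored as synonyms; there is no grammar-level mapping from
    legacy to current identifiers."""

    chromosome: int
    scaffold_index: int
    gene_index: int
    raw: str


def split_variant(variant: str) -> Tuple[str, str]:
    """Split a variant token into its letter part and splice-digit part."""
    m = _VARIANT_RE.match(variant)
    if m is None:
        raise VariantError(f"malformed variant token {variant!r}")
    return m.group("letters"), m.group("digits")


def parse_locus_id(text: str) -> LocusID:
    """Parse an identifier string into a :class:`LocusID`.

    The taxon code is case-insensitive on input; each grammar violation
    raises its own :class:`LocusIDError` subclass.
    """
    if not text:
        raise LocusIDError("empty identifier string")
    m = _ID_RE.match(text)
    if m is None:
        _diagnose_failure(text)
        raise LocusIDError(f"malformed locus identifier {text!r}")

    taxon = m.group("taxon").upper()
    if not 5 <= len(taxon) <= 6:
        raise TaxonCodeError(
            f"taxon code {m.group('taxon')!r} must be 5-6 letters"
        )
    chromosome = int(m.group("chrom"))
    if chromosome > MAX_CHROMOSOME:
        raise ChromosomeRangeError(
            f"chromosome {m.group('chrom')} outside 00-{MAX_CHROMOSOME}"
        )
    object_type = ObjectType.from_token(m.group("otype"))
    numeric_code = int(m.group("code"))
    if numeric_code == 0:
        raise NumericCodeError("numeric code 00000 is not issued")

    variant: Optional[str] = None
    version: Optional[int] = None
    rest = m.group("rest")
    if rest:
        variant, version = _parse_suffixes(rest)
        if variant is not None:
            _check_variant(variant, object_type)
    return LocusID(taxon, chromosome, object_type, numeric_code, variant, version)


def _diagnose_failure(text: str) -> None:
    """Raise the most specific error for a string the overall regex rejects."""
    m = re.match(r"^([A-Za-z]+)", text)
    if m is None:
        return
    taxon = m.group(1)
    if not 5 <= len(taxon) <= 6:
        raise TaxonCodeError(f"taxon code {taxon!r} must be 5-6 letters")
    after = text[m.end():]
    run = re.match(r"^(\d+)", after)
    if run is None or len(run.group(1)) < 2:
        raise ChromosomeRangeError(
            f"expected a two-digit chromosome after taxon code in {text!r}"
        )
    after = after[2:]
    otype = re.match(r"^([A-Za-z]{1,2})", after)
    if otype is None or not otype.group(1).islower():
        raise ObjectTypeError(
            f"expected a lowercase object-type token after chromosome in {text!r}"
        )
    digits = re.match(r"^(\d*)", after[otype.end():])
    if digits is not None and len(digits.group(1)) != 5:
        raise NumericCodeError(
            f"numeric code must be exactly five digits in {text!r}"
        )


def _parse_suffixes(rest: str) -> Tuple[Optional[str], Optional[int]]:
    variant: Optional[str] = None
    version: Optional[int] = None
    if "." in rest:
        rest, _, version_text = rest.partition(".")
        if not version_text.isdigit():
            raise VersionError(f"malformed version suffix {version_text!r}")
        version = int(version_text)
        if version < 1:
            raise VersionError("version must be >= 1")
    if rest:
        if not rest.startswith("-"):
            raise VariantError(f"variant suffix {rest!r} must start with a hyphen")
        variant = rest[1:]
        if not variant:
            raise VariantError("empty variant token after hyphen")
    return variant, version


def _check_variant(variant: str, object_type: ObjectType) -> None:
    letters, digits = split_variant(variant)
    if not letters and not digits:
        raise VariantError("empty variant token")
    if digits and not object_type.allows_splice_variant:
        raise VariantError(
            f"splice-variant digits ({variant!r}) are admissible only on "
            f"object types 't' and 'p', not {object_type.value!r}"
        )


def format_locus_id(locus: LocusID, style: str = "canonical") -> str:
    """Render a :class:`LocusID` as a string.

    ``canonical`` renders the taxon title-case (``Vitvi18g12230``);
    ``uppercase`` renders it fully uppercase (``VITVI18g12230``).
    """
    if style == "canonical":
        taxon = locus.taxon.capitalize()
    elif style == "uppercase":
        taxon = locus.taxon.upper()
    else:
        raise ValueError(f"unknown style {style!r}")
    parts = [
        taxon,
        f"{locus.chromosome:02d}",
        locus.object_type.value,
        f"{locus.numeric_code:05d}",
    ]
    if locus.variant is not None:
        parts.append(f"-{locus.variant}")
    if locus.version is not None:
        parts.append(f".{locus.version}")
    return "".join(parts)


def validate_locus_id(locus: LocusID) -> List[str]:
    """Check a structured identifier against the grammar invariants.

    Returns a list of human-readable violations (empty iff valid); nothing
    is raised, so directly-constructed identifiers can be audited.
    """
    violations: List[str] = []
    if not re.fullmatch(r"[A-Z]{5,6}", locus.taxon):
        violations.append(f"taxon code {locus.taxon!r} must be 5-6 letters")
    if not 0 <= locus.chromosome <= MAX_CHROMOSOME:
        violations.append(
            f"chromosome {locus.chromosome} outside 00-{MAX_CHROMOSOME}"
        )
    if not 1 <= locus.numeric_code <= MAX_NUMERIC_CODE:
        violations.append(
            f"numeric code {locus.numeric_code} outside 1-{MAX_NUMERIC_CODE}"
        )
    if locus.variant is not None:
        m = _VARIANT_RE.match(locus.variant)
        if m is None or not locus.variant:
            violations.append(f"malformed variant token {locus.variant!r}")
        elif m.group("digits") and not locus.object_type.allows_splice_variant:
            violations.append(
                f"splice-variant digits on object type {locus.object_type.value!r} "
                "(admissible only on 't' and 'p')"
            )
    if locus.version is not None and locus.version < 1:
        violations.append(f"version {locus.version} must be >= 1")
    return violations


def parse_legacy_id(text: str) -> LegacyLocusID:
    """Parse a legacy 12X-v1 identifier such as ``VIT06s0009g01380``."""
    if not text:
        raise LegacyIDError("empty identifier string")
    m = _LEGACY_RE.match(text)
    if m is None:
        raise LegacyIDError(f"{text!r} does not match the legacy shape "
                            "VIT<chr:2>s<scaffold:4>g<gene:5>")
    chromosome = int(m.group("chrom"))
    if chromosome > MAX_CHROMOSOME:
        raise ChromosomeRangeError(
            f"legacy chromosome {m.group('chrom')} outside 00-{MAX_CHROMOSOME}"
        )
    return LegacyLocusID(
        chromosome=chromosome,
        scaffold_index=int(m.group("scaf")),
        gene_index=int(m.group("gene")),
        raw=text,
    )


class Ordering(enum.Enum):
    BEFORE = -1
    EQUAL = 0
    AFTER = 1


def compare_ids(a: LocusID, b: LocusID) -> Ordering:
    """Total order on identifiers: taxon, chromosome, numeric code, object
    type, then variant and version.  Equal only when all six elements are."""
    ka, kb = a.sort_key(), b.sort_key()
    if ka < kb:
        return Ordering.BEFORE
    if ka > kb:
        return Ordering.AFTER
    return Ordering.EQUAL


def sort_ids(ids: Iterable[LocusID]) -> List[LocusID]:
    return sorted(ids, key=LocusID.sort_key)
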