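"""Grammar for systematic tropomyosin isoform names.

Mammalian tropomyosins are expressed from four genes (TPM1–TPM4). A systematic
protein name has the form ``Tpm<gene>.<ordinal>[<tissue>] (<exon code>)`` where

* ``gene`` is 1–4 and ``ordinal`` numbers the isoform within its gene;
* the optional tissue tag records the tissue *historically* associated with the
  isoform: ``st`` (striated muscle), ``sm`` (smooth muscle), ``br`` (brain),
  ``cy`` (other cytoplasmic), or the combined ``sm/cy``;
* the exon-usage code is four dot-separated tokens giving the splice variant
  used at each of the four alternatively spliced coding exons (1, 2, 6, 9),
  e.g. ``a.b.b.a``. A dash in the second slot (``b.-.b.d``) means exon 2 is
  skipped, which is the hallmark of the short, low-molecular-weight isoforms
  initiated at exon 1b.

The short style of a name is just ``Tpm<gene>.<ordinal>``.

Exon 9 admits a composite token ``a/c``: the ninth coding segment consists of
exon 9a plus five amino acids encoded by exon 9c (seen in two TPM3 isoforms).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Optional

from . import errors
from .errors import NomenclatureError, NomenclatureWarning

__all__ = [
    "ExonSelection",
    "IsoformName",
    "parse_name",
    "format_name",
    "parse_exon_code",
    "VALID_TISSUES",
    "SLOT_ALPHABETS",
]

#: Recognised tissue tags, lowercase canonical form.
VALID_TISSUES = ("st", "sm", "br", "cy", "sm/cy")

#: Admissible tokens per slot of the four-letter exon-usage code.  ``None``
#: encodes an absent exon 2 (serialised as "-").
SLOT_ALPHABETS = {
    "exon1": ("a", "b"),
    "exon2": ("a", "b", None),
    "exon6": ("a", "b"),
    "exon9": ("a", "b", "c", "d", "a/c"),
}

#: Canonical slot names in gene order.
SLOTS = ("exon1", "exon2", "exon6", "exon9")


@dataclass(frozen=True, order=False)
class ExonSelection:
    """The four-slot splice code of one isoform.

    ``exon2 is None`` encodes a skipped exon 2 (serialised as ``-``); for every
    catalogued mammalian isoform this happens exactly when ``exon1 == "b"``
    (the linkage rule), enforced at parse/validation level and relaxable via an
    explicit flag.
    """

    exon1: str
    exon2: Optional[str]
    exon6: str
    exon9: str

    def __post_init__(self):
        for slot in SLOTS:
            value = getattr(self, slot)
            if value not in SLOT_ALPHABETS[slot]:
                raise NomenclatureError(
                    errors.BAD_EXON_TOKEN,
                    f"{value!r} is not a valid variant for {slot} "
                    f"(allowed: {SLOT_ALPHABETS[slot]})",
                )

    def serialise(self) -> str:
        """Render as the four dot-separated tokens, ``-`` for absent exon 2."""
        tokens = [self.exon1, self.exon2 or "-", self.exon6, self.exon9]
        return ".".join(tokens)

    def astuple(self) -> tuple:
        return (self.exon1, self.exon2, self.exon6, self.exon9)

    def sort_key(self) -> tuple:
        """Slot-lexicographic key following each slot's alphabet order."""
        return tuple(
            SLOT_ALPHABETS[slot].index(getattr(self, slot)) for slot in SLOTS
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialise()


@dataclass(frozen=True)
class IsoformName:
    """Structured systematic name of one tropomyosin isoform."""

    gene: int
    ordinal: int
    tissue: Optional[str] = None
    selection: Optional[ExonSelection] = None
    style: str = "formal"

    def __post_init__(self):
        if self.gene not in (1, 2, 3, 4):
            raise NomenclatureError(
                errors.GENE_OUT_OF_RANGE,
                f"gene {self.gene} out of range: mammals carry TPM1-TPM4 only",
            )
        if self.ordinal < 1:
            raise NomenclatureError(
                errors.BAD_ORDINAL, f"isoform ordinal must be >= 1, got {self.ordinal}"
            )
        if self.tissue is not None and self.tissue not in VALID_TISSUES:
            raise NomenclatureError(
                errors.UNKNOWN_TISSUE,
                f"unknown tissue tag {self.tissue!r} (allowed: {VALID_TISSUES})",
            )
        if self.style not in ("formal", "short"):
            raise NomenclatureError(
                errors.MALFORMED_NAME, f"style must be 'formal' or 'short', got {self.style!r}"
            )

    @property
    def short(self) -> str:
        return f"Tpm{self.gene}.{self.ordinal}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return format_name(self, self.style)


# Grammar: prefix, gene, ".", ordinal, optional tissue letters, optional
# parenthesised exon code with or without a preceding space.
_NAME_RE = re.compile(
    r"""^\s*
        (?P<prefix>[A-Za-z]+)
        (?P<gene>\d+)
        \.
        (?P<ordinal>\d+)
        (?P<tissue>[A-Za-z/]*)
        \s*
        (?:\(\s*(?P<code>[^)]*)\s*\))?
        \s*$""",
    re.VERBOSE,
)

# Typo dialect: a three-token code in which the dash fused with its neighbour,
# e.g. "b.-b.a" for "b.-.b.a" (one registry entry, Tpm1.13, prints this form).
_FUSED_DASH_RE = re.compile(r"^-(?P<rest>[a-d])$|^(?P<rest2>[a-d])-$")


def parse_exon_code(text: str, *, check_linkage: bool = True) -> ExonSelection:
    """Parse a four-token exon-usage code such as ``a.b.b.a`` or ``b.-.a.a/c``.

    The known typo dialect with a fused dash (``b.-b.a``) is normalised to the
    regular three-dot form with a :class:`NomenclatureWarning`.

    Parameters
    ----------
    text : str
        The code, without surrounding parentheses.
    check_linkage : bool
        Enforce the linkage rule exon1 = b ⇔ exon 2 absent (registry-level
        strictness). Pass ``False`` to parse hypothetical codes.
    """
    if not text or not text.strip():
        raise NomenclatureError(errors.EMPTY_INPUT, "empty exon-usage code")
    tokens = [t.strip() for t in text.strip().split(".")]
    if len(tokens) == 3:
        # try the fused-dash normalisation before rejecting the token count
        for i, tok in enumerate(tokens):
            m = _FUSED_DASH_RE.match(tok)
            if m:
                letter = m.group("rest") or m.group("rest2")
                repaired = tokens[:i] + (
                    ["-", letter] if m.group("rest") else [letter, "-"]
                ) + tokens[i + 1 :]
                warnings.warn(
                    f"exon code {text!r} normalised to {'.'.join(repaired)!r} "
                    "(fused-dash typo dialect)",
                    NomenclatureWarning,
                    stacklevel=2,
                )
                tokens = repaired
                break
    if len(tokens) != 4:
        raise NomenclatureError(
            errors.BAD_TOKEN_COUNT,
            f"exon-usage code needs exactly 4 dot-separated tokens, got "
            f"{len(tokens)} in {text!r}",
        )
    values = []
    for slot, tok in zip(SLOTS, tokens):
        tok_l = tok.lower()
        value: Optional[str]
        if slot == "exon2" and tok_l == "-":
            value = None
        else:
            value = tok_l
        if value not in SLOT_ALPHABETS[slot]:
            raise NomenclatureError(
                errors.BAD_EXON_TOKEN,
                f"token {tok!r} invalid for {slot} "
                f"(allowed: {', '.join(v or '-' for v in SLOT_ALPHABETS[slot])})",
            )
        values.append(value)
    sel = ExonSelection(*values)
    if check_linkage and (sel.exon1 == "b") != (sel.exon2 is None):
        raise NomenclatureError(
            errors.LINKAGE_VIOLATION,
            f"code {sel.serialise()!r} violates the linkage rule: exon 2 is "
            "skipped exactly in exon-1b (short form) isoforms",
        )
    return sel


def parse_name(text: str, *, check_linkage: bool = True) -> IsoformName:
    """Parse a systematic name in formal or short style.

    Accepts a case-insensitive ``Tpm``/``TPM`` prefix, an optional tissue tag in
    either case, and an optional parenthesised exon code with or without a
    space before ``(``. The returned name records which style was seen: short
    if neither tissue nor code was present.
    """
    if text is None or not str(text).strip():
        raise NomenclatureError(errors.EMPTY_INPUT, "empty isoform name")
    m = _NAME_RE.match(text)
    if m is None:
        raise NomenclatureError(
            errors.MALFORMED_NAME, f"cannot parse isoform name {text!r}"
        )
    if m.group("prefix").lower() != "tpm":
        raise NomenclatureError(
            errors.BAD_PREFIX,
            f"name must start with 'Tpm', got {m.group('prefix')!r}",
        )
    gene = int(m.group("gene"))
    if gene not in (1, 2, 3, 4):
        raise NomenclatureError(
            errors.GENE_OUT_OF_RANGE,
            f"gene {gene} out of range: mammals carry TPM1-TPM4 only",
        )
    ordinal = int(m.group("ordinal"))
    if ordinal < 1:
        raise NomenclatureError(
            errors.BAD_ORDINAL, f"isoform ordinal must be >= 1, got {ordinal}"
        )
    tissue_raw = m.group("tissue")
    tissue = tissue_raw.lower() if tissue_raw else None
    if tissue is not None and tissue not in VALID_TISSUES:
        raise NomenclatureError(
            errors.UNKNOWN_TISSUE,
            f"unknown tissue tag {tissue_raw!r} (allowed: {VALID_TISSUES})",
        )
    code_raw = m.group("code")
    selection = (
        parse_exon_code(code_raw, check_linkage=check_linkage)
        if code_raw is not None
        else None
    )
    style = "short" if tissue is None and selection is None else "formal"
    return IsoformName(gene=gene, ordinal=ordinal, tissue=tissue,
                       selection=selection, style=style)


def format_name(name: IsoformName, style: str = "formal") -> str:
    """Render a name deterministically.

    Formal style: ``Tpm<g>.<n>[<tissue>] (<e1>.<e2>.<e6>.<e9>)`` with a single
    space before ``(``, lowercase tissue tags and a dash for absent exon 2;
    tissue and code are rendered only when present. Short style emits
    ``Tpm<g>.<n>``.
    """
    if style not in ("formal", "short"):
        raise NomenclatureError(
            errors.MALFORMED_NAME, f"unknown style {style!r}"
        )
    base = f"Tpm{name.gene}.{name.ordinal}"
    if style == "short":
        return base
    out = base
    if name.tissue:
        out += name.tissue
    if name.selection is not None:
        out += f" ({name.selection.serialise()})"
    return out


def as_short(name: IsoformName) -> IsoformName:
    """Return the same name restyled as short."""
    return replace(name, style="short")
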