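"""The packaged tropomyosin isoform catalogue and legacy-name resolution.

The registry holds the 29 catalogued mammalian tropomyosin protein isoforms —
13 from TPM1, 4 from TPM2, 10 from TPM3 and 2 from TPM4 — with their
systematic names, the common and alternate (legacy) names used in the
literature, and per-species RefSeq/GenBank protein accessions for human, mouse
and rat (an explicit ``none`` marks an isoform not documented at the nucleic
acid level in that species).

Legacy-name resolution is exact-after-normalisation: queries are Unicode
normalised, case-folded, Greek letters are unified with their spelled-out
forms (α/alpha, β/beta, γ/gamma, δ/delta, κ/kappa), dash variants are unified
and whitespace is dropped. No fuzzy matching happens in the core — a
nomenclature tool must not silently approximate (edit-distance suggestion is
an explicit opt-in in the CLI).
"""

from __future__ import annotations

import io
import json
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union
import warnings

import pandas as pd

from . import errors
from .errors import NomenclatureWarning, RegistryError
from .gene_models import Policy, ValidationReport, build_gene_models, validate_selection
from .nomenclature import (
    ExonSelection,
    IsoformName,
    format_name,
    parse_exon_code,
    parse_name,
)

__all__ = [
    "IsoformRecord",
    "AliasIndex",
    "load_registry",
    "resolve_alias",
    "lookup_by_code",
    "lookup_by_accession",
    "audit_registry",
    "export_registry",
    "normalise_alias",
    "LOW_CONFIDENCE_ALIASES",
]

SPECIES = ("human", "mouse", "rat")

#: TSV column order (stable; export -> load is the identity).
COLUMNS = ("short_name", "formal_name", "gene", "tissue", "exon_code",
           "common_names", "alternate_names", "acc_human", "acc_mouse",
           "acc_rat")

#: Which source table catalogues each gene.
GENE_TO_TABLE = {1: 1, 3: 2, 2: 3, 4: 4}

#: Alias strings whose delimitation in the source tables is typographically
#: ambiguous; they resolve normally but are excluded from strict coverage
#: checks.
LOW_CONFIDENCE_ALIASES = frozenset({"smooth α-Tm"})

_GREEK = {"α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "κ": "kappa"}
_DASHES = dict.fromkeys("‐‑‒–—−", "-")


def normalise_alias(text: str) -> str:
    """Canonical key for alias lookup.

    NFKC-normalise, map Greek letters to spelled-out names, unify dash
    variants, casefold, and drop all whitespace — so ``κTm``, ``kappa Tm`` and
    ``Kappa-Tm``... the first two collapse to the same key, hyphens are kept
    but unified.
    """
    s = unicodedata.normalize("NFKC", text)
    s = "".join(_GREEK.get(ch, _DASHES.get(ch, ch)) for ch in s)
    s = s.casefold()
    return "".join(s.split())


@dataclass(frozen=True)
class IsoformRecord:
    """One catalogued isoform: names, legacy aliases, per-species accessions."""

    name: IsoformName
    formal_name: str  # verbatim as catalogued (spacing and typos preserved)
    common_names: Tuple[str, ...]
    alternate_names: Tuple[str, ...]
    accessions: Dict[str, Optional[str]]
    source_table: int

    @property
    def gene(self) -> int:
        return self.name.gene

    @property
    def short_name(self) -> str:
        return self.name.short

    @property
    def selection(self) -> ExonSelection:
        return self.name.selection

    @property
    def aliases(self) -> Tuple[str, ...]:
        return self.common_names + self.alternate_names

    def to_row(self) -> dict:
        return {
            "short_name": self.short_name,
            "formal_name": self.formal_name,
            "gene": self.gene,
            "tissue": self.name.tissue or "",
            "exon_code": self.selection.serialise(),
            "common_names": "|".join(self.common_names),
            "alternate_names": "|".join(self.alternate_names),
            "acc_human": self.accessions["human"] or "none",
            "acc_mouse": self.accessions["mouse"] or "none",
            "acc_rat": self.accessions["rat"] or "none",
        }


def _split_aliases(cell: str) -> Tuple[str, ...]:
    if not cell:
        return ()
    return tuple(a.strip() for a in cell.split("|") if a.strip())


def _packaged_registry_text() -> str:
    return resources.files("tpmnom.data").joinpath("registry.tsv").read_text(
        encoding="utf-8")


def load_registry(source: Union[None, str, Path] = None) -> List[IsoformRecord]:
    """Load and schema-check the isoform catalogue.

    With no argument the packaged registry is read (29 records). ``source`` may
    point at a TSV or JSON export produced by :func:`export_registry`.
    """
    if source is None:
        df = pd.read_csv(io.StringIO(_packaged_registry_text()), sep="\t",
                         dtype=str, keep_default_na=False)
    else:
        path = Path(source)
        if path.suffix.lower() == ".json":
            payload = json.loads(path.read_text(encoding="utf-8"))
            check_registry_json(payload)
            df = pd.DataFrame(payload["records"], dtype=str)
            df["gene"] = df["gene"].astype(str)
        else:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError("schema-violation",
                            f"registry is missing columns: {missing}")

    records: List[IsoformRecord] = []
    seen_short = set()
    seen_codes = set()
    for i, row in df.iterrows():
        short = row["short_name"].strip()
        try:
            gene = int(row["gene"])
        except ValueError as exc:
            raise RegistryError("schema-violation",
                                f"row {i}: non-integer gene {row['gene']!r}") from exc
        tissue = row["tissue"].strip() or None
        sel = parse_exon_code(row["exon_code"])
        base = parse_name(short)
        if base.gene != gene:
            raise RegistryError(
                "schema-violation",
                f"row {i}: short name {short!r} disagrees with gene {gene}")
        name = IsoformName(gene=gene, ordinal=base.ordinal, tissue=tissue,
                           selection=sel, style="formal")
        if short in seen_short:
            raise RegistryError("duplicate-short-name",
                                f"duplicate short name {short!r}")
        seen_short.add(short)
        key = (gene, sel)
        if key in seen_codes:
            raise RegistryError(
                "duplicate-exon-code",
                f"duplicate exon code {sel.serialise()!r} within gene {gene}")
        seen_codes.add(key)
        accessions = {
            sp: (None if row[f"acc_{sp}"].strip().lower() in ("", "none")
                 else row[f"acc_{sp}"].strip())
            for sp in SPECIES
        }
        records.append(IsoformRecord(
            name=name,
            formal_name=row["formal_name"].strip(),
            common_names=_split_aliases(row["common_names"]),
            alternate_names=_split_aliases(row["alternate_names"]),
            accessions=accessions,
            source_table=GENE_TO_TABLE[gene],
        ))
    return records


_PACKAGED: Optional[List[IsoformRecord]] = None


def packaged_registry() -> List[IsoformRecord]:
    """The packaged catalogue, loaded once and cached."""
    global _PACKAGED
    if _PACKAGED is None:
        with warnings.catch_warnings():
            # the catalogued Tpm1.13 code prints the fused-dash typo dialect
            warnings.simplefilter("ignore", NomenclatureWarning)
            _PACKAGED = load_registry()
    return _PACKAGED


@dataclass
class AliasIndex:
    """Normalised alias string -> [(record, match-kind)]."""

    index: Dict[str, List[Tuple[IsoformRecord, str]]] = field(default_factory=dict)

    @classmethod
    def build(cls, records: Iterable[IsoformRecord]) -> "AliasIndex":
        idx: Dict[str, List[Tuple[IsoformRecord, str]]] = {}

        def add(key: str, rec: IsoformRecord, kind: str):
            idx.setdefault(key, []).append((rec, kind))

        for rec in records:
            add(normalise_alias(rec.short_name), rec, "systematic")
            add(normalise_alias(rec.formal_name), rec, "systematic")
            add(normalise_alias(format_name(rec.name, "formal")), rec, "systematic")
            for alias in rec.common_names:
                add(normalise_alias(alias), rec, "common")
            for alias in rec.alternate_names:
                add(normalise_alias(alias), rec, "alternate")
            for sp in SPECIES:
                acc = rec.accessions[sp]
                if acc:
                    add(normalise_alias(acc), rec, "accession")
                    add(normalise_alias(acc.split(".")[0]), rec, "accession")
        # de-duplicate while keeping insertion order
        for key, hits in idx.items():
            seen = set()
            uniq = []
            for rec, kind in hits:
                k = (rec.short_name, kind)
                if k not in seen:
                    seen.add(k)
                    uniq.append((rec, kind))
            idx[key] = uniq
        return cls(index=idx)


_RANK = {"systematic": 0, "common": 1, "alternate": 2, "accession": 3}
_INDEX: Optional[AliasIndex] = None


def _packaged_index() -> AliasIndex:
    global _INDEX
    if _INDEX is None:
        _INDEX = AliasIndex.build(packaged_registry())
    return _INDEX


def resolve_alias(query: str,
                  records: Optional[List[IsoformRecord]] = None,
                  ) -> List[Tuple[IsoformRecord, str]]:
    """Resolve a systematic name, legacy alias or accession to its record(s).

    Systematic names are tried through the name parser first; everything else
    goes through the normalised alias index. Ambiguous aliases return all
    candidates ranked systematic > common > alternate > accession; an unknown
    alias returns an empty list (not an error).
    """
    if not query or not query.strip():
        raise RegistryError(errors.EMPTY_INPUT, "empty alias query")
    if records is None:
        recs = packaged_registry()
        index = _packaged_index()
    else:
        recs = records
        index = AliasIndex.build(records)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NomenclatureWarning)
            parsed = parse_name(query)
    except Exception:
        parsed = None
    if parsed is not None:
        hits = [(r, "systematic") for r in recs
                if r.gene == parsed.gene and r.name.ordinal == parsed.ordinal]
        if hits:
            return hits

    hits = index.index.get(normalise_alias(query), [])
    return sorted(hits, key=lambda h: (_RANK[h[1]], h[0].gene,
                                       h[0].name.ordinal))


def lookup_by_code(gene: int, sel: ExonSelection,
                   records: Optional[List[IsoformRecord]] = None,
                   ) -> Optional[IsoformRecord]:
    """The unique record with this exon code in this gene, or ``None``."""
    for rec in (records if records is not None else packaged_registry()):
        if rec.gene == gene and rec.selection == sel:
            return rec
    return None


def lookup_by_accession(acc: str,
                        records: Optional[List[IsoformRecord]] = None,
                        ) -> Optional[Tuple[IsoformRecord, str]]:
    """Find the record and species carrying an accession (version-tolerant)."""
    want = normalise_alias(acc.split(".")[0])
    for rec in (records if records is not None else packaged_registry()):
        for sp in SPECIES:
            have = rec.accessions[sp]
            if have and normalise_alias(have.split(".")[0]) == want:
                return rec, sp
    return None


def audit_registry(records: Optional[List[IsoformRecord]] = None,
                   models: Optional[dict] = None) -> ValidationReport:
    """Mechanised internal-consistency check of the catalogue.

    Checks per-gene exon-code uniqueness, the exon-2 linkage rule on every
    code, validation of every code under its gene model (policy=registry),
    formal-name round-trips, alias-index coverage, and accession coverage
    (relaxed, by documented exception, for the composite-a/c records that
    carry no accession in any species). Returns all violations.
    """
    if records is None:
        records = packaged_registry()
    if models is None:
        models = build_gene_models(records)
    violations: List[Tuple[str, str]] = []

    seen = {}
    for rec in records:
        key = (rec.gene, rec.selection)
        if key in seen:
            violations.append((
                "duplicate-exon-code",
                f"{rec.short_name} duplicates code "
                f"{rec.selection.serialise()} of {seen[key]}"))
        else:
            seen[key] = rec.short_name

    for rec in records:
        sel = rec.selection
        if (sel.exon1 == "b") != (sel.exon2 is None):
            violations.append((
                "exon2-linkage",
                f"{rec.short_name} code {sel.serialise()} violates the "
                "exon-1b/exon-2 linkage rule"))
        report = validate_selection(models[(rec.gene, "human")], sel,
                                    Policy.REGISTRY)
        for rule, reason in report.violations:
            if rule == "exon2-linkage":
                continue  # already reported above
            violations.append((rule, f"{rec.short_name}: {reason}"))

    for rec in records:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NomenclatureWarning)
            reparsed = parse_name(rec.formal_name)
        if (reparsed.gene, reparsed.ordinal) != (rec.gene, rec.name.ordinal) \
                or reparsed.selection != rec.selection \
                or reparsed.tissue != rec.name.tissue:
            violations.append((
                "formal-name-mismatch",
                f"{rec.short_name}: formal name {rec.formal_name!r} does not "
                "re-parse to its catalogued fields"))

    index = AliasIndex.build(records)
    for rec in records:
        for alias in rec.aliases:
            hits = index.index.get(normalise_alias(alias), [])
            if rec not in [h[0] for h in hits]:
                violations.append((
                    "alias-coverage",
                    f"alias {alias!r} of {rec.short_name} is not indexed"))

    for rec in records:
        if all(rec.accessions[sp] is None for sp in SPECIES):
            if rec.selection.exon9 == "a/c":
                continue  # documented exception: composite-a/c records
            violations.append((
                "no-accession",
                f"{rec.short_name} has no accession in any species"))

    return ValidationReport(valid=not violations, policy=Policy.REGISTRY,
                            violations=violations)


def export_registry(records: List[IsoformRecord], path,
                    fmt: str = "tsv") -> None:
    """Write the catalogue as TSV or JSON with stable column/key order."""
    rows = [rec.to_row() for rec in records]
    path = Path(path)
    if fmt == "tsv":
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        payload = {"schema": "tpmnom-registry-v1", "records": rows}
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
    else:
        raise RegistryError("bad-format", f"unknown export format {fmt!r}")


def check_registry_json(payload: dict) -> None:
    """Schema check for the JSON export (explicit field/type checks)."""
    if not isinstance(payload, dict) or "records" not in payload:
        raise RegistryError("schema-violation",
                            "JSON registry must be an object with 'records'")
    if payload.get("schema") not in (None, "tpmnom-registry-v1"):
        raise RegistryError("schema-violation",
                            f"unknown schema tag {payload.get('schema')!r}")
    for i, row in enumerate(payload["records"]):
        if not isinstance(row, dict):
            raise RegistryError("schema-violation", f"record {i} is not an object")
        for col in COLUMNS:
            if col not in row:
                raise RegistryError("schema-violation",
                                    f"record {i} lacks field {col!r}")
        if not str(row["gene"]).isdigit() or int(row["gene"]) not in (1, 2, 3, 4):
            raise RegistryError("schema-violation",
                                f"record {i} has invalid gene {row['gene']!r}")
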