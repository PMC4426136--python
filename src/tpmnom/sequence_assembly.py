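"""Exon-level assembly of tropomyosin protein sequences.

A tropomyosin protein is the concatenation, in gene order, of the peptide
segments encoded by its exons: the alternative exon 1 (a or b), exon 2 when
retained, the invariant middle of the molecule (exons 3, 4, 5, 7 and 8,
modelled here as a single constant pseudo-slot because the four-letter code
only tracks the variable exons), the alternative exon 6, and the alternative
exon 9.  The composite exon 9 ``a/c`` contributes the full 9a segment followed
by exactly the first five residues of the 9c segment.

Post-translational rules: the initiator methionine is removed from every
exon-1b-encoded sequence, and the resulting N-terminal residue is N-acetylated
in all isoforms (annotated only — acetylation does not change the primary
sequence).

Real exon-peptide tables can be supplied as TSV; the fixture generator
produces synthetic, deterministic peptide sets with the same structure so the
assembly logic is testable without downloads.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AssemblyError
from .gene_models import Policy, default_gene_models, validate_selection
from .nomenclature import ExonSelection, IsoformName, format_name

__all__ = [
    "ExonPeptideSet",
    "AssembledProtein",
    "assemble_protein",
    "generate_fixture_peptides",
    "read_peptides",
    "write_peptides",
    "write_assembled",
    "read_assembled",
]

#: Assembly order; "middle" is the constant pseudo-slot covering exons 3-5, 7-8.
ASSEMBLY_ORDER = ("exon1", "exon2", "middle", "exon6", "exon9")

#: Residues admitted in segments: the 20 canonical amino acids.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: Residues of exon 9c contributed by the composite a/c ninth segment.
COMPOSITE_9C_RESIDUES = 5


@dataclass(frozen=True)
class ExonPeptideSet:
    """Amino-acid segments for one gene: (slot, variant) -> peptide."""

    gene: int
    species: str
    segments: Dict[Tuple[str, str], str]
    source: str = "user-supplied"  # or "fixture"

    def __post_init__(self):
        for (slot, variant), seq in self.segments.items():
            if not seq:
                raise AssemblyError(
                    "empty-segment", f"segment ({slot}, {variant}) is empty")
            bad = set(seq) - _CANONICAL_SET
            if bad:
                raise AssemblyError(
                    "non-canonical-residue",
                    f"segment ({slot}, {variant}) contains non-canonical "
                    f"residues {sorted(bad)}")
            if slot == "exon1" and variant == "b" and not seq.startswith("M"):
                raise AssemblyError(
                    "missing-initiator-met",
                    "every exon-1b segment must begin with the initiator Met")

    def get(self, slot: str, variant: str) -> str:
        try:
            return self.segments[(slot, variant)]
        except KeyError:
            raise AssemblyError(
                "missing-segment",
                f"gene {self.gene} peptide set has no segment for "
                f"({slot}, {variant})") from None


@dataclass(frozen=True)
class AssembledProtein:
    """A full-length isoform sequence with its N-terminus annotations."""

    name: Optional[IsoformName]
    sequence: str
    initiator_met_removed: bool
    n_acetylated: bool
    selection: Optional[ExonSelection] = None

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.sequence)


def _exon9_segment(peptides: ExonPeptideSet, variant: str) -> str:
    if variant == "a/c":
        seg_a = peptides.get("exon9", "a")
        seg_c = peptides.get("exon9", "c")
        if len(seg_c) < COMPOSITE_9C_RESIDUES:
            raise AssemblyError(
                "short-9c-segment",
                f"composite a/c needs >= {COMPOSITE_9C_RESIDUES} residues of "
                f"exon 9c, segment has {len(seg_c)}")
        return seg_a + seg_c[:COMPOSITE_9C_RESIDUES]
    return peptides.get("exon9", variant)


def assemble_protein(peptides: ExonPeptideSet, sel: ExonSelection,
                     apply_ptm: bool = True,
                     name: Optional[IsoformName] = None) -> AssembledProtein:
    """Concatenate the segments selected by a splice code.

    The selection must be admissible for the gene under the genomic policy.
    With ``apply_ptm`` the initiator Met of exon-1b-encoded sequences is
    removed; N-acetylation is annotated on every isoform but never alters the
    sequence.  The constant middle pseudo-slot is included when the peptide
    set provides it.
    """
    model = default_gene_models()[(peptides.gene, peptides.species)]
    report = validate_selection(model, sel, Policy.GENOMIC)
    if not report.valid:
        reasons = "; ".join(r for _, r in report.violations)
        raise AssemblyError(
            "inadmissible-selection",
            f"code {sel.serialise()} is not admissible for gene "
            f"TPM{peptides.gene} ({peptides.species}): {reasons}")

    parts: List[str] = [peptides.get("exon1", sel.exon1)]
    if sel.exon2 is not None:
        parts.append(peptides.get("exon2", sel.exon2))
    if ("middle", "const") in peptides.segments:
        parts.append(peptides.segments[("middle", "const")])
    parts.append(peptides.get("exon6", sel.exon6))
    parts.append(_exon9_segment(peptides, sel.exon9))

    sequence = "".join(parts)
    met_removed = False
    if apply_ptm and sel.exon1 == "b":
        sequence = sequence[1:]
        met_removed = True
    return AssembledProtein(
        name=name, sequence=sequence,
        initiator_met_removed=met_removed,
        n_acetylated=True, selection=sel,
    )


def generate_fixture_peptides(gene: int, seed: int,
                              segment_length_range: Tuple[int, int] = (8, 30),
                              species: str = "human") -> ExonPeptideSet:
    """Deterministic synthetic exon-peptide set for one gene.

    Segments are generated for every variant genomically present in the gene
    model (so, e.g., human gene-4 fixtures include exon 9a even though no
    isoform expresses it, and gene-2 fixtures contain no exon-1b segment).
    Every exon-1 segment begins with Met; all segments are pairwise distinct;
    the constant middle pseudo-slot is four times the length of a variable
    segment, roughly matching its share of the real molecule.
    """
    lo, hi = segment_length_range
    if lo < COMPOSITE_9C_RESIDUES:
        raise AssemblyError(
            "segment-too-short",
            f"minimum segment length must be >= {COMPOSITE_9C_RESIDUES} so "
            "the composite a/c ninth segment is always exercisable")
    rng = random.Random(seed)
    model = default_gene_models()[(gene, species)]

    wanted: List[Tuple[str, str]] = []
    for slot in ("exon1", "exon2", "exon6", "exon9"):
        for variant in sorted(v for v in model.slots[slot].present
                              if v is not None):
            wanted.append((slot, variant))
    wanted.append(("middle", "const"))

    segments: Dict[Tuple[str, str], str] = {}
    produced = set()
    for slot, variant in wanted:
        n = rng.randint(lo, hi) * (4 if slot == "middle" else 1)
        while True:
            body = "".join(rng.choice(CANONICAL_AA) for _ in range(n))
            seq = ("M" + body[1:]) if slot == "exon1" else body
            if seq not in produced:
                break
        produced.add(seq)
        segments[(slot, variant)] = seq
    return ExonPeptideSet(gene=gene, species=species, segments=segments,
                          source="fixture")


# ---------------------------------------------------------------------------
# TSV / FASTA I/O


def write_peptides(peptides: ExonPeptideSet, path) -> None:
    """Write a peptide set as TSV (gene, slot, variant, sequence)."""
    order = {slot: i for i, slot in enumerate(ASSEMBLY_ORDER)}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tslot\tvariant\tsequence\n")
        for (slot, variant), seq in sorted(
                peptides.segments.items(),
                key=lambda kv: (order[kv[0][0]], kv[0][1])):
            fh.write(f"{peptides.gene}\t{slot}\t{variant}\t{seq}\n")


def read_peptides(path, species: str = "human",
                  source: str = "user-supplied") -> ExonPeptideSet:
    """Read a peptide-set TSV; malformed rows are reported with line numbers."""
    segments: Dict[Tuple[str, str], str] = {}
    gene: Optional[int] = None
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene", "slot", "variant", "sequence"]:
            raise AssemblyError(
                "bad-header",
                f"expected header gene/slot/variant/sequence, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise AssemblyError(
                    "malformed-row",
                    f"line {lineno}: expected 4 tab-separated fields, got "
                    f"{len(fields)}")
            g_str, slot, variant, seq = fields
            if not g_str.isdigit():
                raise AssemblyError(
                    "malformed-row", f"line {lineno}: non-integer gene {g_str!r}")
            g = int(g_str)
            if gene is None:
                gene = g
            elif g != gene:
                raise AssemblyError(
                    "mixed-genes",
                    f"line {lineno}: gene {g} differs from gene {gene} of "
                    "earlier rows (one gene per peptide set)")
            if slot not in ASSEMBLY_ORDER:
                raise AssemblyError(
                    "malformed-row", f"line {lineno}: unknown slot {slot!r}")
            if (slot, variant) in segments:
                raise AssemblyError(
                    "duplicate-segment",
                    f"line {lineno}: duplicate segment ({slot}, {variant})")
            segments[(slot, variant)] = seq
    if gene is None:
        raise AssemblyError("empty-file", f"{path}: no peptide rows")
    return ExonPeptideSet(gene=gene, species=species, segments=segments,
                          source=source)


def fasta_header(name: IsoformName, species: str,
                 accession: Optional[str]) -> str:
    """``Tpm<g>.<n>|<formal name>|<species>|<accession-or-NA>``."""
    return "|".join([
        name.short,
        format_name(name, "formal"),
        species,
        accession or "NA",
    ])


def write_assembled(proteins: List[AssembledProtein], path,
                    species: str = "human") -> None:
    """Write assembled isoforms as 60-column FASTA.

    Accessions for the header are taken from the packaged catalogue when the
    protein carries a catalogued name; NA otherwise.
    """
    from .registry import packaged_registry  # deferred to avoid cycle at import

    by_short = {r.short_name: r for r in packaged_registry()}
    records = []
    for i, prot in enumerate(proteins, start=1):
        if prot.name is None:
            code = prot.selection.serialise() if prot.selection else "unknown"
            header = f"assembly{i}|({code})|{species}|NA"
        else:
            rec = by_short.get(prot.name.short)
            acc = rec.accessions.get(species) if rec else None
            header = fasta_header(prot.name, species, acc)
        records.append(SeqRecord(Seq(prot.sequence), id=header, description=""))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def read_assembled(path) -> List[Tuple[str, str]]:
    """Read a FASTA of assembled isoforms as (header, sequence) pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id if not rec.description or rec.description == rec.id \
            else rec.description
        out.append((header, str(rec.seq)))
    return out
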