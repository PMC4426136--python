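"""Exon-level assembly: concatenation order, PTM rules, fixtures, I/O."""

import pytest

from tpmnom import (
    AssemblyError,
    ExonPeptideSet,
    ExonSelection,
    assemble_protein,
    generate_fixture_peptides,
    parse_exon_code,
    read_peptides,
    write_assembled,
    write_peptides,
)
from tpmnom.sequence_assembly import COMPOSITE_9C_RESIDUES, read_assembled


@pytest.fixture
def minimal_peptides():
    """Hand-built gene-1 set with known segments (no middle pseudo-slot)."""
    return ExonPeptideSet(
        gene=1, species="human",
        segments={
            ("exon1", "a"): "MDAIKKK",
            ("exon1", "b"): "MAGSSS",
            ("exon2", "a"): "WNDEN",
            ("exon2", "b"): "LDKEN",
            ("exon6", "a"): "KCAEL",
            ("exon6", "b"): "QAEAD",
            ("exon9", "a"): "MALKLC",
            ("exon9", "b"): "HHHHHH",
            ("exon9", "c"): "NDMTSI",
            ("exon9", "d"): "KLVIIESDL",
        },
        source="fixture",
    )


def test_concatenation_in_gene_order(minimal_peptides):
    prot = assemble_protein(minimal_peptides, parse_exon_code("a.b.b.d"))
    assert prot.sequence == "MDAIKKK" + "LDKEN" + "QAEAD" + "KLVIIESDL"
    assert len(prot.sequence) == 26
    assert not prot.initiator_met_removed  # exon-1a Met is retained
    assert prot.n_acetylated


def test_exon1b_initiator_met_removed(minimal_peptides):
    prot = assemble_protein(minimal_peptides, parse_exon_code("b.-.b.d"))
    assert prot.sequence.startswith("AGSSS")
    assert prot.initiator_met_removed
    raw = assemble_protein(minimal_peptides, parse_exon_code("b.-.b.d"),
                           apply_ptm=False)
    assert raw.sequence.startswith("MAGSSS")
    assert not raw.initiator_met_removed


def test_composite_9ac_appends_five_residues_of_9c(minimal_peptides):
    # gene-3 fixture so the composite is admissible under the gene model
    pep3 = ExonPeptideSet(gene=3, species="human",
                          segments=dict(minimal_peptides.segments))
    prot = assemble_protein(pep3, parse_exon_code("b.-.a.a/c"))
    assert prot.sequence.endswith("MALKLC" + "NDMTSI"[:COMPOSITE_9C_RESIDUES])
    assert prot.sequence.endswith("MALKLCNDMTS")


def test_short_9c_segment_rejected(minimal_peptides):
    segs = dict(minimal_peptides.segments)
    segs[("exon9", "c")] = "NDMT"  # 4 < 5 residues
    pep = ExonPeptideSet(gene=3, species="human", segments=segs)
    with pytest.raises(AssemblyError) as exc:
        assemble_protein(pep, parse_exon_code("b.-.a.a/c"))
    assert exc.value.code == "short-9c-segment"


def test_missing_segment_names_slot_and_variant(minimal_peptides):
    segs = dict(minimal_peptides.segments)
    del segs[("exon6", "b")]
    pep = ExonPeptideSet(gene=1, species="human", segments=segs)
    with pytest.raises(AssemblyError) as exc:
        assemble_protein(pep, parse_exon_code("a.b.b.d"))
    assert exc.value.code == "missing-segment"
    assert "exon6" in exc.value.message and "b" in exc.value.message


def test_non_canonical_residue_rejected_at_construction():
    with pytest.raises(AssemblyError) as exc:
        ExonPeptideSet(gene=1, species="human",
                       segments={("exon9", "a"): "WXYZAB"})
    assert exc.value.code == "non-canonical-residue"


def test_inadmissible_selection_rejected(minimal_peptides):
    pep2 = ExonPeptideSet(gene=2, species="human",
                          segments=dict(minimal_peptides.segments))
    with pytest.raises(AssemblyError) as exc:
        assemble_protein(pep2, parse_exon_code("b.-.a.d"))  # TPM2 has no 1b
    assert exc.value.code == "inadmissible-selection"


# -- fixture generator ------------------------------------------------------

def test_fixture_generation_deterministic():
    a = generate_fixture_peptides(1, seed=7)
    b = generate_fixture_peptides(1, seed=7)
    assert a.segments == b.segments
    c = generate_fixture_peptides(1, seed=8)
    assert a.segments != c.segments


def test_gene2_fixture_has_no_exon1b_segment():
    pep = generate_fixture_peptides(2, seed=1)
    assert ("exon1", "b") not in pep.segments
    assert ("exon1", "a") in pep.segments


def test_gene3_fixture_supports_composite_assembly():
    pep = generate_fixture_peptides(3, seed=3)
    assert ("exon9", "a") in pep.segments and ("exon9", "c") in pep.segments
    prot = assemble_protein(pep, parse_exon_code("b.-.a.a/c"))
    seg_a = pep.segments[("exon9", "a")]
    seg_c = pep.segments[("exon9", "c")]
    assert prot.sequence.endswith(seg_a + seg_c[:COMPOSITE_9C_RESIDUES])


def test_fixture_segments_pairwise_distinct_and_met_led():
    for gene in (1, 2, 3, 4):
        pep = generate_fixture_peptides(gene, seed=11)
        seqs = list(pep.segments.values())
        assert len(seqs) == len(set(seqs))
        for (slot, variant), seq in pep.segments.items():
            if slot == "exon1":
                assert seq.startswith("M")


def test_minimum_segment_length_guard():
    with pytest.raises(AssemblyError):
        generate_fixture_peptides(1, seed=1, segment_length_range=(3, 10))


# -- assembly invariants over many seeded fixtures --------------------------

def test_length_conservation_and_prefix_property_over_fixtures(models):
    from tpmnom import enumerate_selections

    checked = 0
    for gene in (1, 2, 3, 4):
        for seed in range(13):
            pep = generate_fixture_peptides(gene, seed=seed)
            model = models[(gene, "human")]
            sels = enumerate_selections(model, "genomic")
            by_prefix = {}
            seen_seqs = set()
            for sel in sels:
                prot = assemble_protein(pep, sel)
                expected = len(pep.segments[("exon1", sel.exon1)])
                if sel.exon2 is not None:
                    expected += len(pep.segments[("exon2", sel.exon2)])
                expected += len(pep.segments[("middle", "const")])
                expected += len(pep.segments[("exon6", sel.exon6)])
                if sel.exon9 == "a/c":
                    expected += len(pep.segments[("exon9", "a")]) \
                        + COMPOSITE_9C_RESIDUES
                else:
                    expected += len(pep.segments[("exon9", sel.exon9)])
                if sel.exon1 == "b":
                    expected -= 1  # initiator Met removed
                assert len(prot.sequence) == expected, (gene, seed, sel)
                # Met removal happens exactly for exon-1b selections
                assert prot.initiator_met_removed == (sel.exon1 == "b")
                # injectivity: distinct selections -> distinct sequences
                assert prot.sequence not in seen_seqs
                seen_seqs.add(prot.sequence)
                # group by everything upstream of exon 9
                stem = len(pep.segments[("exon1", sel.exon1)]) \
                    + (len(pep.segments[("exon2", sel.exon2)])
                       if sel.exon2 is not None else 0) \
                    + len(pep.segments[("middle", "const")]) \
                    + len(pep.segments[("exon6", sel.exon6)]) \
                    - (1 if sel.exon1 == "b" else 0)
                key = (sel.exon1, sel.exon2, sel.exon6)
                by_prefix.setdefault(key, []).append(prot.sequence[:stem])
            # selections differing only in exon 9 share their prefix
            for group in by_prefix.values():
                assert len(set(group)) == 1
            checked += len(sels)
    assert checked >= 200


def test_exon9_prefix_property_explicit(models):
    """Two selections differing only in exon 9 agree up to the exon-6 end."""
    for gene in (1, 3):
        pep = generate_fixture_peptides(gene, seed=5)
        base = "b.-.b.a"
        for other in ("b.-.b.c", "b.-.b.d"):
            a = assemble_protein(pep, parse_exon_code(base))
            b = assemble_protein(pep, parse_exon_code(other))
            stem = len(a.sequence) - len(pep.segments[("exon9", "a")])
            assert a.sequence[:stem] == b.sequence[:stem]


# -- I/O --------------------------------------------------------------------

def test_peptide_tsv_roundtrip_byte_stable(tmp_path):
    pep = generate_fixture_peptides(3, seed=9)
    p1 = tmp_path / "pep.tsv"
    write_peptides(pep, p1)
    back = read_peptides(p1, species="human", source="fixture")
    assert back.segments == pep.segments and back.gene == pep.gene
    p2 = tmp_path / "pep2.tsv"
    write_peptides(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_peptide_tsv_duplicate_row_reports_line(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text(
        "gene\tslot\tvariant\tsequence\n"
        "1\texon6\tb\tQAEAD\n"
        "1\texon6\tb\tQAEAD\n",
        encoding="utf-8")
    with pytest.raises(AssemblyError) as exc:
        read_peptides(path)
    assert exc.value.code == "duplicate-segment"
    assert "line 3" in exc.value.message


def test_peptide_tsv_malformed_row_reports_line(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "gene\tslot\tvariant\tsequence\n"
        "1\texon6\tb\n",
        encoding="utf-8")
    with pytest.raises(AssemblyError) as exc:
        read_peptides(path)
    assert "line 2" in exc.value.message


def test_fasta_output_wrapped_and_byte_stable(tmp_path, records):
    from tpmnom import lookup_by_code

    pep = generate_fixture_peptides(3, seed=4)
    sel = parse_exon_code("b.-.a.d")
    rec = lookup_by_code(3, sel)
    prot = assemble_protein(pep, sel, name=rec.name)
    f1 = tmp_path / "out.fasta"
    write_assembled([prot], f1, species="human")
    text = f1.read_text(encoding="utf-8")
    header = text.splitlines()[0]
    assert header.startswith(">Tpm3.1|")
    assert "NP_705935.1" in header  # catalogued human accession
    assert all(len(line) <= 60 for line in text.splitlines()[1:])
    # read back and compare
    pairs = read_assembled(f1)
    assert len(pairs) == 1
    assert pairs[0][1] == prot.sequence
    f2 = tmp_path / "out2.fasta"
    write_assembled([prot], f2, species="human")
    assert f1.read_bytes() == f2.read_bytes()
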