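# tpmnom

A toolkit for the systematic nomenclature of mammalian tropomyosin (Tpm)
isoforms.

Tropomyosin is a two-chained coiled-coil actin-binding protein expressed from
four mammalian genes (*TPM1*–*TPM4*). Alternative promoter selection and
splicing of four coding exons (1, 2, 6 and 9) produce dozens of distinct
protein isoforms, which decades of tissue-by-tissue discovery left with a
thicket of conflicting legacy names (αTm, Tm5NM1, TmBr3, Tm2, βTm, …). The
systematic scheme names each isoform `Tpm<gene>.<ordinal>` with an optional
historical tissue tag (`st`, `sm`, `br`, `cy`, `sm/cy`) and a four-letter
exon-usage code such as `a.b.b.a` — exon 1 form a, exon 2 form b, exon 6 form
b, exon 9 form a. A dash in the second slot (`b.-.b.d`) marks the short,
low-molecular-weight isoforms that initiate at exon 1b and splice past exon 2.

`tpmnom` makes that scheme executable, so legacy literature and sequence
datasets can be harmonised mechanically. It provides:

* **nomenclature** — parse, validate and canonically format systematic names
  in formal (`Tpm1.12br (b.-.b.c)`) and short (`Tpm1.12`) styles, with stable
  machine-readable error codes and normalisation of known typographic
  dialects;
* **gene models** — per-gene, per-species exon-variant availability with the
  documented constraints (mammalian TPM2 lacks exon 1b; human TPM4 carries
  exon 9a genomically but never expresses it; mouse/rat TPM4 lack 9a; exon 2
  is skipped exactly in exon-1b isoforms), validation under three policies
  (`genomic`, `expressed`, `registry`) and deterministic enumeration of the
  admissible isoform space;
* **registry** — the packaged catalogue of all 29 documented isoforms (13 from
  TPM1, 4 from TPM2, 10 from TPM3, 2 from TPM4) with common/alternate legacy
  names and human/mouse/rat protein accessions; exact-after-normalisation
  alias resolution (Greek letters unified with spelled-out forms), accession
  lookup, a consistency audit, and TSV/JSON export;
* **sequence assembly** — build full-length isoform sequences from exon-level
  peptide segments, applying the composite exon-9 `a/c` rule (9a plus the
  first five residues of 9c) and the post-translational rules (initiator-Met
  removal for exon-1b sequences, N-acetylation annotation), plus a
  deterministic synthetic fixture generator and TSV/FASTA I/O;
* **cli** — `tpmnom parse | validate | resolve | enumerate | assemble |
  rename-fasta` with `--json` structured output and distinct exit codes.

## Worked example

```console
$ tpmnom resolve Tm5NM1
Tpm3.1 — Tpm3.1cy(b.-.a.d)  [common]
```

The legacy name Tm5NM1 denotes the cytoplasmic TPM3 product Tpm3.1, a short
isoform (exon 1b, dash in slot 2) using exon 6a and exon 9d.

```console
$ tpmnom validate --gene 2 --species human b.-.a.d
INVALID: b.-.a.d for TPM2 (human) under policy 'registry'
  [tpm2-no-exon1b] the TPM2 genes of human, mouse and rat do not contain exon 1b, so no gene-2 isoform can use it
```

The same code that is fine for TPM3 is rejected for TPM2 (exit code 3),
because mammalian TPM2 has no exon 1b and therefore no short isoforms.

```console
$ tpmnom enumerate --gene 4 --species human --policy registry-observed
a.b.b.d
b.-.b.d
# 2 admissible codes for TPM4 (human) under policy 'registry'
```

Restricting each slot to the variants observed in the catalogue, TPM4 admits
exactly the two catalogued codes (Tpm4.1 and Tpm4.2). Across all four genes
the human isoform space is 46 codes under the registry-observed policy, 52
under `expressed` and 54 under `genomic` — the enumerator reports counts per
documented policy rather than a single headline number, since the admissible
slot sets differ by policy.

```console
$ tpmnom assemble --gene 3 --code b.-.a.a/c --fixture-seed 7 --json
{"gene": 3, "exon_code": "b.-.a.a/c", "name": "Tpm3.8", "length": 100,
 "initiator_met_removed": true, ...}
```

Assembly of the composite-exon-9 isoform Tpm3.8 from a seeded synthetic
peptide set: the sequence ends with the full 9a segment plus five residues of
9c, and the initiator methionine of the exon-1b segment has been removed
(`initiator_met_removed: true`).

`tpmnom rename-fasta in.fasta out.fasta --report report.tsv` rewrites FASTA
headers containing resolvable legacy aliases (whole-token, longest-first
matching) to systematic names and reports every decision.

## Documentation

See `docs/methods.md` for the model, its assumptions, the policies, the
synthetic-fixture design and known limitations.
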