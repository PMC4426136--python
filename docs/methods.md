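# Methods

## The naming model

A systematic tropomyosin isoform name has four parts: the gene (1–4), an
ordinal within the gene, an optional tissue tag recording the tissue
*historically* associated with the isoform (`st` striated muscle, `sm` smooth
muscle, `br` brain, `cy` other cytoplasmic, and the combined `sm/cy`), and a
four-slot exon-usage code covering the alternatively spliced coding exons 1,
2, 6 and 9. Slot alphabets are: exon 1 ∈ {a, b}; exon 2 ∈ {a, b, absent};
exon 6 ∈ {a, b}; exon 9 ∈ {a, b, c, d, a/c}. Absent exon 2 serialises as a
dash. The code describes protein-coding exons only; splice variation in the
3′ non-coding region of the mRNA is deliberately outside the model, so
"isoforms" here are protein isoforms.

Two structural rules are treated as grammar-level constraints:

* **Linkage rule** — exon 2 is skipped exactly when translation initiates at
  exon 1b. This holds for every catalogued mammalian isoform, so the parser
  enforces it by default (`check_linkage=False` relaxes it for hypothetical
  codes; the validator then still reports the violation under every policy).
* **Composite exon 9 `a/c`** — the ninth coding segment consists of the full
  exon-9a peptide followed by exactly five amino acids encoded by exon 9c.
  Only gene-3 isoforms (Tpm3.8, Tpm3.9) use it. Whether the five 9c residues
  precede or follow the 9a residues is not fully settled; this package
  implements the stated reading (9a first) and documents it as a choice.

### Dialect tolerance and canonical output

Catalogue typography varies: some formal names omit the space before the
parenthesised code (`Tpm3.1cy(b.-.a.d)`), tissue tags appear in either case,
and one entry (Tpm1.13) prints a fused-dash code `(b.-b.a)` with one dot
missing. The parser accepts all of these; the fused-dash form is normalised
to `b.-.b.a` with a `NomenclatureWarning` rather than silently. Canonical
output always renders lowercase tissue tags and a single space before `(`,
following the exhaustive catalogue tables rather than the one differently
typeset worked example. A registry changelog note: the source's prose worked
example assigns Tpm1.3 the code a.a.b.d and Tpm1.4 a.a.a.d, while the
catalogue tables state the reverse; the tables are adopted as authoritative
and the discrepancy is recorded here rather than silently resolved.

Errors carry stable kebab-case codes (`bad-prefix`, `gene-out-of-range`,
`bad-ordinal`, `unknown-tissue`, `bad-token-count`, `bad-exon-token`,
`linkage-violation`, `empty-input`) so callers and the CLI can react without
parsing messages.

## Gene models and policies

For each gene × species (human, mouse, rat) a model stores, per slot, three
variant tiers:

* `observed` — variants appearing in at least one catalogued isoform of the
  gene. Species-agnostic: absence of a documented accession in one species is
  not taken as absence of the splice form.
* `present` — genomically present variants. Derived from `observed` plus the
  documented per-gene adjustments (below).
* `expressed` — variants seen in an expressed protein.

The tiers are derived mechanically from the packaged registry and a small
packaged overrides file (`gene_model_overrides.yaml`), so newly catalogued
isoforms extend the models without code changes. The overrides encode the
three documented footnote facts: mammalian TPM2 lacks exon 1b entirely
(`tpm2-no-exon1b`); human TPM4 carries exon 9a genomically but no isoform
expressing it is reported (`tpm4-human-9a-unexpressed`); mouse and rat TPM4
lack exon 9a (`tpm4-rodent-no-9a`).

Validation and enumeration run under three policies: `genomic` (tier
`present`), `expressed`, and `registry` (alias `registry-observed`, tier
`observed`). The composite `a/c` is never stored in a tier: under the
registry policy it is admitted exactly where a catalogued isoform uses it
(gene 3); under `genomic`/`expressed` it is derived — admitted wherever both
9a and 9c are admissible. Enumeration is the Cartesian product over per-slot
admitted sets, split into the exon-1a branch (exon 2 retained) and exon-1b
branch (exon 2 absent), filtered through the validator, and returned in
deterministic slot-lexicographic order (each slot ordered by its alphabet).

**On headline isoform counts.** Summing the per-gene human spaces gives 46
codes under the registry-observed policy, 52 under `expressed` and 54 under
`genomic`. Published headline totals for "possible distinct isoforms" depend
on an unstated counting rule (plausible slot-set readings span roughly
42–48), so this package reports counts per documented policy and claims no
single number. Two modelling assumptions matter here: exon 9b is catalogued
only in gene 1 and is therefore excluded from the other genes' sets (its
genomic presence elsewhere is unknown — gene-structure diagrams are not part
of the packaged data), and the derived `a/c` composite inflates the
genomic/expressed spaces of genes whose 9a and 9c are both admissible.

## The registry

The packaged catalogue (`data/registry.tsv`) transcribes all 29 documented
isoforms with verbatim formal names (typography preserved), split legacy
aliases, and per-species accessions, where `none` is an explicit absent
marker (an isoform documented in no species would normally violate the
catalogue's own "documented at the nucleic acid level" premise; the two
composite-a/c records Tpm3.8/Tpm3.9 carry no accession in any species and are
the recorded exception). Alias columns in the source tables contain
run-together strings; splits here are discrete, and the one typographically
doubtful alias ("smooth α-Tm" on Tpm2.1) is marked low-confidence and
excluded from strict coverage checks, though it still resolves.

Alias resolution is exact-after-normalisation: NFKC, Greek letters unified
with spelled-out forms (α/alpha, β/beta, γ/gamma, δ/delta, κ/kappa), dash
variants unified, case folded, whitespace dropped. No fuzzy matching happens
in the library; the CLI offers an opt-in edit-distance-1 suggestion mode that
never auto-applies, because a nomenclature tool must not silently
approximate. Accession lookup is version-suffix tolerant (`NP_705935`
matches `NP_705935.1`).

`audit_registry` mechanises the catalogue's internal consistency: per-gene
exon-code uniqueness, the linkage rule on every code, validation of every
code under the registry policy, formal-name re-parsing, alias-index coverage
and the accession invariant. The packaged catalogue audits clean; the test
suite verifies that injected faults (duplicate code, linkage violation) are
caught.

## Sequence assembly

Assembly concatenates, in gene order: exon 1, exon 2 (when retained), the
invariant middle of the molecule, exon 6, exon 9. The invariant exons (3, 4,
5, 7, 8) are modelled as a single constant pseudo-slot per gene because the
four-letter code tracks only the variable exons and per-exon boundaries of
the constant region are not given; this is an explicit simplification that
preserves full-length realism without inventing boundaries. The composite
`a/c` ninth segment is the full 9a peptide plus the first five residues of
9c; a 9c segment shorter than five residues is an error.

Post-translational rules: with `apply_ptm` (default), the initiator
methionine is removed from exon-1b-encoded sequences only — exon-1a
initiators are left untouched, since the documented removal rule names only
1b-encoded sequences. N-acetylation of the N-terminal residue applies to all
isoforms and is recorded as an annotation; it never changes the primary
sequence.

### Synthetic fixtures

Real exon-peptide tables (e.g. transcribed from public sequence databases)
can be supplied as TSV (`gene, slot, variant, sequence`), but none is
required: `generate_fixture_peptides(gene, seed, segment_length_range)`
produces a deterministic synthetic peptide set with one segment per variant
genomically present in the gene model. Defaults: variable segments of 8–30
residues drawn uniformly from the 20 canonical amino acids (the real
alternative exons encode roughly that range), the constant middle pseudo-slot
four times longer (roughly its share of the ~284-residue molecule), every
exon-1 segment starting with Met, and all segments pairwise distinct so that
assembly is injective on selections. The minimum segment length must be ≥ 5
so the composite `a/c` rule is always exercisable.

What fixtures do and do not show: they exercise the combinatorial and
rule-application logic (concatenation order, composite splicing, Met removal,
length bookkeeping, I/O round-trips) exactly as real segments would, but they
are random strings — they say nothing about coiled-coil periodicity, actin
binding, or the actual residue content of any isoform. Tests passing on
fixtures certify the assembly machinery, not biological sequence identity;
verifying real sequences requires supplying real exon-peptide tables through
`read_peptides`.

Outputs are byte-stable given seed and inputs: peptide TSVs are written in a
fixed slot order, FASTA is wrapped at 60 columns with headers
`Tpm<g>.<n>|<formal name>|<species>|<accession-or-NA>`.

## Numerical and design choices

* Determinism everywhere: enumeration order is slot-lexicographic; alias hits
  are ranked systematic > common > alternate > accession, ties broken by gene
  then ordinal; fixture generation uses a seeded `random.Random`.
* Validation collects **all** violations, not just the first, so a report
  explains every reason a code is inadmissible.
* FASTA-header renaming matches aliases as whole tokens (no match across
  letters, digits or hyphens), longest alias first, so `Tm3` never matches
  inside `Tm3-1`; unresolvable headers pass through unchanged and are
  counted.
* Problem sizes in the test and acceptance runs — 1,000 random round-trip
  names, 36 model × policy enumeration comparisons (each over at most 60
  candidate codes), 200 seeded fixtures with three assembly probes each —
  exhaust the small combinatorial spaces involved or sample them far beyond
  the point of diminishing returns; the whole suite runs in seconds.

## Known limitations

* Protein-level only: no nucleotide sequences, genomic coordinates, intron
  structure or splice-site modelling; no non-mammalian gene models (chicken,
  frog and zebrafish exons appear only as the reason behind two footnote
  constraints).
* The catalogue is frozen at its 29 records; no live database queries are
  performed, and accessions are stored as published (September 2014 versions).
* Exon 9b outside gene 1 and the exact extent of 9a in the composite
  isoforms are modelled per the only actionable documentation, as described
  above.
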