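# Documented adjustments applied on top of the slot-variant sets derived
# mechanically from the packaged isoform registry.  Each entry names one
# constraint so validation reports can cite it.
#
# effect semantics: for the given gene/species, add or remove one variant
# from the named availability tiers ("present" = genomically present,
# "expressed" = seen in an expressed protein).
constraints:
  - id: tpm2-no-exon1b
    gene: 2
    species: [human, mouse, rat]
    slot: exon1
    variant: b
    add_to: []
    remove_from: [present, expressed]
    note: >-
      The TPM2 genes of human, mouse and rat lack exon 1b; the exon exists in
      chicken and zebrafish but not in mammals.
  - id: tpm4-human-9a-unexpressed
    gene: 4
    species: [human]
    slot: exon9
    variant: a
    add_to: [present]
    remove_from: [expressed]
    note: >-
      Human TPM4 carries exon 9a genomically, but no isoform expressing it has
      been reported.
  - id: tpm4-rodent-no-9a
    gene: 4
    species: [mouse, rat]
    slot: exon9
    variant: a
    add_to: []
    remove_from: [present, expressed]
    note: >-
      Mouse and rat TPM4 lack exon 9a (present in other vertebrates such as
      chicken, frog and zebrafish).
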