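"""Per-gene, per-species exon-variant availability and splicing constraints.

Four coding exons of the tropomyosin genes are alternatively used (exons 1, 2,
6 and 9).  A :class:`GeneModel` records, for one gene in one species, which
variant of each exon is genomically *present* and which is *expressed* in a
documented protein, plus named constraint rules derived from the catalogue's
footnotes:

* ``tpm2-no-exon1b`` — mammalian TPM2 lacks exon 1b entirely, so gene 2 has no
  short (low-molecular-weight) isoforms;
* ``tpm4-human-9a-unexpressed`` — human TPM4 carries exon 9a genomically but no
  isoform expressing it is reported;
* ``tpm4-rodent-no-9a`` — mouse and rat TPM4 lack exon 9a;
* ``exon2-linkage`` — exon 2 is skipped exactly when transcription initiates at
  exon 1b (the dash convention in the four-letter code).

Slot sets are *derived mechanically* from the packaged registry (the variants
observed in at least one catalogued isoform of the gene) and then adjusted by
the packaged footnote overrides, so newly catalogued isoforms extend the models
without code changes.

Validation policies:

``genomic``
    a variant is admissible if the exon form exists in the genome;
``expressed``
    admissible if some documented protein of this gene/species expresses it;
``registry`` (alias ``registry-observed``)
    admissible if it appears in at least one catalogued isoform of the gene
    (species-agnostic: absence of a documented accession in one species is not
    evidence the splice form does not exist there).

The composite exon-9 token ``a/c`` (9a plus five residues of 9c) is admitted
under ``registry`` policy only where a catalogued isoform uses it (gene 3), and
under ``genomic``/``expressed`` wherever both 9a and 9c are admissible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, List, Optional, Sequence, Tuple

import yaml

from .nomenclature import SLOT_ALPHABETS, SLOTS, ExonSelection

__all__ = [
    "Policy",
    "GeneModel",
    "ValidationReport",
    "build_gene_models",
    "default_gene_models",
    "validate_selection",
    "enumerate_selections",
    "diff_selections",
]

SPECIES = ("human", "mouse", "rat")
GENES = (1, 2, 3, 4)


class Policy(str, Enum):
    GENOMIC = "genomic"
    EXPRESSED = "expressed"
    REGISTRY = "registry"

    @classmethod
    def coerce(cls, value) -> "Policy":
        if isinstance(value, Policy):
            return value
        v = str(value).lower()
        if v == "registry-observed":
            v = "registry"
        return cls(v)


@dataclass(frozen=True)
class SlotAvailability:
    """Variant sets for one exon slot of one gene model."""

    present: frozenset
    expressed: frozenset
    observed: frozenset  # seen in >=1 catalogued isoform of the gene

    def for_policy(self, policy: Policy) -> frozenset:
        if policy is Policy.GENOMIC:
            return self.present
        if policy is Policy.EXPRESSED:
            return self.expressed
        return self.observed


@dataclass(frozen=True)
class GeneModel:
    gene: int
    species: str
    slots: dict  # slot name -> SlotAvailability
    constraints: Tuple[str, ...] = ()
    constraint_notes: dict = field(default_factory=dict)

    def slot_variants(self, slot: str, policy: Policy) -> frozenset:
        """Admissible variants for one slot under a policy, including the
        derived composite a/c for exon 9 where applicable."""
        base = self.slots[slot].for_policy(policy)
        if slot != "exon9":
            return base
        if policy is Policy.REGISTRY:
            return base  # composite appears iff catalogued
        if "a" in base and "c" in base:
            return base | {"a/c"}
        return base - {"a/c"}

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "species": self.species,
            "slots": {
                slot: {
                    "present": sorted(av.present, key=_variant_key(slot)),
                    "expressed": sorted(av.expressed, key=_variant_key(slot)),
                    "observed": sorted(av.observed, key=_variant_key(slot)),
                }
                for slot, av in self.slots.items()
            },
            "constraints": list(self.constraints),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        slots = {
            slot: SlotAvailability(
                present=frozenset(v["present"]),
                expressed=frozenset(v["expressed"]),
                observed=frozenset(v["observed"]),
            )
            for slot, v in d["slots"].items()
        }
        return cls(gene=int(d["gene"]), species=d["species"], slots=slots,
                   constraints=tuple(d.get("constraints", ())))


def _variant_key(slot):
    order = [v for v in SLOT_ALPHABETS[slot] if v is not None]

    def key(v):
        return order.index(v) if v in order else len(order)

    return key


@dataclass
class ValidationReport:
    valid: bool
    policy: Policy
    violations: List[Tuple[str, str]] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.valid

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "policy": self.policy.value,
            "violations": [
                {"rule": rule, "reason": reason} for rule, reason in self.violations
            ],
        }


def _load_overrides() -> list:
    text = resources.files("tpmnom.data").joinpath(
        "gene_model_overrides.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)["constraints"]


def build_gene_models(records: Iterable, overrides: Optional[list] = None) -> dict:
    """Derive all 4 genes x 3 species models from catalogued isoform records.

    ``records`` need only expose ``.gene`` (int) and ``.selection``
    (:class:`ExonSelection`); the packaged registry records do.  Returns a dict
    keyed by ``(gene, species)``.
    """
    if overrides is None:
        overrides = _load_overrides()
    observed = {g: {slot: set() for slot in SLOTS} for g in GENES}
    for rec in records:
        sel = rec.selection
        for slot in SLOTS:
            v = getattr(sel, slot)
            if v is not None:
                observed[rec.gene][slot].add(v)

    models = {}
    for gene in GENES:
        for species in SPECIES:
            slots = {}
            notes = {}
            applicable = [o for o in overrides
                          if o["gene"] == gene and species in o["species"]]
            for slot in SLOTS:
                present = set(observed[gene][slot])
                expressed = set(observed[gene][slot])
                # composite a/c is derived at query time, never stored in tiers
                present.discard("a/c")
                expressed.discard("a/c")
                for o in applicable:
                    if o["slot"] != slot:
                        continue
                    v = o["variant"]
                    if "present" in o.get("add_to", ()):
                        present.add(v)
                    if "expressed" in o.get("add_to", ()):
                        expressed.add(v)
                    if "present" in o.get("remove_from", ()):
                        present.discard(v)
                    if "expressed" in o.get("remove_from", ()):
                        expressed.discard(v)
                slots[slot] = SlotAvailability(
                    present=frozenset(present),
                    expressed=frozenset(expressed),
                    observed=frozenset(observed[gene][slot]),
                )
            for o in applicable:
                notes[o["id"]] = o.get("note", "")
            constraint_ids = tuple(o["id"] for o in applicable) + ("exon2-linkage",)
            models[(gene, species)] = GeneModel(
                gene=gene, species=species, slots=slots,
                constraints=constraint_ids, constraint_notes=notes,
            )
    return models


_DEFAULT_MODELS = None


def default_gene_models() -> dict:
    """Models derived from the packaged registry (cached)."""
    global _DEFAULT_MODELS
    if _DEFAULT_MODELS is None:
        from .registry import load_registry  # deferred: registry audits via us

        _DEFAULT_MODELS = build_gene_models(load_registry())
    return _DEFAULT_MODELS


def validate_selection(model: GeneModel, sel: ExonSelection,
                       policy="registry") -> ValidationReport:
    """Check one splice code against a gene model under a policy.

    All violations are collected, not just the first.  Named footnote
    constraints are cited where they explain a missing variant.
    """
    policy = Policy.coerce(policy)
    violations: List[Tuple[str, str]] = []

    for slot in SLOTS:
        v = getattr(sel, slot)
        if v is None:
            continue  # absent exon 2 is handled by the linkage rule
        allowed = model.slot_variants(slot, policy)
        if v in allowed:
            continue
        rule = f"{slot}-variant-unavailable"
        reason = (f"exon variant {slot[4:]}{v} is not admissible for gene "
                  f"TPM{model.gene} ({model.species}) under policy "
                  f"'{policy.value}'")
        if model.gene == 2 and slot == "exon1" and v == "b":
            rule = "tpm2-no-exon1b"
            reason = ("the TPM2 genes of human, mouse and rat do not contain "
                      "exon 1b, so no gene-2 isoform can use it")
        elif model.gene == 4 and slot == "exon9" and v == "a":
            if policy is Policy.EXPRESSED and "a" in model.slots["exon9"].present:
                rule = "tpm4-human-9a-unexpressed"
                reason = ("human TPM4 contains exon 9a but no isoform "
                          "expressing it has been reported")
            else:
                rule = "tpm4-rodent-no-9a"
                reason = (f"TPM4 of {model.species} does not contain exon 9a")
        elif slot == "exon9" and v == "a/c":
            rule = "composite-9ac-unavailable"
            reason = (f"composite exon 9 a/c requires both 9a and 9c to be "
                      f"admissible for gene TPM{model.gene} under policy "
                      f"'{policy.value}'" if policy is not Policy.REGISTRY else
                      f"no catalogued TPM{model.gene} isoform uses the "
                      f"composite exon 9 a/c")
        violations.append((rule, reason))

    if (sel.exon1 == "b") != (sel.exon2 is None):
        if sel.exon2 is None:
            reason = ("exon 2 marked absent (dash) but exon 1 is not variant "
                      "b: only exon-1b (short form) isoforms skip exon 2")
        else:
            reason = ("exon 1 variant b requires exon 2 to be absent (dash): "
                      "short-form isoforms splice directly past exon 2")
        violations.append(("exon2-linkage", reason))

    return ValidationReport(valid=not violations, policy=policy,
                            violations=violations)


def enumerate_selections(model: GeneModel, policy="registry") -> List[ExonSelection]:
    """All admissible splice codes for a model under a policy.

    The result is the Cartesian product over per-slot admissible variant sets,
    split into the exon-1a branch (exon 2 retained) and the exon-1b branch
    (exon 2 absent), filtered through :func:`validate_selection` under the same
    policy, in deterministic slot-lexicographic order.
    """
    policy = Policy.coerce(policy)
    e1 = model.slot_variants("exon1", policy)
    e2 = model.slot_variants("exon2", policy)
    e6 = model.slot_variants("exon6", policy)
    e9 = model.slot_variants("exon9", policy)

    candidates = []
    if "a" in e1:
        candidates.extend(
            ExonSelection("a", v2, v6, v9)
            for v2, v6, v9 in itertools.product(e2 - {None}, e6, e9)
        )
    if "b" in e1:
        candidates.extend(
            ExonSelection("b", None, v6, v9)
            for v6, v9 in itertools.product(e6, e9)
        )
    admitted = [s for s in candidates
                if validate_selection(model, s, policy).valid]
    return sorted(admitted, key=ExonSelection.sort_key)


def diff_selections(a: ExonSelection, b: ExonSelection) -> List[Tuple[str, object, object]]:
    """Slot-wise differences between two splice codes, in gene order.

    Returns an empty list iff the codes are identical; absent exon 2 is
    reported as ``None``.
    """
    return [
        (slot, getattr(a, slot), getattr(b, slot))
        for slot in SLOTS
        if getattr(a, slot) != getattr(b, slot)
    ]


def save_models(models: dict, path, fmt: str = "yaml") -> None:
    """Serialise gene models to the documented YAML/JSON schema."""
    payload = {"gene_models": [models[k].to_dict()
                               for k in sorted(models.keys())]}
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_models(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    payload = yaml.safe_load(text)
    models = {}
    for d in payload["gene_models"]:
        m = GeneModel.from_dict(d)
        models[(m.gene, m.species)] = m
    return models
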