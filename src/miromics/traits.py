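"""Cardiometabolic trait vocabulary and trait-group partition.

Eighteen traits are studied at the GWAS layer, partitioned into four groups
(anthropometric, glycemic, lipid, cardiovascular) that determine the extra
covariates used by the methylation and expression association stages.
Coronary heart disease (CHD) appears only as a prevalence outcome in the
expression layer; it is carried as an extra cardiovascular code outside the
18-trait GWAS vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

TRAIT_GROUPS: dict[str, tuple[str, ...]] = {
    "anthropometric": ("BMI", "WHR", "WC"),
    "glycemic": ("FG", "G2H", "FI", "Pro-Ins", "HbA1c", "HOMA-IR", "HOMA-B", "T2D"),
    "lipid": ("LDL", "HDL", "TC", "TG"),
    "cardiovascular": ("CAD", "DBP", "SBP"),
}

#: The 18 GWAS-layer trait codes.
TRAITS: tuple[str, ...] = tuple(t for group in TRAIT_GROUPS.values() for t in group)

#: Disease-prevalence traits modelled with a binomial (logistic) link.
BINARY_TRAITS: frozenset[str] = frozenset({"T2D", "CHD", "CAD"})

#: Expression-layer-only codes and the group they borrow covariates from.
EXTRA_TRAIT_GROUP: dict[str, str] = {"CHD": "cardiovascular"}


@dataclass(frozen=True)
class TraitGroup:
    """One of the four trait groups and its member trait codes."""

    group: str
    traits: tuple[str, ...]


def trait_group(trait: str) -> str:
    """Return the group label for a trait code.

    Raises ``KeyError`` for codes outside the vocabulary.
    """
    for group, members in TRAIT_GROUPS.items():
        if trait in members:
            return group
    if trait in EXTRA_TRAIT_GROUP:
        return EXTRA_TRAIT_GROUP[trait]
    raise KeyError(f"unknown trait code: {trait!r}")


def all_trait_groups() -> list[TraitGroup]:
    return [TraitGroup(g, m) for g, m in TRAIT_GROUPS.items()]
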