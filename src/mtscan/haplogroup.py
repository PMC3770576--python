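"""Rule-based candidate haplogroup naming for significant clades.

A SNP panel of ~138 sites is too sparse for full phylotree-style
classification, so clades are named by a three-step shared-variant
procedure:

1. collect the ALT variants shared by every haplotype in the clade;
2. look each variant up in a user-supplied phylotree-style rule table
   (variant -> haplogroups known to carry it, minus haplogroups flagged as
   back-mutated for it);
3. intersect: candidate haplogroups are those consistent with *all* shared
   variants.  A single candidate is a plausible assignment; a small set is a
   plausible set; an empty or uninformatively large set means the markers
   cannot distinguish haplogroups.

The rule table is a TSV snapshot supplied by the user (phylotree is
versioned and not bundled); conflicts between literature sources must be
resolved by the table's author, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genotype_io import Haplotype, VariantDef
from .network import Contrast
from .treescan import ScanReport

__all__ = [
    "HaplogroupRule",
    "HaplogroupCall",
    "read_rule_table",
    "shared_variants",
    "candidate_haplogroups",
    "classify_significant_clades",
    "write_call_report",
]


@dataclass(frozen=True)
class HaplogroupRule:
    variant: str  # m.<pos><REF>><ALT>
    carrier_haplogroups: frozenset[str]
    back_mutated_haplogroups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.carrier_haplogroups:
            raise ValueError(f"rule for {self.variant} has no carrier haplogroups")


@dataclass
class HaplogroupCall:
    clade_id: str
    shared_variants: tuple[str, ...]
    candidates: frozenset[str]
    status: str  # single_plausible | plausible_set | indistinguishable
    unknown_variants: tuple[str, ...] = ()
    branch_defining_variants: tuple[str, ...] = ()


def read_rule_table(path: str | Path) -> dict[str, HaplogroupRule]:
    """Read a TSV rule table: variant, carriers (;-separated), back_mutated."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"variant", "carrier_haplogroups"}
    if required - set(df.columns):
        raise ValueError(f"rule table {path} lacks columns {sorted(required)}")
    rules: dict[str, HaplogroupRule] = {}
    for _, row in df.iterrows():
        variant = row["variant"].strip()
        carriers = frozenset(
            h.strip() for h in row["carrier_haplogroups"].split(";") if h.strip()
        )
        back = frozenset(
            h.strip()
            for h in str(row.get("back_mutated_haplogroups", "")).split(";")
            if h.strip()
        )
        if variant in rules:
            raise ValueError(f"duplicate rule for {variant}")
        rules[variant] = HaplogroupRule(variant, carriers, back)
    return rules


def shared_variants(
    clade_haplotypes: Sequence[Haplotype], variants: Sequence[VariantDef]
) -> tuple[str, ...]:
    """ALT variants carried by every haplotype of the clade."""
    if not clade_haplotypes:
        raise ValueError("empty clade")
    shared = []
    for j, v in enumerate(variants):
        if all(h.alleles[j] == 1 for h in clade_haplotypes):
            shared.append(v.label)
    return tuple(shared)


def candidate_haplogroups(
    variant_set: Sequence[str],
    rules: Mapping[str, HaplogroupRule],
    clade_id: str = "",
    max_candidates: int = 10,
) -> HaplogroupCall:
    """Intersect carrier sets over the query variants.

    Haplogroups flagged back-mutated for any query variant are excluded.
    Unknown variants (absent from the table) are reported and prevent a
    ``single_plausible`` status, since they leave the assignment
    unconstrained.
    """
    known = [v for v in variant_set if v in rules]
    unknown = tuple(v for v in variant_set if v not in rules)
    if not known:
        return HaplogroupCall(
            clade_id=clade_id,
            shared_variants=tuple(variant_set),
            candidates=frozenset(),
            status="indistinguishable",
            unknown_variants=unknown,
        )
    candidates: frozenset[str] | None = None
    excluded: set[str] = set()
    for v in known:
        rule = rules[v]
        carriers = rule.carrier_haplogroups - rule.back_mutated_haplogroups
        excluded |= rule.back_mutated_haplogroups
        candidates = carriers if candidates is None else candidates & carriers
    candidates = frozenset(candidates - excluded)
    if not candidates or len(candidates) > max_candidates:
        status = "indistinguishable"
    elif len(candidates) == 1 and not unknown:
        status = "single_plausible"
    else:
        status = "plausible_set"
    return HaplogroupCall(
        clade_id=clade_id,
        shared_variants=tuple(variant_set),
        candidates=candidates,
        status=status,
        unknown_variants=unknown,
    )


def classify_significant_clades(
    scan_report: ScanReport,
    contrasts: Sequence[Contrast],
    haplotypes: Sequence[Haplotype],
    variants: Sequence[VariantDef],
    rules: Mapping[str, HaplogroupRule],
    max_candidates: int = 10,
) -> list[HaplogroupCall]:
    """One haplogroup call per significant contrast's clade side.

    The clade side is the smaller group (``side_a``); the branch-defining
    variants are the sites of the branches whose cut creates the contrast.
    """
    by_id = {c.contrast_id: c for c in contrasts}
    hap_by_id = {h.haplotype_id: h for h in haplotypes}
    calls: list[HaplogroupCall] = []
    for result in scan_report.significant:
        c = by_id[result.contrast_id]
        clade = [hap_by_id[h] for h in sorted(c.side_a)]
        sv = shared_variants(clade, variants)
        call = candidate_haplogroups(
            sv, rules, clade_id=result.contrast_id, max_candidates=max_candidates
        )
        call.branch_defining_variants = tuple(variants[s].label for s in c.sites)
        calls.append(call)
    return calls


def write_call_report(calls: Sequence[HaplogroupCall], path: str | Path) -> None:
    rows = [
        {
            "clade": c.clade_id,
            "status": c.status,
            "candidates": ";".join(sorted(c.candidates)),
            "shared_variants": ";".join(c.shared_variants),
            "branch_defining_variants": ";".join(c.branch_defining_variants),
            "unknown_variants": ";".join(c.unknown_variants),
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "clade",
            "status",
            "candidates",
            "shared_variants",
            "branch_defining_variants",
            "unknown_variants",
        ],
    ).to_csv(path, sep="\t", index=False)
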