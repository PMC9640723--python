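"""Somatic-variant filtering, LoF/GoF classification and prevalence ranking.

The filter keeps exonic variants passing at least one caller with an
alternative-allele read depth of at least 5 and a maximum population
frequency below 0.01; variants with no population-frequency annotation are
retained (treated as rare).  Loss-of-function (LoF) variants are
frameshifts, nonsense variants, or missense variants with REVEL > 0.5;
missense variants without a REVEL score are not LoF.  Gain-of-function
(GoF) variants are non-LoF variants documented in a COSMIC-style membership
set, occurring in a Tier-1 oncogene whose oncogenic mutation type (per a
Cancer Gene Census-style table) matches the variant's effect.

The COSMIC/CGC lookups ship as small synthetic stand-in TSVs (the real
releases are licensed); any table with the same columns can be substituted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import UNKNOWN, Effect, SomaticVariant

logger = logging.getLogger(__name__)

MIN_ALT_DEPTH = 5
MAX_POP_FREQ = 0.01
REVEL_PATHOGENIC = 0.5


@dataclass(frozen=True)
class FunctionalCall:
    variant: SomaticVariant
    is_lof: bool
    is_gof: bool
    rationale: str


def filter_somatic(variants: list[SomaticVariant],
                   log_exclusions: bool = False) -> list[SomaticVariant]:
    """Apply the somatic filter; keep iff exonic, >=1 caller pass, alt depth
    >= 5, and population frequency < 0.01 or unknown."""
    kept = []
    for v in variants:
        rule = exclusion_rule(v)
        if rule is None:
            kept.append(v)
        elif log_exclusions:
            logger.info("excluded %s:%d %s>%s (%s)", v.chrom, v.pos, v.ref, v.alt, rule)
    return kept


def exclusion_rule(v: SomaticVariant) -> str | None:
    """The first filter rule a variant fails, or None if it passes."""
    if not v.exonic:
        return "not exonic"
    if v.n_callers_pass < 1:
        return "no caller pass"
    if v.alt_depth < MIN_ALT_DEPTH:
        return f"alt depth {v.alt_depth} < {MIN_ALT_DEPTH}"
    if v.pop_freq_max != UNKNOWN and float(v.pop_freq_max) >= MAX_POP_FREQ:
        return f"PopFreqMax {v.pop_freq_max} >= {MAX_POP_FREQ}"
    return None


def classify_lof(variant: SomaticVariant) -> bool:
    """Frameshift, nonsense, or missense with REVEL strictly above 0.5."""
    if variant.effect in (Effect.FRAMESHIFT, Effect.NONSENSE):
        return True
    if variant.effect is Effect.MISSENSE and variant.revel != UNKNOWN:
        return float(variant.revel) > REVEL_PATHOGENIC
    return False


VariantKey = tuple[str, int, str, str]


def classify_gof(variant: SomaticVariant, cosmic_set: set[VariantKey],
                 cgc_table: dict[str, tuple[bool, set[Effect]]]) -> bool:
    """GoF iff: not LoF, in the COSMIC-style membership set, in a Tier-1
    oncogene, and matching that gene's oncogenic mutation type."""
    if cosmic_set is None or cgc_table is None:
        raise ValueError("classify_gof requires local COSMIC/CGC lookup tables")
    if classify_lof(variant):
        return False
    if variant.key() not in cosmic_set:
        return False
    entry = cgc_table.get(variant.gene)
    if entry is None:
        return False
    is_tier1, oncogenic_effects = entry
    return is_tier1 and variant.effect in oncogenic_effects


def classify_functional(variant: SomaticVariant, cosmic_set: set[VariantKey],
                        cgc_table: dict[str, tuple[bool, set[Effect]]]) -> FunctionalCall:
    lof = classify_lof(variant)
    gof = False if lof else classify_gof(variant, cosmic_set, cgc_table)
    if lof:
        if variant.effect is Effect.MISSENSE:
            rationale = f"missense with REVEL {variant.revel} > {REVEL_PATHOGENIC}"
        else:
            rationale = f"{variant.effect.value} is LoF"
    elif gof:
        rationale = "COSMIC-documented oncogenic mutation in Tier-1 oncogene"
    elif variant.effect is Effect.MISSENSE and variant.revel == UNKNOWN:
        rationale = "missense with unknown REVEL treated as non-LoF"
    else:
        rationale = "no rule fired"
    return FunctionalCall(variant, is_lof=lof, is_gof=gof, rationale=rationale)


# ---------------------------------------------------------------------------
# synthetic COSMIC/CGC stand-in lookups
# ---------------------------------------------------------------------------

def load_cosmic_set(path: str | Path | None = None) -> set[VariantKey]:
    """Load a COSMIC-style membership set (synthetic stand-in by default).

    TSV columns: gene, chromosome, position, ref, alt.  The key is
    (chromosome, position, ref, alt)."""
    if path is None:
        ref = resources.files("lohscape.data") / "cosmic_membership_synthetic.tsv"
        df = pd.read_csv(str(ref), sep="\t", dtype={"chromosome": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return {(str(r.chromosome), int(r.position), str(r.ref), str(r.alt))
            for r in df.itertuples()}


def load_cgc_table(path: str | Path | None = None) -> dict[str, tuple[bool, set[Effect]]]:
    """Load a Cancer Gene Census-style table (synthetic stand-in by default).

    TSV columns: gene, tier1_oncogene (0/1), oncogenic_effects
    (comma-separated effect classes)."""
    if path is None:
        ref = resources.files("lohscape.data") / "cgc_tier1_synthetic.tsv"
        df = pd.read_csv(str(ref), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    out: dict[str, tuple[bool, set[Effect]]] = {}
    for r in df.itertuples():
        eff_str = "" if pd.isna(r.oncogenic_effects) else str(r.oncogenic_effects)
        effects = {Effect(e.strip()) for e in eff_str.split(",") if e.strip()}
        out[str(r.gene)] = (bool(int(r.tier1_oncogene)), effects)
    return out


# ---------------------------------------------------------------------------
# cohort-level ranking and shared-variant report
# ---------------------------------------------------------------------------

def rank_genes_by_lof_prevalence(calls: pd.DataFrame, group: str) -> list[tuple[str, int]]:
    """Rank genes by the number of distinct patients with >=1 LoF call.

    ``calls`` has columns gene, patient_id, group, is_lof.  A gene counts at
    most once per patient within the group.  Descending score, ties broken
    lexicographically by gene symbol."""
    if calls.empty:
        return []
    sub = calls[(calls["group"] == group) & calls["is_lof"]]
    counts = sub.groupby("gene")["patient_id"].nunique()
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def shared_variant_report(variants_by_sample: dict[str, list[SomaticVariant]],
                          aaf_threshold: float = 0.05) -> pd.DataFrame:
    """Per-variant AAF matrix across one patient's tumors with sharing flags.

    A variant is ``shared`` when its AAF reaches the threshold in at least
    two tumors, ``private`` (to the named tumor) when it reaches it in
    exactly one, and ``below_threshold`` otherwise.  Variants absent from
    every tumor are not reported."""
    if len(variants_by_sample) < 2:
        raise ValueError("shared-variant report needs >=2 tumors")
    samples = sorted(variants_by_sample)
    aafs: dict[tuple, dict[str, float]] = {}
    genes: dict[tuple, str] = {}
    for sample, variants in variants_by_sample.items():
        for v in variants:
            aafs.setdefault(v.key(), {})[sample] = v.aaf
            genes[v.key()] = v.gene
    rows = []
    for key in sorted(aafs):
        per_sample = {s: aafs[key].get(s, 0.0) for s in samples}
        above = [s for s in samples if per_sample[s] >= aaf_threshold]
        if len(above) >= 2:
            status = "shared"
        elif len(above) == 1:
            status = f"private:{above[0]}"
        else:
            status = "below_threshold"
        row = {"chromosome": key[0], "position": key[1], "ref": key[2], "alt": key[3],
               "gene": genes[key], "status": status}
        row.update({f"aaf_{s}": per_sample[s] for s in samples})
        rows.append(row)
    return pd.DataFrame(rows)
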