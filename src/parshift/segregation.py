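"""Y-linked SNP identification from a genetic cross and wild accessions.

A Y-SNP is an allele that segregates strictly father -> sons (every
genotyped son carries it, no genotyped daughter does, the mother lacks it)
in the cross, the pattern expected for an allele residing on the
non-recombining Y. Because a cross cannot detect rare recombination, each
cross-defined Y-SNP is additionally screened in unrelated wild accessions:
male-specificity there (carried by >= k wild males and no wild females) is
the stronger indicator of genuine sex linkage, evaluated per species and
at two stringency levels (k = 2 and all genotyped males).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GeneAnnotation, GenotypeTable, Role, Sample, Sex, Species

log = logging.getLogger("parshift")

STATUS_ABSENT = "absent"
STATUS_GE_K_MALES = "ge_k_males"
STATUS_ALL_MALES = "all_males"
STATUS_IN_FEMALES = "present_in_females"

CATEGORY_LENIENT = "male-specific-lenient"
CATEGORY_STRICT = "male-specific-strict"
CATEGORY_IN_FEMALES = "in-females"
CATEGORY_ABSENT = "absent"


@dataclass
class YsnpCall:
    """One cross-defined Y-SNP with its wild-sample evidence."""

    gene_id: str
    site_index: int
    position: int  # 0-based reference position
    y_allele: str  # 'ref' or 'alt'
    cross_segregating: bool = True
    wild_status: dict[Species, str] = field(default_factory=dict)
    counts: dict[Species, tuple[int, int, int, int]] = field(default_factory=dict)
    # counts: (males with allele, males genotyped, females with allele, females genotyped)

    def category(self, species: Species) -> str:
        status = self.wild_status.get(species, STATUS_ABSENT)
        if status == STATUS_IN_FEMALES:
            return CATEGORY_IN_FEMALES
        if status == STATUS_ALL_MALES:
            return CATEGORY_STRICT
        if status == STATUS_GE_K_MALES:
            return CATEGORY_LENIENT
        return CATEGORY_ABSENT

    def male_specific(self, species: Species, strict: bool = False) -> bool:
        cat = self.category(species)
        if strict:
            return cat == CATEGORY_STRICT
        return cat in (CATEGORY_STRICT, CATEGORY_LENIENT)


def _carrier_matrix(table: GenotypeTable, allele: str) -> np.ndarray:
    """Boolean sites x samples: genotype carries >= 1 copy of the allele."""
    return table.carries_alt() if allele == "alt" else table.carries_ref()


def call_cross_ysnps(
    table: GenotypeTable,
    samples: list[Sample],
    min_sons: int = 10,
    min_daughters: int = 10,
) -> list[YsnpCall]:
    """Identify Y-SNPs from father -> son segregation in one family.

    A site is called with y_allele = a iff the father is heterozygous
    carrying a, the (genotyped) mother carries no copy of a, every
    genotyped son carries a and no genotyped daughter does, with at least
    ``min_sons``/``min_daughters`` genotyped progeny at the site. Sites
    with a missing parental genotype are uncallable. Sons homozygous for
    the putative Y allele are logged as soft violations (a true Y-SNP
    should be heterozygous in males) but still count as carriers, since
    allele dropout in RNA-seq makes hom/het calls unreliable.
    """
    by_id = {s.id: s for s in samples}
    father_idx = [j for j, sid in enumerate(table.sample_ids) if by_id[sid].role is Role.FATHER]
    mother_idx = [j for j, sid in enumerate(table.sample_ids) if by_id[sid].role is Role.MOTHER]
    son_idx = [j for j, sid in enumerate(table.sample_ids) if by_id[sid].role is Role.SON]
    dau_idx = [j for j, sid in enumerate(table.sample_ids) if by_id[sid].role is Role.DAUGHTER]
    if not father_idx:
        raise ValueError("no father in the sample sheet: cross segregation impossible")
    fj, mj = father_idx[0], mother_idx[0] if mother_idx else None

    calls: list[YsnpCall] = []
    G = table.geno
    for i in range(table.n_sites):
        if G[i, fj] != 1:  # father must be heterozygous
            continue
        if mj is None or G[i, mj] < 0:
            continue  # uncallable without the mother
        for allele in ("alt", "ref"):
            carriers = _carrier_matrix(table, allele)[i]
            if carriers[mj]:
                continue
            sons = [j for j in son_idx if G[i, j] >= 0]
            daughters = [j for j in dau_idx if G[i, j] >= 0]
            if len(sons) < min_sons or len(daughters) < min_daughters:
                continue
            if all(carriers[j] for j in sons) and not any(carriers[j] for j in daughters):
                hom_code = 2 if allele == "alt" else 0
                n_hom = sum(1 for j in sons if G[i, j] == hom_code)
                if n_hom:
                    log.info(
                        "%s pos %d: %d sons homozygous for the Y allele (soft violation)",
                        table.gene_id, int(table.positions[i]) + 1, n_hom,
                    )
                calls.append(
                    YsnpCall(
                        gene_id=table.gene_id,
                        site_index=i,
                        position=int(table.positions[i]),
                        y_allele=allele,
                    )
                )
                break  # at most one Y allele per biallelic site
    return calls


def wild_allele_status(
    table: GenotypeTable,
    samples: list[Sample],
    species: Species,
    site_index: int,
    allele: str,
    k: int = 2,
) -> tuple[str, tuple[int, int, int, int]]:
    """Male-specificity status of one allele among a species' wild samples.

    Returns (status, (males with allele, males genotyped, females with
    allele, females genotyped)). ``present_in_females`` overrides the
    male-specific statuses; ``all_males`` requires every genotyped wild
    male to carry the allele, ``ge_k_males`` at least k of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_id = {s.id: s for s in samples}
    male_idx = [
        j for j, sid in enumerate(table.sample_ids)
        if by_id[sid].species is species and by_id[sid].role is Role.WILD and by_id[sid].sex is Sex.M
    ]
    female_idx = [
        j for j, sid in enumerate(table.sample_ids)
        if by_id[sid].species is species and by_id[sid].role is Role.WILD and by_id[sid].sex is Sex.F
    ]
    carriers = _carrier_matrix(table, allele)[site_index]
    called = table.geno[site_index] >= 0
    males_typed = [j for j in male_idx if called[j]]
    females_typed = [j for j in female_idx if called[j]]
    if not female_idx:
        log.warning("%s: species %s has no wild females; no female screen possible", table.gene_id, species.value)
    m_with = sum(1 for j in males_typed if carriers[j])
    f_with = sum(1 for j in females_typed if carriers[j])
    counts = (m_with, len(males_typed), f_with, len(females_typed))
    if f_with > 0:
        return STATUS_IN_FEMALES, counts
    if males_typed and m_with == len(males_typed) and m_with >= 1:
        return STATUS_ALL_MALES, counts
    if m_with >= k:
        return STATUS_GE_K_MALES, counts
    return STATUS_ABSENT, counts


def classify_sharing(
    ysnps: list[YsnpCall],
    table: GenotypeTable,
    samples: list[Sample],
    k: int = 2,
) -> list[YsnpCall]:
    """Attach per-species wild statuses to cross-defined Y-SNPs.

    Species A and B use the full wild panels; the two-individual species C
    is classified by (present in the male, absent in the female) only. The
    calls are annotated in place and returned.
    """
    for call in ysnps:
        for species in (Species.A, Species.B, Species.C):
            status, counts = wild_allele_status(table, samples, species, call.site_index, call.y_allele, k=k)
            call.wild_status[species] = status
            call.counts[species] = counts
    return ysnps


def sharing_category(call: YsnpCall) -> str:
    """Cross-species sharing class of one Y-SNP.

    ``shared_ancient``: male-specific in both A and B (Y allele predating
    the A-B split); ``A_specific``: male-specific in A only (the signature
    of the recently sex-linked mid region); ``in_females_A``: present in
    wild A females despite Y-like cross segregation (mis-calling or rare
    X-Y recombination; reported, not adjudicated); ``cross_only``
    otherwise.
    """
    a_ms = call.male_specific(Species.A)
    b_ms = call.male_specific(Species.B)
    if call.wild_status.get(Species.A) == STATUS_IN_FEMALES:
        return "in_females_A"
    if a_ms and b_ms:
        return "shared_ancient"
    if a_ms:
        return "A_specific"
    return "cross_only"


SUMMARY_COLUMNS = [
    "n_cross",
    "A_lenient", "A_strict", "A_in_females",
    "B_lenient", "B_strict", "B_in_females",
    "C_male_only",
    "shared_ancient", "A_specific",
]


def gene_ysnp_summary(
    calls_by_gene: dict[str, list[YsnpCall]],
    annotations: dict[str, GeneAnnotation],
) -> pd.DataFrame:
    """Per-gene Y-SNP counts by category, ordered by map position.

    This is the machine-readable form of the per-gene bar chart: cross
    calls, wild male-specific counts per species and stringency, calls in
    wild A females, and the sharing classes.
    """
    order = sorted(annotations.values(), key=lambda a: a.map_pos_cM)
    rows = []
    for ann in order:
        calls = calls_by_gene.get(ann.gene_id, [])
        row = {col: 0 for col in SUMMARY_COLUMNS}
        row["gene_id"] = ann.gene_id
        row["map_pos_cM"] = ann.map_pos_cM
        row["n_cross"] = len(calls)
        for call in calls:
            for species, prefix in ((Species.A, "A"), (Species.B, "B")):
                cat = call.category(species)
                if cat in (CATEGORY_LENIENT, CATEGORY_STRICT):
                    row[f"{prefix}_lenient"] += 1
                if cat == CATEGORY_STRICT:
                    row[f"{prefix}_strict"] += 1
                if cat == CATEGORY_IN_FEMALES:
                    row[f"{prefix}_in_females"] += 1
            c_counts = call.counts.get(Species.C)
            if c_counts and c_counts[0] >= 1 and c_counts[2] == 0:
                row["C_male_only"] += 1
            cat = sharing_category(call)
            if cat in ("shared_ancient", "A_specific"):
                row[cat] += 1
        rows.append(row)
    df = pd.DataFrame(rows, columns=["gene_id", "map_pos_cM"] + SUMMARY_COLUMNS)
    return df.set_index("gene_id")
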