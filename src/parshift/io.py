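"""Readers and writers for the on-disk formats, plus genotype->haplotype adaptation.

Formats: sample sheet TSV, annotation TSV + reference FASTA sidecar, VCF
(v4.2, biallelic SNPs, GT field), fragments TSV, counts TSV. Internal
coordinates are 0-based half-open; VCF POS is 1-based at the interface.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    CountsTable,
    FragmentSet,
    GeneAnnotation,
    GenotypeTable,
    HaplotypeSet,
    Role,
    Sample,
    Sex,
    Species,
)

log = logging.getLogger("parshift")

SHEET_COLUMNS = ["id", "species", "sex", "role", "family"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def _parse_enum(cls, token: str, row: int, column: str):
    try:
        return cls(token)
    except ValueError:
        accepted = ", ".join(m.value for m in cls)
        raise FormatError(f"row {row}: unknown {column} {token!r} (accepted: {accepted})") from None


def read_sample_sheet(path: str | Path) -> list[Sample]:
    """Read a TSV sample sheet with columns id/species/sex/role/family."""
    samples: list[Sample] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(SHEET_COLUMNS)] != SHEET_COLUMNS:
            raise FormatError(f"sample sheet must start with columns {SHEET_COLUMNS}, got {header}")
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"row {i}: expected at least 4 fields")
            sid = parts[0]
            if sid in seen:
                raise FormatError(f"row {i}: duplicate sample id {sid!r}")
            seen.add(sid)
            species = _parse_enum(Species, parts[1], i, "species")
            sex = _parse_enum(Sex, parts[2], i, "sex")
            role = _parse_enum(Role, parts[3], i, "role")
            family = parts[4] if len(parts) > 4 and parts[4] else None
            try:
                samples.append(Sample(sid, species, sex, role, family))
            except ValueError as exc:
                raise FormatError(f"row {i}: {exc}") from None
    log.info("read %d samples from %s", len(samples), path)
    return samples


def write_sample_sheet(samples: list[Sample], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SHEET_COLUMNS) + "\n")
        for s in samples:
            fh.write(f"{s.id}\t{s.species.value}\t{s.sex.value}\t{s.role.value}\t{s.family or ''}\n")


def read_annotation(tsv_path: str | Path, fasta_path: str | Path) -> dict[str, GeneAnnotation]:
    """Read the gene annotation TSV (gene_id, map_pos_cM, cds_start, cds_end,
    frame; one row per CDS interval) with its reference-FASTA sidecar.

    Returns annotations keyed by gene id, in file order.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    rows: dict[str, dict] = {}
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "map_pos_cM", "cds_start", "cds_end", "frame"]
        if header != expected:
            raise FormatError(f"annotation header must be {expected}, got {header}")
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            gene, cm, s, e, frame = line.rstrip("\n").split("\t")
            entry = rows.setdefault(gene, {"cm": float(cm), "frame": int(frame), "cds": []})
            entry["cds"].append((int(s), int(e)))
    out: dict[str, GeneAnnotation] = {}
    for gene, entry in rows.items():
        if gene not in seqs:
            raise FormatError(f"gene {gene} has no sequence in {fasta_path}")
        out[gene] = GeneAnnotation(gene, entry["cm"], entry["cds"], entry["frame"], seqs[gene])
    log.info("read %d gene annotations from %s", len(out), tsv_path)
    return out


def write_annotation(annotations: dict[str, GeneAnnotation], tsv_path: str | Path, fasta_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("gene_id\tmap_pos_cM\tcds_start\tcds_end\tframe\n")
        for ann in annotations.values():
            for s, e in ann.cds_intervals:
                fh.write(f"{ann.gene_id}\t{ann.map_pos_cM:.6g}\t{s}\t{e}\t{ann.frame_offset}\n")
    records = [SeqRecord(Seq(a.ref_seq), id=a.gene_id, description="") for a in annotations.values()]
    SeqIO.write(records, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, annotations: dict[str, GeneAnnotation], samples: list[Sample] | None = None) -> list[GenotypeTable]:
    """Read a multi-sample VCF into one GenotypeTable per gene (CHROM).

    Multi-allelic and indel records are skipped (counted in the log); VCF
    1-based POS becomes a 0-based internal position. If ``samples`` is
    given, the VCF header must contain exactly those sample ids.
    """
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    if samples is not None:
        want = [s.id for s in samples]
        if set(want) != set(vcf_samples):
            raise FormatError("sample mismatch between VCF header and sample sheet")
    per_gene: dict[str, dict[str, list]] = {}
    skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            skipped += 1
            continue
        gene = rec.chrom
        if gene not in annotations:
            raise FormatError(f"VCF contig {gene} not present in annotation")
        store = per_gene.setdefault(gene, {"pos": [], "ref": [], "alt": [], "geno": []})
        store["pos"].append(rec.pos - 1)
        store["ref"].append(rec.ref)
        store["alt"].append(rec.alts[0])
        row = np.full(len(vcf_samples), -1, dtype=np.int8)
        for j, sid in enumerate(vcf_samples):
            gt = rec.samples[sid].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            row[j] = sum(gt)
        store["geno"].append(row)
    tables = []
    for gene, store in per_gene.items():
        tables.append(
            GenotypeTable(
                gene_id=gene,
                positions=np.array(store["pos"]),
                ref=np.array(store["ref"], dtype="S1"),
                alt=np.array(store["alt"], dtype="S1"),
                geno=np.array(store["geno"], dtype=np.int8),
                sample_ids=vcf_samples,
            )
        )
    log.info("read %d genes from %s (%d non-biallelic/indel records skipped)", len(tables), path, skipped)
    return tables


def count_skipped_records(path: str | Path) -> int:
    """Count VCF records that the reader would skip (multi-allelic / indel)."""
    vf = pysam.VariantFile(str(path))
    return sum(
        1
        for rec in vf
        if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1
    )


def write_vcf(tables: list[GenotypeTable], annotations: dict[str, GeneAnnotation], path: str | Path) -> None:
    """Write GenotypeTables as an uncompressed VCF v4.2 with GT fields."""
    header = pysam.VariantHeader()
    header.add_meta("source", "parshift")
    for ann in annotations.values():
        header.contigs.add(ann.gene_id, length=ann.length)
    header.formats.add("GT", 1, "String", "Genotype")
    sample_ids = tables[0].sample_ids
    for sid in sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for table in tables:
            if table.sample_ids != sample_ids:
                raise FormatError("all genotype tables must share one sample set")
            for i in range(table.n_sites):
                rec = out.new_record(
                    contig=table.gene_id,
                    start=int(table.positions[i]),
                    alleles=(table.ref[i].decode(), table.alt[i].decode()),
                )
                for j, sid in enumerate(sample_ids):
                    d = int(table.geno[i, j])
                    rec.samples[sid]["GT"] = (None, None) if d < 0 else ((0, 0), (0, 1), (1, 1))[d]
                    rec.samples[sid].phased = False
                out.write(rec)


# ---------------------------------------------------------------------------
# Fragments and counts
# ---------------------------------------------------------------------------

def write_fragments(fragment_sets: list[FragmentSet], path: str | Path) -> None:
    """Fragments TSV: sample, gene, comma-joined ``column:allele`` pairs."""
    with open(path, "w") as fh:
        fh.write("sample\tgene\tobservations\n")
        for fs in fragment_sets:
            for sample_id, obs in fs.fragments:
                joined = ",".join(f"{c}:{a}" for c, a in obs)
                fh.write(f"{sample_id}\t{fs.gene_id}\t{joined}\n")


def read_fragments(path: str | Path) -> dict[str, FragmentSet]:
    per_gene: dict[str, list] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sample", "gene", "observations"]:
            raise FormatError(f"unexpected fragments header {header}")
        for line in fh:
            if not line.strip():
                continue
            sample_id, gene, joined = line.rstrip("\n").split("\t")
            obs = []
            for item in joined.split(","):
                col, allele = item.split(":")
                obs.append((int(col), allele))
            per_gene.setdefault(gene, []).append((sample_id, obs))
    return {gene: FragmentSet(gene, frags) for gene, frags in per_gene.items()}


TOTALS_ROW = "__total_mapped__"


def write_counts(table: CountsTable, path: str | Path) -> None:
    """Counts TSV: gene rows with effective length, plus a totals row
    (``__total_mapped__``) holding per-sample total mapped reads."""
    with open(path, "w") as fh:
        fh.write("gene_id\teffective_length\t" + "\t".join(table.sample_ids) + "\n")
        totals = "\t".join(f"{t:.0f}" for t in table.total_mapped)
        fh.write(f"{TOTALS_ROW}\t0\t{totals}\n")
        for i, gene in enumerate(table.gene_ids):
            row = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{gene}\t{table.effective_length[i]:.1f}\t{row}\n")


def read_counts(path: str | Path) -> CountsTable:
    gene_ids: list[str] = []
    lengths: list[float] = []
    counts: list[list[int]] = []
    total_mapped = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "effective_length"]:
            raise FormatError("counts TSV must start with gene_id, effective_length columns")
        sample_ids = header[2:]
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == TOTALS_ROW:
                total_mapped = np.array([float(x) for x in parts[2:]])
                continue
            gene_ids.append(parts[0])
            lengths.append(float(parts[1]))
            counts.append([int(x) for x in parts[2:]])
    if total_mapped is None:
        raise FormatError("counts TSV lacks the totals row")
    return CountsTable(gene_ids, sample_ids, np.array(counts), np.array(lengths), total_mapped)


# ---------------------------------------------------------------------------
# Genotype -> haplotype adaptation
# ---------------------------------------------------------------------------

PHASE_POLICIES = ("true-phase", "y-aware", "random")


def genotypes_to_haplotypes(
    table: GenotypeTable,
    annotation: GeneAnnotation,
    samples: list[Sample],
    ysnps: dict[int, str] | None = None,
    policy: str = "y-aware",
    seed: int = 0,
    min_called_alleles: int = 4,
) -> HaplotypeSet:
    """Expand diploid genotypes into two pseudo-phased haplotypes per sample.

    Heterozygote phase is not observable in the real data, so this is an
    approximation used for haplotype statistics (Kst*, ZnS). Under the
    ``y-aware`` policy males get an X- and a Y-labelled copy and, at sites
    with a Y-SNP call (``ysnps`` maps 0-based position -> 'ref'/'alt'), the
    Y allele is placed on the Y copy; all remaining heterozygous sites are
    split by a seeded uniform draw. ``random`` ignores Y-SNP information.
    ``true-phase`` is only available for simulator output, which is already
    phased, so requesting it here is an error.

    ``min_called_alleles`` is recorded for downstream per-site filtering and
    kept here for interface symmetry.
    """
    if policy not in PHASE_POLICIES:
        raise ValueError(f"unknown phasing policy {policy!r}")
    if policy == "true-phase":
        raise ValueError("true-phase requested on unphased input: genotype tables carry no phase")
    ysnps = ysnps or {}
    rng = np.random.default_rng(seed)
    by_id = {s.id: s for s in samples}
    ref_arr = np.frombuffer(annotation.ref_seq.encode(), dtype="S1")
    hap_rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    copy_labels: list[str] = []
    for j, sid in enumerate(table.sample_ids):
        sample = by_id[sid]
        male = sample.sex is Sex.M
        labels = ("X", "Y") if (male and policy == "y-aware") else ("h1", "h2")
        h = np.tile(ref_arr, (2, 1)).copy()
        for i in range(table.n_sites):
            pos = table.positions[i]
            d = table.geno[i, j]
            if d < 0:
                h[:, pos] = b"N"
            elif d == 0:
                h[:, pos] = table.ref[i]
            elif d == 2:
                h[:, pos] = table.alt[i]
            else:
                y_allele = ysnps.get(int(pos))
                if male and policy == "y-aware" and y_allele is not None:
                    y_base = table.alt[i] if y_allele == "alt" else table.ref[i]
                    x_base = table.ref[i] if y_allele == "alt" else table.alt[i]
                    h[0, pos] = x_base
                    h[1, pos] = y_base
                else:
                    first = int(rng.integers(2))
                    h[first, pos] = table.ref[i]
                    h[1 - first, pos] = table.alt[i]
        hap_rows.extend([h[0], h[1]])
        sample_ids.extend([sid, sid])
        copy_labels.extend(labels)
    return HaplotypeSet(
        gene_id=table.gene_id,
        sample_ids=sample_ids,
        copy_labels=copy_labels,
        H=np.array(hap_rows, dtype="S1"),
        seg_positions=table.positions.copy(),
    )
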