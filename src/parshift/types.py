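"""Domain types shared across the pipeline.

Coordinates are 0-based half-open internally; the VCF interface is 1-based.
Genes play the role of VCF contigs (transcriptome-style reference).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

NUC_CODE = {b"A": 0, b"C": 1, b"G": 2, b"T": 3, b"N": -1}
CODE_NUC = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


class Species(str, enum.Enum):
    """Species groups: A and B are the recently diverged sister dioecious
    species (latifolia-like and dioica-like), C a more distant dioecious
    relative (diclinis-like), plus a non-dioecious outgroup."""

    A = "A"
    B = "B"
    C = "C"
    OUTGROUP = "outgroup"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"
    NA = "NA"


class Role(str, enum.Enum):
    FATHER = "father"
    MOTHER = "mother"
    SON = "son"
    DAUGHTER = "daughter"
    WILD = "wild"
    OUTGROUP = "outgroup"


CROSS_ROLES = {Role.FATHER, Role.MOTHER, Role.SON, Role.DAUGHTER}


@dataclass(frozen=True)
class Sample:
    """One sequenced accession.

    Cross members (father/mother/son/daughter) must carry a family id; the
    outgroup has no sex; sons are male and daughters female by definition.
    """

    id: str
    species: Species
    sex: Sex
    role: Role
    family: str | None = None

    def __post_init__(self) -> None:
        if self.role in CROSS_ROLES and not self.family:
            raise ValueError(f"sample {self.id}: role {self.role.value} requires a family id")
        if self.role is Role.OUTGROUP and self.sex is not Sex.NA:
            raise ValueError(f"sample {self.id}: outgroup samples have sex NA")
        if self.role is Role.SON and self.sex is not Sex.M:
            raise ValueError(f"sample {self.id}: sons must be M")
        if self.role is Role.DAUGHTER and self.sex is not Sex.F:
            raise ValueError(f"sample {self.id}: daughters must be F")
        if self.role is Role.FATHER and self.sex is not Sex.M:
            raise ValueError(f"sample {self.id}: father must be M")
        if self.role is Role.MOTHER and self.sex is not Sex.F:
            raise ValueError(f"sample {self.id}: mother must be F")


@dataclass
class GeneAnnotation:
    """Gene on the reference transcriptome with its genetic-map position.

    ``cds_intervals`` are 0-based half-open on ``ref_seq``; ``frame_offset``
    trims the first 0-2 bases of the concatenated CDS so that translation
    starts in frame.
    """

    gene_id: str
    map_pos_cM: float
    cds_intervals: list[tuple[int, int]]
    frame_offset: int
    ref_seq: str

    def __post_init__(self) -> None:
        if self.map_pos_cM < 0:
            raise ValueError(f"{self.gene_id}: map position must be >= 0")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"{self.gene_id}: frame offset must be 0, 1 or 2")
        ivals = sorted(self.cds_intervals)
        L = len(self.ref_seq)
        prev_end = 0
        for s, e in ivals:
            if s < prev_end or e <= s or e > L:
                raise ValueError(f"{self.gene_id}: CDS intervals must be sorted, disjoint and within the reference")
            prev_end = e
        self.cds_intervals = ivals

    @property
    def length(self) -> int:
        return len(self.ref_seq)

    def cds_positions(self) -> np.ndarray:
        """Reference positions of the concatenated CDS, in coding order."""
        parts = [np.arange(s, e) for s, e in self.cds_intervals]
        return np.concatenate(parts) if parts else np.empty(0, dtype=int)


@dataclass
class GenotypeTable:
    """Biallelic diploid genotypes for one gene.

    ``geno`` is a sites x samples int8 matrix of alt-allele dosages
    (0, 1, 2) with -1 for missing calls.
    """

    gene_id: str
    positions: np.ndarray  # 0-based, strictly increasing
    ref: np.ndarray  # dtype S1
    alt: np.ndarray  # dtype S1
    geno: np.ndarray  # int8, (n_sites, n_samples)
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"{self.gene_id}: site positions must be strictly increasing")
        if self.geno.shape != (len(self.positions), len(self.sample_ids)):
            raise ValueError(f"{self.gene_id}: genotype matrix shape mismatch")
        if np.any((self.geno < -1) | (self.geno > 2)):
            raise ValueError(f"{self.gene_id}: genotype dosages must be in {{-1,0,1,2}}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def carries_alt(self) -> np.ndarray:
        """Boolean sites x samples: genotype contains >=1 alt copy."""
        return self.geno >= 1

    def carries_ref(self) -> np.ndarray:
        """Boolean sites x samples: genotype contains >=1 ref copy."""
        return (self.geno >= 0) & (self.geno <= 1)


@dataclass
class HaplotypeSet:
    """Per-gene haplotypes as full-length nucleotide sequences.

    ``copy_labels`` mark the chromosome of origin where known: males carry
    one ``X`` and one ``Y`` copy (physical residence, meaningful for
    sex-linked genes), females and the outgroup carry ``h1``/``h2``.
    ``seg_positions`` indexes the segregating-site columns on the reference.
    """

    gene_id: str
    sample_ids: list[str]
    copy_labels: list[str]
    H: np.ndarray  # (n_hap, L) dtype S1
    seg_positions: np.ndarray

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype="S1")
        self.seg_positions = np.asarray(self.seg_positions, dtype=np.int64)
        if self.H.ndim != 2 or self.H.shape[0] != len(self.sample_ids):
            raise ValueError(f"{self.gene_id}: haplotype matrix shape mismatch")
        if len(self.copy_labels) != len(self.sample_ids):
            raise ValueError(f"{self.gene_id}: one copy label per haplotype required")

    @property
    def n_hap(self) -> int:
        return self.H.shape[0]

    @property
    def length(self) -> int:
        return self.H.shape[1]

    def rows_for(self, sample_id: str) -> list[int]:
        return [i for i, s in enumerate(self.sample_ids) if s == sample_id]

    def select(self, rows: list[int] | np.ndarray) -> "HaplotypeSet":
        rows = list(rows)
        return HaplotypeSet(
            gene_id=self.gene_id,
            sample_ids=[self.sample_ids[i] for i in rows],
            copy_labels=[self.copy_labels[i] for i in rows],
            H=self.H[rows],
            seg_positions=self.seg_positions,
        )

    def allele_codes(self, positions: np.ndarray) -> np.ndarray:
        """Integer-coded alleles (A,C,G,T -> 0..3, N/other -> -1) at the
        given reference positions, shape (n_hap, len(positions))."""
        sub = self.H[:, np.asarray(positions, dtype=np.int64)]
        out = np.full(sub.shape, -1, dtype=np.int8)
        for nuc, code in NUC_CODE.items():
            if code >= 0:
                out[sub == nuc] = code
        return out


@dataclass
class FragmentSet:
    """Read-pair fragments reduced to the segregating sites they cover.

    Each fragment is (sample_id, [(site_column, allele), ...]) where the
    allele is 'ref' or 'alt' and columns are strictly increasing indices
    into the gene's segregating-site list.
    """

    gene_id: str
    fragments: list[tuple[str, list[tuple[int, str]]]]

    def __post_init__(self) -> None:
        for sample_id, obs in self.fragments:
            cols = [c for c, _ in obs]
            if any(b <= a for a, b in zip(cols, cols[1:])):
                raise ValueError(f"{self.gene_id}/{sample_id}: fragment site columns must be strictly increasing")
            if any(a not in ("ref", "alt") for _, a in obs):
                raise ValueError(f"{self.gene_id}/{sample_id}: fragment alleles must be 'ref' or 'alt'")


@dataclass
class CountsTable:
    """Gene x sample read counts with per-gene effective length (bp) and
    per-sample total mapped reads (totals cover the whole transcriptome, so
    they are >= the column sums over the analysed genes)."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) int64
    effective_length: np.ndarray  # (n_genes,) float
    total_mapped: np.ndarray  # (n_samples,) float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.effective_length = np.asarray(self.effective_length, dtype=float)
        self.total_mapped = np.asarray(self.total_mapped, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts matrix shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("read counts must be non-negative")
        if np.any(self.total_mapped < self.counts.sum(axis=0)):
            raise ValueError("per-sample totals must cover the analysed genes")
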