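"""Codon degeneracy classification and 4-fold degenerate site selection.

Synonymous diversity and divergence throughout the pipeline are computed at
third codon positions that are 4-fold degenerate given the reference codon
context: any of the four nucleotides there encodes the same amino acid, so
these positions evolve approximately neutrally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .types import GeneAnnotation, HaplotypeSet

log = logging.getLogger("parshift")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
NUCS = "ACGT"

NON_CODING = -1


def _codon_aa(codon: str) -> str | None:
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table.get(codon)


def _position_degeneracy(codon: str, pos: int) -> int:
    """Number of nucleotides at ``pos`` (0..2) that leave the amino acid
    encoded by ``codon`` unchanged (1 = 0-fold, 4 = 4-fold)."""
    aa = _codon_aa(codon)
    count = 0
    for nuc in NUCS:
        alt = codon[:pos] + nuc + codon[pos + 1 :]
        if _codon_aa(alt) == aa:
            count += 1
    return count


@dataclass
class DegeneracyMask:
    """Per-reference-position degeneracy classes for one gene.

    ``degeneracy`` holds 1/2/3/4 inside the CDS and -1 (non-coding)
    elsewhere; ``codon_id``/``codon_pos`` link each coding position to its
    codon so that codon-context checks can find the partner positions.
    """

    gene_id: str
    degeneracy: np.ndarray  # int8, -1 non-coding else 1..4
    codon_id: np.ndarray  # int32, -1 outside codons
    codon_pos: np.ndarray  # int8, 0..2 or -1

    def __post_init__(self) -> None:
        self._codon_members: dict[int, np.ndarray] | None = None

    @property
    def fourfold_positions(self) -> np.ndarray:
        return np.flatnonzero(self.degeneracy == 4)

    def codon_members(self, cid: int) -> np.ndarray:
        """Reference positions belonging to codon ``cid`` (cached)."""
        if self._codon_members is None:
            members: dict[int, list[int]] = {}
            for pos, c in enumerate(self.codon_id):
                if c >= 0:
                    members.setdefault(int(c), []).append(pos)
            self._codon_members = {c: np.array(v) for c, v in members.items()}
        return self._codon_members[int(cid)]

    def to_bed(self) -> list[tuple[str, int, int, str]]:
        """BED-like rows (gene, start, end, class) merging runs of equal class."""
        rows = []
        cls = self.degeneracy
        start = 0
        for i in range(1, len(cls) + 1):
            if i == len(cls) or cls[i] != cls[start]:
                # degeneracy count 1 == "0-fold" in the conventional naming
                label = "non-coding" if cls[start] == NON_CODING else {1: "0-fold", 2: "2-fold", 3: "3-fold", 4: "4-fold"}[int(cls[start])]
                rows.append((self.gene_id, start, i, label))
                start = i
        return rows


def classify_degeneracy(annotation: GeneAnnotation) -> DegeneracyMask:
    """Classify every CDS position of a gene by synonymous degeneracy.

    Degeneracy is evaluated against the reference codon under the standard
    genetic code. An internal stop codon triggers a warning and everything
    from the stop onwards is left non-coding (likely mis-annotated frame).
    """
    L = annotation.length
    deg = np.full(L, NON_CODING, dtype=np.int8)
    codon_id = np.full(L, -1, dtype=np.int32)
    codon_pos = np.full(L, -1, dtype=np.int8)
    cds = annotation.cds_positions()[annotation.frame_offset :]
    n_codons = len(cds) // 3
    for c in range(n_codons):
        idx = cds[3 * c : 3 * c + 3]
        codon = "".join(annotation.ref_seq[p] for p in idx)
        if "N" in codon:
            continue
        if codon in _STANDARD.stop_codons and c < n_codons - 1:
            log.warning("%s: internal stop codon at codon %d; rest of CDS left non-coding", annotation.gene_id, c)
            break
        for k in range(3):
            deg[idx[k]] = _position_degeneracy(codon, k)
            codon_id[idx[k]] = c
            codon_pos[idx[k]] = k
    return DegeneracyMask(annotation.gene_id, deg, codon_id, codon_pos)


def fourfold_sites(mask: DegeneracyMask, haps: HaplotypeSet) -> tuple[np.ndarray, int]:
    """4-fold positions usable for synonymous statistics, and their count L4.

    A 4-fold third position is kept when the first two positions of its
    codon are monomorphic and ungapped (non-N) across all analysed
    haplotypes; a polymorphic or missing codon context would make the
    synonymous status allele-dependent, so such codons are excluded.
    Monomorphic 4-fold positions count towards L4 (the per-gene
    denominator) just like segregating ones.
    """
    cand = mask.fourfold_positions
    if len(cand) == 0:
        return cand, 0
    keep = np.ones(len(cand), dtype=bool)
    for i, pos in enumerate(cand):
        for p in mask.codon_members(mask.codon_id[pos]):
            if p == pos:
                continue
            col = haps.H[:, p]
            if np.any(col == b"N") or np.any(col != col[0]):
                keep[i] = False
                break
    kept = cand[keep]
    return kept, int(len(kept))
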