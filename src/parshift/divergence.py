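"""X/Y gametolog consensus reconstruction and silent divergence.

Y-SNP calls tag read fragments as X- or Y-derived; per-label majority
consensus over the tagged fragments reconstructs the two gametolog
sequences on shared reference coordinates, and Jukes-Cantor-corrected
mismatch fractions at 4-fold degenerate sites give the silent divergence
dS (X vs Y, or ingroup vs outgroup).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .degeneracy import DegeneracyMask
from .types import FragmentSet, GenotypeTable

log = logging.getLogger("parshift")


@dataclass
class TaggedFragments:
    """Fragments partitioned by gametolog origin.

    A fragment is Y-tagged if it carries the Y allele at >= 1 Y-SNP and the
    X allele at none, X-tagged in the mirror case; fragments carrying both
    are conflicts (discarded but counted), the rest are uninformative.
    """

    gene_id: str
    y_fragments: list[tuple[str, list[tuple[int, str]]]]
    x_fragments: list[tuple[str, list[tuple[int, str]]]]
    n_conflict: int
    n_uninformative: int


@dataclass
class ConsensusPair:
    gene_id: str
    x_seq: np.ndarray  # S1 array, reference length, N where uncalled
    y_seq: np.ndarray
    x_depth: np.ndarray
    y_depth: np.ndarray


@dataclass
class DivergenceRecord:
    gene_id: str
    ds_xy: float | None
    ds_outgroup: float | None
    sites_xy: int
    sites_outgroup: int


def tag_fragments(fragments: FragmentSet, ysnps: dict[int, str]) -> TaggedFragments:
    """Label fragments by the Y-SNP alleles they carry.

    ``ysnps`` maps fragment site columns to the Y allele ('ref'/'alt') at
    that column.
    """
    y_frags, x_frags = [], []
    n_conflict = n_uninf = 0
    for sample_id, obs in fragments.fragments:
        has_y = has_x = False
        for col, allele in obs:
            y_allele = ysnps.get(col)
            if y_allele is None:
                continue
            if allele == y_allele:
                has_y = True
            else:
                has_x = True
        if has_y and has_x:
            n_conflict += 1
        elif has_y:
            y_frags.append((sample_id, obs))
        elif has_x:
            x_frags.append((sample_id, obs))
        else:
            n_uninf += 1
    if n_conflict:
        log.info("%s: %d conflicting fragments discarded", fragments.gene_id, n_conflict)
    return TaggedFragments(fragments.gene_id, y_frags, x_frags, n_conflict, n_uninf)


def build_consensus(
    fragments: list[tuple[str, list[tuple[int, str]]]],
    table: GenotypeTable,
    ref_seq: str,
    min_depth: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-rule consensus sequence from one label's fragments.

    Non-segregating positions take the reference base. At each segregating
    column the majority allele among covering fragments is called; ties or
    depth below ``min_depth`` give N. Returns (sequence, per-column depth).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    L = len(ref_seq)
    seq = np.frombuffer(ref_seq.encode(), dtype="S1").copy()
    n_sites = table.n_sites
    ref_votes = np.zeros(n_sites, dtype=np.int64)
    alt_votes = np.zeros(n_sites, dtype=np.int64)
    for _, obs in fragments:
        for col, allele in obs:
            if allele == "alt":
                alt_votes[col] += 1
            else:
                ref_votes[col] += 1
    depth = ref_votes + alt_votes
    if not fragments:
        log.warning("%s: no fragments for consensus; emitting all-N at segregating sites", table.gene_id)
    for i in range(n_sites):
        pos = table.positions[i]
        if depth[i] < min_depth or ref_votes[i] == alt_votes[i]:
            seq[pos] = b"N"
        elif alt_votes[i] > ref_votes[i]:
            seq[pos] = table.alt[i]
        else:
            seq[pos] = table.ref[i]
    full_depth = np.zeros(L, dtype=np.int64)
    full_depth[table.positions] = depth
    return seq, full_depth


def major_allele_consensus(table: GenotypeTable, ref_seq: str, sample_indices: list[int]) -> np.ndarray:
    """Population consensus: the majority allele over called genotypes of
    the given samples at each segregating site, reference elsewhere.
    Ties and sites with no calls give N."""
    seq = np.frombuffer(ref_seq.encode(), dtype="S1").copy()
    G = table.geno[:, sample_indices]
    called = G >= 0
    alt_copies = np.where(called, G, 0).sum(axis=1)
    total_copies = 2 * called.sum(axis=1)
    ref_copies = total_copies - alt_copies
    for i in range(table.n_sites):
        pos = table.positions[i]
        if total_copies[i] == 0 or alt_copies[i] == ref_copies[i]:
            seq[pos] = b"N"
        else:
            seq[pos] = table.alt[i] if alt_copies[i] > ref_copies[i] else table.ref[i]
    return seq


def jc_distance(p_diff: float) -> float:
    """Jukes-Cantor corrected distance d = -(3/4) ln(1 - 4p/3)."""
    if not 0 <= p_diff < 0.75:
        raise ValueError(f"p_diff = {p_diff} outside [0, 0.75): saturated or invalid")
    return float(-0.75 * np.log1p(-4.0 * p_diff / 3.0))


def silent_divergence(
    seq_a: np.ndarray,
    seq_b: np.ndarray,
    mask: DegeneracyMask,
    min_sites: int = 10,
) -> tuple[float | None, int]:
    """Jukes-Cantor silent divergence at comparable 4-fold sites.

    A 4-fold position is comparable when it and its two codon partners are
    non-N in both sequences and the partners agree between the sequences
    (so the synonymous status holds for both). Returns (dS, n_sites), with
    dS None below ``min_sites`` comparable positions.
    """
    seq_a = np.asarray(seq_a, dtype="S1")
    seq_b = np.asarray(seq_b, dtype="S1")
    if seq_a.shape != seq_b.shape:
        raise ValueError("sequences must share coordinates")
    comparable = 0
    mismatches = 0
    for pos in mask.fourfold_positions:
        codon_positions = mask.codon_members(mask.codon_id[pos])
        ok = True
        for p in codon_positions:
            if seq_a[p] == b"N" or seq_b[p] == b"N":
                ok = False
                break
            if p != pos and seq_a[p] != seq_b[p]:
                ok = False
                break
        if not ok:
            continue
        comparable += 1
        if seq_a[pos] != seq_b[pos]:
            mismatches += 1
    if comparable < min_sites:
        return None, comparable
    return jc_distance(mismatches / comparable), comparable


def gametolog_divergence(
    fragments: FragmentSet,
    ysnps: dict[int, str],
    table: GenotypeTable,
    ref_seq: str,
    mask: DegeneracyMask,
    outgroup_indices: list[int] | None = None,
    ingroup_indices: list[int] | None = None,
    min_depth: int = 1,
    min_sites: int = 10,
) -> tuple[ConsensusPair, DivergenceRecord]:
    """Full per-gene divergence computation: tag fragments, build X and Y
    consensi, and measure silent X-Y and ingroup-outgroup divergence."""
    tagged = tag_fragments(fragments, ysnps)
    y_seq, y_depth = build_consensus(tagged.y_fragments, table, ref_seq, min_depth)
    x_seq, x_depth = build_consensus(tagged.x_fragments, table, ref_seq, min_depth)
    pair = ConsensusPair(table.gene_id, x_seq, y_seq, x_depth, y_depth)
    ds_xy, n_xy = silent_divergence(x_seq, y_seq, mask, min_sites)
    ds_out, n_out = None, 0
    if outgroup_indices and ingroup_indices:
        out_seq = major_allele_consensus(table, ref_seq, outgroup_indices)
        in_seq = major_allele_consensus(table, ref_seq, ingroup_indices)
        ds_out, n_out = silent_divergence(in_seq, out_seq, mask, min_sites)
    return pair, DivergenceRecord(table.gene_id, ds_xy, ds_out, n_xy, n_out)
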