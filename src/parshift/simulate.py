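"""Synthetic dataset generator with the statistical structure the pipeline assumes.

Haplotypes are drawn from a structured Kingman coalescent with
infinite-sites mutation: within each species, X- and Y-chromosome lineage
pools coalesce separately wherever a gene is sex-linked in that species,
and the pools merge backwards in time at the recombination-arrest age of
the gene's stratum; species pools merge at the species split times and an
outgroup lineage joins last. Three gene regimes emulate the map around a
recently shifted PAR boundary:

* ``left``  - pseudoautosomal in every dioecious species (one panmictic
  pool per species),
* ``mid``   - sex-linked in species A only, with a recent arrest age,
* ``right`` - anciently sex-linked in species A, B and C.

A two-generation genetic cross (father, mother, 20 sons, 32 daughters) is
simulated forward from the parental haplotypes with Haldane crossovers on
the genetic map; male meioses recombine only distal to species A's
suppression boundary, and the obligate X-Y crossover concentrates male
recombination in the PAR, which the male map models with an expansion
factor over the sex-averaged cM. Fragments (read pairs reduced to the
segregating sites they cover) and negative-binomial expression counts with
a Y-expression factor delta per regime complete the dataset, alongside a
ground-truth record of everything the generator knows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

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

REGIME_LEFT = "left"
REGIME_MID = "mid"
REGIME_RIGHT = "right"

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic datasets.

    Times are in units of 2N generations of the reference (autosomal)
    population; theta is the per-site population mutation rate 4*N*mu.
    The stratum ages t_mid/t_right and the outgroup split are calibrated
    so that the expected consensus-based silent X-Y divergence matches
    0.016 (mid) and 0.049 (right) and the outgroup silent divergence is
    ~0.10, reproducing the magnitudes the analysis is designed around.
    """

    # gene panel
    n_left: int = 20
    n_mid: int = 16
    n_right: int = 21
    gene_length: int = 1200  # full-CDS gene, frame 0, multiple of 3

    # population-genetic parameters
    theta: float = 0.015  # per site
    par_k: float = 1.0  # diversity multiplier for left (PAR) genes
    sigma_x: float = 0.75  # X-pool relative size where sex-linked
    sigma_y: float = 0.10  # Y-pool relative size where sex-linked

    # event times, units of 2N generations (calibrated; see class docstring)
    t_mid: float = 0.30  # arrest age of the mid stratum (species A only)
    t_ab: float = 1.0  # species A-B split
    t_c: float = 1.4  # split of species C from the A+B ancestor
    t_right: float = 1.62  # arrest age of the right (ancient) stratum
    t_out: float = 6.5  # outgroup split

    # genetic map (sex-averaged cM; right = proximal to the sex-determining region)
    left_lo_cM: float = 0.0
    left_hi_cM: float = 6.65
    boundary_a_cM: float = 7.0  # species A suppression boundary
    mid_lo_cM: float = 7.35
    mid_hi_cM: float = 12.6
    boundary_b_cM: float = 13.0  # species B/C suppression boundary
    right_lo_cM: float = 13.3
    right_hi_cM: float = 20.3
    sd_pos_cM: float = 25.0  # sex-determining locus
    male_par_expansion: float = 7.0  # male-map expansion of PAR distances

    # sample plan
    n_sons: int = 20
    n_daughters: int = 32
    n_wild_per_sex: int = 7  # per species A and B

    # fragments
    fragment_len_sites: int = 3
    fragment_coverage: int = 10
    fragment_error: float = 0.0

    # expression
    expr_base_mean: float = 200.0
    expr_log_sd: float = 0.7
    expr_dispersion: float = 0.3
    libsize_log_sd: float = 0.4
    total_scale: float = 50.0
    delta_mid: float = 0.75  # Y-allele expression factor, mid stratum
    delta_right: float = 0.5  # Y-allele expression factor, ancient stratum

    # calibrated expected consensus dS per sex-linked regime
    expected_ds_mid: float = 0.016
    expected_ds_right: float = 0.049

    @property
    def n_genes(self) -> int:
        return self.n_left + self.n_mid + self.n_right

    def regimes(self) -> list[str]:
        return [REGIME_LEFT] * self.n_left + [REGIME_MID] * self.n_mid + [REGIME_RIGHT] * self.n_right

    def map_positions(self) -> np.ndarray:
        return np.concatenate(
            [
                np.linspace(self.left_lo_cM, self.left_hi_cM, self.n_left),
                np.linspace(self.mid_lo_cM, self.mid_hi_cM, self.n_mid),
                np.linspace(self.right_lo_cM, self.right_hi_cM, self.n_right),
            ]
        )

    def gene_ids(self) -> list[str]:
        return [f"g{i + 1:03d}" for i in range(self.n_genes)]


def build_samples(config: SimulationConfig) -> list[Sample]:
    """The sample sheet of the emulated study design."""
    fam = "fam1"
    samples = [
        Sample("A_father", Species.A, Sex.M, Role.FATHER, fam),
        Sample("A_mother", Species.A, Sex.F, Role.MOTHER, fam),
    ]
    samples += [Sample(f"A_son{i + 1:02d}", Species.A, Sex.M, Role.SON, fam) for i in range(config.n_sons)]
    samples += [Sample(f"A_dau{i + 1:02d}", Species.A, Sex.F, Role.DAUGHTER, fam) for i in range(config.n_daughters)]
    for sp in (Species.A, Species.B):
        samples += [Sample(f"{sp.value}_wm{i + 1}", sp, Sex.M, Role.WILD) for i in range(config.n_wild_per_sex)]
        samples += [Sample(f"{sp.value}_wf{i + 1}", sp, Sex.F, Role.WILD) for i in range(config.n_wild_per_sex)]
    samples += [
        Sample("C_m1", Species.C, Sex.M, Role.WILD),
        Sample("C_f1", Species.C, Sex.F, Role.WILD),
        Sample("OUT_1", Species.OUTGROUP, Sex.NA, Role.OUTGROUP),
    ]
    return samples


def _founder_chromosomes(config: SimulationConfig) -> list[tuple[str, str, Species, Sex]]:
    """Coalescent leaves: two chromosome copies per founder individual
    (cross parents, wild accessions, outgroup); progeny are derived from
    the parents by meiosis, not sampled from the coalescent."""
    chroms: list[tuple[str, str, Species, Sex]] = [
        ("A_father", "X", Species.A, Sex.M),
        ("A_father", "Y", Species.A, Sex.M),
        ("A_mother", "h1", Species.A, Sex.F),
        ("A_mother", "h2", Species.A, Sex.F),
    ]
    for sp in (Species.A, Species.B):
        for i in range(config.n_wild_per_sex):
            chroms += [(f"{sp.value}_wm{i + 1}", "X", sp, Sex.M), (f"{sp.value}_wm{i + 1}", "Y", sp, Sex.M)]
        for i in range(config.n_wild_per_sex):
            chroms += [(f"{sp.value}_wf{i + 1}", "h1", sp, Sex.F), (f"{sp.value}_wf{i + 1}", "h2", sp, Sex.F)]
    chroms += [
        ("C_m1", "X", Species.C, Sex.M),
        ("C_m1", "Y", Species.C, Sex.M),
        ("C_f1", "h1", Species.C, Sex.F),
        ("C_f1", "h2", Species.C, Sex.F),
        ("OUT_1", "h1", Species.OUTGROUP, Sex.NA),
        ("OUT_1", "h2", Species.OUTGROUP, Sex.NA),
    ]
    return chroms


# ---------------------------------------------------------------------------
# Structured coalescent
# ---------------------------------------------------------------------------

@dataclass
class _Lineage:
    mask: np.ndarray  # bool over leaves
    birth: float


def _structured_coalescent(
    pool_of_leaf: list[str],
    pool_sizes: dict[str, float],
    events: list[tuple[float, list[tuple[list[str], str, float]]]],
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, float]]:
    """Simulate coalescence of labelled lineage pools.

    ``events`` are (time, merges) with merges = [(source pools, destination
    pool, destination relative size), ...]; pools coalesce internally at
    rate C(k,2)/sigma between events. Returns branches as (leaf mask,
    length) pairs covering the whole genealogy below the GMRCA.
    """
    n = len(pool_of_leaf)
    pools: dict[str, list[_Lineage]] = {}
    for leaf, pool in enumerate(pool_of_leaf):
        mask = np.zeros(n, dtype=bool)
        mask[leaf] = True
        pools.setdefault(pool, []).append(_Lineage(mask, 0.0))
    sizes = dict(pool_sizes)
    branches: list[tuple[np.ndarray, float]] = []
    t = 0.0

    def coalesce_until(t_stop: float) -> float:
        nonlocal t
        while True:
            rates = {p: len(ls) * (len(ls) - 1) / 2.0 / sizes[p] for p, ls in pools.items() if len(ls) >= 2}
            total = sum(rates.values())
            if total == 0:
                t = t_stop if np.isfinite(t_stop) else t
                return t
            wait = rng.exponential(1.0 / total)
            if t + wait > t_stop:
                t = t_stop
                return t
            t += wait
            pick = rng.uniform(0, total)
            for p, r in rates.items():
                pick -= r
                if pick <= 0:
                    break
            ls = pools[p]
            i, j = rng.choice(len(ls), size=2, replace=False)
            a, b = ls[i], ls[j]
            branches.append((a.mask, t - a.birth))
            branches.append((b.mask, t - b.birth))
            merged = _Lineage(a.mask | b.mask, t)
            pools[p] = [l for idx, l in enumerate(ls) if idx not in (i, j)] + [merged]

    for t_event, merges in sorted(events, key=lambda e: e[0]):
        coalesce_until(t_event)
        for sources, dest, sigma in merges:
            moved = []
            for src in sources:
                moved.extend(pools.pop(src, []))
            if moved:
                pools.setdefault(dest, []).extend(moved)
            sizes[dest] = sigma
    coalesce_until(np.inf)
    return branches


def _gene_pool_structure(config: SimulationConfig, regime: str, chroms) -> tuple[list[str], dict[str, float], list]:
    """Pool label per founder chromosome plus the merge-event schedule."""
    k = config.par_k if regime == REGIME_LEFT else 1.0
    sx, sy = config.sigma_x * k, config.sigma_y * k

    def y_pooled(sp: Species) -> bool:
        if regime == REGIME_RIGHT:
            return sp in (Species.A, Species.B, Species.C)
        if regime == REGIME_MID:
            return sp is Species.A
        return False

    labels = []
    for sample_id, copy, sp, sex in chroms:
        if sp is Species.OUTGROUP:
            labels.append("O")
        elif y_pooled(sp) and copy == "Y":
            labels.append(f"{sp.value}_Y")
        elif y_pooled(sp):
            labels.append(f"{sp.value}_X")
        else:
            labels.append(sp.value)
    sizes: dict[str, float] = {"O": 1.0}
    for sp in (Species.A, Species.B, Species.C):
        if y_pooled(sp):
            sizes[f"{sp.value}_X"] = sx
            sizes[f"{sp.value}_Y"] = sy
        else:
            sizes[sp.value] = 1.0 * k

    if regime == REGIME_LEFT:
        events = [
            (config.t_ab, [(["A", "B"], "AB", 1.0 * k)]),
            (config.t_c, [(["AB", "C"], "ABC", 1.0 * k)]),
            (config.t_out, [(["ABC", "O"], "ROOT", 1.0)]),
        ]
    elif regime == REGIME_MID:
        events = [
            (config.t_mid, [(["A_X", "A_Y"], "A", 1.0)]),
            (config.t_ab, [(["A", "B"], "AB", 1.0)]),
            (config.t_c, [(["AB", "C"], "ABC", 1.0)]),
            (config.t_out, [(["ABC", "O"], "ROOT", 1.0)]),
        ]
    else:
        events = [
            (config.t_ab, [(["A_X", "B_X"], "AB_X", sx), (["A_Y", "B_Y"], "AB_Y", sy)]),
            (config.t_c, [(["AB_X", "C_X"], "ABC_X", sx), (["AB_Y", "C_Y"], "ABC_Y", sy)]),
            (config.t_right, [(["ABC_X", "ABC_Y"], "ABC", 1.0)]),
            (config.t_out, [(["ABC", "O"], "ROOT", 1.0)]),
        ]
    return labels, sizes, events


@dataclass
class GeneSim:
    """One simulated gene: founder haplotypes plus bookkeeping."""

    gene_id: str
    regime: str
    annotation: GeneAnnotation
    haplotypes: HaplotypeSet  # founder chromosomes only
    chrom_index: dict[tuple[str, str], int]


def _random_cds(length: int, rng: np.random.Generator) -> str:
    codons = rng.choice(_SENSE_CODONS, size=length // 3)
    return "".join(codons)


def simulate_neutral_panmictic(n_hap: int, theta: float, L: int, seed_or_rng) -> np.ndarray:
    """Segregating-site matrix for one neutral panmictic coalescent gene.

    A single Kingman pool of ``n_hap`` lineages with infinite-sites
    mutation at per-site rate ``theta`` over ``L`` sites; returns an
    (n_hap x S) int8 matrix of 0/1 (ancestral/derived) alleles. Used for
    null calibration of the summary statistics.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    branches = _structured_coalescent(["P"] * n_hap, {"P": 1.0}, [], rng)
    cols = []
    rate = 0.5 * theta * L
    for mask, length in branches:
        for _ in range(rng.poisson(rate * length)):
            cols.append(mask.astype(np.int8))
    if not cols:
        return np.zeros((n_hap, 0), dtype=np.int8)
    return np.array(cols, dtype=np.int8).T


def simulate_gene(config: SimulationConfig, regime: str, seed_or_rng, gene_id: str = "g001", map_pos: float = 0.0) -> GeneSim:
    """Simulate founder haplotypes for one gene under a regime.

    Deterministic for a fixed seed. The gene is an all-CDS sequence in
    frame 0; infinite-sites mutations are placed Poisson((theta/2) *
    branch length * L) at uniform, previously unused positions.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    chroms = _founder_chromosomes(config)
    labels, sizes, events = _gene_pool_structure(config, regime, chroms)
    branches = _structured_coalescent(labels, sizes, events, rng)

    L = config.gene_length
    ref_seq = _random_cds(L, rng)
    ref_arr = np.frombuffer(ref_seq.encode(), dtype="S1")
    H = np.tile(ref_arr, (len(chroms), 1)).copy()
    used: set[int] = set()
    seg_positions: list[int] = []
    rate = 0.5 * config.theta * L
    for mask, length in branches:
        n_mut = rng.poisson(rate * length)
        for _ in range(n_mut):
            pos = int(rng.integers(L))
            while pos in used:
                pos = int(rng.integers(L))
            used.add(pos)
            ref_base = ref_seq[pos]
            alt_base = "ACGT"[(["A", "C", "G", "T"].index(ref_base) + int(rng.integers(1, 4))) % 4]
            H[mask, pos] = alt_base.encode()
            seg_positions.append(pos)
    seg_positions = sorted(seg_positions)
    ann = GeneAnnotation(gene_id, map_pos, [(0, L)], 0, ref_seq)
    haps = HaplotypeSet(
        gene_id=gene_id,
        sample_ids=[c[0] for c in chroms],
        copy_labels=[c[1] for c in chroms],
        H=H,
        seg_positions=np.array(seg_positions, dtype=np.int64),
    )
    chrom_index = {(c[0], c[1]): i for i, c in enumerate(chroms)}
    return GeneSim(gene_id, regime, ann, haps, chrom_index)


# ---------------------------------------------------------------------------
# Cross simulation
# ---------------------------------------------------------------------------

def _haldane_switch_prob(d_cM: float) -> float:
    """Probability of an odd number of crossovers over d centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))


def _male_distance(config: SimulationConfig, a: float, b: float) -> float:
    """Male-meiosis effective distance between map points a < b: only the
    segment distal to the species-A suppression boundary recombines, with
    the PAR expansion factor applied."""
    lo, hi = min(a, b), max(a, b)
    par_len = max(0.0, min(hi, config.boundary_a_cM) - min(lo, config.boundary_a_cM))
    return par_len * config.male_par_expansion


def simulate_cross(
    config: SimulationConfig,
    gene_sims: list[GeneSim],
    rng: np.random.Generator,
) -> tuple[dict[str, dict[str, tuple[int, int]]], dict[str, dict[str, str]]]:
    """Transmit parental haplotypes to the 52 progeny.

    Returns (progeny_rows, paternal_phase): per progeny, per gene, the
    (paternal row, maternal row) founder-haplotype indices, and the
    paternal phase ('X'/'Y') used for the truth record. Crossovers follow
    the Haldane model along the map; male meioses recombine only in the
    PAR (distal to the suppression boundary) and sons receive the gamete
    carrying the proximal sex-determining end.
    """
    order = np.argsort([-g.annotation.map_pos_cM for g in gene_sims])  # proximal -> distal
    progeny = [f"A_son{i + 1:02d}" for i in range(config.n_sons)]
    progeny += [f"A_dau{i + 1:02d}" for i in range(config.n_daughters)]
    rows: dict[str, dict[str, tuple[int, int]]] = {p: {} for p in progeny}
    phases: dict[str, dict[str, str]] = {p: {} for p in progeny}
    for p in progeny:
        is_son = p.startswith("A_son")
        pat_phase = "Y" if is_son else "X"  # phase at the sex-determining locus
        mat_phase = "h1" if rng.integers(2) == 0 else "h2"
        prev_pos = config.sd_pos_cM
        for idx in order:
            g = gene_sims[idx]
            pos = g.annotation.map_pos_cM
            d_male = _male_distance(config, pos, prev_pos)
            d_female = abs(prev_pos - pos)
            if rng.uniform() < _haldane_switch_prob(d_male):
                pat_phase = "X" if pat_phase == "Y" else "Y"
            if rng.uniform() < _haldane_switch_prob(d_female):
                mat_phase = "h1" if mat_phase == "h2" else "h2"
            pat_row = g.chrom_index[("A_father", pat_phase)]
            mat_row = g.chrom_index[("A_mother", mat_phase)]
            rows[p][g.gene_id] = (pat_row, mat_row)
            phases[p][g.gene_id] = pat_phase
            prev_pos = pos
    return rows, phases


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset."""

    regimes: dict[str, str]
    boundary_a_cut: int  # index of the first sex-linked gene in species A
    boundary_b_cut: int
    theta: float
    par_k: float
    expected_ds: dict[str, float]
    father_xy_diffs: dict[str, dict[int, str]]  # gene -> {0-based pos: y allele 'ref'/'alt'}
    paternal_phase: dict[str, dict[str, str]]  # progeny -> gene -> 'X'/'Y'

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["father_xy_diffs"] = {
            g: {str(pos): a for pos, a in d.items()} for g, d in self.father_xy_diffs.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["father_xy_diffs"] = {
            g: {int(pos): a for pos, a in d.items()} for g, d in payload["father_xy_diffs"].items()
        }
        return cls(**payload)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    samples: list[Sample]
    annotations: dict[str, GeneAnnotation]
    tables: list[GenotypeTable]
    haplotypes: dict[str, HaplotypeSet]  # true-phase, all samples
    fragments: dict[str, FragmentSet]
    counts: CountsTable | None
    truth: SyntheticTruth


def _genotype_from_rows(H: np.ndarray, row_pairs: list[tuple[int, int]], positions: np.ndarray,
                        ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Dosage matrix (sites x individuals) from haplotype row pairs."""
    geno = np.zeros((len(positions), len(row_pairs)), dtype=np.int8)
    alt_col = alt[:, None]
    for j, (r1, r2) in enumerate(row_pairs):
        sub = H[[r1, r2]][:, positions]
        geno[:, j] = (sub.T == alt_col).sum(axis=1)
    return geno


def _emit_fragments(
    config: SimulationConfig,
    gene: GeneSim,
    hap_rows: dict[str, list[int]],
    table: GenotypeTable,
    rng: np.random.Generator,
) -> FragmentSet:
    """Fragments for male samples: per haplotype, per coverage pass, runs
    of ``fragment_len_sites`` adjacent segregating columns at a random
    tiling offset; alleles optionally flipped at the error rate."""
    n_sites = table.n_sites
    alt = table.alt
    frags: list[tuple[str, list[tuple[int, str]]]] = []
    flen = config.fragment_len_sites

    def tiling(is_alt: np.ndarray, offset: int, with_error: bool) -> list[list[tuple[int, str]]]:
        out = []
        start = offset
        while start < n_sites:
            obs = []
            for c in range(start, min(start + flen, n_sites)):
                a = "alt" if is_alt[c] else "ref"
                if with_error and rng.uniform() < config.fragment_error:
                    a = "ref" if a == "alt" else "alt"
                obs.append((c, a))
            if obs:
                out.append(obs)
            start += flen
        return out

    with_error = config.fragment_error > 0
    for sample_id, rows in hap_rows.items():
        for row in rows:
            alleles = gene.haplotypes.H[row][table.positions]
            is_alt = alleles == alt
            # error-free fragments repeat across passes: precompute per offset
            cache: dict[int, list] = {}
            for _ in range(config.fragment_coverage):
                offset = int(rng.integers(flen)) if n_sites > flen else 0
                if with_error:
                    pieces = tiling(is_alt, offset, True)
                else:
                    if offset not in cache:
                        cache[offset] = tiling(is_alt, offset, False)
                    pieces = cache[offset]
                frags.extend((sample_id, obs) for obs in pieces)
    return FragmentSet(gene.gene_id, frags)


def _emit_counts(
    config: SimulationConfig,
    samples: list[Sample],
    regimes: dict[str, str],
    rng: np.random.Generator,
) -> CountsTable:
    """Negative-binomial counts: male expression at a gene sex-linked in
    the sample's species is (1 + delta)/2 of the female mean.

    Per-sample totals model the whole transcriptome (library factor x a
    sex-independent constant), not the analysed genes' column sums: the
    analysed panel is a sliver of the real library, so its sex-linked
    composition must not leak into the FPKM denominator.
    """
    gene_ids = list(regimes)
    lib = np.exp(rng.normal(0.0, config.libsize_log_sd, size=len(samples)))
    r = 1.0 / config.expr_dispersion
    counts = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    base_means = np.zeros(len(gene_ids))
    for i, gene in enumerate(gene_ids):
        base = float(np.exp(rng.normal(np.log(config.expr_base_mean), config.expr_log_sd)))
        base_means[i] = base
        regime = regimes[gene]
        for j, s in enumerate(samples):
            delta = 1.0
            if s.sex is Sex.M:
                linked_in_species = (
                    regime == REGIME_RIGHT and s.species in (Species.A, Species.B, Species.C)
                ) or (regime == REGIME_MID and s.species is Species.A)
                if linked_in_species:
                    delta = config.delta_mid if regime == REGIME_MID else config.delta_right
            mean = base * lib[j] * (1.0 + delta) / 2.0 if s.sex is Sex.M else base * lib[j]
            p = r / (r + mean)
            counts[i, j] = rng.negative_binomial(r, p)
    totals = np.maximum(base_means.sum() * lib * config.total_scale, counts.sum(axis=0))
    return CountsTable(gene_ids, [s.id for s in samples], counts,
                       np.full(len(gene_ids), float(config.gene_length)), totals)


def simulate_dataset(
    config: SimulationConfig,
    seed: int,
    with_fragments: bool = True,
    with_counts: bool = True,
) -> SyntheticDataset:
    """Generate a complete in-memory dataset (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    samples = build_samples(config)
    regimes = config.regimes()
    map_pos = config.map_positions()
    gene_ids = config.gene_ids()

    gene_sims = [
        simulate_gene(config, regimes[i], rng, gene_id=gene_ids[i], map_pos=float(map_pos[i]))
        for i in range(config.n_genes)
    ]
    progeny_rows, paternal_phase = simulate_cross(config, gene_sims, rng)

    annotations = {g.gene_id: g.annotation for g in gene_sims}
    tables: list[GenotypeTable] = []
    haplotypes: dict[str, HaplotypeSet] = {}
    fragments: dict[str, FragmentSet] = {}
    father_xy_diffs: dict[str, dict[int, str]] = {}
    sample_ids = [s.id for s in samples]

    for g in gene_sims:
        H = g.haplotypes.H
        positions = g.haplotypes.seg_positions
        ref_arr = np.frombuffer(g.annotation.ref_seq.encode(), dtype="S1")
        ref = ref_arr[positions]
        # the single derived allele per infinite-sites position
        alt = np.empty(len(positions), dtype="S1")
        for k, pos in enumerate(positions):
            col = H[:, pos]
            non_ref = col[col != ref[k]]
            alt[k] = non_ref[0] if len(non_ref) else b"N"

        # per-sample haplotype row pairs (founders direct, progeny via meiosis)
        row_pairs: list[tuple[int, int]] = []
        hap_rows_all: list[np.ndarray] = []
        hap_sample_ids: list[str] = []
        hap_copy_labels: list[str] = []
        for s in samples:
            if s.role in (Role.SON, Role.DAUGHTER):
                pat, mat = progeny_rows[s.id][g.gene_id]
                pair = (pat, mat)
                labels = ("Y", "X") if s.role is Role.SON else ("h2", "h1")
            else:
                rows = [g.chrom_index[key] for key in g.chrom_index if key[0] == s.id]
                pair = (rows[0], rows[1])
                labels = (g.haplotypes.copy_labels[rows[0]], g.haplotypes.copy_labels[rows[1]])
            row_pairs.append(pair)
            hap_rows_all.extend([H[pair[0]], H[pair[1]]])
            hap_sample_ids.extend([s.id, s.id])
            hap_copy_labels.extend(labels)

        geno = _genotype_from_rows(H, row_pairs, positions, ref, alt)
        # keep only sites segregating among the emitted genotypes
        seg = ~np.all(geno == geno[:, [0]], axis=1) | (geno[:, 0] == 1)
        table = GenotypeTable(
            gene_id=g.gene_id,
            positions=positions[seg],
            ref=ref[seg],
            alt=alt[seg],
            geno=geno[seg],
            sample_ids=sample_ids,
        )
        tables.append(table)
        haplotypes[g.gene_id] = HaplotypeSet(
            gene_id=g.gene_id,
            sample_ids=hap_sample_ids,
            copy_labels=hap_copy_labels,
            H=np.array(hap_rows_all, dtype="S1"),
            seg_positions=positions[seg],
        )
        fx = g.chrom_index[("A_father", "X")]
        fy = g.chrom_index[("A_father", "Y")]
        diffs = {}
        for k, pos in enumerate(table.positions):
            bx, by = H[fx, pos], H[fy, pos]
            if bx != by:
                diffs[int(pos)] = "alt" if by == table.alt[k] else "ref"
        father_xy_diffs[g.gene_id] = diffs
        if with_fragments:
            # fragments are used for X/Y consensus reconstruction, a
            # species-A male analysis (father + wild A males)
            male_rows = {
                s.id: [g.chrom_index[(s.id, "X")], g.chrom_index[(s.id, "Y")]]
                for s in samples
                if s.sex is Sex.M and s.species is Species.A and s.role in (Role.FATHER, Role.WILD)
            }
            fragments[g.gene_id] = _emit_fragments(config, g, male_rows, table, rng)

    regime_map = dict(zip(gene_ids, regimes))
    counts = _emit_counts(config, samples, regime_map, rng) if with_counts else None
    truth = SyntheticTruth(
        regimes=regime_map,
        boundary_a_cut=config.n_left,
        boundary_b_cut=config.n_left + config.n_mid,
        theta=config.theta,
        par_k=config.par_k,
        expected_ds={REGIME_MID: config.expected_ds_mid, REGIME_RIGHT: config.expected_ds_right},
        father_xy_diffs=father_xy_diffs,
        paternal_phase=paternal_phase,
    )
    return SyntheticDataset(config, samples, annotations, tables, haplotypes, fragments, counts, truth)


def emit_dataset(config: SimulationConfig, seed: int, outdir: str | Path) -> SyntheticDataset:
    """Write a complete dataset to ``outdir`` (VCF, FASTA, sample sheet,
    annotation, fragments, counts, truth JSON). A marker file flags a
    partial write and is removed on success."""
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "_INCOMPLETE"
    marker.write_text("dataset emission in progress\n")
    ds = simulate_dataset(config, seed)
    pio.write_sample_sheet(ds.samples, outdir / "samples.tsv")
    pio.write_annotation(ds.annotations, outdir / "annotation.tsv", outdir / "reference.fasta")
    pio.write_vcf(ds.tables, ds.annotations, outdir / "variants.vcf")
    pio.write_fragments(list(ds.fragments.values()), outdir / "fragments.tsv")
    pio.write_counts(ds.counts, outdir / "counts.tsv")
    ds.truth.to_json(outdir / "truth.json")
    (outdir / "config.json").write_text(json.dumps(dataclasses.asdict(ds.config), indent=1))
    marker.unlink()
    log.info("dataset with %d genes / %d samples written to %s", config.n_genes, len(ds.samples), outdir)
    return ds
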