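"""End-to-end orchestration: Y-SNPs -> regions -> statistics -> divergence
-> HKA -> expression -> report tables.

Every stage is a pure function of its inputs plus the master seed; stage
outputs are pandas DataFrames that can be written as TSVs, so a report can
be rebuilt byte-identically from the stage files. The synthetic dataset
carries true haplotype phase; real genotype input is pseudo-phased with
the y-aware policy.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import popgen
from .boundary import RegionAssignment, assign_regions, segment_regression
from .degeneracy import DegeneracyMask, classify_degeneracy, fourfold_sites
from .divergence import gametolog_divergence
from .expression import fpkm, sex_bias
from .hka import HkaLocus, PLOIDY_AUTOSOMAL, PLOIDY_X_LINKED, concatenate_loci, hka_test, mlhka_fit
from .segregation import call_cross_ysnps, classify_sharing, gene_ysnp_summary
from .simulate import SyntheticDataset
from .types import GenotypeTable, HaplotypeSet, Role, Sample, Sex, Species

log = logging.getLogger("parshift")


@dataclass
class RunConfig:
    """Pipeline run parameters: stringency k for the lenient wild screen,
    permutation/bootstrap counts and the master seed every random stage
    derives from."""

    k_lenient: int = 2
    min_sons: int = 10
    min_daughters: int = 10
    n_perm: int = 1000
    n_boot: int = 1000
    min_depth: int = 1
    min_sites: int = 10
    seed: int = 0
    wild_only_expression: bool = True


@dataclass
class PipelineResult:
    ysnp_table: pd.DataFrame
    ysnp_summary: pd.DataFrame
    regions: RegionAssignment
    gene_stats: pd.DataFrame
    divergence: pd.DataFrame
    hka_concat: pd.DataFrame
    mlhka_per_gene: pd.DataFrame
    expression_bias: pd.DataFrame
    expression_contrasts: pd.DataFrame
    region_contrasts: pd.DataFrame
    config: RunConfig

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "ysnp_table": self.ysnp_table,
            "ysnp_summary": self.ysnp_summary,
            "regions": self.regions.to_frame(),
            "gene_stats": self.gene_stats,
            "divergence": self.divergence,
            "hka_concat": self.hka_concat,
            "mlhka_per_gene": self.mlhka_per_gene,
            "expression_bias": self.expression_bias,
            "expression_contrasts": self.expression_contrasts,
            "region_contrasts": self.region_contrasts,
        }

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write all stage tables as TSVs; returns content digests."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        digests = {}
        for name, df in self.tables().items():
            path = outdir / f"{name}.tsv"
            df.to_csv(path, sep="\t", float_format="%.10g")
            digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        (outdir / "run_config.json").write_text(json.dumps(dataclasses.asdict(self.config), indent=1))
        (outdir / "digests.json").write_text(json.dumps(digests, indent=1))
        return digests


# ---------------------------------------------------------------------------
# Stage: Y-SNP calling
# ---------------------------------------------------------------------------

def ysnp_stage(tables: list[GenotypeTable], samples: list[Sample], annotations, run: RunConfig):
    calls_by_gene = {}
    rows = []
    for table in tables:
        calls = call_cross_ysnps(table, samples, run.min_sons, run.min_daughters)
        classify_sharing(calls, table, samples, k=run.k_lenient)
        calls_by_gene[table.gene_id] = calls
        for c in calls:
            rows.append(
                {
                    "gene_id": c.gene_id,
                    "pos_1based": c.position + 1,
                    "y_allele": c.y_allele,
                    "cross": int(c.cross_segregating),
                    "status_A": c.wild_status[Species.A],
                    "status_B": c.wild_status[Species.B],
                    "status_C": c.wild_status[Species.C],
                    "A_males": c.counts[Species.A][0],
                    "A_females": c.counts[Species.A][2],
                    "B_males": c.counts[Species.B][0],
                    "B_females": c.counts[Species.B][2],
                    "C_males": c.counts[Species.C][0],
                    "C_females": c.counts[Species.C][2],
                }
            )
    columns = ["gene_id", "pos_1based", "y_allele", "cross", "status_A", "status_B", "status_C",
               "A_males", "A_females", "B_males", "B_females", "C_males", "C_females"]
    table_df = pd.DataFrame(rows, columns=columns)
    summary = gene_ysnp_summary(calls_by_gene, annotations)
    return calls_by_gene, table_df, summary


def boundary_stage(summary: pd.DataFrame, annotations, run: RunConfig, strict: bool = False) -> RegionAssignment:
    col_a = "A_strict" if strict else "A_lenient"
    col_b = "B_strict" if strict else "B_lenient"
    ind_a = (summary[col_a] >= 1).to_numpy()
    ind_b = (summary[col_b] >= 1).to_numpy()
    return assign_regions(ind_a, ind_b, annotations, n_boot=run.n_boot, seed=run.seed)


# ---------------------------------------------------------------------------
# Stage: per-gene statistics
# ---------------------------------------------------------------------------

def _wild_rows(haps: HaplotypeSet, samples: list[Sample], species: Species, sex: Sex | None):
    by_id = {s.id: s for s in samples}
    rows = []
    for i, sid in enumerate(haps.sample_ids):
        s = by_id[sid]
        if s.role is not Role.WILD or s.species is not species:
            continue
        if sex is not None and s.sex is not sex:
            continue
        rows.append(i)
    return rows


def gene_stats_stage(
    haplotypes: dict[str, HaplotypeSet],
    masks: dict[str, DegeneracyMask],
    samples: list[Sample],
    run: RunConfig,
) -> pd.DataFrame:
    """Per-gene diversity/LD/differentiation at 4-fold sites for wild
    samples of species A and B, split by sex, plus the male/female Kst*
    permutation test and the between-species Fst per sex."""
    rows = []
    by_id = {s.id: s for s in samples}
    for gene_id, haps in haplotypes.items():
        mask = masks[gene_id]
        for species in (Species.A, Species.B):
            sp_rows = _wild_rows(haps, samples, species, None)
            sub = haps.select(sp_rows)
            sites4, L4 = fourfold_sites(mask, sub)
            codes_all = sub.allele_codes(sites4) if L4 else np.empty((len(sp_rows), 0), dtype=np.int8)
            sex_of_row = np.array([by_id[sid].sex.value for sid in sub.sample_ids])
            ind_of_row = list(sub.sample_ids)
            for sex in (Sex.M, Sex.F):
                rsel = np.flatnonzero(sex_of_row == sex.value)
                codes = codes_all[rsel]
                S = popgen.segregating_sites(codes) if L4 else 0
                entry = {
                    "gene_id": gene_id,
                    "species": species.value,
                    "group": sex.value,
                    "n_hap": len(rsel),
                    "L4": L4,
                    "S": S,
                    "pi": popgen.pi(codes, L4) if L4 else None,
                    "tajimas_d": popgen.tajimas_d(codes) if L4 and len(rsel) >= 4 else None,
                    "zns": popgen.kellys_zns(codes) if L4 else None,
                }
                rows.append(entry)
            # male vs female differentiation within the species
            if L4 and len(np.unique(sex_of_row)) == 2:
                kst, p = popgen.kst_permutation_p(
                    codes_all,
                    ind_of_row,
                    {sid: by_id[sid].sex.value for sid in set(ind_of_row)},
                    n_perm=run.n_perm,
                    seed=run.seed + (zlib.crc32(gene_id.encode()) % 100000),
                )
            else:
                kst = p = None
            rows[-2]["kst_star"] = rows[-1]["kst_star"] = kst
            rows[-2]["kst_p"] = rows[-1]["kst_p"] = p
        # between-species Fst per sex on the union sample
        for sex in (Sex.M, Sex.F):
            rows_a = _wild_rows(haplotypes[gene_id], samples, Species.A, sex)
            rows_b = _wild_rows(haplotypes[gene_id], samples, Species.B, sex)
            sub = haplotypes[gene_id].select(rows_a + rows_b)
            sites4, L4 = fourfold_sites(mask, sub)
            if L4:
                codes = sub.allele_codes(sites4)
                labels = ["A"] * len(rows_a) + ["B"] * len(rows_b)
                fst = popgen.hudson_fst(codes, labels)
            else:
                fst = None
            for r in rows[-4:]:
                if r["gene_id"] == gene_id and r["group"] == sex.value:
                    r["fst_AB"] = fst
    df = pd.DataFrame(rows)
    return df.set_index(["gene_id", "species", "group"])


# ---------------------------------------------------------------------------
# Stage: divergence
# ---------------------------------------------------------------------------

def divergence_stage(
    tables: list[GenotypeTable],
    annotations,
    masks,
    fragments,
    calls_by_gene,
    samples: list[Sample],
    run: RunConfig,
) -> pd.DataFrame:
    by_id = {s.id: s for s in samples}
    out_idx_cache = None
    rows = []
    for table in tables:
        gene = table.gene_id
        frag = fragments.get(gene)
        if frag is None:
            log.info("%s: no fragments; divergence skipped", gene)
            continue
        ysnp_map = {}
        for c in calls_by_gene.get(gene, []):
            col = int(np.searchsorted(table.positions, c.position))
            ysnp_map[col] = c.y_allele
        if out_idx_cache is None:
            out_idx_cache = [j for j, sid in enumerate(table.sample_ids) if by_id[sid].species is Species.OUTGROUP]
        ingroup = [
            j for j, sid in enumerate(table.sample_ids)
            if by_id[sid].species is Species.A and by_id[sid].role is Role.WILD
        ]
        # X/Y consensus from species-A male fragments only
        a_male_ids = {s.id for s in samples if s.species is Species.A and s.sex is Sex.M and s.role in (Role.FATHER, Role.WILD)}
        frag_a = type(frag)(gene, [f for f in frag.fragments if f[0] in a_male_ids])
        _, record = gametolog_divergence(
            frag_a, ysnp_map, table, annotations[gene].ref_seq, masks[gene],
            outgroup_indices=out_idx_cache, ingroup_indices=ingroup,
            min_depth=run.min_depth, min_sites=run.min_sites,
        )
        rows.append(
            {
                "gene_id": gene,
                "ds_xy": record.ds_xy,
                "ds_outgroup": record.ds_outgroup,
                "sites_xy": record.sites_xy,
                "sites_outgroup": record.sites_outgroup,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Stage: HKA / ML-HKA
# ---------------------------------------------------------------------------

def hka_locus_from_haplotypes(
    gene_id: str,
    haps: HaplotypeSet,
    mask: DegeneracyMask,
    samples: list[Sample],
    species: Species,
    sex: Sex,
    x: float,
) -> HkaLocus | None:
    """S, n, L, D for one gene: polymorphism among the chosen wild sample
    and divergence of its majority base from the outgroup's, both over the
    same 4-fold site list."""
    by_id = {s.id: s for s in samples}
    pop_rows = _wild_rows(haps, samples, species, sex)
    out_rows = [i for i, sid in enumerate(haps.sample_ids) if by_id[sid].species is Species.OUTGROUP]
    if len(pop_rows) < 2 or not out_rows:
        return None
    sub = haps.select(pop_rows + out_rows)
    sites4, L4 = fourfold_sites(mask, sub)
    if L4 == 0:
        return None
    codes = sub.allele_codes(sites4)
    pop = codes[: len(pop_rows)]
    out = codes[len(pop_rows):]
    S = popgen.segregating_sites(pop)
    D = 0
    for j in range(codes.shape[1]):
        pc = pop[:, j][pop[:, j] >= 0]
        oc = out[:, j][out[:, j] >= 0]
        if len(pc) == 0 or len(oc) == 0:
            continue
        pop_major = np.bincount(pc).argmax()
        out_major = np.bincount(oc).argmax()
        if pop_major != out_major:
            D += 1
    return HkaLocus(gene_id, S=S, n=len(pop_rows), L=L4, D=D, x=x)


def hka_stage(
    haplotypes,
    masks,
    samples,
    regions: RegionAssignment,
    run: RunConfig,
    species: Species = Species.A,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenated left-vs-right HKA and per-gene ML-HKA (left and mid
    genes against the right-region X-linked reference set), in females of
    one species."""
    region_of = dict(zip(regions.gene_ids, regions.regions))
    loci: dict[str, HkaLocus] = {}
    for gene_id in regions.gene_ids:
        region = region_of[gene_id]
        x = PLOIDY_X_LINKED if region == "right" else PLOIDY_AUTOSOMAL
        loc = hka_locus_from_haplotypes(gene_id, haplotypes[gene_id], masks[gene_id], samples, species, Sex.F, x)
        if loc is not None:
            loci[gene_id] = loc

    left = [loci[g] for g in regions.gene_ids if region_of[g] == "left" and g in loci]
    right = [loci[g] for g in regions.gene_ids if region_of[g] == "right" and g in loci]
    concat_rows = []
    if len(left) >= 1 and len(right) >= 1:
        pair = [concatenate_loci(left, "left_concat"), concatenate_loci(right, "right_concat")]
        res = hka_test(pair, seed=run.seed)
        concat_rows.append(
            {
                "contrast": "left_vs_right", "species": species.value,
                "S_left": pair[0].S, "L_left": pair[0].L, "D_left": pair[0].D,
                "S_right": pair[1].S, "L_right": pair[1].L, "D_right": pair[1].D,
                "x2": res.x2, "df": res.df, "p": res.p,
            }
        )
    concat_df = pd.DataFrame(concat_rows)

    ml_rows = []
    reference = right
    for gene_id in regions.gene_ids:
        if region_of[gene_id] == "right" or gene_id not in loci:
            continue
        test_loci = reference + [loci[gene_id]]
        try:
            res = mlhka_fit(test_loci, [gene_id], seed=run.seed)
        except ValueError as exc:
            log.warning("%s: mlhka failed (%s)", gene_id, exc)
            continue
        ml_rows.append(
            {
                "gene_id": gene_id, "region": region_of[gene_id], "species": species.value,
                "k_hat": res.k[gene_id], "lrt": res.lrt, "p": res.p,
            }
        )
    ml_df = pd.DataFrame(ml_rows)
    if len(ml_df):
        # Benjamini-Hochberg column alongside the raw p-values
        p = ml_df["p"].to_numpy()
        order = np.argsort(p)
        ranked = np.empty_like(p)
        m = len(p)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            val = min(prev, p[i] * m / (rank_pos + 1))
            ranked[i] = val
            prev = val
        ml_df["p_bh"] = ranked
        ml_df = ml_df.set_index("gene_id")
    return concat_df, ml_df


# ---------------------------------------------------------------------------
# Stage: region contrasts
# ---------------------------------------------------------------------------

def region_contrasts(gene_stats: pd.DataFrame, regions: RegionAssignment) -> pd.DataFrame:
    """Paired t-tests between sexes per region (same genes) and Welch
    t-tests between regions, for each statistic and species, plus the
    per-region group means behind the box-plot style summaries."""
    region_of = dict(zip(regions.gene_ids, regions.regions))
    df = gene_stats.reset_index()
    df["region"] = df["gene_id"].map(region_of)
    rows = []
    stats_cols = ["pi", "tajimas_d", "zns", "fst_AB"]
    for species in df["species"].unique():
        sub = df[df["species"] == species]
        for region in ("left", "mid", "right"):
            in_region = sub[sub["region"] == region]
            males = in_region[in_region["group"] == "M"].set_index("gene_id")
            females = in_region[in_region["group"] == "F"].set_index("gene_id")
            shared = males.index.intersection(females.index)
            for col in stats_cols:
                mv = pd.to_numeric(males.loc[shared, col], errors="coerce")
                fv = pd.to_numeric(females.loc[shared, col], errors="coerce")
                ok = mv.notna() & fv.notna()
                if ok.sum() >= 3:
                    diffs = (mv[ok] - fv[ok]).to_numpy()
                    if np.allclose(diffs, 0.0):
                        t, p = 0.0, 1.0  # identical paired vectors
                    else:
                        t, p = sps.ttest_rel(mv[ok], fv[ok])
                else:
                    t = p = np.nan
                rows.append(
                    {
                        "species": species, "region": region, "statistic": col,
                        "mean_M": mv.mean(), "mean_F": fv.mean(),
                        "contrast": "M_vs_F_paired", "t": t, "p": p, "n": int(ok.sum()),
                    }
                )
        # between-region Welch tests on female values (and male values)
        for group in ("M", "F"):
            gsub = sub[sub["group"] == group]
            for col in stats_cols:
                for ra, rb in (("left", "right"), ("left", "mid"), ("mid", "right")):
                    xa = pd.to_numeric(gsub[gsub["region"] == ra][col], errors="coerce").dropna()
                    xb = pd.to_numeric(gsub[gsub["region"] == rb][col], errors="coerce").dropna()
                    if len(xa) >= 3 and len(xb) >= 3:
                        t, p = sps.ttest_ind(xa, xb, equal_var=False)
                    else:
                        t = p = np.nan
                    rows.append(
                        {
                            "species": species, "region": f"{ra}_vs_{rb}", "statistic": col,
                            "mean_M": xa.mean() if group == "M" else np.nan,
                            "mean_F": xa.mean() if group == "F" else np.nan,
                            "contrast": f"{group}_{ra}_vs_{rb}_welch", "t": t, "p": p,
                            "n": int(len(xa) + len(xb)),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(dataset: SyntheticDataset, run: RunConfig | None = None, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage on a dataset (synthetic or loaded from disk).

    Stage order: ysnp -> boundary/regions -> gene stats -> divergence ->
    HKA/ML-HKA -> expression -> region contrasts. Fragment-dependent
    stages degrade gracefully when fragments are absent.
    """
    run = run or RunConfig()
    samples = dataset.samples
    annotations = dataset.annotations
    masks = {g: classify_degeneracy(ann) for g, ann in annotations.items()}

    calls_by_gene, ysnp_table, summary = ysnp_stage(dataset.tables, samples, annotations, run)
    regions = boundary_stage(summary, annotations, run)
    stats_df = gene_stats_stage(dataset.haplotypes, masks, samples, run)
    if dataset.fragments:
        div_df = divergence_stage(dataset.tables, annotations, masks, dataset.fragments, calls_by_gene, samples, run)
    else:
        log.info("fragments input disabled: divergence stage skipped")
        div_df = pd.DataFrame(columns=["ds_xy", "ds_outgroup", "sites_xy", "sites_outgroup"])
    hka_df, ml_df = hka_stage(dataset.haplotypes, masks, samples, regions, run)
    if dataset.counts is not None:
        fp = fpkm(dataset.counts)
        mask_ids = None
        if run.wild_only_expression:
            mask_ids = [s.id for s in samples if s.role is Role.WILD and s.species is Species.A]
        region_of = dict(zip(regions.gene_ids, regions.regions))
        records, contrasts = sex_bias(fp, samples, region_of, sample_mask=mask_ids)
        bias_df = pd.DataFrame([r.__dict__ for r in records]).set_index("gene_id")
    else:
        bias_df = pd.DataFrame()
        contrasts = pd.DataFrame()
    contrasts_df = region_contrasts(stats_df, regions)
    result = PipelineResult(
        ysnp_table=ysnp_table,
        ysnp_summary=summary,
        regions=regions,
        gene_stats=stats_df,
        divergence=div_df,
        hka_concat=hka_df,
        mlhka_per_gene=ml_df,
        expression_bias=bias_df,
        expression_contrasts=contrasts,
        region_contrasts=contrasts_df,
        config=run,
    )
    if outdir is not None:
        result.write(outdir)
    return result
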