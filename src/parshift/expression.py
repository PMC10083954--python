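"""FPKM computation and female/male expression-bias contrasts.

Expression per gene and sample is FPKM = counts * 1e9 / (effective length
in bp * total mapped reads). The sex-bias statistic per gene is
log2(median female FPKM) - log2(median male FPKM); positive values mean
female-biased expression, as expected where Y-linked alleles have
degenerated. Region contrasts compare per-gene bias between map segments
with Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import CountsTable, Sample, Sex

PSEUDOCOUNT = 0.01


def fpkm(table: CountsTable) -> pd.DataFrame:
    """Gene x sample FPKM matrix."""
    if np.any(table.effective_length <= 0):
        raise ValueError("effective lengths must be positive")
    if np.any(table.total_mapped <= 0):
        raise ValueError("total mapped read counts must be positive")
    values = table.counts * 1e9 / (table.effective_length[:, None] * table.total_mapped[None, :])
    return pd.DataFrame(values, index=table.gene_ids, columns=table.sample_ids)


@dataclass
class BiasRecord:
    gene_id: str
    region: str
    bias: float
    median_f: float
    median_m: float
    n_f: int
    n_m: int
    pseudocount_used: bool


def sex_bias(
    fpkm_table: pd.DataFrame,
    samples: list[Sample],
    regions: dict[str, str],
    sample_mask: list[str] | None = None,
) -> tuple[list[BiasRecord], pd.DataFrame]:
    """Per-gene sex bias and between-region Welch t-test contrasts.

    ``regions`` maps gene -> region label. ``sample_mask`` restricts the
    medians to a subset of sample ids (e.g. wild accessions only). Genes
    with a zero median get the pseudocount and are flagged. Requires >= 3
    samples per sex; a sex entirely absent is an error.
    """
    by_id = {s.id: s for s in samples}
    use = [sid for sid in fpkm_table.columns if sample_mask is None or sid in sample_mask]
    f_ids = [sid for sid in use if by_id[sid].sex is Sex.F]
    m_ids = [sid for sid in use if by_id[sid].sex is Sex.M]
    if not f_ids or not m_ids:
        raise ValueError("both sexes must be present for a bias contrast")
    if len(f_ids) < 3 or len(m_ids) < 3:
        raise ValueError("need at least 3 samples per sex")
    records = []
    for gene in fpkm_table.index:
        if gene not in regions:
            continue
        med_f = float(fpkm_table.loc[gene, f_ids].median())
        med_m = float(fpkm_table.loc[gene, m_ids].median())
        pseudo = med_f == 0 or med_m == 0
        bias = np.log2(med_f + (PSEUDOCOUNT if pseudo else 0)) - np.log2(med_m + (PSEUDOCOUNT if pseudo else 0))
        records.append(BiasRecord(gene, regions[gene], float(bias), med_f, med_m, len(f_ids), len(m_ids), pseudo))

    df = pd.DataFrame([r.__dict__ for r in records])
    contrasts = []
    region_labels = sorted(df["region"].unique())
    for i, ra in enumerate(region_labels):
        for rb in region_labels[i + 1 :]:
            xa = df.loc[df["region"] == ra, "bias"].to_numpy()
            xb = df.loc[df["region"] == rb, "bias"].to_numpy()
            if len(xa) < 3 or len(xb) < 3:
                t = p = np.nan
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=False)
            contrasts.append(
                {"region_a": ra, "region_b": rb, "mean_a": xa.mean() if len(xa) else np.nan,
                 "mean_b": xb.mean() if len(xb) else np.nan, "t": t, "p": p}
            )
    return records, pd.DataFrame(contrasts)
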