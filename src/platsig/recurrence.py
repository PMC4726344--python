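"""Significantly mutated genes and response-group enrichment.

The significance test asks whether a gene collects more mutations across
the cohort than its coding length would attract under each sample's
background mutation rate. Per sample, the gene's mutation count is modelled
Binomial(coding_length, per-base rate); the exact null distribution of the
cohort total is the convolution of the per-sample binomials, and the
p-value is the upper tail at the observed total. This is a single-category
convolution test: no stratification by substitution type and no per-gene
coverage correction, since neither is recoverable from a MAF alone.

Group enrichment uses the two-sided Fisher exact test on patient-level 2x2
tables (a patient counts once no matter how many mutations it carries in
the gene), both between response groups within the cohort and against
external per-gene cohort counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import DEFAULT_EXOME_MB, MutationTable


@dataclass(frozen=True)
class GeneModel:
    """Gene symbols with coding lengths (bases); the exposure of the smg test."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        bad = [g for g, L in self.lengths.items() if L < 1]
        if bad:
            raise ValueError(f"coding_length must be >= 1 for {bad}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.lengths

    def __getitem__(self, gene: str) -> int:
        return self.lengths[gene]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneModel":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lower() for c in df.columns]
        if df["gene"].duplicated().any():
            raise ValueError("gene names must be unique")
        return cls(dict(zip(df["gene"], df["coding_length"].astype(int))))


def load_toy_gene_model() -> GeneModel:
    """The small bundled gene-length table (synthetic lengths, for tests/demos)."""
    ref = resources.files("platsig.data") / "gene_model_synthetic.tsv"
    with resources.as_file(ref) as p:
        return GeneModel.read_tsv(p)


@dataclass(frozen=True)
class SmgResult:
    gene: str
    n_mutated_patients: int
    n_mutations: int
    p_value: float
    q_value: float
    scope: str


@dataclass(frozen=True)
class EnrichmentResult:
    gene: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    odds_direction: str  # which margin the mutated fraction favours


def filter_variants(
    table: MutationTable, vaf_min: float = 0.2
) -> MutationTable:
    """Keep variants with VAF strictly greater than ``vaf_min``.

    Low-frequency variants are treated as likely passengers from ongoing
    mutagenesis or subclonal events and excluded from driver analysis.
    Records with missing VAF are dropped and counted in the result's
    ``parse_report``.
    """
    df = table.df
    missing = df["vaf"].isna()
    kept = df[~missing & (df["vaf"] > vaf_min)].reset_index(drop=True)
    out = MutationTable(kept, group_of=table.group_of)
    out.parse_report = {
        "n_dropped_missing_vaf": int(missing.sum()),
        "n_dropped_low_vaf": int((~missing).sum() - len(kept)),
    }
    return out


def background_rates(
    table: MutationTable, exome_mb: float = DEFAULT_EXOME_MB
) -> pd.Series:
    """Per-sample per-base mutation rate over the coding exome."""
    counts = table.df["sample"].value_counts()
    return pd.Series(
        {s: counts.get(s, 0) / (exome_mb * 1e6) for s in table.sample_ids},
        name="rate_per_base",
    )


def convolution_test(
    observed_total: int,
    gene_length: int,
    rates: Sequence[float],
) -> float:
    """Exact upper-tail p-value for a gene's cohort-wide mutation count.

    The null model is ``sum_s Binomial(gene_length, rate_s)``; the exact
    distribution of the total is built by convolving the per-sample pmfs.
    Each pmf is truncated at ``observed_total`` terms: any outcome involving
    a larger per-sample count already puts the total at or above the
    observed value, so ``P(total <= observed-1)`` is computed exactly and
    ``p = 1 - P(total <= observed-1)``.
    """
    rates = np.asarray(rates, dtype=float)
    if observed_total < 0 or gene_length < 1:
        raise ValueError("observed_total must be >= 0 and gene_length >= 1")
    if (rates < 0).any() or (rates > 1).any():
        raise ValueError("rates must lie in [0, 1]")
    if observed_total == 0:
        return 1.0
    support = np.arange(min(observed_total, gene_length + 1))
    dist = np.ones(1)
    for r in rates:
        pmf = stats.binom.pmf(support, gene_length, r)
        dist = np.convolve(dist, pmf)[:observed_total]
    return float(np.clip(1.0 - dist.sum(), 0.0, 1.0))


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Two-sidedness by the conventional exact rule: the sum of hypergeometric
    point probabilities (margins fixed) that do not exceed the observed
    table's probability, within relative tolerance 1e-7.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    if t.sum() == 0 or (t.sum(axis=0) == 0).all() or (t.sum(axis=1) == 0).all():
        raise ValueError("at least one margin must be positive")
    return float(stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")[1])


def _patient_gene_counts(table: MutationTable, gene: str, samples: Sequence[str]):
    df = table.df
    hit = df[(df["gene"] == gene) & df["sample"].isin(samples)]
    patients = set(hit["sample"])
    return len(patients), len(hit)


def smg_scan(
    table: MutationTable,
    genes: GeneModel,
    samples: Sequence[str] | None = None,
    scope_label: str = "overall",
    fdr_max: float = 0.2,
    min_patients: int = 2,
    exome_mb: float = DEFAULT_EXOME_MB,
    return_all: bool = False,
) -> list[SmgResult]:
    """Scan for genes mutated above background in a (sub)cohort.

    Tests every gene in the gene model mutated in at least ``min_patients``
    patients of the scope; p-values come from :func:`convolution_test` with
    scope-restricted background rates, and Benjamini-Hochberg adjustment is
    applied over the tested genes only. Returns genes with q < ``fdr_max``
    sorted by p (all tested genes if ``return_all``). The input table is
    expected to be VAF-filtered already.
    """
    scope = table if samples is None else table.subset_samples(samples)
    if not scope.sample_ids:
        raise ValueError("scope contains no samples")
    rates = background_rates(scope, exome_mb)
    df = scope.df
    known = df["gene"].notna() & df["gene"].isin(genes.lengths)
    n_unknown_genes = df.loc[df["gene"].notna() & ~known, "gene"].nunique()
    if n_unknown_genes:
        warnings.warn(
            f"{n_unknown_genes} mutated gene(s) absent from the gene model; excluded"
        )
    by_gene = df[known].groupby("gene")["sample"]
    candidates = [
        (g, s.nunique(), len(s)) for g, s in by_gene if s.nunique() >= min_patients
    ]
    if not candidates:
        return []
    pvals = [
        convolution_test(n_mut, genes[g], rates.to_numpy())
        for g, _, n_mut in candidates
    ]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = [
        SmgResult(g, n_pat, n_mut, float(p), float(q), scope_label)
        for (g, n_pat, n_mut), p, q in zip(candidates, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.gene))
    if return_all:
        return results
    return [r for r in results if r.q_value < fdr_max]


@dataclass
class SubgroupDiscovery:
    overall: list[SmgResult]
    by_group: dict[str, list[SmgResult]]
    subgroup_only: dict[str, list[str]]


def subgroup_discovery(
    table: MutationTable,
    genes: GeneModel,
    fdr_max: float = 0.2,
    min_patients: int = 2,
    exome_mb: float = DEFAULT_EXOME_MB,
) -> SubgroupDiscovery:
    """Find genes significant within a response group but not cohort-wide."""
    if not table.group_of:
        raise ValueError("subgroup discovery requires response-group labels")
    overall = smg_scan(
        table, genes, fdr_max=fdr_max, min_patients=min_patients, exome_mb=exome_mb
    )
    overall_genes = {r.gene for r in overall}
    by_group: dict[str, list[SmgResult]] = {}
    subgroup_only: dict[str, list[str]] = {}
    groups = sorted(set(table.group_of.values()))
    for grp in groups:
        members = [s for s in table.sample_ids if table.group_of[s] == grp]
        res = smg_scan(
            table,
            genes,
            samples=members,
            scope_label=grp,
            fdr_max=fdr_max,
            min_patients=min_patients,
            exome_mb=exome_mb,
        )
        by_group[grp] = res
        subgroup_only[grp] = sorted(
            {r.gene for r in res} - overall_genes
        )
    return SubgroupDiscovery(overall, by_group, subgroup_only)


def group_enrichment(
    table: MutationTable, gene: str, group_a: str, group_b: str
) -> EnrichmentResult:
    """Patient-level Fisher test of a gene's mutations between two groups."""
    if not table.group_of:
        raise ValueError("group enrichment requires response-group labels")
    a_samples = [s for s in table.sample_ids if table.group_of[s] == group_a]
    b_samples = [s for s in table.sample_ids if table.group_of[s] == group_b]
    a_mut, _ = _patient_gene_counts(table, gene, a_samples)
    b_mut, _ = _patient_gene_counts(table, gene, b_samples)
    t = ((a_mut, len(a_samples) - a_mut), (b_mut, len(b_samples) - b_mut))
    p = fisher_two_sided(t)
    fa = a_mut / len(a_samples) if a_samples else 0.0
    fb = b_mut / len(b_samples) if b_samples else 0.0
    direction = "group_a" if fa > fb else "group_b" if fb > fa else "none"
    return EnrichmentResult(gene, t, p, direction)


def cohort_comparison(
    counts_a: Mapping[str, tuple[int, int]],
    counts_b: Mapping[str, tuple[int, int]],
) -> list[EnrichmentResult]:
    """Per-gene Fisher test of mutated-patient fractions between two cohorts.

    Each mapping gives gene -> (patients mutated, cohort size). Genes absent
    from either cohort are skipped with a warning.
    """
    results = []
    skipped = [g for g in counts_a if g not in counts_b]
    if skipped:
        warnings.warn(f"gene(s) missing from second cohort, skipped: {skipped}")
    for gene in counts_a:
        if gene not in counts_b:
            continue
        (ka, na), (kb, nb) = counts_a[gene], counts_b[gene]
        if not (0 <= ka <= na and 0 <= kb <= nb):
            raise ValueError(f"invalid counts for {gene}")
        t = ((ka, na - ka), (kb, nb - kb))
        p = fisher_two_sided(t)
        fa, fb = ka / na if na else 0.0, kb / nb if nb else 0.0
        direction = "group_a" if fa > fb else "group_b" if fb > fa else "none"
        results.append(EnrichmentResult(gene, t, p, direction))
    return results


def read_cohort_counts(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a (gene, mutated, n) TSV of external per-gene cohort counts."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return {
        g: (int(m), int(n)) for g, m, n in zip(df["gene"], df["mutated"], df["n"])
    }
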