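"""Mutation tables, 96-channel catalogs, and cohort summary statistics.

This module owns the universal input of the pipeline — a MAF-like table of
somatic variants — and the per-cohort observables computed from it: the
samples x 96 substitution-in-context count matrix used for signature
extraction, per-sample mutation rates over the coding exome,
transition/transversion ratios, and the variant-allele-frequency spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import (
    BASES,
    CHANNEL_LABELS,
    AmbiguousBaseError,
    channel_of,
    is_transition,
)

#: Average megabases of protein-coding sequence with adequate coverage in a
#: whole exome; the denominator of mutations/Mb rates.
DEFAULT_EXOME_MB = 30.0

_REQUIRED_COLUMNS = ("sample", "chrom", "pos", "ref", "alt")
_COLUMN_ALIASES = {
    "sample": ("sample", "sample_id", "tumor_sample_barcode"),
    "chrom": ("chrom", "chromosome", "chr"),
    "pos": ("pos", "position", "start_position", "start"),
    "ref": ("ref", "reference_allele", "ref_allele"),
    "alt": ("alt", "tumor_seq_allele2", "alt_allele"),
    "vaf": ("vaf", "allele_frequency", "af", "tumor_vaf"),
    "gene": ("gene", "hugo_symbol", "gene_symbol"),
    "context": ("context", "trinucleotide", "trinucleotide_context"),
}

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"


class MafFormatError(ValueError):
    """The input table is missing a mandatory column or is malformed."""


class RecordValidationError(ValueError):
    """One or more rows violate record-level invariants (offending rows listed)."""


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic variant.

    ``context`` is the reference-strand trinucleotide centred on the mutated
    base; for SNVs its middle base must equal ``ref``. ``vaf`` is the
    fraction of reads supporting the alternate allele.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float | None = None
    gene: str | None = None
    context: str | None = None
    variant_class: str = SNV

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.variant_class == SNV:
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise ValueError(f"invalid SNV alleles {self.ref}>{self.alt}")
            if self.context is not None and self.context[1] != self.ref:
                raise ValueError(
                    f"context {self.context} middle base != ref {self.ref}"
                )


def _infer_variant_class(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return SNV
    return INSERTION if len(alt) > len(ref) else DELETION


@dataclass
class MutationTable:
    """An ordered collection of somatic variants plus optional response groups.

    The records live in a pandas DataFrame (columns: sample, chrom, pos, ref,
    alt, vaf, gene, context, variant_class; extra input columns preserved).
    ``group_of`` maps each sample to a response-group label (e.g. sensitive /
    resistant) and, when present, must cover every sample.
    """

    df: pd.DataFrame
    group_of: dict[str, str] | None = None
    parse_report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group_of is not None:
            missing = set(self.sample_ids) - set(self.group_of)
            if missing:
                raise ValueError(f"group_of does not cover samples: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.df["sample"]))

    @property
    def n_records(self) -> int:
        return len(self.df)

    def records(self) -> Iterable[MutationRecord]:
        for row in self.df.itertuples(index=False):
            yield MutationRecord(
                sample_id=row.sample,
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                vaf=None if pd.isna(row.vaf) else float(row.vaf),
                gene=None if pd.isna(row.gene) else row.gene,
                context=None if pd.isna(row.context) else row.context,
                variant_class=row.variant_class,
            )

    def snvs(self) -> pd.DataFrame:
        return self.df[self.df["variant_class"] == SNV]

    def subset_samples(self, samples: Sequence[str]) -> "MutationTable":
        keep = [s for s in self.sample_ids if s in set(samples)]
        df = self.df[self.df["sample"].isin(keep)].reset_index(drop=True)
        groups = {s: self.group_of[s] for s in keep} if self.group_of else None
        return MutationTable(df, group_of=groups)

    @classmethod
    def from_records(
        cls,
        records: Iterable[MutationRecord],
        group_of: Mapping[str, str] | None = None,
    ) -> "MutationTable":
        rows = [
            (r.sample_id, r.chrom, r.pos, r.ref, r.alt, r.vaf, r.gene, r.context,
             r.variant_class)
            for r in records
        ]
        df = pd.DataFrame(
            rows,
            columns=["sample", "chrom", "pos", "ref", "alt", "vaf", "gene",
                     "context", "variant_class"],
        )
        return cls(df, group_of=dict(group_of) if group_of else None)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.rename(
            columns={"sample": "Sample", "chrom": "Chrom", "pos": "Pos",
                     "ref": "Ref", "alt": "Alt", "vaf": "VAF", "gene": "Gene",
                     "context": "Context"}
        )
        out.to_csv(path, sep="\t", index=False)


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    mapping: dict[str, str] = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                mapping[canonical] = lower[alias]
                break
    missing = [c for c in _REQUIRED_COLUMNS if c not in mapping]
    if missing:
        raise MafFormatError(
            f"missing mandatory column(s): {', '.join(missing)} "
            f"(found: {', '.join(columns)})"
        )
    return mapping


def read_maf(
    path: str | Path,
    fasta: "object | None" = None,
    groups: Mapping[str, str] | None = None,
) -> MutationTable:
    """Read a MAF-like tab-separated mutation table.

    Parameters
    ----------
    path : str or Path
        Tab-separated file with a header naming at least sample, chrom, pos,
        ref and alt (common MAF aliases are accepted). Coordinates are
        1-based on the reference strand.
    fasta : optional
        A ``pyfaidx.Fasta`` (or any mapping of chrom -> indexable sequence)
        used to look up trinucleotide contexts for SNV rows lacking a
        Context column.
    groups : optional
        Mapping sample -> response-group label.

    Raises
    ------
    MafFormatError
        If a mandatory column is absent.
    RecordValidationError
        If any SNV has a context whose middle base differs from its ref.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty:
        raise MafFormatError(f"no records in {path}")
    mapping = _resolve_columns(list(raw.columns))

    df = pd.DataFrame(
        {
            "sample": raw[mapping["sample"]],
            "chrom": raw[mapping["chrom"]],
            "pos": pd.to_numeric(raw[mapping["pos"]]).astype(int),
            "ref": raw[mapping["ref"]].str.upper(),
            "alt": raw[mapping["alt"]].str.upper(),
        }
    )
    if "vaf" in mapping:
        df["vaf"] = pd.to_numeric(raw[mapping["vaf"]].replace("", np.nan))
    else:
        df["vaf"] = np.nan
    if "gene" in mapping:
        gene = raw[mapping["gene"]]
        df["gene"] = gene.where(gene != "", other=None)
    else:
        df["gene"] = pd.Series([None] * len(df), dtype=object)
    if "context" in mapping:
        ctx = raw[mapping["context"]].str.upper()
        df["context"] = ctx.where(ctx != "", other=None)
    else:
        df["context"] = pd.Series([None] * len(df), dtype=object)
    df["variant_class"] = [
        _infer_variant_class(r, a) for r, a in zip(df["ref"], df["alt"])
    ]
    # carry through any extra columns untouched
    used = set(mapping.values())
    for col in raw.columns:
        if col not in used:
            df[col] = raw[col]

    is_snv = df["variant_class"] == SNV
    n_filled = 0
    if fasta is not None:
        need = is_snv & df["context"].isna()
        contexts = []
        for row in df[need].itertuples(index=True):
            seq = fasta[str(row.chrom)]
            tri = str(seq[row.pos - 2 : row.pos + 1]).upper()
            contexts.append((row.Index, tri))
        for i, tri in contexts:
            df.at[i, "context"] = tri
        n_filled = len(contexts)

    bad = df.index[
        is_snv & df["context"].notna() & (df["context"].str[1] != df["ref"])
    ]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:20])  # +2: header + 1-based
        raise RecordValidationError(
            f"{len(bad)} SNV row(s) whose context middle base != ref "
            f"(file lines {rows}{'...' if len(bad) > 20 else ''})"
        )

    report = {
        "n_rows": len(df),
        "n_snv": int(is_snv.sum()),
        "n_indel": int((~is_snv).sum()),
        "n_context_filled_from_fasta": n_filled,
        "n_snv_missing_context": int((is_snv & df["context"].isna()).sum()),
    }
    table = MutationTable(df, group_of=dict(groups) if groups else None)
    table.parse_report = report
    return table


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, group) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample" not in cols or "group" not in cols:
        raise MafFormatError("group file needs columns: sample, group")
    df.columns = cols
    return dict(zip(df["sample"], df["group"]))


@dataclass
class Catalog96:
    """Samples x 96 matrix of SNV counts in fixed channel order."""

    counts: np.ndarray
    sample_ids: list[str]
    channel_labels: tuple[str, ...] = CHANNEL_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sample_ids), 96):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({len(self.sample_ids)}, 96)"
            )
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """96 rows (channel label) x sample columns, the on-disk layout."""
        return pd.DataFrame(
            self.counts.T, index=list(self.channel_labels), columns=self.sample_ids
        ).rename_axis("channel")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Catalog96":
        frame = frame.reindex(list(CHANNEL_LABELS))
        if frame.isna().any().any():
            raise ValueError("catalog table does not cover all 96 channels")
        return cls(frame.to_numpy().T, list(frame.columns))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Catalog96":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


def build_catalog(table: MutationTable, samples: Sequence[str] | None = None) -> Catalog96:
    """Count each sample's SNVs into the 96 channels.

    Indels are excluded. SNVs with missing context or ambiguous bases (N) are
    excluded and tallied in the returned catalog's companion report on the
    table's ``parse_report`` under ``n_unmappable``. Samples with zero SNVs
    appear as zero rows.
    """
    sample_ids = list(samples) if samples is not None else table.sample_ids
    index = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(sample_ids), 96), dtype=float)
    n_unmappable = 0
    snvs = table.snvs()
    for row in snvs.itertuples(index=False):
        if row.sample not in index:
            continue
        if pd.isna(row.context):
            n_unmappable += 1
            continue
        try:
            ch = channel_of(row.ref, row.alt, row.context)
        except AmbiguousBaseError:
            n_unmappable += 1
            continue
        counts[index[row.sample], ch.index] += 1
    table.parse_report["n_unmappable"] = n_unmappable
    if n_unmappable:
        warnings.warn(f"{n_unmappable} SNV(s) excluded from catalog as unmappable")
    return Catalog96(counts, sample_ids)


def titv_ratio(table: MutationTable, per_sample: bool = False):
    """Transition/transversion ratio of the cohort (or per sample + median).

    Transitions are C>T, T>C, G>A, A>G; the remaining eight substitutions are
    transversions. A sample with zero transversions yields ``inf``.
    """
    snvs = table.snvs()

    def _ratio(df: pd.DataFrame) -> float:
        ti = sum(is_transition(r, a) for r, a in zip(df["ref"], df["alt"]))
        tv = len(df) - ti
        return float(ti) / tv if tv else float("inf")

    if not per_sample:
        return _ratio(snvs)
    ratios = pd.Series(
        {s: _ratio(snvs[snvs["sample"] == s]) for s in table.sample_ids},
        name="titv",
    )
    finite = ratios[np.isfinite(ratios)]
    return ratios, float(finite.median()) if len(finite) else float("nan")


def mutation_rate(
    table: MutationTable, exome_mb: float = DEFAULT_EXOME_MB
) -> tuple[pd.Series, float]:
    """Per-sample mutations/Mb over the coding exome, plus the cohort median.

    All coding mutations (SNVs and indels) count toward the rate.
    """
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    counts = table.df["sample"].value_counts()
    rates = pd.Series(
        {s: counts.get(s, 0) / exome_mb for s in table.sample_ids}, name="rate_per_mb"
    )
    return rates, float(rates.median())


@dataclass(frozen=True)
class VafSpectrum:
    """Fractions of SNVs below a VAF threshold, overall and per substitution."""

    threshold: float
    overall: float
    by_substitution: dict[str, float]
    n_with_vaf: int
    n_missing_vaf: int


def vaf_spectrum(table: MutationTable, threshold: float = 0.2) -> VafSpectrum:
    """Fraction of SNVs with VAF below ``threshold``.

    Also reports the same fraction within each of the six pyrimidine-reference
    substitution classes, e.g. to isolate the low-VAF behaviour of C>A
    transversions. Records without a VAF are excluded and counted.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    snvs = table.snvs()
    have = snvs[snvs["vaf"].notna()].copy()
    n_missing = len(snvs) - len(have)
    if have.empty:
        return VafSpectrum(threshold, float("nan"), {}, 0, n_missing)

    def _pyr_sub(ref: str, alt: str) -> str:
        from .channels import PYRIMIDINES, complement

        if ref not in PYRIMIDINES:
            ref, alt = complement(ref), complement(alt)
        return f"{ref}>{alt}"

    have["sub"] = [_pyr_sub(r, a) for r, a in zip(have["ref"], have["alt"])]
    below = have["vaf"] < threshold
    by_sub = {
        sub: float(below[have["sub"] == sub].mean())
        for sub in sorted(have["sub"].unique())
    }
    return VafSpectrum(threshold, float(below.mean()), by_sub, len(have), n_missing)


def summary_statistics(
    table: MutationTable,
    exome_mb: float = DEFAULT_EXOME_MB,
    vaf_threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-sample rate, Ti/Tv and low-VAF fraction in one table."""
    rates, _ = mutation_rate(table, exome_mb)
    ratios, _ = titv_ratio(table, per_sample=True)
    snvs = table.snvs()
    frac = {}
    for s in table.sample_ids:
        v = snvs.loc[snvs["sample"] == s, "vaf"].dropna()
        frac[s] = float((v < vaf_threshold).mean()) if len(v) else float("nan")
    out = pd.DataFrame(
        {
            "rate_per_mb": rates,
            "titv": ratios,
            f"frac_vaf_below_{vaf_threshold:g}": pd.Series(frac),
        }
    )
    out.index.name = "sample"
    return out
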