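"""Synthetic exome cohorts with known signature mixtures and planted drivers.

The generator emulates the statistical structure of a platinum-treated
recurrent-tumor exome cohort: 18 samples split into response groups (7
sensitive / 11 resistant), per-sample mutation loads log-uniform across
4.8-80.9 mutations/Mb over a 30 Mb coding exome, each mutation drawn from
a per-sample Dirichlet mixture of named 96-channel signature profiles
(including a platinum-like profile concentrated on C>A at CpCpA/CpCpG),
variant allele frequencies drawn from origin-specific beta distributions
(platinum-origin mutations predominantly subclonal), and optional driver
genes planted in a designated response group with VAF above the driver
filter. Ground truth (exposures, per-mutation origins, planted drivers) is
returned alongside, so recovery by every downstream stage is testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import MutationTable
from .channels import CHANNEL_LABELS, reverse_complement
from .recurrence import GeneModel
from .signatures import load_reference_signatures

#: Cohort-scale defaults: sample count and response-group split, the
#: observed span of mutation loads, and the coding-exome size.
DEFAULT_N_SAMPLES = 18
DEFAULT_GROUP_SIZES = (7, 11)
DEFAULT_LOAD_RANGE = (4.8, 80.9)
DEFAULT_EXOME_MB = 30.0

_CHANNEL_PARTS = [
    (lab[2], lab[4], lab[0] + lab[2] + lab[6]) for lab in CHANNEL_LABELS
]  # (ref, alt, context) in pyrimidine representation


@dataclass(frozen=True)
class VafModel:
    """Origin-specific VAF distributions.

    Platinum-origin mutations are late, chemotherapy-induced and mostly
    subclonal: Beta(1.2, 13) puts ~92% of its mass below VAF 0.2. Mutations
    of other origins are a mixture of a subclonal component Beta(1.8, 10)
    and a clonal component Beta(6, 4); with ``clonal_weight`` 0.16 about
    61% of them fall below 0.2. Because the high-load samples are the
    platinum-dominated ones, the mutation-weighted platinum share is ~0.48
    and the cohort-wide fraction of SNVs below VAF 0.2 lands at ~76%.
    Driver mutations are clonal, truncated to VAF > 0.2 so they survive
    the driver-analysis filter.
    """

    platinum_beta: tuple[float, float] = (1.2, 13.0)
    subclonal_beta: tuple[float, float] = (1.8, 10.0)
    clonal_beta: tuple[float, float] = (6.0, 4.0)
    clonal_weight: float = 0.16


@dataclass(frozen=True)
class DriverSpec:
    """A gene planted in one response group.

    Either ``prob`` (independent per-patient Bernoulli) or ``n_patients``
    (exactly the first n patients of the group, deterministic) selects the
    mutated patients; each receives ``mutations_per_patient`` mutations
    (a tuple gives per-patient counts in selection order).
    """

    gene: str
    group: str
    prob: float | None = None
    n_patients: int | None = None
    mutations_per_patient: int | tuple[int, ...] = 1


@dataclass
class SimulationConfig:
    n_samples: int = DEFAULT_N_SAMPLES
    group_sizes: tuple[int, int] = DEFAULT_GROUP_SIZES
    group_names: tuple[str, str] = ("sensitive", "resistant")
    signature_profiles: Mapping[str, np.ndarray] | None = None  # default: bundled set
    platinum_name: str = "Platinum"
    #: Dirichlet parameters: a (n_signatures,) vector shared by all samples,
    #: a (n_samples, n_signatures) matrix, or None for the default
    #: dominant-process scheme (see :func:`dominant_process_alphas`).
    exposure_concentration: np.ndarray | None = None
    load_range: tuple[float, float] = DEFAULT_LOAD_RANGE
    #: Platinum mutagenesis is what drives loads up in a cisplatin-treated
    #: cohort, so by default the drawn loads are assigned to samples in
    #: order of realized platinum exposure (highest exposure, highest load).
    couple_load_to_platinum: bool = True
    exome_mb: float = DEFAULT_EXOME_MB
    vaf_model: VafModel = field(default_factory=VafModel)
    drivers: tuple[DriverSpec, ...] = ()
    gene_model: GeneModel | None = None  # default: full-exome synthetic model
    seed: int = 0

    def resolve(self) -> "SimulationConfig":
        """Fill defaulted fields; validate invariants."""
        if sum(self.group_sizes) != self.n_samples:
            raise ValueError("group sizes must sum to n_samples")
        if self.load_range[0] <= 0 or self.load_range[1] < self.load_range[0]:
            raise ValueError("load_range must be positive and ordered")
        if self.signature_profiles is None:
            refs = load_reference_signatures()
            self.signature_profiles = {
                n: refs[n] for n in refs.names
            }
        for name, p in self.signature_profiles.items():
            if abs(float(np.sum(p)) - 1.0) > 1e-6 or (np.asarray(p) < 0).any():
                raise ValueError(f"signature profile {name!r} is not normalized")
        if self.exposure_concentration is None:
            names = list(self.signature_profiles)
            platinum_index = (
                names.index(self.platinum_name) if self.platinum_name in names else 0
            )
            self.exposure_concentration = dominant_process_alphas(
                self.n_samples, len(names), platinum_index
            )
        if self.gene_model is None:
            self.gene_model = default_gene_model(self.exome_mb, seed=self.seed)
        return self


def dominant_process_alphas(
    n_samples: int,
    n_signatures: int,
    platinum_index: int = 0,
    dominant: float = 4.0,
    base: float = 0.45,
    platinum_fraction: float = 1 / 3,
) -> np.ndarray:
    """Per-sample Dirichlet parameters with one dominant process per tumor.

    Real platinum-treated cohorts show strongly patient-specific mutational
    processes (transition/transversion ratios spanning an order of
    magnitude), so each synthetic sample favours one signature: the
    platinum process dominates ``platinum_fraction`` of the cohort and the
    remaining signatures take tiers of the rest (4/3/3/2 samples of an
    18-sample cohort), which keeps all of them identifiable and makes the
    merge order of sub-maximal factorizations deterministic; the
    cohort-mean platinum exposure is ~0.28.
    """
    alphas = np.full((n_samples, n_signatures), base)
    n_plat = max(1, round(n_samples * platinum_fraction))
    others = [j for j in range(n_signatures) if j != platinum_index] or [platinum_index]
    # tiered allocation of the remaining samples: unequal process strengths
    # give a deterministic merge order when fewer clusters than processes
    # are requested, which keeps sub-maximal factorizations reproducible
    n_rest = n_samples - n_plat
    counts = [n_rest // len(others)] * len(others)
    for j in range(n_rest - sum(counts)):
        counts[j] += 1
    if len(counts) >= 2 and len(set(counts)) == 1 and counts[-1] >= 2:
        counts[0] += 1
        counts[-1] -= 1
    designated = [platinum_index] * n_plat + [
        s for s, c in zip(others, counts) for _ in range(c)
    ]
    for i, sig in enumerate(designated):
        alphas[i, sig] = dominant
    return alphas


def default_gene_model(
    exome_mb: float = DEFAULT_EXOME_MB,
    n_background: int = 190,
    seed: int = 0,
) -> GeneModel:
    """A synthetic gene model whose coding lengths tile the whole exome.

    A handful of named genes with realistic coding lengths, plus coarse
    background regions (~150 kb of aggregated coding territory each) until
    the total reaches ``exome_mb``. Covering the full exome keeps the
    generator consistent with the smg null model — a mutation falling
    anywhere in the exome lands in exactly one modelled unit — and the
    coarse background keeps expected per-unit counts well away from zero,
    so the recurrently-mutated screen (>= 2 patients) does not by itself
    select extreme observations.
    """
    named = [
        ("TP53", 1182), ("CDKN2A", 471), ("FBXW7", 2124), ("KRAS", 570),
        ("REV3L", 9390), ("EPYC", 966), ("NOTCH1", 7668), ("PIK3CA", 3207),
        ("HRAS", 570), ("CASP8", 1440),
    ]
    rng = np.random.default_rng([int(seed), 987])
    lengths = dict(named)
    budget = int(exome_mb * 1e6) - sum(lengths.values())
    weights = rng.lognormal(0.0, 0.4, size=n_background)
    sizes = np.floor(budget * weights / weights.sum()).astype(int)
    sizes[-1] += budget - int(sizes.sum())
    for i, L in enumerate(sizes, start=1):
        lengths[f"REGION{i:03d}"] = int(L)
    return GeneModel(lengths)


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator."""

    exposures: pd.DataFrame  # samples x signatures, rows sum to 1
    origins: list[str]  # per-mutation origin, aligned with the table rows
    drivers: tuple[DriverSpec, ...]
    driver_patients: dict[str, list[str]]
    vaf_model: VafModel
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "exposures": {
                s: dict(zip(self.exposures.columns, map(float, row)))
                for s, row in zip(self.exposures.index, self.exposures.to_numpy())
            },
            "drivers": [asdict(d) for d in self.drivers],
            "driver_patients": self.driver_patients,
            "vaf_model": asdict(self.vaf_model),
            "origins": self.origins,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _gene_layout(gene_model: GeneModel):
    genes = list(gene_model.lengths)
    lengths = np.array([gene_model.lengths[g] for g in genes], dtype=float)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(int)
    return genes, lengths, starts


def _draw_vaf(rng, origin: str, platinum_name: str, vm: VafModel) -> float:
    if origin == "driver":
        while True:
            v = rng.beta(*vm.clonal_beta)
            if round(v, 4) > 0.2:  # must survive the strict driver-VAF filter
                return float(v)
    if origin == platinum_name:
        return float(rng.beta(*vm.platinum_beta))
    if rng.random() < vm.clonal_weight:
        return float(rng.beta(*vm.clonal_beta))
    return float(rng.beta(*vm.subclonal_beta))


def simulate_cohort(config: SimulationConfig) -> tuple[MutationTable, SyntheticTruth]:
    """Generate a cohort MAF-like table plus its ground truth.

    Per sample: a mutation load is drawn log-uniformly over the configured
    mutations/Mb range and multiplied by the exome size; exposures come
    from a Dirichlet; each mutation picks an origin signature by exposure,
    a channel from that signature's 96-vector, a reference-strand
    representation uniformly between the two strands, a gene proportional
    to coding length, a position within the gene, and an origin-specific
    VAF. Planted driver genes receive additional patient-level mutations in
    their designated group with VAF > 0.2 and are withheld from the
    background gene pool so the planted contingency is exact.
    Fully reproducible from ``config.seed``.
    """
    cfg = config.resolve()
    rng = np.random.default_rng(cfg.seed)
    # VAFs draw from their own stream so reconfiguring the VAF model never
    # perturbs the realized channels, genes or positions
    vaf_rng = np.random.default_rng([cfg.seed, 7])
    sig_names = list(cfg.signature_profiles)
    profiles = np.vstack([cfg.signature_profiles[n] for n in sig_names])
    samples = [f"T{i + 1:02d}" for i in range(cfg.n_samples)]
    group_of = {}
    for i, s in enumerate(samples):
        group_of[s] = (
            cfg.group_names[0] if i < cfg.group_sizes[0] else cfg.group_names[1]
        )

    genes, lengths, starts = _gene_layout(cfg.gene_model)
    driver_genes = {d.gene for d in cfg.drivers}
    bg_mask = np.array([g not in driver_genes for g in genes])
    bg_p = lengths * bg_mask
    bg_p = bg_p / bg_p.sum()

    alpha = np.asarray(cfg.exposure_concentration, dtype=float)
    if alpha.ndim == 1:
        exposures = rng.dirichlet(alpha, size=cfg.n_samples)
    else:
        if alpha.shape != (cfg.n_samples, len(sig_names)):
            raise ValueError(
                f"exposure_concentration shape {alpha.shape} != "
                f"({cfg.n_samples}, {len(sig_names)})"
            )
        exposures = np.vstack([rng.dirichlet(a) for a in alpha])
    lo, hi = cfg.load_range
    loads_mb = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_samples))
    if cfg.couple_load_to_platinum and cfg.platinum_name in sig_names:
        pi = sig_names.index(cfg.platinum_name)
        sorted_loads = np.sort(loads_mb)[::-1]
        if alpha.ndim == 2:
            # platinum-designated tumors take the top loads; the remaining
            # loads rotate across the other processes so each spans high
            # and low mutation burdens
            designated = alpha.argmax(axis=1)
            order = [i for i in range(cfg.n_samples) if designated[i] == pi]
            groups: dict[int, list[int]] = {}
            for i in range(cfg.n_samples):
                if designated[i] != pi:
                    groups.setdefault(int(designated[i]), []).append(i)
            pools = list(groups.values())
            gi = 0
            while any(pools):
                pool = pools[gi % len(pools)]
                if pool:
                    order.append(pool.pop(0))
                gi += 1
        else:
            order = list(np.argsort(-exposures[:, pi], kind="stable"))
        loads_mb[order] = sorted_loads
    n_mut = np.rint(loads_mb * cfg.exome_mb).astype(int)

    rows: list[tuple] = []
    origins: list[str] = []
    for i, s in enumerate(samples):
        origin_idx = rng.choice(len(sig_names), size=n_mut[i], p=exposures[i])
        gene_idx = rng.choice(len(genes), size=n_mut[i], p=bg_p)
        for o, gi in zip(origin_idx, gene_idx):
            ch = int(rng.choice(96, p=profiles[o]))
            ref, alt, context = _CHANNEL_PARTS[ch]
            if rng.random() < 0.5:  # report on the opposite strand
                context = reverse_complement(context)
                ref, alt = context[1], reverse_complement(alt)
            pos = int(starts[gi]) + int(rng.integers(lengths[gi])) + 1
            vaf = _draw_vaf(vaf_rng, sig_names[o], cfg.platinum_name, cfg.vaf_model)
            rows.append((s, "chr1", pos, ref, alt, round(vaf, 4), genes[gi],
                         context, "SNV"))
            origins.append(sig_names[o])

    driver_patients: dict[str, list[str]] = {}
    for d in cfg.drivers:
        members = [s for s in samples if group_of[s] == d.group]
        if d.n_patients is not None:
            chosen = members[: d.n_patients]
        elif d.prob is not None:
            chosen = [s for s in members if rng.random() < d.prob]
        else:
            raise ValueError(f"driver {d.gene}: set prob or n_patients")
        driver_patients[d.gene] = chosen
        gi = genes.index(d.gene)
        per_patient = (
            d.mutations_per_patient
            if isinstance(d.mutations_per_patient, tuple)
            else (d.mutations_per_patient,) * len(chosen)
        )
        for s, n_drv in zip(chosen, per_patient):
            for _ in range(n_drv):
                ch = int(rng.integers(96))
                ref, alt, context = _CHANNEL_PARTS[ch]
                pos = int(starts[gi]) + int(rng.integers(lengths[gi])) + 1
                vaf = _draw_vaf(vaf_rng, "driver", cfg.platinum_name, cfg.vaf_model)
                rows.append((s, "chr1", pos, ref, alt, round(vaf, 4), d.gene,
                             context, "SNV"))
                origins.append("driver")

    df = pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "vaf", "gene",
                 "context", "variant_class"],
    )
    df["origin"] = origins
    # group rows by sample (driver rows were appended last), keeping
    # per-sample order stable
    df["sample"] = pd.Categorical(df["sample"], categories=samples)
    df = df.sort_values("sample", kind="stable").reset_index(drop=True)
    df["sample"] = df["sample"].astype(str)
    origins = list(df.pop("origin"))
    table = MutationTable(df, group_of=group_of)
    truth = SyntheticTruth(
        exposures=pd.DataFrame(exposures, index=samples, columns=sig_names),
        origins=origins,
        drivers=tuple(cfg.drivers),
        driver_patients=driver_patients,
        vaf_model=cfg.vaf_model,
        seed=cfg.seed,
    )
    return table, truth


def write_cohort(
    table: MutationTable, truth: SyntheticTruth, out_dir: str | Path,
    gene_model: GeneModel | None = None,
) -> dict[str, Path]:
    """Write the MAF-like TSV, group TSV, gene-model TSV and truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "maf": out / "mutations.tsv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.json",
    }
    table.to_tsv(paths["maf"])
    pd.DataFrame(
        {"sample": list(table.group_of), "group": list(table.group_of.values())}
    ).to_csv(paths["groups"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    if gene_model is not None:
        paths["genes"] = out / "gene_model.tsv"
        pd.DataFrame(
            {"gene": list(gene_model.lengths), "coding_length": list(
                gene_model.lengths.values())}
        ).to_csv(paths["genes"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# fixture suite

FIXTURE_SEED = 20160121


def _tiny_fixture_table() -> MutationTable:
    """Three samples with hand-checkable counts: 5, 3 and 4 SNVs plus one
    indel in sample A (the indel is excluded from the 96-channel catalog)."""
    rows = [
        ("A", "chr1", 101, "C", "A", 0.15, "TP53", "CCA", "SNV"),
        ("A", "chr1", 205, "C", "A", 0.10, "TP53", "CCG", "SNV"),
        ("A", "chr1", 309, "G", "T", 0.05, "KRAS", "TGG", "SNV"),
        ("A", "chr1", 412, "C", "T", 0.45, "FBXW7", "ACG", "SNV"),
        ("A", "chr1", 500, "T", "C", 0.30, "REV3L", "ATA", "SNV"),
        ("A", "chr1", 550, "C", "CT", 0.40, "REV3L", None, "insertion"),
        ("B", "chr1", 120, "C", "A", 0.12, "TP53", "CCA", "SNV"),
        ("B", "chr1", 220, "T", "G", 0.55, "EPYC", "TTT", "SNV"),
        ("B", "chr1", 320, "A", "G", 0.60, "KRAS", "CAC", "SNV"),
        ("C", "chr1", 130, "C", "A", 0.08, "TP53", "CCG", "SNV"),
        ("C", "chr1", 230, "C", "G", 0.25, "CDKN2A", "TCA", "SNV"),
        ("C", "chr1", 330, "C", "T", 0.35, "FBXW7", "GCG", "SNV"),
        ("C", "chr1", 430, "G", "T", 0.18, "REV3L", "CGG", "SNV"),
    ]
    df = pd.DataFrame(
        rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "vaf", "gene",
                 "context", "variant_class"],
    )
    return MutationTable(df, group_of={"A": "sensitive", "B": "sensitive",
                                       "C": "resistant"})


def make_fixture_suite(out_dir: str | Path, seed: int = FIXTURE_SEED) -> dict[str, Path]:
    """Write the standard test fixtures.

    i.   ``cohort5``: the 18-sample cohort with all five planted signatures.
    ii.  ``null``: same structure, different seed, no planted drivers.
    iii. ``rev3l``: drivers planted so the REV3L-like patient-level
         contingency (3/7 sensitive vs 0/11 resistant) is exact.
    iv.  ``tiny``: a 3-sample worked example with hand-checkable counts
         (5, 3 and 4 SNVs; one indel).
    """
    out = Path(out_dir)
    paths: dict[str, Path] = {}

    cfg_i = SimulationConfig(seed=seed)
    table, truth = simulate_cohort(cfg_i)
    write_cohort(table, truth, out / "cohort5", gene_model=cfg_i.gene_model)
    paths["cohort5"] = out / "cohort5"

    cfg_ii = SimulationConfig(seed=seed + 1)
    table, truth = simulate_cohort(cfg_ii)
    write_cohort(table, truth, out / "null", gene_model=cfg_ii.gene_model)
    paths["null"] = out / "null"

    cfg_iii = SimulationConfig(
        seed=seed + 2,
        drivers=(
            DriverSpec(
                "REV3L", "sensitive", n_patients=3, mutations_per_patient=(2, 2, 1)
            ),
        ),
    )
    table, truth = simulate_cohort(cfg_iii)
    write_cohort(table, truth, out / "rev3l", gene_model=cfg_iii.gene_model)
    paths["rev3l"] = out / "rev3l"

    tiny = _tiny_fixture_table()
    (out / "tiny").mkdir(parents=True, exist_ok=True)
    tiny.to_tsv(out / "tiny" / "mutations.tsv")
    pd.DataFrame(
        {"sample": list(tiny.group_of), "group": list(tiny.group_of.values())}
    ).to_csv(out / "tiny" / "groups.tsv", sep="\t", index=False)
    paths["tiny"] = out / "tiny"
    return paths


def read_config(path: str | Path) -> SimulationConfig:
    """Parse a flat ``key = value`` simulation config file.

    Recognized keys: n_samples, group_sizes (e.g. ``7,11``), load_range,
    exome_mb, seed, clonal_weight. Unknown keys raise.
    """
    cfg = SimulationConfig()
    vm = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "n_samples":
            cfg.n_samples = int(value)
        elif key == "group_sizes":
            cfg.group_sizes = tuple(int(v) for v in value.split(","))
        elif key == "load_range":
            cfg.load_range = tuple(float(v) for v in value.split(","))
        elif key == "exome_mb":
            cfg.exome_mb = float(value)
        elif key == "seed":
            cfg.seed = int(value)
        elif key == "clonal_weight":
            vm["clonal_weight"] = float(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    if vm:
        cfg.vaf_model = VafModel(**vm)
    return cfg
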