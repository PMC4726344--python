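"""End-to-end cohort analysis: catalog, signatures, drivers, enrichment.

``run_pipeline`` chains the module stages in cohort-report order — parse the
mutation table, build the 96-channel catalog and summary statistics, select
the number of signatures and extract them, annotate against the reference
set and score the platinum profile, VAF-filter, scan for significantly
mutated genes overall and per response group, and test group enrichment —
writing every stage's table plus a human-readable summary and a run
manifest. Output is a pure function of (inputs, parameters, seed).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import (
    DEFAULT_EXOME_MB,
    Catalog96,
    MutationTable,
    build_catalog,
    mutation_rate,
    read_groups,
    read_maf,
    summary_statistics,
    titv_ratio,
    vaf_spectrum,
)
from .recurrence import (
    GeneModel,
    filter_variants,
    group_enrichment,
    subgroup_discovery,
)
from .signatures import (
    SignatureSelector,
    annotate_signatures,
    load_reference_signatures,
    platinum_score,
)


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineParams:
    k_min: int = 1
    k_max: int = 10
    n_bootstrap: int = 100
    stability_min: float = 0.8
    annotate_min_cos: float = 0.8
    vaf_min: float = 0.2
    fdr_max: float = 0.2
    min_patients: int = 2
    exome_mb: float = DEFAULT_EXOME_MB


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def run_pipeline(
    maf: str | Path,
    genes: str | Path,
    groups: str | Path,
    out: str | Path,
    refs: str | Path | None = None,
    params: PipelineParams | None = None,
    seed: int = 0,
) -> Path:
    """Run the full analysis; returns the report directory."""
    params = params or PipelineParams()
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    maf, genes, groups = Path(maf), Path(genes), Path(groups)

    try:
        group_of = read_groups(groups)
        table = read_maf(maf, groups=group_of)
        gene_model = GeneModel.read_tsv(genes)
        reference = load_reference_signatures(refs)
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort
        raise PipelineError("parse", str(exc)) from exc
    _log("parse", f"{table.n_records} records, {len(table.sample_ids)} samples")

    try:
        catalog = build_catalog(table)
        catalog.to_tsv(out_dir / "catalog.tsv")
        stats = summary_statistics(table, params.exome_mb, params.vaf_min)
        stats.to_csv(out_dir / "summary_stats.tsv", sep="\t")
        _, rate_median = mutation_rate(table, params.exome_mb)
        _, titv_median = titv_ratio(table, per_sample=True)
        spectrum = vaf_spectrum(table, params.vaf_min)
    except Exception as exc:
        raise PipelineError("catalog", str(exc)) from exc
    _log("catalog", f"median rate {rate_median:.1f}/Mb, median Ti/Tv {titv_median:.2f}")

    try:
        selector = SignatureSelector(
            k_min=params.k_min,
            k_max=params.k_max,
            stability_min=params.stability_min,
            n_bootstrap=params.n_bootstrap,
            random_state=seed,
        ).fit(catalog)
        selector.curve_.to_csv(out_dir / "stability_curve.tsv", sep="\t", index=False)
        best = selector.best_
        labels = annotate_signatures(best, reference, params.annotate_min_cos)
        sig_names = [
            f"S{i + 1}:{label}" for i, (label, _) in enumerate(labels)
        ]
        pd.DataFrame(
            best.profiles_.T, index=list(catalog.channel_labels), columns=sig_names
        ).rename_axis("channel").to_csv(out_dir / "signatures.tsv", sep="\t")
        pd.DataFrame(
            best.exposures_, index=catalog.sample_ids, columns=sig_names
        ).rename_axis("sample").to_csv(out_dir / "exposures.tsv", sep="\t")
        annotations = pd.DataFrame(
            {
                "signature": sig_names,
                "label": [l for l, _ in labels],
                "cosine": [c for _, c in labels],
                "platinum_score": [platinum_score(p) for p in best.profiles_],
                "stability": best.per_signature_stability_,
            }
        )
        annotations.to_csv(out_dir / "signature_annotations.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("signatures", str(exc)) from exc
    _log("signatures", f"selected k={selector.k_} (stability {best.stability_:.3f})")

    try:
        filtered = filter_variants(table, params.vaf_min)
        discovery = subgroup_discovery(
            filtered,
            gene_model,
            fdr_max=params.fdr_max,
            min_patients=params.min_patients,
            exome_mb=params.exome_mb,
        )

        def _smg_frame(results):
            return pd.DataFrame(
                [
                    (r.gene, r.n_mutated_patients, r.n_mutations, r.p_value,
                     r.q_value, r.scope)
                    for r in results
                ],
                columns=["gene", "patients", "mutations", "p", "q", "scope"],
            )

        _smg_frame(discovery.overall).to_csv(
            out_dir / "smg_overall.tsv", sep="\t", index=False
        )
        for grp, results in discovery.by_group.items():
            _smg_frame(results).to_csv(
                out_dir / f"smg_{grp}.tsv", sep="\t", index=False
            )
        pd.DataFrame(
            [(grp, g) for grp, gs in discovery.subgroup_only.items() for g in gs],
            columns=["group", "gene"],
        ).to_csv(out_dir / "smg_subgroup_only.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("smg", str(exc)) from exc
    n_sig = len(discovery.overall) + sum(
        len(v) for v in discovery.subgroup_only.values()
    )
    _log("smg", f"{n_sig} significant gene(s) across scopes")

    try:
        group_names = list(dict.fromkeys(group_of.values()))  # input order
        candidates = sorted(
            {r.gene for r in discovery.overall}
            | {r.gene for rs in discovery.by_group.values() for r in rs}
        )
        enrich_rows = []
        for gene in candidates:
            res = group_enrichment(filtered, gene, group_names[0], group_names[1])
            (a11, a12), (a21, a22) = res.table
            enrich_rows.append((gene, a11, a12, a21, a22, res.p_two_sided))
        enrichment = pd.DataFrame(
            enrich_rows, columns=["gene", "a11", "a12", "a21", "a22", "p"]
        )
        enrichment.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("enrichment", str(exc)) from exc
    _log("enrichment", f"{len(enrichment)} gene(s) tested")

    _write_report(
        out_dir, stats, rate_median, titv_median, spectrum, selector,
        annotations, discovery, enrichment, group_names,
    )
    manifest = {
        "tool": "platsig",
        "version": __version__,
        "seed": seed,
        "inputs": {
            "maf": _digest(maf),
            "genes": _digest(genes),
            "groups": _digest(groups),
            "refs": _digest(Path(refs)) if refs else "bundled",
        },
        "params": asdict(params),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def _write_report(
    out_dir, stats, rate_median, titv_median, spectrum, selector,
    annotations, discovery, enrichment, group_names,
) -> None:
    lines = ["platsig cohort report", "=" * 21, ""]
    lines.append(f"Samples: {len(stats)}")
    lines.append(f"Median mutation rate: {rate_median:.1f} mutations/Mb")
    lines.append(f"Median Ti/Tv: {titv_median:.2f}")
    lines.append(
        f"SNVs below VAF {spectrum.threshold:g}: {100 * spectrum.overall:.1f}%"
    )
    for sub, frac in spectrum.by_substitution.items():
        lines.append(f"  {sub}: {100 * frac:.1f}%")
    lines.append("")
    lines.append(f"Selected number of signatures: {selector.k_}"
                 + (" (no k reached the stability threshold)" if selector.flagged_ else ""))
    lines.append("Stability curve:")
    for row in selector.curve_.itertuples(index=False):
        lines.append(
            f"  k={row.k}: stability {row.stability:.3f}, "
            f"KL error {row.reconstruction_error:.1f}"
        )
    lines.append("")
    lines.append("Signatures (label, cosine to reference, platinum score):")
    for row in annotations.itertuples(index=False):
        lines.append(
            f"  {row.signature}: cos={row.cosine:.3f}, "
            f"platinum={row.platinum_score:.3f}, stability={row.stability:.3f}"
        )
    lines.append("")
    lines.append("Significantly mutated genes (q < FDR threshold):")
    for scope, results in [("overall", discovery.overall)] + list(
        discovery.by_group.items()
    ):
        shown = ", ".join(f"{r.gene} (p={r.p_value:.2g})" for r in results) or "none"
        lines.append(f"  {scope}: {shown}")
    for grp, gs in discovery.subgroup_only.items():
        lines.append(f"  {grp} only: {', '.join(gs) or 'none'}")
    lines.append("")
    lines.append(f"Group enrichment ({group_names[0]} vs {group_names[1]}):")
    for row in enrichment.itertuples(index=False):
        lines.append(
            f"  {row.gene}: [[{row.a11},{row.a12}],[{row.a21},{row.a22}]] "
            f"p={row.p:.2g}"
        )
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
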