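"""End-to-end orchestration: simulate -> filter -> burden -> spectra ->
circular-DNA analysis, with all artifacts written as TSV/JSON.

Every stage is deterministic given the seed; thresholds are surfaced in
the config and the report records each filter's removal count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import io as io_mod
from .eccdna import analyze_circles
from .filters import FilterConfig, run_filter_ladder
from .model import VariantType
from .simulate import GeneratorConfig, SyntheticCohort, generate_cohort
from .spectra import build_sbs_spectrum, classify_indels_svs, cosine_similarity, lr_spectrum_test

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_study"]


@dataclasses.dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    scale: float = 1.0  # multiplies duplex bases per sample
    filter_config: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    write_sample_tables: bool = True


def simulate_study(seed: int = 0, scale: float = 1.0) -> SyntheticCohort:
    """Generate the standard matched blood/sperm cohort (6 + 6 samples)."""
    bases = int(1_250_000_000 * scale)
    blood = GeneratorConfig.blood(seed=seed, duplex_bases_per_sample=bases)
    sperm = GeneratorConfig.sperm(seed=seed, duplex_bases_per_sample=bases)
    return generate_cohort([blood, sperm], seed=seed)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-study pipeline and write the report bundle.

    Returns the report dictionary (also written to report.json).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    cohort = simulate_study(seed=config.seed, scale=config.scale)
    panel = cohort.panel
    io_mod.write_panel(panel, outdir / "panel.bed", outdir / "panel.fa")
    if config.write_sample_tables:
        for sid, sample in cohort.samples.items():
            io_mod.write_variant_table(sample.calls, outdir / f"{sid}.variants.tsv")
            io_mod.write_alignment_geometry(sample.geometry, outdir / f"{sid}.geometry.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataclasses.asdict(cohort.truth), fh, default=_json_default)

    filtered, report = run_filter_ladder(cohort.calls_by_sample(), config.filter_config)
    for name, n in sorted(report.removed.items()):
        logger.info("filter %s removed %d calls", name, n)

    burden_rows = []
    results_by_tissue: dict[str, list] = {"blood": [], "sperm": []}
    for sid, calls in filtered.items():
        sample = cohort.samples[sid]
        res = burden_mod.sample_burden(sid, sample.tissue, calls, sample.depth, panel)
        results_by_tissue[sample.tissue].append(res)
        burden_rows.append(
            {
                "sample_id": sid,
                "tissue": sample.tissue,
                "duplex_bases": res.duplex_bases,
                **{f"n_{k}": v for k, v in res.counts.items()},
                **{f"mf_{k}": burden_mod.format_mf(v) for k, v in res.mf.items()},
                "cpg_ct_fraction": res.cpg_ct_fraction,
            }
        )
    burden_df = pd.DataFrame(burden_rows).sort_values("sample_id")
    burden_df.to_csv(outdir / "burden.tsv", sep="\t", index=False)

    spectra_stats: dict = {}
    sbs6 = {}
    for tissue in ("blood", "sperm"):
        snvs = [
            c
            for sid, calls in filtered.items()
            if cohort.samples[sid].tissue == tissue
            for c in calls
            if c.vtype is VariantType.SNV
        ]
        spec6 = build_sbs_spectrum(snvs, panel, kind="sbs6")
        spec96 = build_sbs_spectrum(snvs, panel, kind="sbs96")
        sbs6[tissue] = spec6
        pd.DataFrame(
            {"context": spec96.labels, "count": spec96.counts}
        ).to_csv(outdir / f"{tissue}.sbs96.tsv", sep="\t", index=False)
    g, df, p, _ = lr_spectrum_test(sbs6["blood"].counts, sbs6["sperm"].counts)
    spectra_stats["sbs6_blood_vs_sperm"] = {"G": g, "df": df, "p": p}
    spectra_stats["sbs6_cosine_blood_sperm"] = cosine_similarity(
        sbs6["blood"].proportions, sbs6["sperm"].proportions
    )

    circles_report = {}
    for tissue in ("blood", "sperm"):
        sids = [s for s in filtered if cohort.samples[s].tissue == tissue]
        # large-insertion analysis bypasses the VAF gate: reuse the
        # collapsed pre-gate calls from the raw tables
        from .filters import collapse_clonal

        pooled_calls = []
        pooled_geom = []
        bases = 0
        for sid in sids:
            unique, _ = collapse_clonal(cohort.samples[sid].calls)
            pooled_calls.extend(unique)
            pooled_geom.extend(cohort.samples[sid].geometry)
            bases += cohort.samples[sid].depth.total_duplex_bases
        jcs, res = analyze_circles(
            pooled_calls,
            panel,
            pooled_geom,
            median_insert=233,
            duplex_bases=bases,
            vaf_max=config.filter_config.vaf_max,
        )
        circles_report[tissue] = {
            "n_insertions_gt20": res.n_insertions_gt20,
            "n_with_junction": res.n_with_junction,
            "n_candidates": len(res.candidate_microdnas),
            "n_candidates_vaf_filtered": res.candidate_count_vaf_filtered,
            "candidate_frequency": res.candidate_frequency,
            "binomial_k": res.n_fragments_below_median,
            "binomial_n": sum(
                len(jc.supporting_fragments) for jc in res.subset_below_median
            ),
            "binomial_p": res.binomial_p,
            "classifications": {
                cls: sum(jc.classification == cls for jc in jcs if jc.has_DA_junction)
                for cls in ("circle_consistent", "tandem_duplication", "ambiguous")
            },
        }
        bed_rows = [
            f"{jc.variant_key[1]}\t{jc.variant_key[2]}\t{jc.variant_key[2] + jc.allele_length}\t{jc.variant_key[0]}"
            for jc in res.candidate_microdnas
        ]
        (outdir / f"{tissue}.candidate_circles.bed").write_text(
            "\n".join(bed_rows) + ("\n" if bed_rows else "")
        )

    full_report = {
        "seed": config.seed,
        "scale": config.scale,
        "filters": report.to_dict(),
        "burden": burden_rows,
        "pooled_mf": {
            tissue: {
                k: burden_mod.pooled_mf(results_by_tissue[tissue], k)
                for k in ("SNV", "MNV", "indel", "SV")
            }
            for tissue in ("blood", "sperm")
            if results_by_tissue[tissue]
        },
        "spectra": spectra_stats,
        "circles": circles_report,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(full_report, fh, indent=2, default=_json_default)
    return full_report
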