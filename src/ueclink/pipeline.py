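"""End-to-end synthetic linkage run: generate, degrade, resolve, link,
assemble, evaluate.  This is the orchestration the acceptance checks and
the worked examples use; every step is also callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import assembly, deterministic, generate, ingest, linkage
from .config import GeneratorConfig

__all__ = ["run_pipeline", "write_outputs", "PipelineResult"]


@dataclass
class PipelineResult:
    config: GeneratorConfig
    records: pd.DataFrame  # validated records, pipeline view
    truth: dict
    validation_report: ingest.ValidationReport
    entity_map_deterministic: deterministic.EntityMap
    step_counts: pd.DataFrame
    comparisons: pd.DataFrame  # scored candidate pairs
    model: linkage.FellegiSunterResults
    curve: linkage.ThresholdCurve
    links: pd.DataFrame
    entity_map: deterministic.EntityMap  # after probabilistic adjudication
    platform: pd.DataFrame
    final_entity_map: deterministic.EntityMap
    report: assembly.AssemblyReport
    evaluation: assembly.LinkageEvaluation


def run_pipeline(
    config: GeneratorConfig,
    *,
    target_specificity: float = 0.999,
    name_similarity_threshold: float = 0.8,
) -> PipelineResult:
    """Run the whole linkage exercise on a freshly generated synthetic
    platform and evaluate the result against the generator's ground truth."""
    persons = generate.generate_population(config)
    events = generate.generate_activity(persons, config)
    raw = generate.degrade_records(events, config)
    truth = generate.ground_truth(raw)

    sites = [f"SITE{j:02d}" for j in range(config.n_sites)]
    clean, vreport = ingest.validate_records(
        generate.strip_truth(raw), ingest.default_code_sets(sites)
    )

    emap_det, step_counts = deterministic.resolve(clean)

    amb = clean[(clean["source"] == "AMB") & (clean["conveyed"] == True)]  # noqa: E712
    ed = clean[clean["source"] == "ED"]
    ip = clean[clean["source"] == "IP"]
    pairs = linkage.generate_candidates(amb, ed, ip)
    hosp = pd.concat([ed, ip], ignore_index=True)
    comparisons = linkage.compare_pairs(
        pairs, amb, hosp, name_similarity_threshold=name_similarity_threshold
    )
    model = linkage.FellegiSunterModel(
        comparisons, name_similarity_threshold=name_similarity_threshold
    ).fit()
    comparisons = comparisons.copy()
    comparisons["weight"] = model.score(comparisons)
    curve = linkage.select_threshold(comparisons, target_specificity=target_specificity)
    links, emap = linkage.adjudicate(
        comparisons, curve.chosen_threshold, emap_det, clean
    )

    platform, final_map, report = assembly.assemble(
        clean, emap, config.period_start, config.period_end
    )
    evaluation = assembly.evaluate_against_truth(final_map, truth)

    result = PipelineResult(
        config=config,
        records=clean,
        truth=truth,
        validation_report=vreport,
        entity_map_deterministic=emap_det,
        step_counts=step_counts,
        comparisons=comparisons,
        model=model,
        curve=curve,
        links=links,
        entity_map=emap,
        platform=platform,
        final_entity_map=final_map,
        report=report,
        evaluation=evaluation,
    )
    return result


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write every pipeline artefact as plain files under ``outdir``:
    entity assignments with step provenance, the step-count table, the
    scored candidate pairs, the fitted model (JSON), the threshold curve
    (CSV and plot), the accepted links, per-source platform CSVs and the
    assembly report."""
    import json
    from pathlib import Path

    from . import generate, linkage

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    result.final_entity_map.to_frame().to_csv(outdir / "assignments.csv", index=False)
    result.step_counts.to_csv(outdir / "step_counts.csv")
    result.comparisons.to_csv(outdir / "candidate_pairs.csv", index=False)

    model = result.model
    (outdir / "model.json").write_text(
        json.dumps(
            {
                "fields": list(model.fields),
                "m": model.m.tolist(),
                "u": model.u.tolist(),
                "p": model.p,
                "agreement_weight": model.agreement_weight.tolist(),
                "disagreement_weight": model.disagreement_weight.tolist(),
                "log_likelihood_trace": model.loglik_trace.tolist(),
                "converged": model.converged,
            },
            indent=2,
        )
    )

    curve = result.curve
    curve.table.to_csv(outdir / "threshold_curve.csv", index=False)
    linkage.plot_threshold_curve(curve, path=outdir / "threshold_curve.png")
    result.links.to_csv(outdir / "accepted_links.csv", index=False)

    generate.write_records(result.platform, outdir / "platform", config=result.config)
    result.report.counts.to_csv(outdir / "assembly_report.csv")
    (outdir / "assembly_report.txt").write_text(result.report.to_text() + "\n")
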