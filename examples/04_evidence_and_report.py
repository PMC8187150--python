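"""Secondary evidence and final report composition.

Beyond the MVP score, a candidate match is reviewed by hierarchical
clustering and MDS of the test sample against the disorder's reference
cases and controls.  A 50% mosaic sample lands between the two reference
clouds ("intermediate" evidence) and is reported inconclusive even though
its score alone might look decisive.
"""

import episig as ep

cohort = ep.simulate_cohort(ep.SimulationConfig(
    n_background_probes=2000,
    disorders=(ep.DisorderSim("SYND_A", 100, 0.2, 12, 2),),
    n_controls=30, n_test_controls=2,
    mosaic_samples=(ep.MosaicSim("SYND_A", 0.5),),
    seed=23,
))
kdb = ep.build_kdb(cohort.beta, cohort.sheet,
                   annotation=cohort.annotation, cv_folds=6, seed=23)

truth = cohort.truth
full_case = truth.loc[truth["group"] == "test_case", "sample_id"].iloc[0]
mosaic = truth.loc[truth["group"] == "mosaic", "sample_id"].iloc[0]

for sid in (full_case, mosaic):
    report = ep.analyze_sample(cohort.beta, cohort.sheet, kdb, sid,
                               annotation=cohort.annotation)
    print("=" * 60)
    print(ep.render_text(report))
    for d, ev in report.cluster_evidence.items():
        print(f"cluster evidence {d}: {ev.call} "
              f"(margin {ev.margin:+.2f}, assigned {ev.assignment})")
# The full case is POSITIVE (score ~1, clusters with cases, margin near +1);
# the 50% mosaic is flagged: its profile sits between cases and controls.
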