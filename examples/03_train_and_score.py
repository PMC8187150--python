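"""Train one-vs-rest classifiers and score held-out samples with MVP scores.

Each disorder gets a linear SVM on its signature probes (positive class =
its cases; negative class = other disorders' cases plus controls) and a
Platt link fitted on out-of-fold decision values, mapping decisions to
MVP scores in [0, 1].  Scores > 0.5 are positive, < 0.1 negative, and the
band [0.1, 0.5] inconclusive.
"""

import episig as ep

cohort = ep.simulate_cohort(ep.SimulationConfig(
    n_background_probes=3000,
    disorders=(ep.DisorderSim("SYND_A", 80, 0.15, 12, 3),
               ep.DisorderSim("SYND_B", 80, 0.15, 12, 3)),
    n_controls=40, n_test_controls=4, seed=19,
))
kdb = ep.build_kdb(cohort.beta, cohort.sheet, cv_folds=6, seed=19)

truth = cohort.truth.set_index("sample_id")
held_out = truth[truth["group"].isin(["test_case", "test_control"])]
print(f"{'sample':<22s} {'truth':<12s} " +
      " ".join(f"{d:>8s}" for d in sorted(kdb.classifiers)))
for sid, row in held_out.iterrows():
    res = ep.score_sample(kdb.classifiers, cohort.beta.sample(sid), sid)
    label = row["disorder_id"] or "control"
    scores = " ".join(f"{res.scores[d]:8.3f}" for d in sorted(res.scores))
    print(f"{sid:<22s} {label:<12s} {scores}")
# Held-out cases score near 1 for their own disorder and near 0 elsewhere;
# held-out controls score near 0 for every disorder.
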