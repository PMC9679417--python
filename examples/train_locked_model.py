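"""Train the locked stacked classifier and score it on each test bucket.

Fits the five-family stack once on the pre-1997 development pool and then
evaluates the same frozen model on every chronological bucket, printing the
seven metrics per bucket.  Under the stationary generator all buckets score
similarly; the spread reflects bucket-level sampling noise only.
"""

from adaptabench import fast_config, make_dilist_fixture, make_split_plan, run_locked

split = make_split_plan(make_dilist_fixture(seed=0))
model, reports = run_locked(split, fast_config(seed=0))

print(f"locked model: {len(model.learners)} base learners selected, "
      f"internal validation MCC {model.internal_validation_mcc:.3f}")
header = f"{'bucket':>10} {'AUC':>6} {'acc':>6} {'sens':>6} {'spec':>6} {'F1':>6} {'MCC':>6} {'BA':>6}"
print(header)
for i, rep in enumerate(reports, 1):
    m = rep.as_dict()
    print(
        f"{split.bucket_spec.label(i - 1):>10} "
        + " ".join(f"{m[k]:6.3f}" for k in ("auc", "accuracy", "sensitivity",
                                            "specificity", "f1", "mcc", "ba"))
    )
print("MCC is the primary metric: 1 = perfect, 0 = chance, -1 = inverted.")
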