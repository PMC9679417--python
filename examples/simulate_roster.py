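"""Generate a synthetic compound roster and inspect its time-split structure.

Builds the audit-shaped fixture (1,002 drugs: 753 pre-1997 development
drugs plus five chronological test buckets) and prints the composition of
each part.  The printed bucket sizes and +/- label counts are fixed by
construction; descriptor values vary with the seed.
"""

from adaptabench import make_dilist_fixture, make_split_plan

roster = make_dilist_fixture(seed=0)
split = make_split_plan(roster)

print(f"roster: {len(roster)} drugs x {roster.n_descriptors} descriptors")
print(f"locked development pool (< {split.cutoff_year}): {len(split.locked_pool)} drugs")
print(f"test pool (>= {split.cutoff_year}): {len(split.test_pool)} drugs")
for i, bucket in enumerate(split.buckets, 1):
    pos = int(bucket.labels.sum())
    print(
        f"  bucket {i} ({split.bucket_spec.label(i - 1)}): "
        f"{len(bucket)} drugs ({pos}+/{len(bucket) - pos}-)"
    )
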