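"""Simulate a small experiment and push it through the full pipeline.

Generates reads for the three-group demonstration design with PCR
duplicates and sequencing chimeras injected at known rates, removes clones
via the degenerate VBBN tags, demultiplexes over all tag combinations and
prints the per-class chimera percentages.
"""

from quadchim import (
    DemuxParams,
    SimParams,
    build_three_group_scheme,
    demultiplex_run,
    remove_clones,
    simulate_experiment,
    summarize_chimeras,
)

scheme = build_three_group_scheme()
params = SimParams(
    reads_per_sample=500,
    dup_rate=0.10,
    pcr_chimera_rate=0.01,
    seq_chimera_rate=0.01,
    index_hop_rate=0.002,
    error_rate=0.001,
    seed=7,
)
run = simulate_experiment(scheme, params)
print(f"simulated {run.n_reads} read pairs")
print("truth events:", run.truth["event"].value_counts().to_dict())

filtered = {}
removed = 0
for gid, pairs in run.reads_by_group.items():
    kept, n = remove_clones(pairs)
    filtered[gid] = kept
    removed += n
print(f"clone filter removed {removed} duplicates "
      f"(truth: {(run.truth['event'] == 'pcr_duplicate').sum()})")

counts, _ = demultiplex_run(filtered, scheme, DemuxParams(max_mismatch=1))
summary = summarize_chimeras(counts, scheme)
by_class = summary.groupby("chimera_class", observed=True)["reads"].sum()
total = by_class.sum()
print("\nreads by class after demultiplexing (k=1):")
for cls, reads in by_class.items():
    print(f"  {cls:8s} {reads:7d}  ({100 * reads / total:.2f}%)")
print(
    "\nThe non-genuine percentages measure artifact formation: within-group "
    "recombination lands in type I, cross-group events in types II-IV."
)
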