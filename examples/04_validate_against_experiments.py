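"""Score a model against an experiment table.

Generates an oracle-labelled experiment set for the autocrine motif (the
expectations are computed by exhaustive enumeration, so the model must score
100%), then corrupts 20% of the records to show how the report pinpoints
failing measurements.
"""

from qnsim import score_experiments, synthetic

net = synthetic.make_motif("tnf_autocrine", max_level=2)

records, _ = synthetic.generate_experiment_set(net, 10, seed=42)
report = score_experiments(net, records)
print("uncorrupted oracle-labelled set:")
print(report.to_text())

records, corrupted = synthetic.generate_experiment_set(
    net, 10, seed=42, corrupt_fraction=0.2
)
report = score_experiments(net, records)
print(f"\nafter corrupting records {corrupted}:")
print(report.to_text())

# The per-measurement verdicts (predicted vs expected, with the baseline for
# directional expectations) are what lets a modeler trace each failure to a
# specific mechanism in the network.
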