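"""Score pipeline predictions against simulated ground truth.

Simulates a dataset with 20% decoy reads, scores two idealised pipelines —
one that copies the truth (accuracy and F1 both 100%) and one that rejects
every read (its true negatives equal the decoy read count) — and prints
the report percentages used when comparing pipelines against external
validation (e.g. RT-qPCR): a pipeline that called 31 molecules of which 17
were validated has %FP = (1 - 17/31) x 100 = 45.16.
"""

from srnakit import (
    RnaClass,
    SimConfig,
    accuracy,
    f1,
    make_fixture_records,
    pct_false_negative,
    pct_false_positive,
    score_against_truth,
    simulate,
)

refs = make_fixture_records(n_mirna=40, n_pirna=20, n_novel=10,
                            n_chromosomes=4, rng_seed=5)
config = SimConfig(total_reads=20_000, pct_known_mirna=40,
                   pct_novel_mirna=20, pct_pirna=20, min_depth=5,
                   distribution=("poisson", 30.0), rng_seed=6)
_, truth = simulate(config, refs)

labels = dict(zip(truth["molecule_name"], truth["rna_class"]))
weights = dict(zip(truth["molecule_name"], truth["expression_count"]))

perfect = score_against_truth(labels, labels, weights)
print(f"truth-copy predictor:  accuracy {accuracy(perfect):.2f}%  F1 {f1(perfect):.2f}%")

reject_all = {name: RnaClass.OTHER for name in labels}
rejecting = score_against_truth(reject_all, labels, weights)
print(f"reject-all predictor:  TP {rejecting.tp}  TN {rejecting.tn} "
      f"(= decoy reads)  FN {rejecting.fn}")

print(f"%FP for 17 validated of 31 called:    {pct_false_positive(31, 17)}")
print(f"%FN for 12 recovered of 31 validated: {pct_false_negative(12, 31)}")
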