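"""Detect modules with the dynamic tree cut and check planted recovery.

Runs the full Gamma pipeline (calibration, cosine similarity, soft
threshold, TOM, UPGMA, dynamic cut) on the default planted benchmark and
compares the detected modules with the planted ground truth by the
adjusted Rand index (1 = identical partitions, 0 = chance agreement).
"""

from sklearn.metrics import adjusted_rand_score

from gcncalib import SyntheticSpec, generate_expression, run_gamma

spec = SyntheticSpec(seed=0)  # 1000 genes, 50 samples, 5 x 150-gene modules
expr, truth = generate_expression(spec)

result = run_gamma(expr)
assignment = result.assignment
print(f"chosen beta: {result.provenance['chosen_beta']}")
print(f"detected modules: {assignment.n_modules}")
print(f"unassigned genes: {100 * assignment.unassigned_fraction():.1f}%")

planted = truth.labels_array(expr.gene_ids)
detected = assignment.as_array(expr.gene_ids)
ari = adjusted_rand_score(planted, detected)
print(f"adjusted Rand index vs planted modules: {ari:.3f}")
print(
    "\nAn ARI above 0.8 means the five planted co-expression modules were\n"
    "recovered almost exactly; unassigned genes are the simulated background\n"
    "that belongs to no module."
)
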