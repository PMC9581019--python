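"""Score modules by hypergeometric term enrichment (Q and Q-bar).

Generates a benchmark with planted-enriched annotation terms, runs the
Gamma pipeline, and scores every detected module: six hypergeometric
test batteries (BP/CC/MF x over/under), five smallest p-values kept, and
module quality Q = -(mean log10 p).  Q-bar is the average over modules.
"""

from gcncalib import generate_benchmark, run_gamma

expr, anno, truth = generate_benchmark(seed=0)
result = run_gamma(expr, None, anno)
report = result.quality

print(f"{'module':>6} {'size':>5} {'Q':>7}   top term (direction, p)")
for mod in report.modules:
    best = mod.retained[0]
    print(
        f"{mod.label:>6} {mod.size:>5} {mod.q:>7.2f}   "
        f"{best.term_id} ({best.direction}, p={best.p_value:.2e})"
    )
print(f"\npipeline average quality Q_bar = {report.q_bar:.2f}")
print(
    "\nEach module's top term should be its planted term (TERM:M<k>_0): the\n"
    "annotation was generated with 90% precision/recall against the planted\n"
    "membership, so a correct module detection makes the planted term's\n"
    "over-representation p-value astronomically small (Q of ~30 means the\n"
    "five best p-values average 1e-30 on the log scale). Decoy terms are\n"
    "uniform draws and never rank first."
)
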