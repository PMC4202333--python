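"""Power of the exact test at the study's annotated sample sizes.

How often would the exact test detect a true absolute difference delta in
the in-category proportion between the autosomal set (n1 = 1,073 annotated
genes) and a comparison set — the X-linked set (n2 = 567) or the much
smaller X-hemizygous set (n2 = 95)? Each cell simulates 2,000 replicate
datasets at the pooled N-mt baseline proportion.

The small hemizygous set drives the study's caveat: a 5-point shift there
is detected only rarely, and roughly a 10-point shift is needed before
power becomes appreciable.
"""

import numpy as np

from cytonuclear import simulate_power

p0 = 301 / 1735  # pooled N-mt proportion among annotated genes
print(f"baseline proportion p0 = {p0:.4f}, alpha = 0.05, 2,000 reps/cell\n")
print("n2     delta   power   mc_se")
streams = iter(np.random.SeedSequence(11).spawn(6))
for n2 in (567, 95):
    for delta in (0.02, 0.05, 0.10):
        est = simulate_power(
            1073, n2, p0, delta, n_reps=2000,
            seed=np.random.default_rng(next(streams)),
        )
        print(f"{n2:4d}   {delta:.2f}   {est.power:.3f}   {est.mc_se:.3f}")
print(
    "\nPower rises with both the effect size and the comparison-set size;\n"
    "the 95-gene hemizygous set has little power below a ~10-point shift."
)
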