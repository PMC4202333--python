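"""Parameter recovery on synthetic data with a planted enrichment effect.

Generates an annotation table at the study's set sizes with a two-fold
multiplicative enrichment of N-mt genes on the X-linked set (all other
effects null), then runs the analysis. The recovered X-linked ratio is
attenuated below the planted rho = 2 because the expected count uses the
pooled proportion, which the enriched set itself inflates: the analytic
value is rho / (1 + w (rho - 1)) with w the enriched set's share of
annotated genes (~0.33 here, giving ~1.5).
"""

from cytonuclear import GeneSet, SyntheticConfig, run_analysis

config = SyntheticConfig(effects={"N-mt": {GeneSet.X_LINKED: 2.0}}, seed=7)
report = run_analysis(synthetic_config=config, n_boot=10_000, seed=7)

summary = report.count_summary
w = summary.n_annotated[GeneSet.X_LINKED] / summary.total_annotated
print(f"planted effect rho = 2.0 on X-linked N-mt; attenuation weight w = {w:.3f}")
print(f"analytic attenuated ratio = {2.0 / (1 + w * 1.0):.3f}\n")

est = report.ratio_estimates["N-mt"][GeneSet.X_LINKED]
print(
    f"recovered X-linked N-mt ratio {est.ratio:.3f} "
    f"95% CI [{est.ci_low:.3f}, {est.ci_high:.3f}]"
)
result = report.exact_tests["N-mt"]
print(f"exact 2x3 test: p = {result.p_value:.3g}")
print(
    "\nThe CI excludes 1 and the exact test rejects decisively: an effect\n"
    "of this size at these sample sizes is readily detectable."
)
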