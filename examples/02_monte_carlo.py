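"""Monte Carlo propagation of the assigned probability distributions.

Samples every input of the packaged budget from its assigned distribution
(normal, rectangular or triangular), evaluates the content model per trial,
and summarizes the output distribution including its empirical coverage
factor and the trial-count convergence study.
"""

from mubudget import convergence_study, mcs_text_summary, mpz_budget, run_mcs, summarize

budget = mpz_budget()

M = 1_000_000
samples = run_mcs(budget, M, seed=0)
result = summarize(samples, seed=0)
print(mcs_text_summary(result))
print()
print(
    "The output distribution is effectively normal (skewness near 0), so the\n"
    "empirical coverage factor sits just below the Gaussian 1.96 and the\n"
    "sample sd agrees with the GUM combined uncertainty to a few tenths of\n"
    "a percent."
)
print()

conv = convergence_study(budget, [10_000, 100_000, 1_000_000], seed=0)
print(conv.to_string(index=False))
print()
print(
    "Between 1e5 and 1e6 trials the 95% interval width changes by less than\n"
    "0.01 content-%, i.e. the simulation has stabilized."
)
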