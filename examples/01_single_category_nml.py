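"""Judge enrichment of a single category with the NML Bayes factor.

A tiny study: N=6 reference genes, n=3 selected; the category holds s=2
genes of which t=1 is selected.  With only one category the mixture and
rank-based estimators cannot be fitted, but the normalized-maximum-
likelihood ratio still approximates the Bayes factor, and a supplied null
prior converts it into a local FDR.
"""

from enrichlfdr import nml_constant, nml_ratio, nmle_lfdr, HypothesisSet

t, s, n, N = 1, 2, 3, 6

K = nml_constant(s, n, N, HypothesisSet.ALTERNATIVE)
bf = nml_ratio(t, s, n, N)
print(f"NML normalizer K(alternative) = {K:.4f}")
print(f"NML ratio (Bayes factor approximation) = {bf:.4f}")
for pi0 in (0.5, 0.9):
    print(f"NMLE local FDR at pi0={pi0}: {nmle_lfdr(bf, pi0):.4f}")

# A Bayes factor below 1 means the observed count is better predicted by
# the null (no enrichment); the local FDR is the posterior probability of
# no enrichment, so values near 1 say the category is likely not enriched.
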