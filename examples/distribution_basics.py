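"""Evaluate the NE_Fr distribution and its quantile-based shape summaries.

Builds a parameter triple, evaluates the distribution functions at a point,
and prints the quartiles, Bowley skewness and Moors kurtosis — the scale-free
shape summaries that exist even when the heavy tail kills ordinary moments.
"""

from nefr import NEFrParams, nefr_cdf, nefr_hrf, nefr_pdf, nefr_quantile, quantile_summary

p = NEFrParams(alpha=0.4, beta=0.4, lam=0.9)
print(f"parameters: alpha={p.alpha}, beta={p.beta}, lam={p.lam}"
      f"  (tail index beta*lam = {p.tail_index:.2f})")

z = 2.0
print(f"F({z}) = {nefr_cdf(z, p):.6f}   f({z}) = {nefr_pdf(z, p):.6f}"
      f"   h({z}) = {nefr_hrf(z, p):.6f}")
print(f"median Q(0.5) = {nefr_quantile(0.5, p):.5f}")

qs = quantile_summary(p)
print(f"Q1={qs.Q1:.5f}  Q2={qs.Q2:.5f}  Q3={qs.Q3:.5f}  BSK={qs.BSK:.5f}  MKUR={qs.MKUR:.5f}")
print("BSK near 1 and MKUR far above 1.23 (the normal reference) mean a"
      " strongly right-skewed, very heavy-tailed law: with beta*lam = 0.36"
      " not even the mean exists, so these quantile summaries are the only"
      " meaningful shape numbers.")
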