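"""Fit the niche-neutral hybrid model to a niche-differentiated
metacommunity.

Generates ten sites whose species pools differ in their biodiversity
parameter (theta from 6 to 16), treats each site as one niche, fits the
per-niche species-abundance distribution phi_n = theta x^n
Gamma(n+gamma) / (Gamma(n+1) Gamma(1+gamma)) on Preston octaves, and
combines the per-niche chi-squares into the metacommunity-level test.
"""

import numpy as np

import nichedrift as nd

cfg = nd.SyntheticConfig(
    regime="nnh", n_sites=10, n_individuals=1, J_target=5000,
    theta=list(np.linspace(6.0, 16.0, 10)), seed=5,
)
meta = nd.simulate_bank(cfg).metacommunity([0] * 10)

result = nd.nnh_meta_test(meta)
print(f"{'niche':>6} {'J':>7} {'S':>4} {'theta':>8} {'x':>7} {'gamma':>7} "
      f"{'R2':>6} {'chi2':>8} {'p':>6}")
for fit in result.per_niche:
    if fit.included:
        print(f"{fit.niche_id:>6} {fit.J:>7} {fit.S:>4} {fit.theta:>8.2f} "
              f"{fit.x:>7.3f} {fit.gamma:>7.3f} {fit.R2:>6.2f} "
              f"{fit.chi2:>8.2f} {fit.p:>6.3f}")
    else:
        print(f"{fit.niche_id:>6} {fit.J:>7} {fit.S:>4}  (too few occupied "
              "octaves; excluded)")

print(f"\ncombined: chi2 = {result.chi2_total:.2f}, df = {result.df_total}, "
      f"p = {result.p_meta:.3f}, niches passing: {result.N_pass}/{result.N}")
print("p > 0.05 means the metacommunity is indistinguishable from the "
      "hybrid model: niche differentiation between sites, neutral drift "
      "within each.")
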