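"""Chi-square sensitivity analysis for a lineup study design.

With N participants each contributing four lineup decisions, what is the
smallest Cohen's w a df=2 test detects at alpha = 0.05 with 95% power?
"""

import lineup2ht as l2

for n_participants in (1537, 1596):
    n_obs = n_participants * 4
    w = l2.minimal_detectable_w(n_obs, df=2, alpha=0.05, power=0.95)
    achieved = l2.power_noncentral_chi2(w, n_obs, df=2, alpha=0.05)
    print(
        f"N = {n_participants} participants ({n_obs} decisions): "
        f"minimal detectable w = {w:.4f} (power check: {achieved:.4f})"
    )

print()
print(
    "Both packaged studies were sensitive to effects as small as w = 0.05 —\n"
    "'small' on Cohen's scale — so null results there are not explained by\n"
    "a lack of power."
)
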