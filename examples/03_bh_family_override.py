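"""Benjamini-Hochberg with an explicit family size and tie handling.

When only the leading rows of a larger test family are available (as in a
published summary table), the adjustment can still be reproduced exactly by
supplying the full family size. Tied p-values — e.g. two merged units with
identical carriers — both receive the largest rank in their tie group, so a
tied top pair is adjusted by m/2, not m/1.
"""

from tmburden import bh_adjust

# seven leading p-values out of a 67-test family
p = [7.910e-09, 9.500e-08, 1.938e-04, 4.897e-03, 9.044e-03, 2.453e-02, 2.367e-02]
adj = bh_adjust(p, total_tests=67)
for raw, a in zip(p, adj):
    print(f"raw {raw:.3e}  ->  adjusted {a:.3e}")
print("\nNote the last two: the step-up minimum gives both the same adjusted")
print("value even though their raw p-values differ.\n")

# a tied top pair in a 208-test family: both adjusted at rank 2
tied = [7.907e-09, 7.907e-09, 3.466e-07]
adj = bh_adjust(tied, total_tests=208)
print(f"tied pair adjusted: {adj[0]:.3e} = raw * 208/2 (largest tie rank)")
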