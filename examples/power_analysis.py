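"""Sample-size planning for a two-group strength comparison.

Computes the per-group n needed to detect a between-group effect with an
exact noncentral-t power analysis, the way such studies are planned.
"""

from lv1rm import power_sample_size

# Effect size d = 1.1 (as reported for young vs. middle-aged handgrip
# power), alpha = 0.05, target power = 0.95, one-tailed.
n = power_sample_size(d=1.1, alpha=0.05, power=0.95, tails=1)
print(f"required sample size: {n} per group ({2 * n} total)")

# Smaller effects need markedly more athletes:
for d in (0.5, 0.8, 1.1):
    n = power_sample_size(d, alpha=0.05, power=0.95, tails=1)
    print(f"  d = {d:.1f} -> {n:3d} per group")

# The printed n is the smallest integer whose exact noncentral-t power
# (df = 2n-2, noncentrality d*sqrt(n/2)) reaches 0.95.
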