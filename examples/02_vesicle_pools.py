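"""Pool vesicle-to-active-zone distances and identify vesicle pools.

Generates a condition's worth of synthetic terminals, measures every
vesicle's shortest distance to the active-zone membrane, fits a Gaussian
KDE (Silverman bandwidth), and prints the identified pool peaks with the
probability mass each carries.
"""

import synmorph as sm

cfg = sm.SyntheticConfig(n_terminals=20, seed=42, vesicle_count_mean=300)
annotations, _ = sm.generate_condition(cfg)
report = sm.analyze_condition(annotations)

dist = report.distributions["active_zone"]
print(f"pooled vesicles : {dist.histogram.n_total}")
print(f"KDE bandwidth   : {dist.bandwidth:.2f} nm (Silverman)")
print("pool peaks (location, density, probability over one 10 nm bin):")
for pk in dist.peaks:
    print(f"  {pk.location:6.1f} nm   {pk.density:.5f} /nm   {pk.probability:5.2f} %")

near = report.near_counts["active_zone"]
print(f"vesicles < 50 nm of AZ: {near.n_within}/{near.n_total} "
      f"= {near.fraction:.3f}")

# The two peaks correspond to the readily-releasable pool (narrow, ~32 nm)
# and the reserve pool (broad, ~97 nm); the <50 nm fraction is the
# contingency-table numerator used for between-condition comparisons.
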