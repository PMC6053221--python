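"""Full cross-condition comparison on a synthetic three-condition dataset.

Generates small bundles for the three stimulation conditions, analyses
each, and applies the group statistics: Fisher's exact tests on pooled
near-membrane counts and Kruskal-Wallis with Dunn's correction on the
per-terminal metrics and apposition gaps.
"""

import synmorph as sm

configs = {
    cond: sm.SyntheticConfig(n_terminals=25, seed=300 + i, condition=cond,
                             vesicle_count_mean=120,
                             **{"gap_mean_nm": gap})
    for i, (cond, gap) in enumerate(
        [("unstimulated", 5.82), ("low_freq", 6.01), ("high_freq", 6.26)]
    )
}
dataset = sm.generate_dataset(configs)
reports = {cond: sm.analyze_condition(anns) for cond, (anns, _) in dataset.items()}

stats = sm.compare_conditions(reports, pair=("low_freq", "high_freq"))
for comp, (table, res) in stats["fisher"].items():
    print(f"Fisher {comp}: p = {res.p_two_sided:.4f} "
          f"({table.a}/{table.a + table.b} vs {table.c}/{table.c + table.d})")

for metric, comp in stats["kruskal"].items():
    print(f"Kruskal-Wallis {metric}: H = {comp.H:.2f}, p = {comp.p_value:.4f}")
    for pw in comp.pairwise:
        print(f"  {pw.group_a} vs {pw.group_b}: z = {pw.z:+.2f}, "
              f"adjusted p = {pw.p_adjusted:.4f}")

# With these small synthetic groups the geometry metrics should not differ
# (the generator draws them identically); the apposition-gap comparison can
# detect the configured 5.82 -> 6.26 nm shift when enough regions are pooled.
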