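"""Detectability of disease clusters for the scan design.

Estimates, by simulation on a small background tree, the power to detect
an injected cluster at 10% comparator prevalence across risk ratios, and
the smallest risk ratio reaching 80% power.  (The study-scale run with a
1,000-leaf tree and 200 simulations per point lives in
scripts/acceptance.py; this example keeps sizes small.)
"""

import regiscan as rs
from regiscan.power import PowerTreeConfig

tree_cfg = PowerTreeConfig(branching=(5, 5, 5), background_risk=0.01)

for rr in (1.3, 1.6, 2.0):
    pt = rs.power_at(
        n_exposed=712, n_comparators=3560, prevalence=0.10, risk_ratio=rr,
        tree_config=tree_cfg, n_replicates=499, n_simulations=50, seed=31,
    )
    print(f"RR {rr:.1f}: power {pt.power:.2f} "
          f"(MC se {pt.mc_standard_error:.3f})")

res = rs.minimum_detectable_rr(
    n_exposed=712, n_comparators=3560, prevalence=0.10, target_power=0.8,
    grid=(1.4, 1.6, 1.8, 2.0), tree_config=tree_cfg,
    n_replicates=499, n_simulations=50, seed=32,
)
print(f"minimum detectable RR at 10% prevalence (half study size): "
      f"{res.risk_ratio:g}")
# Halving the cohort raises the detectable risk ratio; at the full
# 1,424/7,120 size the same analysis lands near 1.5.
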