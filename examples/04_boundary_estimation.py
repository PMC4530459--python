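"""Estimate the converted tract's boundaries with the corrected t scan.

Both test trees are fitted once on the full alignment; per-column lnL
differences (delta-site-lnL) are then scanned with a Welch t statistic over
every window of every width from 30 to 90 columns.  A max-statistic
permutation test per width corrects for the number of windows examined,
and the best significant window is reported as the conversion region.
"""

import paraconv as pc

scenario = pc.ConversionScenario(seed=7)  # true tract: columns 111-190
alignment, _ = pc.generate(scenario)
model = pc.build_model("LG", gamma_shape=0.7)

table = pc.build_site_table(alignment, scenario.conv_clade, model, seed=4)
result = pc.scan_boundaries(table, min_width=30, max_width=90,
                            n_perm=2000, level=0.01, seed=5)

print(f"mean delta-site-lnL inside true tract:  "
      f"{table.delta_site[110:190].mean():+.3f}")
print(f"mean delta-site-lnL outside true tract: "
      f"{(table.delta_site.sum() - table.delta_site[110:190].sum()) / 150:+.3f}")
if result.best_window:
    start, end, width = result.best_window
    print(f"estimated conversion region: columns {start}-{end} (width {width})")
    print(f"max t = {result.t_obs:.2f}, permutation p = {result.p_value:.4f}")
else:
    print("no window significant at the 0.01 level")
print("true tract:                  columns 111-190 (width 80)")

# The estimate should bracket the implanted tract to within a few columns;
# per-width best windows are in result.per_width for inspection.
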