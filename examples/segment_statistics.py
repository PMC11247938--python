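"""Segment morphometrics: widths, segments per sucker, two-way ANOVA.

Generates a measurement table with the structure seen along an octopus arm
(widths tapering from proximal to distal, external-side segments wider than
internal, 24 replicates per condition), summarises it with the two-step
averaging convention, and tests both effects with a two-way ANOVA followed
by Tukey's post-hoc comparisons at α = 0.05.
"""

from ancmorph import segments_per_sucker, summarize_widths, two_way_anova_tukey
from ancmorph.synthetic import TableSpec, gen_segment_table

spec = TableSpec(base_width=40.0, taper_rate=8.0, territory_offset=5.0,
                 noise_sd=3.0, replicates=24, seed=0)
tables = gen_segment_table(spec)

row = tables.suckers.iloc[0]
sps = segments_per_sucker(int(row.count_anterior), int(row.count_posterior))
print(f"segments/sucker from counts ({row.count_anterior}, "
      f"{row.count_posterior}) over six suckers: {sps:.2f}")

print("\nwidth summary (mean ± sem, μm); 'total' averages the ExA and InA "
      "means:")
summary = summarize_widths(tables.segments)
for r in summary.itertuples():
    sem = "" if r.territory == "total" else f" ± {r.sem:.2f}"
    print(f"  {r.position:12s} {r.territory:6s} {r.mean:6.2f}{sem}")

res = two_way_anova_tukey(tables.segments, "width", "position", "territory")
print("\ntwo-way ANOVA on width:")
for factor in ("position", "territory", "interaction"):
    print(f"  {factor:12s} F = {res.f_stats[factor]:8.2f}   "
          f"p = {res.p_values[factor]:.2e}   "
          f"{'significant' if res.significant[factor] else 'n.s.'}")
print("\nTukey HSD along the proximal-distal axis:")
print(res.tukey["position"].to_string(index=False))
print("-> both the taper and the ExA>InA offset injected by the generator "
      "are detected; the Tukey table localises the taper to every pair of "
      "positions.")
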