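"""Four confidence intervals for the common 95th percentile of daily
rainfall across five Thai regions.

The bundled dataset has many exact zeros (dry stations) and a right-skewed
positive part, so each region is modelled as delta-lognormal.  The common
percentile pools the five regional 95th percentiles by precision weighting;
each method turns that pooled estimate into a 95% confidence interval.
"""

from dlnq import (
    PercentileSpec,
    bayes_interval,
    common_percentile_estimate,
    fgci_interval,
    mover_interval,
    rainfall_fixture,
    summarize,
)

spec = PercentileSpec(p=0.95, alpha=0.05)
summaries = [summarize(g) for g in rainfall_fixture()]

for s in summaries:
    print(f"{s.label:14s} n={s.n:3d} zeros={s.n0:3d} "
          f"log-mean={s.ybar1:5.2f} log-var={s.s2_1:5.2f}")

est = common_percentile_estimate(summaries, spec.p)
print(f"\npoint estimate of the common 95th percentile: {est.theta:.2f} mm")

print("\n95% confidence intervals (mm):")
results = [
    mover_interval(summaries, spec),
    fgci_interval(summaries, spec, m=1000, rng=1),
    bayes_interval(summaries, spec, m=1000, variant="bs1", rng=2),
    bayes_interval(summaries, spec, m=1000, variant="bs2", rng=3),
]
for r in results:
    print(f"  {r.method:6s} [{r.L:8.4f}, {r.U:9.4f}]  length {r.length:9.4f}")

print(
    "\nEach interval covers the pooled 95th-percentile rainfall with 95% "
    "confidence; shorter is better at equal coverage.  The BS1 interval is "
    "typically the shortest on this dataset."
)
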