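"""Run the full synthetic cohort pipeline under the hypothesis-2 scenario.

Simulates 8 subjects x 2 hemispheres, analyzes every stage and prints the
group statistics that correspond to the study's headline findings: the V1
percent-signal-change reduction during ambiguous motion, hMT+ invariance,
the positive V1 differential-profile slope, and the positive V1 ambiguous
event-related responses for both cluster roles.
"""

import numpy as np

from lamiquartet.config import PipelineConfig, small_cohort_config
from lamiquartet.pipeline import run_pipeline

config = PipelineConfig(seed=1, scenario="hypothesis2", cohort=small_cohort_config())
res = run_pipeline(config)

print(f"cluster recovery (agreement with ground truth): "
      f"V1 {100 * res.recovery['V1']:.0f}%, hMT+ {100 * res.recovery['hMT']:.0f}%")

print("\nphysical vs ambiguous cluster PSC (Wilcoxon signed-rank, N=16):")
for (roi, cl), t in res.psc_tests.items():
    print(f"  {roi:3s} {cl}-cluster: p = {t.p_value:.2g}")
# V1 clusters respond much less during ambiguous motion (small p);
# hMT+ clusters are condition-invariant (large p)

for roi in ("V1", "hMT"):
    s = res.slopes[roi]
    p = "undefined" if s.comparison is None else f"{s.comparison.p_value:.2g}"
    print(f"\n{roi} differential-profile slope: mean {np.mean(s.slopes):.2f} "
          f"PSC/unit depth, Wilcoxon p = {p}")
# a positive V1 slope means the physical-ambiguous difference grows toward
# the cortical surface (reduced draining-vein tilt in the feedback state)

pref = res.era_curves[("V1", "ambiguous", "preferred")]
npref = res.era_curves[("V1", "ambiguous", "not_preferred")]
print(f"\nV1 ambiguous ERA peaks: preferred {max(pref['mean']):.2f} PSC, "
      f"not-preferred {max(npref['mean']):.2f} PSC (both positive -> hypothesis 2)")
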