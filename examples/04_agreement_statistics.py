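"""Agreement statistics on their own: Bland-Altman limits, AAMI, BHS.

The graders operate on any vector of (estimate - reference) differences, so
they are usable with measurements from any device, not only this pipeline.
"""

import numpy as np

from dualppg import ErrorStats, aami_check, bhs_grade, bland_altman_limits

# limits of agreement [mu - 1.96 sigma, mu + 1.96 sigma] from an ME/SD pair
for label, me, sd in [("device A", 0.44, 6.00), ("device B", -0.50, 6.20)]:
    ba = bland_altman_limits(me, sd)
    ok = aami_check(ErrorStats(me=me, sd=sd, n=1000))
    print(
        f"{label}: ME {me:+.2f} mmHg, SD {sd:.2f} mmHg -> "
        f"LOA [{ba.loa_lower:.2f}, {ba.loa_upper:.2f}] mmHg, "
        f"AAMI (|ME| < 5, SD < 8): {'pass' if ok else 'fail'}"
    )

# BHS cumulative-error grading of a simulated error vector
rng = np.random.default_rng(0)
errors = rng.normal(0.5, 6.0, size=5000)
g = bhs_grade(errors)
print(
    f"BHS: {g.pct_le5:.1f}% within 5 mmHg, {g.pct_le10:.1f}% within 10, "
    f"{g.pct_le15:.1f}% within 15 -> grade {g.grade}"
)
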