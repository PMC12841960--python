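"""Compare the Harboe method against the hemolysis-index estimate.

Generates a synthetic ECMO cohort, then runs Passing-Bablok regression,
Bland-Altman agreement and Spearman correlation of index-estimated efHb
against Harboe fHb — on the full cohort and on the low-bilirubin stratum
where the Harboe channel is free of icteric interference.
"""

import numpy as np

from pfhb import PairedMeasurements, compare_methods
from pfhb.cohort import CohortParams, generate

params = CohortParams(n=244)  # four study-sized batches pooled
samples = generate(params, seed=7)

fhb = np.array([s.record.fhb for s in samples])
efhb = np.array([s.record.hil.h_index * params.h_to_fhb_factor for s in samples])
tbil = np.array([s.record.tbil for s in samples])


def report(label, mask):
    res = compare_methods(PairedMeasurements(fhb[mask], efhb[mask]))
    pb, ba, sp = res.passing_bablok, res.bland_altman, res.spearman
    print(f"--- {label} (n={res.n})")
    print(f"  Passing-Bablok slope     = {pb.slope:6.3f}  "
          f"95% CI ({pb.slope_ci.low:.3f}, {pb.slope_ci.high:.3f})")
    print(f"  Passing-Bablok intercept = {pb.intercept:6.1f}  "
          f"95% CI ({pb.intercept_ci.low:.1f}, {pb.intercept_ci.high:.1f}) mg/L")
    print(f"  Bland-Altman bias        = {ba.bias:6.1f} mg/L, "
          f"LoA ({ba.loa_low:.1f}, {ba.loa_high:.1f})")
    print(f"  Spearman rho             = {sp.rho:6.3f}  (p = {sp.p_value:.2g})")


report("full cohort", np.ones_like(tbil, dtype=bool))
report("tBil < 75 umol/L", tbil < params.interference_onset)

# In the low-bilirubin stratum the slope CI contains 1 (no proportional
# difference) and the intercept sits near the generating constant offset
# of -91 mg/L: the index estimate tracks the Harboe value minus a fixed
# amount.  On the full cohort, bilirubin interference inflates the Harboe
# channel, widening the limits of agreement and flattening the slope.
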