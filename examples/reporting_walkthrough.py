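"""Walk the reporting algorithm over the hand-authored 12-sample fixture.

Each record exercises one branch of the four-step interference
algorithm; the printed trace shows which rule decided each sample.
"""

from pfhb import decide_batch
from pfhb.cohort import fixture_batch

records = fixture_batch()
decisions = decide_batch(records)

for rec, d in zip(records, decisions):
    fired = [r.rule_id for r in d.rule_trace if r.fired]
    notes = f"  notes={list(d.annotations)}" if d.annotations else ""
    print(f"{d.sample_id}: {d.status.value:24s} fired={fired or ['-']}{notes}")

# REPORT              : released as measured
# REPORT_WITH_ANNOTATION: released, but flagged (icteric or lipemic context)
# CLINICIAN_REQUEST_ONLY: withheld unless the clinician explicitly asks
# REQUEST_NEW_SAMPLE  : lipemia source can be paused -> redraw the sample
# VERIFY_PREANALYTICS : possible sampling artifact, check venipuncture
# NEEDS_TBIL          : icterus or very high fHb demands a bilirubin reflex test
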