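"""One adaptive session for a simulated respondent, step by step.

A respondent with true measure 2.30 logits answers items drawn by
maximum information; the measure is re-estimated after each response
once the 3-item burn-in is over, and the session stops when the standard
error reaches the 0.68 SEM target (never before 10 items).  The printed
table mirrors the administration report: each row shows the item's
difficulty, the model probability of the observed category, the response
(* = unexpected at the 5% level), the expected score, and the running
measure, standard error and outfit.
"""

import sys
import numpy as np

from raschcat import (
    CatConfig,
    misfit_filter,
    packaged_bank,
    run_cat,
    simulate_response,
    write_session_report,
)

bank, _ = misfit_filter(packaged_bank())
rng = np.random.default_rng(1)
TRUE_THETA = 2.30

session = run_cat(
    lambda item: simulate_response(TRUE_THETA, item, bank.scale, rng),
    bank,
    CatConfig(se_target=0.68, min_items=10),
    global_rating=3,  # "good" on the 1-4 global self-rating -> start at 0.5
)

write_session_report(session, "session_report.txt", seed=1)
sys.stdout.write(open("session_report.txt").read())
print(f"\ntrue measure {TRUE_THETA:.2f}; estimated "
      f"{session.final.theta:.2f} +/- {session.final.se:.2f} after "
      f"{len(session.steps)} of {len(bank.calibrated)} items "
      f"(stop: {session.stop_reason})")
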