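"""Person-fit screening: a careless responder versus a consistent one.

The adversarial respondent endorses the hardest items maximally and the
easiest minimally — a pattern no single measure can produce.  The outfit
mean-square (mean squared standardized residual, expectation 1 under the
model) rises above the 2.0 aberrance threshold and individual responses
get flagged at |z| > 1.96, while a model-consistent respondent stays
near 1.
"""

import numpy as np

from raschcat import (
    CatConfig,
    misfit_filter,
    packaged_bank,
    run_cat,
    simulate_response,
)

bank, _ = misfit_filter(packaged_bank())
config = CatConfig(se_target=0.0, min_items=10)  # run the full bank

rng = np.random.default_rng(3)
honest = run_cat(
    lambda item: simulate_response(1.0, item, bank.scale, rng), bank, config
)

median = float(np.median([it.difficulty for it in bank.calibrated]))
careless = run_cat(
    lambda item: 3 if item.difficulty > median else 0, bank, config
)

for name, s in [("consistent", honest), ("adversarial", careless)]:
    flagged = sum(step.unexpected for step in s.steps)
    print(f"{name:12s}: outfit {s.outfit:5.2f}  "
          f"aberrant={s.aberrant}  unexpected responses={flagged}/{len(s.steps)}")
print("\noutfit > 2.0 marks the record for review (guessing, inattention,")
print("misunderstanding); flags point at the specific unexpected answers.")
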