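#!/usr/bin/env python
"""Simulate the synthetic cohorts and write their trial logs.

Writes two CSV trial logs under results/:
  cohort_included.csv  -- 21/21/18 ASD/LAD/TD-like engaged observers
                          (the included-sample stand-in)
  cohort_full.csv      -- 29/27/23 with a disengaged (coin-flipping)
                          subgroup per group (the pre-exclusion cohort)
"""

import argparse
from pathlib import Path

from contrabias.io import write_trial_log
from contrabias.observer import default_cohort, full_cohort

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
inc = default_cohort(seed=args.seed)
write_trial_log(inc, args.out / "cohort_included.csv")
pre = full_cohort(seed=args.seed)
write_trial_log(pre, args.out / "cohort_full.csv")

print(f"included-like cohort: {inc.subject_id.nunique()} subjects, {len(inc)} trials")
print(f"pre-exclusion cohort: {pre.subject_id.nunique()} subjects, {len(pre)} trials")
print(f"mean accuracy (included-like): {inc.correct.mean():.3f}")
print(f"wrote {args.out}/cohort_included.csv and {args.out}/cohort_full.csv")
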