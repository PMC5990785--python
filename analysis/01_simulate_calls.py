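#!/usr/bin/env python
"""Generate the study-like synthetic call table.

Produces a 271-call table from 29 subjects with the published roster
structure: unbalanced call counts over rest/travel/alert, 11 subjects
contributing to all three contexts, observer-by-context and
device-by-context imbalance, and bout structure in which rest hoos are
almost always single calls.  Writes results/synthetic_calls.csv.
"""

import argparse
from pathlib import Path

from hoovar.call_table import write_call_table
from hoovar.simulate import generate_feature_table, paper_like_truth


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic_calls.csv"))
    args = ap.parse_args()

    fm, truth = generate_feature_table(paper_like_truth(seed=args.seed))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    write_call_table(fm, args.out)

    rec = fm.records
    rest = rec[rec["context"] == "rest"]
    singles = int(rest["inter_call_interval_s"].isna().sum())
    print(f"wrote {len(rec)} calls from {rec['subject_id'].nunique()} subjects to {args.out}")
    print("calls per context:", rec["context"].value_counts().to_dict())
    print(f"single rest hoos: {singles}/{len(rest)} ({100 * singles / len(rest):.1f}%)")
    both = rec.groupby("subject_id")["context"].nunique()
    print(f"subjects contributing to all three contexts: {(both == 3).sum()}")


if __name__ == "__main__":
    main()
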