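#!/usr/bin/env python
"""Decide presence of each non-redundant fill in the reference (Primary),
the synthetic ALT set, two primate-like datasets and a published-NRS-like
set (>= 95% identity over >= 80% merged coverage), and count the novel
non-reference sequence left over.
"""

import argparse
from pathlib import Path

from gapfill.presence import intersection_counts
from gapfill.study import default_config, run_study

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "presence")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    res = run_study(default_config(args.seed))
    m = res.presence_matrix
    m.to_csv(args.out / "presence_matrix.tsv", sep="\t")
    counts = intersection_counts(m)
    with open(args.out / "intersections.tsv", "w") as fh:
        fh.write("datasets\tcount\n")
        for key, n in counts.items():
            fh.write(f"{'+'.join(key) if key else '(none)'}\t{n}\n")

    for ds in m.columns:
        print(f"{ds}: {int(m[ds].sum())}/{len(m)} sequences present")
    n, bp, _ = res.novel
    print(f"novel NRS (absent from Primary and ALT): {n} sequences, {bp:,} bp")


if __name__ == "__main__":
    main()
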