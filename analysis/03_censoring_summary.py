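#!/usr/bin/env python
"""Per-survey monitoring bookkeeping for the synthetic study.

Counts nest groups, nests and right-censored nests per survey window (the
table every decay study reports first), and writes
results/censoring_summary.csv.
"""

from pathlib import Path

from nestdecay.core import censor_summary, read_nest_table, read_survey_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    records = read_nest_table(ROOT / "study" / "nests.csv")
    windows = read_survey_table(ROOT / "study" / "surveys.csv")
    table = censor_summary(records, windows)
    table.to_csv(ROOT / "censoring_summary.csv", index=False)
    print(table.to_string(index=False))
    print(f"wrote {ROOT / 'censoring_summary.csv'}")


if __name__ == "__main__":
    main()
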