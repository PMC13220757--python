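"""Baseline-table statistics and stratified alpha-diversity group tests.

Chi-square / Fisher comparisons of the subject-level factors, paired
pre-versus-post signed-rank tests of Shannon and Faith PD within ileostomy
strata, and unpaired SDD rank-sum tests within timepoints. Writes tables
under results/cohort_stats/.
"""

import argparse
from pathlib import Path

import pandas as pd

from perigut.cohort_stats import alpha_group_tests, baseline_table
from perigut.io_formats import read_metadata

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    argparse.ArgumentParser().parse_args()
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv")
    alpha = pd.read_csv(ROOT / "diversity" / "alpha_diversity.tsv", sep="\t")
    meta = meta[meta["sample_id"].isin(alpha["sample_id"])].reset_index(drop=True)
    out = ROOT / "cohort_stats"
    out.mkdir(parents=True, exist_ok=True)

    base = baseline_table(meta)
    base.to_csv(out / "baseline_table.tsv", sep="\t", index=False)
    print(base.to_string(index=False))

    tests = alpha_group_tests(alpha, meta)
    tests.to_csv(out / "alpha_group_tests.tsv", sep="\t", index=False)
    print()
    print(tests.to_string(index=False))


if __name__ == "__main__":
    main()
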