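"""Per-genus mixed-model differential abundance and composition summaries.

Fits one linear mixed model per taxon (random subject intercepts; fixed
effects timepoint, SDD, ileostomy) on relative abundances from the rarefied
table, BH-adjusts within each factor, and writes volcano-style tables plus
the top-genera composition summary under results/differential_abundance/.
"""

import argparse
import math
from pathlib import Path

from perigut.differential_abundance import (
    composition_summary,
    differential_abundance,
    to_relative,
    volcano_table,
)
from perigut.io_formats import read_count_table, read_metadata

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--top-genera", type=int, default=21)
    args = parser.parse_args()

    counts = read_count_table(ROOT / "diversity" / "rarefied_counts.tsv")
    meta = read_metadata(ROOT / "cohort" / "metadata.tsv")
    meta = meta[meta["sample_id"].isin(counts.sample_ids)].reset_index(drop=True)
    out = ROOT / "differential_abundance"
    out.mkdir(parents=True, exist_ok=True)

    results = differential_abundance(counts, meta)
    results.to_csv(out / "lmm_results.tsv", sep="\t", index=False)
    for factor in ("timepoint", "ileostomy", "sdd"):
        volcano = volcano_table(results, factor)
        volcano.to_csv(out / f"volcano_{factor}.tsv", sep="\t", index=False)
        hits = volcano[volcano["neg_log10_q"] > -math.log10(0.05)]
        print(f"{factor}: {len(hits)} of {len(volcano)} taxa significant at q < 0.05")

    comp = composition_summary(to_relative(counts), meta, k=min(args.top_genera, counts.n_taxa))
    comp.to_csv(out / "composition_summary.tsv", sep="\t", index=False)
    print(f"composition summary of the top {min(args.top_genera, counts.n_taxa)} genera written")


if __name__ == "__main__":
    main()
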