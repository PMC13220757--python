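"""Rarefaction, alpha diversity and weighted UniFrac beta diversity.

Reads the cohort written by 01_simulate_cohort.py, rarefies every sample to
10 000 counts, computes per-sample Shannon entropy and Faith phylogenetic
diversity, the all-pairs weighted UniFrac distance matrix and its principal
coordinates. Writes tables under results/diversity/.
"""

import argparse
from pathlib import Path

from perigut.diversity import alpha_diversity_table, pairwise_weighted_unifrac, pcoa, rarefy
from perigut.io_formats import (
    read_count_table,
    read_newick,
    write_count_table,
    write_distance_matrix,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--depth", type=int, default=10_000)
    args = parser.parse_args()

    counts = read_count_table(ROOT / "cohort" / "counts.tsv")
    tree = read_newick(ROOT / "cohort" / "tree.nwk")
    out = ROOT / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    rare, excluded = rarefy(counts, depth=args.depth, seed=args.seed)
    write_count_table(rare, out / "rarefied_counts.tsv")
    print(f"rarefied {rare.n_samples} samples to {args.depth} counts; excluded {len(excluded)}")

    alpha = alpha_diversity_table(rare, tree)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
    print(
        f"alpha diversity: Shannon {alpha['shannon'].mean():.3f} +/- {alpha['shannon'].std():.3f} nats, "
        f"Faith PD {alpha['faith_pd'].mean():.3f} +/- {alpha['faith_pd'].std():.3f}"
    )

    dm = pairwise_weighted_unifrac(rare, tree)
    write_distance_matrix(dm, out / "weighted_unifrac.tsv")
    ordination = pcoa(dm)
    eig, coords = ordination.to_frames()
    eig.to_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index=False)
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pe = ordination.proportion_explained
    print(f"PCoA: PC1 {100 * pe[0]:.1f}%, PC2 {100 * pe[1]:.1f}% of positive-eigenvalue variance")


if __name__ == "__main__":
    main()
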