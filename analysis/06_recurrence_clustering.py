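#!/usr/bin/env python
"""Recurrence counts and bi-clustering of the published variant table.

Builds the gene x strain presence matrix from the packaged table of filtered
variants in the nine butanol-tolerant mutant strains, recomputes the
recurrence numbers, and clusters genes and strains by complete linkage over
the binary (Jaccard-complement) distance.  Writes the matrix, the leaf
orderings and a heatmap.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from clonalvar import compare, io

RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    df = io.load_table3_variants()
    by_strain = {s: g.loc[g["locus"] != "", "locus"].tolist() for s, g in df.groupby("strain")}
    matrix = compare.build_binary_matrix(by_strain)
    counts = compare.recurrence_counts(matrix)

    print(f"matrix: {len(matrix.gene_labels)} genes x {len(matrix.strain_labels)} strains")
    print(f"genes mutated in >=2 strains: {compare.genes_at_least(matrix, 2)}")
    recurrent = counts[counts >= 2].sort_values(ascending=False)
    for locus, n in recurrent.items():
        print(f"  {locus}: {n} strains")

    gene_link, strain_link = compare.bicluster(matrix)
    frame = matrix.to_frame().loc[gene_link.leaf_order, strain_link.leaf_order]
    frame.to_csv(RESULTS / "mutation_matrix.tsv", sep="\t")
    with open(RESULTS / "cluster_order.tsv", "w") as fh:
        fh.write("genes\t" + "\t".join(gene_link.leaf_order) + "\n")
        fh.write("strains\t" + "\t".join(strain_link.leaf_order) + "\n")
    print("strain leaf order:", " ".join(strain_link.leaf_order))

    fig, ax = plt.subplots(figsize=(5, 9))
    ax.imshow(frame.values, aspect="auto", cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(len(frame.columns)), frame.columns, rotation=90)
    ax.set_yticks(range(len(frame.index)), frame.index, fontsize=6)
    fig.tight_layout()
    fig.savefig(RESULTS / "mutation_heatmap.png", dpi=150)
    print(f"wrote {RESULTS}/mutation_matrix.tsv, cluster_order.tsv, mutation_heatmap.png")


if __name__ == "__main__":
    main()
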