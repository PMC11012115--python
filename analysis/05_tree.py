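"""Build the bootstrapped gene tree over intact ORs, rooted on non-class-2.

Aligns the intact OR coding sequences, computes Jukes-Cantor distances with
pairwise deletion, builds a neighbor-joining tree, attaches column-bootstrap
supports, and roots the tree on the branch separating the non-class-2 ORs.
Reports whether the ORs called expressed form a single clade.
"""

import argparse

import pandas as pd

from orexpress.io_utils import read_fasta, read_models
from orexpress.phylo import align, bootstrap_and_root, write_fasta_alignment, write_phylip


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results/run")
    ap.add_argument("--bootstrap", type=int, default=100)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    out = args.outdir

    cds = read_fasta(f"{out}/intact_cds.fasta")
    models = read_models(f"{out}/models.tsv")
    nonclass2 = [m.gene_id for m in models if m.status == "intact" and m.or_class == "nonclass2"]

    aln = align(cds)
    tree = bootstrap_and_root(aln, args.bootstrap, args.seed, nonclass2)
    with open(f"{out}/tree.nwk", "w") as fh:
        fh.write(tree.newick() + "\n")
    write_fasta_alignment(aln, f"{out}/intact_alignment.fasta")
    write_phylip(aln, f"{out}/intact_alignment.phy")

    print(f"tree over {len(tree.leaves())} intact ORs ({args.bootstrap} bootstrap replicates)")
    print(f"non-class-2 outgroup monophyletic: {tree.monophyletic_outgroup}")
    sides = [sorted(c.leaves()) for c in tree.root.children]
    print(f"root split: {len(sides[0])} vs {len(sides[1])} leaves")

    # are the expressed ORs clustered? count the smallest clade containing all
    calls = pd.read_csv(f"{out}/expressed_calls.tsv", sep="\t", index_col=0)
    expressed = sorted(g for g in calls.index if calls.loc[g].any())
    if expressed:
        def smallest_clade(node):
            best = None
            for c in node.children:
                found = smallest_clade(c)
                if found is not None:
                    best = found
            if best is not None:
                return best
            leaves = set(node.leaves())
            return leaves if set(expressed) <= leaves else None

        clade = smallest_clade(tree.root) or set(tree.leaves())
        print(
            f"{len(expressed)} expressed ORs; smallest containing clade holds "
            f"{len(clade)} of {len(tree.leaves())} leaves"
            + (" (expressed ORs do not form their own cluster)" if len(clade) > len(expressed) else "")
        )


if __name__ == "__main__":
    main()
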