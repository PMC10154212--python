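#!/usr/bin/env python
"""Build the consensus coabundance network and extract the health-associated
guild.

Per-study robust fits between clr abundances of taxon pairs are pooled with
random-effects models and Bonferroni-corrected per focal taxon; pairs with a
positive pooled estimate at q <= 0.001 become edges.  Node centralities
(degree, betweenness, hub score) are compared between the Kendall-negative
and Kendall-positive groups, and the guild rule (every member adjacent to at
least 50% of the others) is applied to the Kendall-negative roster.  Writes
results/network_{edges,nodes}.tsv and results/guild.txt.
"""

import argparse

import pandas as pd

from microaging.networks import (
    build_consensus_network,
    extract_guild,
    node_centralities,
    pairwise_taxon_associations,
)
from microaging.pipeline import load_collection
from microaging.profiles import filter_prevalent_taxa


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--groups", default="results/groups.tsv")
    ap.add_argument("--edge-q", type=float, default=0.001)
    ap.add_argument("--max-taxa", type=int, default=25)
    args = ap.parse_args()

    collection = load_collection(args.data)
    groups = pd.read_csv(args.groups, sep="\t", index_col="taxon")
    roster = filter_prevalent_taxa(collection)[: args.max_taxa]
    pairs = pairwise_taxon_associations(collection, roster)
    net = build_consensus_network(
        pairs, edge_q=args.edge_q, groups=groups["group"].to_dict(), nodes=roster
    )
    cent = node_centralities(net)
    cent["group"] = [net.nodes[t]["group"] for t in cent.index]
    cent.to_csv("results/network_nodes.tsv", sep="\t", float_format="%.10g")
    edges = pd.DataFrame(
        [dict(taxon_a=a, taxon_b=b, pooled_estimate=d["pooled_estimate"],
              q_value=d["q_value"]) for a, b, d in sorted(net.edges(data=True))]
    )
    edges.to_csv("results/network_edges.tsv", sep="\t", index=False, float_format="%.10g")
    print(f"consensus network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")
    summary = cent.groupby("group")[["degree", "betweenness", "hub_score"]].mean()
    print("\nmean centrality by taxon group:")
    print(summary.round(3).to_string())

    seed = list(groups.index[groups["group"] == "kendall_negative"])
    seed = [t for t in seed if t in net] or list(net.nodes)
    guild = extract_guild(net, seed, frac=0.5)
    pd.Series(guild.members, name="taxon_id").to_csv(
        "results/guild.txt", index=False, header=False
    )
    print(f"\nguild: {len(guild.members)} taxa, internal-connectivity rule "
          f"satisfied: {guild.density_ok}")


if __name__ == "__main__":
    main()
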