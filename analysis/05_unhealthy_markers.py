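#!/usr/bin/env python
"""Rank microbiome features by the consistency of their associations with
unhealthy-aging measures across data repositories.

The feature panel combines the five summary indices, the grouped abundances
of the two Kendall-defined taxon groups and the clr abundances of every
prevalent taxon.  Continuous measures use robust regression, binary ones
rank-sum tests, with BH correction per repository-measure scenario; a
feature is a marker when it hits the same direction (q <= 0.1) in at least
three repositories with at most two opposite hits.  Writes
results/marker_ranking.tsv.
"""

import argparse

import pandas as pd
import yaml

from microaging.markers import associate_panel, rank_consistent_markers
from microaging.pipeline import (
    RunConfig,
    _assemble_feature_panel,
    _measures_from_metadata,
    load_collection,
)
from microaging.profiles import filter_prevalent_taxa


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--indices", default="results/indices.tsv")
    ap.add_argument("--groups", default="results/groups.tsv")
    ap.add_argument("--out", default="results/marker_ranking.tsv")
    args = ap.parse_args()

    collection = load_collection(args.data)
    indices = pd.read_csv(args.indices, sep="\t", index_col="sample_id")
    groups = pd.read_csv(args.groups, sep="\t", index_col="taxon")
    polarity = yaml.safe_load(open(f"{args.data}/polarity.yaml"))
    prevalent = filter_prevalent_taxa(collection)
    rosters = {
        name: list(groups.index[groups["group"] == name])
        for name in ("kendall_negative", "kendall_positive")
    }
    cfg = RunConfig()
    features = _assemble_feature_panel(collection, indices, prevalent, rosters, cfg)
    meta_frame, measures = _measures_from_metadata(collection, polarity)
    assocs = associate_panel(features, measures, meta_frame, min_n=cfg.scenario_floor)
    ranking = rank_consistent_markers(assocs)
    ranking.to_csv(args.out, sep="\t")
    markers = ranking[ranking["verdict"] != "none"]
    print(f"{len(markers)} of {len(ranking)} features qualify as consistent markers")
    print("\ntop of the ranking:")
    print(ranking.head(8).to_string())


if __name__ == "__main__":
    main()
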