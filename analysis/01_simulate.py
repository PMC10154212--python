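#!/usr/bin/env python
"""Generate the synthetic multi-study cohorts that the rest of the analysis
consumes.

Writes per-study abundance TSVs, sample metadata (ages, profiling type,
clinical measures), the polarity registry and the planted ground truth under
results/data/.  The default scale (6 studies, 120-160 samples each, 50
species) keeps every downstream script interactive; pass --full for the
10-study / 120-taxon configuration.
"""

import argparse

from microaging.pipeline import save_collection
from microaging.simulate import SyntheticConfig, generate_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", default="results/data")
    ap.add_argument("--full", action="store_true",
                    help="full-scale configuration (10 studies, 120 taxa)")
    args = ap.parse_args()

    if args.full:
        cfg = SyntheticConfig(seed=args.seed)
    else:
        cfg = SyntheticConfig(
            n_studies=6, samples_per_study=(120, 160), n_taxa=50,
            n_health_core=10, n_disease_subhub_1=5, n_disease_subhub_2=5,
            depth=20_000, seed=args.seed,
        )
    collection, truth = generate_dataset(cfg)
    save_collection(collection, args.out, truth)
    n = sum(t.shape[1] for t in collection.tables.values())
    print(f"wrote {len(collection.tables)} studies, {n} samples, "
          f"{cfg.n_taxa} taxa to {args.out}")
    print(f"planted rosters: {len(truth.health_core)} health-core, "
          f"{len(truth.disease_roster)} disease-subhub taxa")


if __name__ == "__main__":
    main()
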