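"""End-to-end orchestration: simulate -> indices -> taxon groups -> age
screen -> unhealthy-aging markers -> coabundance network.

Every stage writes plain-text tables under the run directory and the run
manifest records the seed, a hash of the configuration and per-stage row
counts, so that a rerun with the same seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .groups import (
    age_association_screen,
    associate_taxa_with_index,
    classify_by_kendall_association,
    group_abundance_collection,
)
from .indices import compute_summary_indices
from .markers import ClinicalMeasure, associate_panel, rank_consistent_markers
from .meta import EffectEstimate, consistency_score, permutation_test_re, random_effects_pool
from .networks import (
    build_consensus_network,
    extract_guild,
    node_centralities,
    pairwise_taxon_associations,
)
from .profiles import (
    SampleMetadata,
    StudyCollection,
    ValidationError,
    clr_transform,
    filter_prevalent_taxa,
    read_abundance_table,
    read_sample_metadata,
    write_abundance_table,
    write_sample_metadata,
)
from .simulate import SyntheticConfig, SyntheticTruth, generate_dataset

__all__ = ["RunConfig", "run_full_analysis", "save_collection", "load_collection"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds of the analysis, each defaulting to its conventional
    printed value, plus the synthetic-data configuration."""

    seed: int = 0
    out_dir: str = "run"
    simulate: bool = True
    input_dir: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # prevalence filter
    min_sample_frac: float = 0.05
    min_study_frac: float = 0.60
    per_data_type: bool = True
    pseudocount: str | float = "auto"
    # taxon-group classification
    group_q_max: float = 0.05
    group_min_consistency: float = 2 / 3
    # age screen
    min_age: float = 60.0
    min_n_old: int = 50
    age_direction_frac: float = 2 / 3
    age_q_max: float = 0.1
    # markers
    marker_q_max: float = 0.10
    marker_min_repositories: int = 3
    marker_max_opposite: int = 2
    scenario_floor: int = 20
    # network
    edge_q: float = 0.001
    guild_frac: float = 0.5
    network_max_taxa: int = 40
    # stage toggles
    stages: tuple = ("simulate", "indices", "groups", "age_screen", "markers", "network")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(synthetic=syn, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # environment, not analysis: keeps reruns byte-identical
        d["stages"] = list(d["stages"])
        for k in ("samples_per_study", "age_range"):
            d["synthetic"][k] = list(d["synthetic"][k])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def save_collection(collection: StudyCollection, out_dir, truth: SyntheticTruth | None = None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab_dir = out / "tables"
    tab_dir.mkdir(exist_ok=True)
    for study, table in sorted(collection.tables.items()):
        write_abundance_table(table, tab_dir / f"{study}.tsv")
    write_sample_metadata(collection.metadata, out / "metadata.tsv")
    repo = pd.DataFrame(
        sorted(collection.repository.items()), columns=["study_id", "repository"]
    )
    repo.to_csv(out / "repositories.tsv", sep="\t", index=False)
    if truth is not None:
        with open(out / "truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        with open(out / "polarity.yaml", "w") as fh:
            yaml.safe_dump(truth.measure_polarity, fh, sort_keys=True)


def load_collection(in_dir, level: str = "species", scale: str = "counts") -> StudyCollection:
    src = Path(in_dir)
    meta_path = src / "metadata.tsv"
    if not meta_path.exists():
        raise ValidationError(f"metadata file not found: {meta_path}")
    metadata = read_sample_metadata(meta_path)
    tables = {}
    for path in sorted((src / "tables").glob("*.tsv")):
        tables[path.stem] = read_abundance_table(path, level=level, scale=scale)
    repository = {}
    repo_path = src / "repositories.tsv"
    if repo_path.exists():
        repo = pd.read_csv(repo_path, sep="\t")
        repository = dict(zip(repo["study_id"], repo["repository"]))
    return StudyCollection(tables=tables, metadata=metadata, repository=repository)


def _measures_from_metadata(
    collection: StudyCollection, polarity: dict
) -> tuple[pd.DataFrame, list[ClinicalMeasure]]:
    meta = collection.metadata.frame.copy()
    s2s = collection.sample_to_study()
    meta = meta.loc[s2s.index]
    meta["repository"] = s2s.map(collection.repository)
    measures = []
    for col in collection.metadata.clinical_columns:
        vals = meta[col].dropna()
        kind = "binary" if set(vals.unique()) <= {0.0, 1.0} else "continuous"
        if col not in polarity:
            raise ValidationError(f"no polarity declared for clinical measure {col!r}")
        for repo in sorted(set(meta["repository"])):
            measures.append(ClinicalMeasure(col, kind, polarity[col], repository=repo))
    return meta, measures


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the staged analysis; returns the run manifest (also written
    as ``manifest.json`` in the run directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
    }
    truth = None
    if config.simulate and "simulate" in config.stages:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        collection, truth = generate_dataset(syn)
        save_collection(collection, out / "data", truth)
        manifest["stages"]["simulate"] = {
            "n_studies": len(collection.tables),
            "n_samples": int(sum(t.shape[1] for t in collection.tables.values())),
            "n_taxa": int(collection.tables[collection.study_ids[0]].shape[0]),
        }
        polarity = truth.measure_polarity
    else:
        if not config.input_dir:
            raise ValidationError("simulation disabled and no input_dir given")
        collection = load_collection(config.input_dir)
        pol_path = Path(config.input_dir) / "polarity.yaml"
        polarity = yaml.safe_load(open(pol_path)) if pol_path.exists() else {}
        manifest["stages"]["load"] = {"n_studies": len(collection.tables)}

    prevalent = filter_prevalent_taxa(
        collection, config.min_sample_frac, config.min_study_frac, config.per_data_type
    )
    pd.Series(prevalent, name="taxon_id").to_csv(
        out / "prevalent_taxa.txt", index=False, header=False
    )

    indices = None
    if "indices" in config.stages:
        indices = compute_summary_indices(collection, pseudocount=config.pseudocount)
        indices.to_csv(out / "indices.tsv", sep="\t", float_format="%.10g")
        manifest["stages"]["indices"] = {"n_rows": int(indices.shape[0])}

    assignments = []
    if "groups" in config.stages:
        if indices is None:
            raise ValidationError("groups stage requires the indices stage")
        meta_list = associate_taxa_with_index(
            collection, indices, "uniq_ken", taxa=prevalent, pseudocount=config.pseudocount
        )
        assignments = classify_by_kendall_association(
            meta_list, config.group_q_max, config.group_min_consistency
        )
        gdf = pd.DataFrame(
            [
                dict(taxon=a.taxon, group=a.group, pooled_estimate=a.pooled_estimate,
                     q_value=a.q_value, consistency=a.consistency)
                for a in assignments
            ]
        ).set_index("taxon")
        gdf.to_csv(out / "groups.tsv", sep="\t", float_format="%.10g")
        manifest["stages"]["groups"] = {
            g: int((gdf["group"] == g).sum())
            for g in ("kendall_negative", "kendall_positive", "other")
        }

    rosters = {
        "kendall_negative": [a.taxon for a in assignments if a.group == "kendall_negative"],
        "kendall_positive": [a.taxon for a in assignments if a.group == "kendall_positive"],
    }

    if "age_screen" in config.stages:
        screen = age_association_screen(
            collection,
            prevalent,
            min_age=config.min_age,
            min_n_old=config.min_n_old,
            direction_frac=config.age_direction_frac,
            q_max=config.age_q_max,
            pseudocount=config.pseudocount,
        )
        screen.to_csv(out / "age_screen.tsv", sep="\t", float_format="%.10g")
        # grouped-abundance age trends for the two signed rosters
        trend_rows = []
        for name, roster in rosters.items():
            if not roster:
                continue
            ga = group_abundance_collection(collection, roster, config.pseudocount)
            effs = _group_age_effects(collection, ga, config)
            if len(effs) >= 2:
                ms = random_effects_pool(effs)
                ms.consistency = (
                    consistency_score(effs, ms.pooled_estimate) if ms.pooled_estimate else 0.0
                )
                ms.p_perm = permutation_test_re(effs, B=999, rng=config.seed)
                trend_rows.append(
                    dict(group=name, pooled_estimate=ms.pooled_estimate, p_perm=ms.p_perm,
                         p_z=ms.p_value, consistency=ms.consistency, k=ms.k)
                )
        pd.DataFrame(trend_rows).to_csv(
            out / "group_age_trends.tsv", sep="\t", index=False, float_format="%.10g"
        )
        manifest["stages"]["age_screen"] = {
            "n_retained": int(screen["retained"].sum()),
            "n_flagged": int(screen["flagged"].sum()),
        }

    if "markers" in config.stages:
        features = _assemble_feature_panel(collection, indices, prevalent, rosters, config)
        meta_frame, measures = _measures_from_metadata(collection, polarity)
        assocs = associate_panel(features, measures, meta_frame, min_n=config.scenario_floor)
        ranking = rank_consistent_markers(
            assocs,
            q_max=config.marker_q_max,
            min_repositories=config.marker_min_repositories,
            max_opposite=config.marker_max_opposite,
        )
        ranking.to_csv(out / "marker_ranking.tsv", sep="\t")
        manifest["stages"]["markers"] = {
            "n_features": int(features.shape[1]),
            "n_scenarios": int(len({(a.repository, a.measure) for a in assocs})),
            "n_markers": int((ranking["verdict"] != "none").sum()),
        }

    if "network" in config.stages:
        net_taxa = prevalent[: config.network_max_taxa]
        pair_meta = pairwise_taxon_associations(collection, net_taxa, pseudocount=config.pseudocount)
        groups_map = {a.taxon: a.group for a in assignments}
        net = build_consensus_network(pair_meta, edge_q=config.edge_q, groups=groups_map,
                                      nodes=net_taxa)
        cent = node_centralities(net)
        cent["group"] = [net.nodes[t]["group"] for t in cent.index]
        cent.to_csv(out / "network_nodes.tsv", sep="\t", float_format="%.10g")
        edges = pd.DataFrame(
            [
                dict(taxon_a=a, taxon_b=b, pooled_estimate=d["pooled_estimate"],
                     q_value=d["q_value"])
                for a, b, d in sorted(net.edges(data=True))
            ]
        )
        edges.to_csv(out / "network_edges.tsv", sep="\t", index=False, float_format="%.10g")
        nx.write_graphml(net, out / "network.graphml")
        seed_roster = rosters["kendall_negative"] or list(net.nodes)
        seed_roster = [t for t in seed_roster if t in net]
        guild = extract_guild(net, seed_roster, frac=config.guild_frac)
        pd.Series(guild.members, name="taxon_id").to_csv(
            out / "guild.txt", index=False, header=False
        )
        manifest["stages"]["network"] = {
            "n_nodes": int(net.number_of_nodes()),
            "n_edges": int(net.number_of_edges()),
            "guild_size": len(guild.members),
            "guild_density_ok": bool(guild.density_ok),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _group_age_effects(collection, group_abund: pd.Series, config: RunConfig):
    """Per-study robust fits of a grouped abundance on age past onset."""
    from .meta import robust_linear_fit

    effs = []
    for study in collection.study_ids:
        meta = collection.study_metadata(study)
        old = meta.index[(meta["age"] >= config.min_age).fillna(False)]
        old = [s for s in old if s in group_abund.index]
        if len(old) < config.min_n_old:
            continue
        ages = collection.metadata.for_samples(old)["age"].to_numpy(dtype=float)
        y = group_abund.loc[old].to_numpy(dtype=float)
        try:
            fit = robust_linear_fit(y, ages)
        except ValidationError:
            continue
        effs.append(EffectEstimate("group", study, fit.estimate, fit.std_error, fit.p_value, fit.n))
    return effs


def _assemble_feature_panel(collection, indices, prevalent, rosters, config: RunConfig):
    """Samples x features: summary indices, grouped abundances and the clr
    abundances of the prevalent taxa (the marker candidate panel)."""
    if indices is None:
        raise ValidationError("markers stage requires the indices stage")
    features = indices.drop(columns=["study_id"]).copy()
    for name, roster in rosters.items():
        if roster:
            features[f"group_{name}"] = group_abundance_collection(
                collection, roster, config.pseudocount
            )
    clr_cols = {}
    for study in collection.study_ids:
        table = collection.tables[study]
        clr = table if table.scale == "clr" else clr_transform(table, config.pseudocount)
        for taxon in prevalent:
            if taxon in clr.values.index:
                clr_cols.setdefault(taxon, []).append(clr.values.loc[taxon])
    for taxon, parts in clr_cols.items():
        features[taxon] = pd.concat(parts)
    return features
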