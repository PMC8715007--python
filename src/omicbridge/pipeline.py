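"""End-to-end orchestration: simulate/load → filter → diversity → screens →
trends → reversal → qPCR validation → ensemble network → tripartite network →
bridge ranking.

Stage order is fixed (the procedure is linear); every stage writes its outputs
to disk under the run directory, and a deterministic manifest records the
config snapshot, seed and per-output SHA-256 checksums. Wall-clock timings go
to a separate timings file so the manifest itself is reproducible
byte-for-byte for identical inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import alpha_diversity_table, distance_matrix, pcoa
from .io import (
    AbundanceTable,
    FeatureTable,
    SampleMetadata,
    read_abundance_table,
    read_feature_table,
    read_json,
    write_json,
    write_metadata,
    write_network,
    write_table,
)
from .network import conet
from .qpcr import validate_responsive
from .screening import (
    differential_screen,
    filter_features,
    reversal_screen,
    screen_to_frame,
    total_ion_normalize,
    trend_consistency,
    trend_to_frame,
)
from .simulate import StudyConfig, SyntheticStudy, generate_study, substream, summarize_truth
from .tripartite import rank_bridge_metabolites, tripartite_network


class PipelineConfigError(ValueError):
    """The pipeline config violates its schema."""


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters, with defaults matching the published workflow:
    abundance filter sum ≥ 120 & occurrence ≥ 12, taxon VIP > 0.7, metabolite
    VIP > 1 with p < 0.05, candidate tails of 1000, 1000 permutation/bootstrap
    iterations, q < 0.05."""

    simulate: StudyConfig | None = None
    abundance_path: str | None = None
    metabolite_path: str | None = None
    indicator_path: str | None = None
    metadata_path: str | None = None
    filter_min_sum: float = 120.0
    filter_min_occurrence: int = 12
    taxon_vip_threshold: float = 0.7
    taxon_p_threshold: float | None = None
    metabolite_vip_threshold: float = 1.0
    metabolite_p_threshold: float = 0.05
    n_components: int = 2
    conet_top_n: int = 1000
    conet_bottom_n: int = 1000
    conet_iterations: int = 1000
    conet_min_support: int = 2
    conet_renormalize: bool = True
    q_threshold: float = 0.05
    qpcr_alpha: float = 0.05
    seed: int = 0
    out_dir: str = "omicbridge_run"

    def __post_init__(self) -> None:
        if self.simulate is None:
            missing = [
                name
                for name in ("abundance_path", "metabolite_path", "indicator_path", "metadata_path")
                if getattr(self, name) is None
            ]
            if missing:
                raise PipelineConfigError(
                    f"config needs either a simulate block or input paths; missing: {missing}"
                )
        for name in ("q_threshold", "metabolite_p_threshold", "qpcr_alpha"):
            v = getattr(self, name)
            if v is not None and not 0 < v <= 1:
                raise PipelineConfigError(f"{name} must be in (0, 1], got {v}")
        for name in ("taxon_vip_threshold", "metabolite_vip_threshold"):
            if getattr(self, name) < 0:
                raise PipelineConfigError(f"{name} must be >= 0")
        if self.conet_iterations < 100:
            raise PipelineConfigError("conet_iterations must be >= 100")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = StudyConfig.from_dict(d["simulate"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages: dict[str, dict[str, str]]  # stage -> {filename: sha256}
    timings: dict[str, float]  # stage -> seconds (written separately)

    def to_dict(self) -> dict:
        # out_dir describes where the run landed, not what it computed; two
        # identical runs in different directories must compare byte-identical
        config = {k: v for k, v in self.config.items() if k != "out_dir"}
        return {
            "config": config,
            "version": self.version,
            "seed": self.seed,
            "stages": self.stages,
        }


def _load_study(config: PipelineConfig) -> tuple[AbundanceTable, FeatureTable, FeatureTable, SampleMetadata, SyntheticStudy | None]:
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        study = generate_study(sim_cfg)
        return study.abundance, study.metabolites, study.indicators, study.metadata, study
    abundance, metadata = read_abundance_table(config.abundance_path, config.metadata_path)
    metabolites = read_feature_table(config.metabolite_path)
    indicators = read_feature_table(config.indicator_path)
    return abundance, metabolites, indicators, metadata, None


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage in order; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict[str, str]] = {}
    timings: dict[str, float] = {}

    def record(stage: str, *paths: Path) -> None:
        stages[stage] = {p.name: _sha256(p) for p in sorted(paths)}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.perf_counter() - t0, 3)

    # --- stage: inputs -------------------------------------------------------
    t0 = time.perf_counter()
    abundance, metabolites, indicators, metadata, study = _load_study(config)
    files = []
    for name, frame in (
        ("abundance.tsv", abundance.counts),
        ("metabolites.tsv", metabolites.values),
        ("indicators.tsv", indicators.values),
    ):
        write_table(frame, out / name)
        files.append(out / name)
    write_metadata(metadata, out / "metadata.tsv")
    files.append(out / "metadata.tsv")
    if study is not None:
        write_json(study.truth.to_dict(), out / "truth.json")
        write_table(summarize_truth(study).set_index("feature"), out / "truth_summary.tsv",
                    index_label="feature")
        files += [out / "truth.json", out / "truth_summary.tsv"]
    record("inputs", *files)
    tick("inputs", t0)

    meta = metadata.frame
    groups = tuple(config.simulate.groups) if config.simulate is not None else tuple(
        pd.unique(meta["group"])
    )
    if len(groups) != 3:
        raise PipelineConfigError(f"expected 3 groups (control, disease, treated), got {groups}")
    control, disease, treated = groups
    timepoints = sorted(pd.unique(meta["timepoint"]))

    # --- stage: filter -------------------------------------------------------
    t0 = time.perf_counter()
    condition = meta["group"].astype(str)
    filtered, discarded = filter_features(
        abundance, condition, config.filter_min_sum, config.filter_min_occurrence
    )
    write_table(filtered.counts, out / "abundance_filtered.tsv")
    write_json({"discarded_taxa": discarded}, out / "filter_report.json")
    record("filter", out / "abundance_filtered.tsv", out / "filter_report.json")
    tick("filter", t0)

    # --- stage: diversity ----------------------------------------------------
    t0 = time.perf_counter()
    alpha = alpha_diversity_table(filtered)
    write_table(alpha, out / "alpha_diversity.tsv")
    bc = distance_matrix(filtered, metric="braycurtis")
    write_table(bc, out / "braycurtis.tsv")
    ord_res = pcoa(bc, n_axes=min(3, len(filtered.samples) - 1))
    write_table(ord_res.coordinates, out / "pcoa.tsv")
    record("diversity", out / "alpha_diversity.tsv", out / "braycurtis.tsv", out / "pcoa.tsv")
    tick("diversity", t0)

    # --- stage: per-timepoint screens ---------------------------------------
    t0 = time.perf_counter()
    rel = filtered.relative()
    met_norm = total_ion_normalize(metabolites).values
    taxa_screens, met_screens = [], []
    screen_files = []
    for tp in timepoints:
        at_tp = meta[(meta["timepoint"] == tp) & meta["group"].isin([control, disease])]
        samples = at_tp.index
        grouping = at_tp["group"]
        t_screen = differential_screen(
            rel.loc[samples], grouping, config.taxon_vip_threshold,
            config.taxon_p_threshold, config.n_components, timepoint=tp, case_group=disease,
        )
        m_screen = differential_screen(
            met_norm.loc[samples], grouping, config.metabolite_vip_threshold,
            config.metabolite_p_threshold, config.n_components, timepoint=tp, case_group=disease,
        )
        taxa_screens.append(t_screen)
        met_screens.append(m_screen)
        for label, screen in (("taxa", t_screen), ("metabolites", m_screen)):
            path = out / f"screen_{label}_t{tp}.tsv"
            screen_to_frame(screen).to_csv(path, sep="\t", index=False)
            screen_files.append(path)
    record("screen", *screen_files)
    tick("screen", t0)

    # --- stage: trends -------------------------------------------------------
    t0 = time.perf_counter()
    taxa_trends = trend_consistency(taxa_screens)
    met_trends = trend_consistency(met_screens)
    trend_to_frame(taxa_trends).to_csv(out / "trends_taxa.tsv", sep="\t", index=False)
    trend_to_frame(met_trends).to_csv(out / "trends_metabolites.tsv", sep="\t", index=False)
    record("trends", out / "trends_taxa.tsv", out / "trends_metabolites.tsv")
    tick("trends", t0)
    consistent_taxa = [t.feature for t in taxa_trends if t.consistent]
    consistent_mets = [t.feature for t in met_trends if t.consistent]

    # --- stage: reversal (metabolites, post-treatment timepoints) ------------
    t0 = time.perf_counter()
    treatment_tps = [tp for tp in timepoints[1:]]
    reversal = reversal_screen(
        met_norm, metadata, consistent_mets, treatment_tps, groups,
    ) if consistent_mets else pd.DataFrame(columns=["feature", "reversed"])
    reversal.to_csv(out / "reversal_metabolites.tsv", sep="\t", index=False)
    record("reversal", out / "reversal_metabolites.tsv")
    tick("reversal", t0)
    reversed_mets = list(reversal.loc[reversal["reversed"] == True, "feature"]) if len(reversal) else []  # noqa: E712

    # --- stage: qPCR-style validation of responsive taxa ---------------------
    # Absolute copy numbers are emulated by per-sample relative abundances at
    # the final timepoint (the real workflow measures species-specific qPCR).
    t0 = time.perf_counter()
    final_tp = timepoints[-1]
    at_final = meta[meta["timepoint"] == final_tp]
    copies = {
        taxon: {
            g: rel.loc[at_final.index[at_final["group"] == g], taxon].values
            for g in groups
        }
        for taxon in consistent_taxa
    }
    calls = validate_responsive(copies, alpha=config.qpcr_alpha, groups=groups) if copies else []
    pd.DataFrame(calls).to_csv(out / "responsive_taxa.tsv", sep="\t", index=False)
    record("qpcr", out / "responsive_taxa.tsv")
    tick("qpcr", t0)
    responsive = [c["taxon"] for c in calls if c["responsive"]]

    # --- stage: ensemble co-occurrence network (disease-group samples) -------
    t0 = time.perf_counter()
    disease_samples = meta.index[meta["group"] == disease]
    conet_seed = int(substream(config.seed, "conet").integers(2**31))
    edges, conflicts = conet(
        filtered.counts.loc[disease_samples].values,
        filtered.taxa,
        top_n=config.conet_top_n,
        bottom_n=config.conet_bottom_n,
        iterations=config.conet_iterations,
        q_threshold=config.q_threshold,
        min_support=config.conet_min_support,
        renormalize=config.conet_renormalize,
        seed=conet_seed,
    )
    taxa_nodes = {t: "taxon" for t in filtered.taxa}
    write_network(taxa_nodes, edges, out / "conet_edges.tsv", format="edge_tsv")
    write_network(taxa_nodes, edges, out / "conet.graphml", format="graphml")
    write_json({"sign_conflicts": [list(c) for c in conflicts]}, out / "conet_report.json")
    record("conet", out / "conet_edges.tsv", out / "conet.graphml", out / "conet_report.json")
    tick("conet", t0)

    # --- stage: tripartite network -------------------------------------------
    t0 = time.perf_counter()
    taxa_layer = responsive if responsive else consistent_taxa
    met_layer = reversed_mets
    tri_edges = []
    if taxa_layer and met_layer:
        tri = tripartite_network(
            rel[taxa_layer], met_norm[met_layer], indicators.values,
            q_threshold=config.q_threshold,
        )
        tri_edges = tri.edges
        tri_nodes = tri.nodes
    else:
        tri = None
        tri_nodes = {
            **{t: "taxon" for t in taxa_layer},
            **{m: "metabolite" for m in met_layer},
            **{i: "indicator" for i in indicators.features},
        }
    write_network(tri_nodes, tri_edges, out / "tripartite_edges.tsv", format="edge_tsv")
    write_network(tri_nodes, tri_edges, out / "tripartite.graphml", format="graphml")
    record("tripartite", out / "tripartite_edges.tsv", out / "tripartite.graphml")
    tick("tripartite", t0)

    # --- stage: bridge ranking ------------------------------------------------
    t0 = time.perf_counter()
    bridges = rank_bridge_metabolites(tri) if tri is not None else pd.DataFrame(
        columns=["metabolite", "degree", "taxon_edges", "indicator_edges", "sum_abs_rho"]
    )
    bridges.to_csv(out / "bridge_metabolites.tsv", sep="\t", index=False)
    files = [out / "bridge_metabolites.tsv"]
    if study is not None:
        recovery = _recovery_report(
            study, consistent_taxa, responsive, reversed_mets, bridges
        )
        write_json(recovery, out / "recovery.json")
        files.append(out / "recovery.json")
    record("bridges", *files)
    tick("bridges", t0)

    manifest = RunManifest(
        config=config.to_dict(), version=__version__, seed=config.seed,
        stages=stages, timings=timings,
    )
    write_json(manifest.to_dict(), out / "manifest.json")
    write_json(timings, out / "timings.json")
    return manifest


def _recovery_report(
    study: SyntheticStudy,
    consistent_taxa: list[str],
    responsive: list[str],
    reversed_mets: list[str],
    bridges: pd.DataFrame,
) -> dict:
    """Precision/recall of the planted structure when truth is available."""
    true_taxa = set(study.truth.responsive_taxa)
    true_mets = set(study.truth.mediating_metabolites)
    top10 = list(bridges["metabolite"].head(10)) if len(bridges) else []

    def pr(found: list[str], truth: set[str]) -> dict:
        found_set = set(found)
        tp = len(found_set & truth)
        return {
            "n_found": len(found_set),
            "n_true": len(truth),
            "true_positives": tp,
            "precision": tp / len(found_set) if found_set else float("nan"),
            "recall": tp / len(truth) if truth else float("nan"),
        }

    return {
        "trend_consistent_taxa": pr(consistent_taxa, true_taxa),
        "validated_responsive_taxa": pr(responsive, true_taxa),
        "reversed_metabolites": pr(reversed_mets, true_mets),
        "bridges_top10": pr(top10, true_mets),
        "false_bridges_top10": len(set(top10) - true_mets),
    }


def load_pipeline_config(path: str) -> PipelineConfig:
    return PipelineConfig.from_dict(read_json(path))
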