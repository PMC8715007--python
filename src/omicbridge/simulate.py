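"""Synthetic longitudinal three-group multi-omics studies with planted truth.

The generator emulates the processed data layer of a chronic-disease mouse
study: a control group, a disease group whose planted taxa drift monotonically
with age, and a treated group in which that drift is partially reversed after
dosing begins. Mediating metabolites track their source taxon's latent
log-abundance, and linked indicators track their mediating metabolites, so the
full screening → reversal → tripartite-network chain is recoverable from the
planted structure.

All randomness flows from one integer seed through named substreams, so each
layer is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd

from .io import AbundanceTable, FeatureTable, SampleMetadata


class ConfigError(ValueError):
    """A StudyConfig field violates its invariant."""


@dataclasses.dataclass
class StudyConfig:
    """Design and effect-size parameters of a simulated study.

    Defaults mirror a 3-group × 3-timepoint rodent design with 6 subjects per
    group: 100 taxa (5 planted drug-responsive), 300 metabolite features
    (5 planted mediators), 11 pathological/neurochemical indicators, a 2.5-fold
    disease effect per timepoint step and 80% treatment reversal.
    """

    n_subjects_per_group: int = 6
    groups: tuple[str, str, str] = ("WT", "Tg", "TgR")  # control, disease, treated
    timepoints: tuple[float, ...] = (8, 9, 10)  # months of age
    n_taxa: int = 100
    n_metabolites: int = 300
    n_indicators: int = 11
    n_responsive_taxa: int = 5
    n_mediating_metabolites: int = 5
    disease_effect: float = 2.5  # multiplicative fold change per timepoint step
    reversal_fraction: float = 0.8  # share of the disease effect undone by treatment
    library_size_mean: float = 50_000.0
    library_size_dispersion: float = 0.3  # sd of log library size
    taxon_base_logmean_sd: float = 1.0
    metabolite_noise_sd: float = 0.3
    indicator_noise_sd: float = 0.3
    link_strength: float = 1.0  # slope: mediator log-intensity per unit taxon log-abundance
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects_per_group": self.n_subjects_per_group,
            "n_taxa": self.n_taxa,
            "n_metabolites": self.n_metabolites,
            "n_indicators": self.n_indicators,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if not 0 <= self.n_responsive_taxa <= self.n_taxa:
            raise ConfigError("n_responsive_taxa must be in [0, n_taxa]")
        if not 0 <= self.n_mediating_metabolites <= self.n_metabolites:
            raise ConfigError("n_mediating_metabolites must be in [0, n_metabolites]")
        if self.n_mediating_metabolites > 0 and self.n_responsive_taxa == 0:
            raise ConfigError("mediating metabolites require at least one responsive taxon")
        if self.disease_effect <= 0:
            raise ConfigError("disease_effect must be > 0")
        if not 0 <= self.reversal_fraction <= 1:
            raise ConfigError("reversal_fraction must be in [0, 1]")
        if len(self.groups) != 3:
            raise ConfigError("groups must name (control, disease, treated)")
        if len(self.timepoints) < 1:
            raise ConfigError("at least one timepoint required")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["timepoints"] = list(self.timepoints)
        return d


@dataclasses.dataclass
class TruthLabels:
    """Ground truth emitted alongside a synthetic study."""

    responsive_taxa: dict[str, int]  # taxon id -> direction (+1 disease-up, -1 down)
    mediating_metabolites: dict[str, dict]  # metabolite id -> {source_taxon, indicators: [...]}
    linked_indicators: list[str]

    def to_dict(self) -> dict:
        return {
            "responsive_taxa": self.responsive_taxa,
            "mediating_metabolites": self.mediating_metabolites,
            "linked_indicators": self.linked_indicators,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthLabels":
        return cls(
            responsive_taxa={k: int(v) for k, v in d["responsive_taxa"].items()},
            mediating_metabolites=d["mediating_metabolites"],
            linked_indicators=list(d["linked_indicators"]),
        )


@dataclasses.dataclass
class SyntheticStudy:
    abundance: AbundanceTable
    metabolites: FeatureTable
    indicators: FeatureTable
    metadata: SampleMetadata
    truth: TruthLabels


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG: independent, reproducible streams per stage/layer."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _latent_taxon_log_abundance(config: StudyConfig, base: np.ndarray,
                                directions: np.ndarray, responsive_idx: np.ndarray,
                                group: str, t_index: int) -> np.ndarray:
    """Expected log-abundance of every taxon in one group × timepoint cell.

    The disease group multiplies each responsive taxon's expected abundance by
    disease_effect^(t_index+1) in the planted direction; the treated group
    receives that effect scaled by (1 - reversal_fraction) at post-treatment
    timepoints (indices >= 1) and the full effect at the pre-treatment baseline.
    """
    log_mu = base.copy()
    control, disease, treated = config.groups
    if group == control or config.n_responsive_taxa == 0:
        return log_mu
    effect = np.log(config.disease_effect) * (t_index + 1)
    if group == treated and t_index >= 1:
        effect *= 1.0 - config.reversal_fraction
    log_mu[responsive_idx] = log_mu[responsive_idx] + directions * effect
    return log_mu


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Draw one complete synthetic study (deterministic given config.seed)."""
    rng_taxa = substream(config.seed, "taxa")
    rng_counts = substream(config.seed, "counts")
    rng_metab = substream(config.seed, "metabolites")
    rng_indic = substream(config.seed, "indicators")

    taxa = [f"taxon_{i:03d}" for i in range(config.n_taxa)]
    metabolites = [f"met_{i:04d}" for i in range(config.n_metabolites)]
    indicators = [f"indicator_{i:02d}" for i in range(config.n_indicators)]

    # planted structure ------------------------------------------------------
    responsive_idx = rng_taxa.choice(config.n_taxa, size=config.n_responsive_taxa, replace=False)
    responsive_idx.sort()
    # both disease-up and disease-down taxa, alternating for a balanced plant
    directions = np.array([1 if k % 2 == 0 else -1 for k in range(config.n_responsive_taxa)])
    mediator_idx = rng_metab.choice(
        config.n_metabolites, size=config.n_mediating_metabolites, replace=False
    )
    mediator_idx.sort()
    n_linked = min(config.n_indicators, max(1, config.n_mediating_metabolites)) if config.n_mediating_metabolites else 0
    linked_ind_idx = np.arange(n_linked)
    # each mediator sources from one responsive taxon, round-robin; each links
    # to one indicator, round-robin over the linked set
    mediator_source = (
        responsive_idx[np.arange(config.n_mediating_metabolites) % max(config.n_responsive_taxa, 1)]
        if config.n_mediating_metabolites
        else np.array([], dtype=int)
    )
    mediator_indicator = (
        linked_ind_idx[np.arange(config.n_mediating_metabolites) % max(n_linked, 1)]
        if config.n_mediating_metabolites
        else np.array([], dtype=int)
    )

    base = rng_taxa.normal(0.0, config.taxon_base_logmean_sd, size=config.n_taxa)

    # design -----------------------------------------------------------------
    rows = []
    for g_index, group in enumerate(config.groups):
        for s in range(config.n_subjects_per_group):
            subject = f"{group}_s{s + 1}"
            for t_index, tp in enumerate(config.timepoints):
                rows.append(
                    {
                        "sample": f"{subject}_t{t_index}",
                        "subject": subject,
                        "group": group,
                        "timepoint": tp,
                        "t_index": t_index,
                    }
                )
    design = pd.DataFrame(rows).set_index("sample")
    n_samples = len(design)

    # latent log-abundance per sample (deterministic per group × timepoint) ---
    latent = np.empty((n_samples, config.n_taxa))
    for i, (_, row) in enumerate(design.iterrows()):
        latent[i] = _latent_taxon_log_abundance(
            config, base, directions, responsive_idx, row["group"], int(row["t_index"])
        )

    # multinomial counts after closure ---------------------------------------
    props = np.exp(latent)
    props /= props.sum(axis=1, keepdims=True)
    lib_mu = np.log(config.library_size_mean) - 0.5 * config.library_size_dispersion**2
    library = np.maximum(
        1,
        np.round(
            rng_counts.lognormal(lib_mu, config.library_size_dispersion, size=n_samples)
        ).astype(np.int64),
    )
    counts = np.empty((n_samples, config.n_taxa), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng_counts.multinomial(library[i], props[i])

    # metabolites -------------------------------------------------------------
    met_base = rng_metab.normal(0.0, 1.0, size=config.n_metabolites)
    log_met = met_base + rng_metab.normal(
        0.0, config.metabolite_noise_sd, size=(n_samples, config.n_metabolites)
    )
    # mediators track their source taxon's latent log-abundance
    mediator_latent = np.zeros((n_samples, config.n_mediating_metabolites))
    for k in range(config.n_mediating_metabolites):
        mediator_latent[:, k] = config.link_strength * latent[:, mediator_source[k]]
        log_met[:, mediator_idx[k]] = (
            met_base[mediator_idx[k]]
            + mediator_latent[:, k]
            + rng_metab.normal(0.0, config.metabolite_noise_sd, size=n_samples)
        )

    # indicators: signed sum of their mediating metabolites' latent values -----
    ind_base = rng_indic.normal(0.0, 1.0, size=config.n_indicators)
    log_ind = ind_base + rng_indic.normal(
        0.0, config.indicator_noise_sd, size=(n_samples, config.n_indicators)
    )
    ind_signs = np.array([1 if k % 2 == 0 else -1 for k in range(config.n_mediating_metabolites)])
    for j in linked_ind_idx:
        members = np.nonzero(mediator_indicator == j)[0]
        signal = sum(ind_signs[k] * mediator_latent[:, k] for k in members)
        log_ind[:, j] = ind_base[j] + signal + rng_indic.normal(
            0.0, config.indicator_noise_sd, size=n_samples
        )

    # assemble ----------------------------------------------------------------
    metadata = SampleMetadata(design[["subject", "group", "timepoint"]].copy())
    abundance = AbundanceTable(pd.DataFrame(counts, index=design.index, columns=taxa))
    met_table = FeatureTable(
        pd.DataFrame(np.exp(log_met), index=design.index, columns=metabolites),
        annotation=pd.DataFrame(
            {
                "mz": np.round(rng_metab.uniform(80, 1000, config.n_metabolites), 4),
                "rt": np.round(rng_metab.uniform(0.5, 14.0, config.n_metabolites), 3),
            },
            index=pd.Index(metabolites, name="feature"),
        ),
    )
    ind_table = FeatureTable(pd.DataFrame(np.exp(log_ind), index=design.index, columns=indicators))

    truth = TruthLabels(
        responsive_taxa={taxa[i]: int(d) for i, d in zip(responsive_idx, directions)},
        mediating_metabolites={
            metabolites[mediator_idx[k]]: {
                "source_taxon": taxa[mediator_source[k]],
                "indicators": [indicators[mediator_indicator[k]]],
                "direction": int(directions[np.nonzero(responsive_idx == mediator_source[k])[0][0]]),
            }
            for k in range(config.n_mediating_metabolites)
        },
        linked_indicators=[indicators[j] for j in linked_ind_idx],
    )
    return SyntheticStudy(abundance, met_table, ind_table, metadata, truth)


def summarize_truth(study: SyntheticStudy) -> pd.DataFrame:
    """One row per planted feature: (feature, layer, role, direction)."""
    if study.truth is None:
        raise ValueError("study carries no truth labels")
    rows = []
    for taxon, direction in sorted(study.truth.responsive_taxa.items()):
        rows.append({"feature": taxon, "layer": "taxon", "role": "responsive", "direction": direction})
    for met, info in sorted(study.truth.mediating_metabolites.items()):
        rows.append(
            {
                "feature": met,
                "layer": "metabolite",
                "role": f"mediator(source={info['source_taxon']})",
                "direction": int(info.get("direction", 0)),
            }
        )
    for ind in sorted(study.truth.linked_indicators):
        rows.append({"feature": ind, "layer": "indicator", "role": "linked", "direction": 0})
    return pd.DataFrame(rows, columns=["feature", "layer", "role", "direction"])
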