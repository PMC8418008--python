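"""Simulation configuration for the synthetic multi-omic study design.

The default configuration mirrors the experimental layout the pipeline is
built for: three cellular contexts (tumor-repopulating cells, the parental
cancer line, and a normal-liver analog) treated at three retinoid doses
(0, 1 and 5 uM) in triplicate, profiled on the log2 expression scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

DEFAULT_CONTEXTS: tuple[str, ...] = ("TRC", "parental", "liver")

#: Oncogenic pathway families emphasized by the ranking's pathway criterion.
ONCOGENIC_PATHWAY_IDS: tuple[str, ...] = (
    "RAS_SIGNALING",
    "CELL_CYCLE",
    "PLURIPOTENCY_OF_STEM_CELLS",
    "UBIQUITIN_MEDIATED_PROTEOLYSIS",
)


@dataclass(frozen=True)
class DriverSpec:
    """Planted evidence for the driver gene.

    Every quantity strictly exceeds the pipeline's default thresholds
    (degree >= 18, membership >= 0.2, peak M >= 0.5) so that the driver is
    recoverable by the four-priority ranking.

    Parameters
    ----------
    target_degree
        Number of companion genes generated as noisy affine copies of the
        driver's dose-response profile; these become the driver's network
        neighbors at the |r| > 0.9 edge threshold.
    n_pathways
        Number of catalog pathways containing the driver (all drawn from the
        oncogenic families).
    peak_m
        M-value of the driver's planted promoter peak.
    cluster_pattern
        Index (0-based) of the archetype pattern the driver follows; must be
        one of the monotonically decreasing patterns.
    membership_floor
        Minimum fuzzy-cluster membership the planted design must support.
    n_companion_peaks
        How many companion genes also receive a passing promoter peak, so the
        ranking has genuine high-degree competitors.
    """

    target_degree: int = 25
    n_pathways: int = 4
    peak_m: float = 1.2
    cluster_pattern: int = 0
    membership_floor: float = 0.2
    n_companion_peaks: int = 3

    def validate(self) -> None:
        if self.target_degree < 18:
            raise ValueError("target_degree must be >= 18 (degree filter default)")
        if self.peak_m < 0.5:
            raise ValueError("peak_m must exceed the default M-value filter (0.5)")
        if not (0 <= self.membership_floor <= 1):
            raise ValueError("membership_floor must lie in [0, 1]")
        if self.n_companion_peaks > self.target_degree:
            raise ValueError("cannot plant more companion peaks than companions")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for the synthetic dataset.

    ``noise_sd`` is the replicate-level Gaussian noise on log2 expression;
    ``gene_jitter_sd`` is per-gene condition-level biological variability that
    keeps unrelated same-pattern genes below the co-expression edge threshold.
    """

    n_genes: int = 200
    contexts: tuple[str, ...] = DEFAULT_CONTEXTS
    doses: tuple[float, ...] = (0.0, 1.0, 5.0)
    n_replicates: int = 3
    n_clusters_planted: int = 8
    noise_sd: float = 0.05
    gene_jitter_sd: float = 0.5
    companion_rel_sd: float = 0.38
    pattern_amplitude: float = 1.0
    n_decoy_peaks: int = 100
    peak_pass_fraction: float = 0.4
    driver_spec: DriverSpec = field(default_factory=DriverSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_clusters_planted:
            raise ValueError("n_genes must be >= n_clusters_planted")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError(f"doses must be strictly increasing, got {self.doses}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gene_jitter_sd < 0:
            raise ValueError("gene_jitter_sd must be >= 0")
        if self.companion_rel_sd < 0:
            raise ValueError("companion_rel_sd must be >= 0")
        if len(self.contexts) != len(set(self.contexts)):
            raise ValueError("contexts must be unique")
        for c in self.contexts:
            if "_" in c or not c:
                raise ValueError(f"context labels may not be empty or contain '_': {c!r}")
        if not (0 <= self.peak_pass_fraction <= 1):
            raise ValueError("peak_pass_fraction must lie in [0, 1]")
        if self.n_genes < self.driver_spec.target_degree + 1:
            raise ValueError("n_genes too small for the planted driver clique")
        self.driver_spec.validate()

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    @property
    def n_conditions(self) -> int:
        return self.n_contexts * len(self.doses)

    @property
    def n_samples(self) -> int:
        return self.n_conditions * self.n_replicates

    def replace(self, **kwargs) -> "SimulationConfig":
        data = asdict(self)
        driver = data.pop("driver_spec")
        data["driver_spec"] = DriverSpec(**driver)
        data["contexts"] = tuple(data["contexts"])
        data["doses"] = tuple(data["doses"])
        data.update(kwargs)
        return SimulationConfig(**data)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a SimulationConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    driver = DriverSpec(**raw.pop("driver_spec", {}))
    for key in ("contexts", "doses"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimulationConfig(driver_spec=driver, **raw)


def dump_config(config: SimulationConfig, path: str | Path) -> None:
    data = asdict(config)
    data["contexts"] = list(config.contexts)
    data["doses"] = list(config.doses)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
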