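"""Simulation configuration.

All rates are per gene copy per unit of species-tree time unless noted.
A seed is mandatory wherever randomness exists; there is no default seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

OPSIN_FAMILIES = ("UV", "blue", "LW", "RH7", "c-opsin")


@dataclass
class PlantedEvent:
    """An event fixed by hand rather than drawn from the rate process.

    ``branch`` is the species-tree edge (named by its child node label on
    internal nodes, or the leaf label) on which the event occurs; ``family``
    selects the opsin family acted on, ``copy_index`` which extant copy of
    that family in the lineage is the source.
    """

    kind: str  # duplication_tandem | duplication_dispersed | duplication_retro
    #            | loss | translocation | chromosome_fusion
    branch: str
    family: str = "LW"
    copy_index: int = 0
    dest_chrom: str | None = None  # for dispersed/retro/translocation/fusion source


@dataclass
class SimulationConfig:
    seed: int
    n_species: int = 12
    birth: float = 1.0
    death: float = 0.0

    # gene-family event rates (per copy per unit time)
    rate_tandem: float = 0.0
    rate_dispersed: float = 0.0
    rate_retro: float = 0.0
    rate_loss: float = 0.0
    rate_translocation: float = 0.0
    rate_fusion: float = 0.0  # per lineage per unit time
    planted_events: list[PlantedEvent] = field(default_factory=list)

    # codon model
    kappa: float = 2.0
    omega_background: float = 0.15
    omega_retro: float = 0.5
    rate_scale: float = 0.4  # neutral substitutions/site per unit of tree time
    #                          (pipelines normalize tree height to 1, making
    #                           this the root-to-tip neutral divergence)
    n_codons: int = 350
    n_introns: int = 7  # ancestral opsins carry 7 introns, like LWS1
    intron_length: int = 90

    # genome layout
    n_autosomes: int = 6
    background_genes_per_chrom: int = 12
    intergenic_mean: float = 1500.0
    tandem_spacing: float = 6000.0  # tandem paralogs sit ~6 kb apart
    families: tuple[str, ...] = OPSIN_FAMILIES

    # expression
    stages: tuple[str, ...] = ("larva_instar1", "adult_male_head", "adult_female_head")
    replicates_per_stage: int = 3
    expression_mean: float = 200.0
    expression_dispersion: float = 10.0
    stage_bias_fold: float = 50.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for name in ("rate_tandem", "rate_dispersed", "rate_retro", "rate_loss",
                     "rate_translocation", "rate_fusion", "omega_background",
                     "omega_retro", "birth", "death"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        planted = [PlantedEvent(**e) for e in raw.pop("planted_events", [])]
        cfg = cls(**raw)
        cfg.planted_events = planted
        cfg.validate()
        return cfg
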