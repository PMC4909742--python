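"""Default physiological constants and the experiment configuration.

Values collected here are the study conditions used throughout the
package: electrophysiological fitting targets for layer II/III
somatosensory pyramidal neurons, spine geometry, and discretization /
binning choices.  Everything is overridable through
:class:`ExperimentConfig` (YAML-serializable for the CLI).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

# --- morphology / spines ----------------------------------------------------
SOMA_AREA_UM2 = 452.0
SPINE_AREA_UM2 = 1.5
SPINE_DENSITY_PER_UM = {"WT": 2.0, "TG": 1.5, "TG_PRIME": 1.5}
MAX_COMPARTMENT_LEN_UM = 37.0

# --- membrane / fitting -----------------------------------------------------
RA_OHMCM = 150.0
FIXED_RM_KOHMCM2 = 50.0  # the non-fitted side in non-uniform membrane models
TARGET_RIN_MOHM = 130.0
RIN_TOL_MOHM = 0.1
TARGET_TAU_MS = {"WT": 17.0, "TG": 16.9}
CM_GRID_STEP_UF_CM2 = 0.5

# --- site placement / binning ----------------------------------------------
MAX_SITE_SPACING_UM = 37.0
MAX_SITE_SPACING_LAMBDA = 0.2
BIN_WIDTH_PATH_UM = 25.0
BIN_WIDTH_NORMALIZED_PCT = 5.0
BIN_WIDTH_TRANSFER = 0.05
BIN_WIDTH_DELAY_MS = 1.0
MIN_NEURONS_PER_BIN = 5
ALPHA = 0.05

MODEL_KINDS = ("leaky_soma", "uniform", "leaky_dendrite")


@dataclass
class ExperimentConfig:
    """Full configuration of a generate -> fit -> analyze -> compare run."""

    seed: int = 1
    n_per_group: int = 29
    model_kinds: tuple[str, ...] = MODEL_KINDS
    soma_area_um2: float = SOMA_AREA_UM2
    spine_area_um2: float = SPINE_AREA_UM2
    spine_density_per_um: dict = field(
        default_factory=lambda: dict(SPINE_DENSITY_PER_UM)
    )
    max_compartment_len_um: float = MAX_COMPARTMENT_LEN_UM
    ra_ohmcm: float = RA_OHMCM
    fixed_rm_kohmcm2: float = FIXED_RM_KOHMCM2
    target_rin_mohm: float = TARGET_RIN_MOHM
    rin_tol_mohm: float = RIN_TOL_MOHM
    target_tau_ms: dict = field(default_factory=lambda: dict(TARGET_TAU_MS))
    cm_grid_step: float = CM_GRID_STEP_UF_CM2
    cm_mode: str = "grid"  # "grid" | "continuous"
    bin_width_path_um: float = BIN_WIDTH_PATH_UM
    bin_width_transfer: float = BIN_WIDTH_TRANSFER
    bin_width_delay_ms: float = BIN_WIDTH_DELAY_MS
    min_neurons_per_bin: int = MIN_NEURONS_PER_BIN
    alpha: float = ALPHA
    out_dir: str = "results"

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for k in self.model_kinds:
            if k not in MODEL_KINDS:
                raise ValueError(f"unknown membrane model kind {k!r}")
        if self.cm_mode not in ("grid", "continuous"):
            raise ValueError("cm_mode must be 'grid' or 'continuous'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["model_kinds"] = list(self.model_kinds)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text) or {}
        if "model_kinds" in d:
            d["model_kinds"] = tuple(d["model_kinds"])
        cfg = cls(**d)
        cfg.validate()
        return cfg
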