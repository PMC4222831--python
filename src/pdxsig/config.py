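"""Configuration objects shared across the simulation and analysis stages.

Two dataclasses drive everything: :class:`SimulationConfig` parameterizes the
synthetic study generator (growth curves, Ct tables, patient cohort) and
:class:`SelectionConfig` parameterizes the gene-signature selection procedure.
Both can be round-tripped through YAML for CLI use, and a single root seed can
be fanned out deterministically to per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

# Candidate panel emulating a hypothesis-driven qPCR screen around a TNF-family
# receptor: signature genes, stemness/EMT markers, NF-kB pathway members,
# inflammation/angiogenesis genes, plus murine (stromal) counterparts.
SIGNATURE_GENES_UP: tuple[str, ...] = ("MCL1", "WNT5A", "CD24", "HGF", "CDKN1A", "HIF1A")
SIGNATURE_GENES_DOWN: tuple[str, ...] = ("PROM1", "VIM")

_UNINFORMATIVE_HUMAN: tuple[str, ...] = (
    "ALDH1A1", "CXCL10", "CXCL12", "GLI1", "IL1A", "IL1B", "IL6",
    "MMP1", "MMP9", "PECAM1", "SELE", "SNAI2", "KDR", "CD44",
)

_OTHER_HUMAN: tuple[str, ...] = (
    "TNFRSF12A", "TNFSF12", "NFKB1", "NFKB2", "RELA", "TRAF1", "TRAF2",
    "BIRC2", "BIRC3", "BCL2L1", "BCL2", "BAX", "CASP3", "CCND1", "MYC",
    "MKI67", "EGFR", "ERBB2", "ESR1", "PGR", "MET", "CDH1", "CDH2",
    "SNAI1", "TWIST1", "ZEB1", "FN1",
)

HUMAN_GENES: tuple[str, ...] = SIGNATURE_GENES_UP + SIGNATURE_GENES_DOWN + _UNINFORMATIVE_HUMAN + _OTHER_HUMAN

MURINE_GENES: tuple[str, ...] = (
    "mm-Flt1", "mm-Kdr", "mm-Pecam1", "mm-Il6", "mm-Tnf", "mm-Tgfb1",
    "mm-Col1a1", "mm-Acta2",
)

#: Genes the generator plants as uninformative, split between "invariant"
#: (never detected in any sample) and "single_model" (detected in one model
#: only).  Both patterns are removed by the invariance filter downstream.
DEFAULT_UNINFORMATIVE: Mapping[str, str] = {
    **{g: "invariant" for g in _UNINFORMATIVE_HUMAN[:8]},
    **{g: "single_model" for g in _UNINFORMATIVE_HUMAN[8:]},
    "mm-Flt1": "single_model",
}

# Control gene names used in Ct tables.
TOTAL_TBP = "Total-TBP"
HS_TBP = "Hs-TBP"
MM_TBP = "Mm-TBP"

DEFAULT_PLANTED: tuple[tuple[str, str, float], ...] = tuple(
    [(g, "up", 2.0) for g in SIGNATURE_GENES_UP] + [(g, "down", 2.0) for g in SIGNATURE_GENES_DOWN]
)

#: Target optimal TGI (percent) per responder model, matching the magnitudes a
#: clearly active antibody produces in sensitive PDX models.
DEFAULT_TARGET_TGI: Mapping[str, float] = {
    "PDX1": 65.0, "PDX2": 59.0, "PDX3": 80.0, "PDX4": 91.0,
}


def treatment_effect_for_target_tgi(target_tgi: float, growth_rate: float, day: float) -> float:
    """Growth-rate multiplier giving the requested noise-free optimal TGI.

    With exponential growth, the treated/control mean-RTV ratio at time ``t``
    is ``exp(r*(f-1)*t)`` for a treated rate ``f*r``; solving
    ``1 - ratio = TGI/100`` at the last measurement day gives ``f``.
    """
    if not 0 <= target_tgi < 100:
        raise ValueError("target TGI must be in [0, 100)")
    ratio = 1.0 - target_tgi / 100.0
    return 1.0 + math.log(ratio) / (growth_rate * day)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic preclinical study.

    Defaults emulate a study of 8 PDX models (4 responders), two arms of 10
    mice measured twice weekly for 35 days, a 57-gene qPCR screen on 5 control
    tumors per model with mouse stromal contamination, and a 134-patient IHC
    cohort with censored survival.
    """

    seed: int = 0
    # --- in vivo growth study ---
    n_models: int = 8
    responder_models: tuple[str, ...] = ("PDX1", "PDX2", "PDX3", "PDX4")
    mice_per_arm: int = 10
    measurement_days: tuple[int, ...] = (0, 3, 7, 10, 14, 17, 21, 24, 28, 31, 35)
    initial_volume_range: tuple[float, float] = (60.0, 200.0)
    control_growth_rate: float = 0.085  # per day, ~130 -> 2500 mm^3 in 35 d
    target_tgi: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TARGET_TGI))
    treatment_effect: Mapping[str, float] | None = None  # overrides target_tgi
    volume_noise_cv: float = 0.15
    sacrifice_volume: float = 2500.0
    aspect_ratio: float = 1.3  # a/b used to emit caliper diameters
    # --- relapse / maintenance arm ---
    relapse_hazard_control: float = math.log(2) / 66.0  # per day
    relapse_hazard_treated: float = math.log(2) / 116.0
    relapse_followup: float = 120.0
    relapse_mice_control: int = 11
    relapse_mice_treated: int = 10
    # --- qPCR screen ---
    n_human_genes: int = 49
    n_murine_genes: int = 8
    tumors_per_model: int = 5
    planted_genes: tuple[tuple[str, str, float], ...] = DEFAULT_PLANTED
    uninformative_genes: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_UNINFORMATIVE))
    effect_sd_unit: float = 1.0   # log2 units per planted-effect "SD"
    model_effect_sd: float = 0.3  # log2 units, between models within a class
    residual_sd: float = 0.95     # log2 units, tumor-to-tumor within a model
    contamination_range: tuple[float, float] = (5.0, 30.0)  # percent mouse cells
    basal_ct: float = 35.0
    undetected_ct: float = 38.0
    control_ct: float = 27.0      # typical Total-TBP Ct
    control_ct_sd: float = 0.25
    n_replicates: int = 2
    ct_replicate_sd: float = 0.15
    # --- patient cohort ---
    n_patients: int = 134
    subtype_weights: Mapping[str, int] = field(
        default_factory=lambda: {"basal-like": 39, "ERBB2+": 31, "luminal A": 28, "luminal B": 36}
    )
    covariate_log_odds: float = 0.0   # association covariate <-> positivity
    survival_log_hr: float = 0.0      # log hazard ratio positive vs negative
    survival_median_months: float = 47.0
    followup_max_months: float = 109.0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("need at least 2 models")
        if self.mice_per_arm < 2:
            raise ValueError("mice_per_arm must be >= 2")
        if self.control_growth_rate <= 0:
            raise ValueError("control_growth_rate must be positive")
        if self.relapse_hazard_control <= 0 or self.relapse_hazard_treated <= 0:
            raise ValueError("relapse hazards must be positive")
        if self.volume_noise_cv < 0:
            raise ValueError("volume_noise_cv must be >= 0")
        lo, hi = self.contamination_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError("contamination_range must lie within [0, 100]")
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        unknown = [m for m in self.responder_models if m not in self.model_ids]
        if unknown:
            raise ValueError(f"responder models not among model ids: {unknown}")
        bad = [g for g, _, _ in self.planted_genes if g not in self.human_genes]
        if bad:
            raise ValueError(f"planted genes must be human candidate genes: {bad}")
        for _, direction, effect in self.planted_genes:
            if direction not in ("up", "down"):
                raise ValueError(f"planted direction must be 'up' or 'down', got {direction!r}")
            if effect <= 0:
                raise ValueError("planted effect sizes must be positive")
        if self.tumors_per_model < 2:
            raise ValueError("tumors_per_model must be >= 2")

    @property
    def model_ids(self) -> tuple[str, ...]:
        return tuple(f"PDX{i + 1}" for i in range(self.n_models))

    @property
    def human_genes(self) -> tuple[str, ...]:
        if self.n_human_genes > len(HUMAN_GENES):
            extra = tuple(f"GENE{i}" for i in range(self.n_human_genes - len(HUMAN_GENES)))
            return HUMAN_GENES + extra
        return HUMAN_GENES[: self.n_human_genes]

    @property
    def murine_genes(self) -> tuple[str, ...]:
        if self.n_murine_genes > len(MURINE_GENES):
            extra = tuple(f"mm-Gene{i}" for i in range(self.n_murine_genes - len(MURINE_GENES)))
            return MURINE_GENES + extra
        return MURINE_GENES[: self.n_murine_genes]

    @property
    def total_noise_sd(self) -> float:
        """Total per-tumor log2 SD (model effects plus residual noise).

        Under the defaults this equals ``effect_sd_unit`` (1.0), so planted
        effect sizes read as multiples of the per-tumor noise SD; the unit
        itself stays fixed when the noise dials are turned down, so
        closed-form checks with noise off remain meaningful.
        """
        return math.sqrt(self.model_effect_sd**2 + self.residual_sd**2)

    def rate_multiplier(self, model_id: str) -> float:
        """Treated-arm growth-rate multiplier for ``model_id`` (1 = no effect)."""
        if self.treatment_effect is not None:
            return float(self.treatment_effect.get(model_id, 1.0))
        if model_id not in self.responder_models:
            return 1.0
        tgi = float(self.target_tgi.get(model_id, 0.0))
        if tgi <= 0:
            return 1.0
        return treatment_effect_for_target_tgi(
            tgi, self.control_growth_rate, float(max(self.measurement_days))
        )


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the resampling-stabilized signature selection."""

    alpha: float = 0.05
    n_subsets: int = 30
    samples_per_model: int = 3
    log_base: float = 2.0
    pseudocount: float = 1.0
    seed: int = 0
    subset_adjusted: bool = False  # threshold BH-adjusted p inside subsets
    cv_tolerance: float = 1e-6    # invariance filter CV cutoff

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.samples_per_model < 1:
            raise ValueError("samples_per_model must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` reproducible 31-bit child seeds from a root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def to_yaml(config, path=None) -> str:
    """Serialize a config dataclass to YAML (returned, optionally written)."""
    text = yaml.safe_dump(_to_plain(config), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def simulation_config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**{k: _tuplify(v) for k, v in raw.items()})


def selection_config_from_yaml(path) -> SelectionConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(SelectionConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown selection config keys: {sorted(unknown)}")
    return SelectionConfig(**raw)
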