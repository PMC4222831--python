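"""Synthetic preclinical study generator.

Emits every input the analysis chain consumes, with the statistical
structure the methods assume: a two-arm caliper-measurement study per
xenograft model (exponential growth, multiplicative lognormal measurement
noise, sacrifice censoring at a volume endpoint), a long-format qPCR Ct
table for a human/murine candidate-gene panel with species-specific
endogenous controls and mouse stromal contamination, relapse times for a
maintenance-therapy arm, and a patient IHC cohort with subtype structure
and censored survival.

All randomness flows from the config seed through independent named
streams, so identical configs give byte-identical outputs while the
individual tables remain reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import HS_TBP, MM_TBP, TOTAL_TBP, SimulationConfig
from .growth import GrowthStudy

_STREAMS = ("growth", "ct", "cohort", "relapse")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS.index(stream)])


# ---------------------------------------------------------------------------
# growth study


def _diameters(volume: np.ndarray, aspect: float) -> tuple[np.ndarray, np.ndarray]:
    # V = a*b^2/2 with a = aspect*b  =>  b = (2V/aspect)^(1/3)
    b = (2.0 * volume / aspect) ** (1.0 / 3.0)
    return aspect * b, b


def simulate_growth_study(config: SimulationConfig) -> GrowthStudy:
    """Two-arm longitudinal caliper study for every model in the config.

    Each mouse grows exponentially from a random starting volume; treated
    arms of responder models grow at a reduced rate chosen to hit the
    configured target TGI at the last measurement day.  Observed volumes
    carry multiplicative lognormal noise with the configured CV, and a mouse
    stops being measured after its first observation above the sacrifice
    volume.
    """
    rng = _rng(config, "growth")
    sigma = math.sqrt(math.log(1.0 + config.volume_noise_cv**2))
    lo, hi = config.initial_volume_range
    rows = []
    for model_id in config.model_ids:
        multiplier = config.rate_multiplier(model_id)
        if multiplier * config.control_growth_rate < 0:
            raise ValueError(f"negative treated growth rate for {model_id}")
        for arm, rate in (("control", config.control_growth_rate),
                          ("treated", config.control_growth_rate * multiplier)):
            for j in range(config.mice_per_arm):
                mouse = f"{model_id}-{arm[0]}{j + 1}"
                v0 = rng.uniform(lo, hi)
                for day in config.measurement_days:
                    true_v = v0 * math.exp(rate * day)
                    if sigma > 0:
                        obs = true_v * math.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0)
                    else:
                        obs = true_v
                    a, b = _diameters(np.asarray(obs), config.aspect_ratio)
                    rows.append({"mouse": mouse, "model": model_id, "arm": arm,
                                 "day": day, "a": float(a), "b": float(b)})
                    if obs > config.sacrifice_volume:
                        break  # sacrificed; no further measurements
    metadata = {m: ("responder" if m in config.responder_models else "non-responder")
                for m in config.model_ids}
    return GrowthStudy(pd.DataFrame(rows), metadata)


def simulate_relapse(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Exponential relapse times per maintenance arm (may exceed follow-up)."""
    rng = _rng(config, "relapse")
    return {
        "control": rng.exponential(1.0 / config.relapse_hazard_control,
                                   size=config.relapse_mice_control),
        "treated": rng.exponential(1.0 / config.relapse_hazard_treated,
                                   size=config.relapse_mice_treated),
    }


# ---------------------------------------------------------------------------
# qPCR Ct table


@dataclass
class SimulatedCtTable:
    """A simulated Ct table plus the ground truth behind it."""

    table: pd.DataFrame                    # sample, gene, species, ct, replicate
    sample_model: Mapping[str, str]
    model_response: Mapping[str, str]
    reference_samples: list[str]
    contamination: pd.Series               # true percent per sample
    true_log2: pd.DataFrame                # planted log2 N (NaN where undetected)
    config: SimulationConfig = field(repr=False, default=None)

    def to_csv(self, path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        out = self.table.copy()
        out["ct"] = out["ct"].map(lambda v: "undetected" if pd.isna(v) else f"{v:.6f}")
        out.to_csv(path, sep=sep, index=False)


def _floor_ct(rng: np.random.Generator, config: SimulationConfig) -> float:
    """Ct emitted for a 'not expressed' reaction: above the zero-scoring bound."""
    return float(rng.uniform(config.undetected_ct + 0.5, config.undetected_ct + 3.5))


def simulate_ct_table(config: SimulationConfig) -> SimulatedCtTable:
    """Long-format Ct rows for the candidate panel over control-arm tumors.

    Human genes carry per-gene baselines, per-model random effects and
    residual tumor-to-tumor noise on the log2 scale; planted genes are
    additionally shifted by ``effect x noise_sd_unit`` (up or down) in
    responder models.  Murine genes ride on the sampled mouse-cell fraction.
    Expression converts to Ct by inverting the anchored comparative-Ct
    formula, so quantification recovers the planted means; controls
    (Total-TBP, Hs-TBP, Mm-TBP) and four pure mouse reference tissues are
    emitted alongside.
    """
    rng = _rng(config, "ct")
    human = config.human_genes
    murine = config.murine_genes
    uninformative = dict(config.uninformative_genes)
    planted = {g: (d, e) for g, d, e in config.planted_genes}
    models = config.model_ids
    responders = set(config.responder_models)

    samples = [f"{m}-T{k + 1}" for m in models for k in range(config.tumors_per_model)]
    sample_model = {f"{m}-T{k + 1}": m for m in models for k in range(config.tumors_per_model)}
    model_response = {m: ("responding" if m in responders else "non-responding") for m in models}

    lo, hi = config.contamination_range
    contamination = pd.Series(rng.uniform(lo, hi, size=len(samples)), index=samples)

    # per-sample Total-TBP Ct; the generator's reference control is the median,
    # matching what the quantifier recomputes from the emitted table
    ct_total = pd.Series(
        config.control_ct + rng.normal(0.0, config.control_ct_sd, size=len(samples)),
        index=samples,
    )
    ct_ref = float(ct_total.median())

    single_model_assign: dict[str, str] = {}
    smi = 0
    for gene, kind in uninformative.items():
        if kind == "single_model":
            single_model_assign[gene] = models[smi % len(models)]
            smi += 1

    all_genes = list(human) + list(murine)
    baseline = pd.Series(rng.uniform(2.0, 8.0, size=len(human)), index=list(human))
    baseline_mur = pd.Series(rng.uniform(2.0, 5.0, size=len(murine)), index=list(murine))
    model_effect = pd.DataFrame(
        rng.normal(0.0, config.model_effect_sd, size=(len(all_genes), len(models))),
        index=all_genes, columns=models,
    )

    sd_unit = config.effect_sd_unit
    rows = []
    true_log2 = pd.DataFrame(np.nan, index=all_genes, columns=samples)

    def emit(sample, gene, species, ct_value):
        for rep in range(1, config.n_replicates + 1):
            if ct_value is None:
                rows.append({"sample": sample, "gene": gene, "species": species,
                             "ct": np.nan, "replicate": rep})
            else:
                noisy = ct_value + (rng.normal(0.0, config.ct_replicate_sd)
                                    if config.ct_replicate_sd > 0 else 0.0)
                rows.append({"sample": sample, "gene": gene, "species": species,
                             "ct": float(noisy), "replicate": rep})

    for sample in samples:
        model_id = sample_model[sample]
        responding = model_id in responders
        phi = contamination[sample] / 100.0
        ctt = float(ct_total[sample])

        emit(sample, TOTAL_TBP, "total_control", ctt)
        # human fraction 1-phi, mouse fraction phi of the combined TBP signal
        emit(sample, HS_TBP, "human_control",
             ctt - math.log2(1.0 - phi) if phi < 1 else None)
        emit(sample, MM_TBP, "murine_control",
             ctt - math.log2(phi) if phi > 0 else None)

        for gene in all_genes:
            species = "human" if gene in human else "murine"
            kind = uninformative.get(gene)
            if kind == "invariant":
                emit(sample, gene, species, _floor_ct(rng, config))
                true_log2.loc[gene, sample] = np.nan
                continue
            if kind == "single_model" and single_model_assign[gene] != model_id:
                emit(sample, gene, species, _floor_ct(rng, config))
                true_log2.loc[gene, sample] = np.nan
                continue
            if species == "human":
                x = baseline[gene] + model_effect.loc[gene, model_id]
                if gene in planted and responding:
                    direction, effect = planted[gene]
                    x += (1.0 if direction == "up" else -1.0) * effect * sd_unit
            else:
                if phi <= 0:
                    emit(sample, gene, species, None)
                    true_log2.loc[gene, sample] = np.nan
                    continue
                x = baseline_mur[gene] + model_effect.loc[gene, model_id] + math.log2(phi)
            if config.residual_sd > 0:
                x = x + rng.normal(0.0, config.residual_sd)
            # invert the anchored formula: N = 2^(35-ct) * 2^(ct_ref - ct_total)
            ct_gene = config.basal_ct - x + (ct_ref - ctt)
            if ct_gene > config.undetected_ct:
                emit(sample, gene, species, _floor_ct(rng, config))
                true_log2.loc[gene, sample] = np.nan
            else:
                emit(sample, gene, species, float(ct_gene))
                true_log2.loc[gene, sample] = x

    # pure mouse reference tissues: Mm-TBP amplifies exactly like Total-TBP
    reference_samples = [f"mouse-tissue-{i + 1}" for i in range(4)]
    for ref in reference_samples:
        ctt = config.control_ct + rng.normal(0.0, config.control_ct_sd)
        emit(ref, TOTAL_TBP, "total_control", float(ctt))
        emit(ref, MM_TBP, "murine_control", float(ctt))

    return SimulatedCtTable(
        table=pd.DataFrame(rows),
        sample_model=sample_model,
        model_response=model_response,
        reference_samples=reference_samples,
        contamination=contamination,
        true_log2=true_log2,
        config=config,
    )


# ---------------------------------------------------------------------------
# patient cohort


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """IHC/clinical cohort table with subtype strata and censored survival.

    Subtype counts follow the configured weights; staining percent and
    intensity are drawn so that roughly half the cohort clears the median
    H-score threshold.  A binary covariate can be associated with positivity
    (``covariate_log_odds``) and survival can depend on positivity
    (``survival_log_hr``) for power and calibration experiments.
    """
    if config.n_patients < 10:
        raise ValueError("n_patients must be >= 10")
    rng = _rng(config, "cohort")
    subtypes = list(config.subtype_weights)
    weights = np.array([config.subtype_weights[s] for s in subtypes], dtype=float)
    counts = np.floor(weights / weights.sum() * config.n_patients).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = weights / weights.sum() * config.n_patients - counts
    for i in np.argsort(-frac)[: config.n_patients - counts.sum()]:
        counts[i] += 1
    subtype_col = np.repeat(subtypes, counts)

    n = config.n_patients
    intensity = rng.choice([0, 1, 2, 3], size=n, p=(0.25, 0.30, 0.30, 0.15))
    percent = np.round(rng.beta(1.2, 2.2, size=n) * 100.0)
    percent[intensity == 0] = 0.0
    h = percent * intensity
    positive = h > 30.0

    logit = config.covariate_log_odds * positive.astype(float)
    covariate = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    base_hazard = math.log(2) / config.survival_median_months
    hazard = base_hazard * np.exp(config.survival_log_hr * positive.astype(float))
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(6.0, config.followup_max_months, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    return pd.DataFrame(
        {
            "patient": [f"P{i + 1:03d}" for i in range(n)],
            "percent_stained": percent,
            "intensity": intensity,
            "subtype": subtype_col,
            "covariate": covariate,
            "survival_time": time,
            "event": event,
            "outcome_type": "OS",
        }
    )
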