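"""Species-aware RT-qPCR quantification for human-in-mouse xenograft samples.

Expression is quantified by the comparative-Ct method against a combined
endogenous control (``Total-TBP``, a primer pair amplifying both the human
and the murine TATA-box binding protein transcripts), so that tumor (human)
and stromal (mouse) transcripts are measured on one common scale:

    raw N_target = 2 ** (Ct_Total-TBP - Ct_target)

Values are then anchored so that a target amplifying at the basal cycle
threshold (Ct = 35) under reference control conditions scores exactly 1, and
targets that fail to amplify by Ct 38 score 0 ("not expressed").  The murine
control (``Mm-TBP``) against ``Total-TBP`` additionally estimates the
percentage of contaminating mouse cells per sample, scaled so the median over
four pure mouse reference tissues is 100.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import HS_TBP, MM_TBP, TOTAL_TBP

logger = logging.getLogger(__name__)

#: Token accepted in Ct tables for reactions with no amplification signal.
UNDETECTED = "undetected"

BASAL_CT = 35.0
ZERO_CT = 38.0

SPECIES_TAGS = ("human", "murine", "total_control", "human_control", "murine_control")

REQUIRED_COLUMNS = ("sample", "gene", "species", "ct")


class InvalidSampleError(ValueError):
    """Raised when a sample's endogenous control cannot be used."""


def parse_ct(value) -> float:
    """Ct value as float; the ``undetected`` token (or NaN) becomes NaN."""
    if isinstance(value, str):
        if value.strip().lower() == UNDETECTED:
            return float("nan")
        value = float(value)
    value = float(value)
    if np.isnan(value):
        return value
    if not 0 < value <= 45:
        raise ValueError(f"detected Ct must lie in (0, 45], got {value}")
    return value


def replicate_average(cts: Sequence) -> float:
    """Mean Ct over detected replicates; NaN when all are undetected."""
    vals = np.array([parse_ct(c) for c in cts], dtype=float)
    detected = vals[~np.isnan(vals)]
    if detected.size == 0:
        return float("nan")
    return float(detected.mean())


def ntarget(
    ct_target: float,
    ct_total_tbp: float,
    ref_control_ct: float | None = None,
    basal_ct: float = BASAL_CT,
    zero_ct: float = ZERO_CT,
) -> float:
    """Anchored comparative-Ct expression value for one gene in one sample.

    ``N = 2**(basal_ct - ct_target) * 2**(ref_control_ct - ct_total_tbp)``:
    the first factor anchors a target at the basal Ct to 1, the second removes
    run-to-run shifts of the endogenous control relative to a reference
    control Ct (by default the control itself, i.e. no correction).  A target
    averaging above ``zero_ct`` (or undetected) scores 0; an undetected
    control invalidates the sample.
    """
    ct_total_tbp = parse_ct(ct_total_tbp)
    if np.isnan(ct_total_tbp):
        raise InvalidSampleError("Total-TBP control undetected; sample invalid")
    ct_target = parse_ct(ct_target)
    if np.isnan(ct_target) or ct_target > zero_ct:
        return 0.0
    if ref_control_ct is None:
        ref_control_ct = ct_total_tbp
    return float(2.0 ** (basal_ct - ct_target) * 2.0 ** (ref_control_ct - ct_total_tbp))


def mouse_reference_raw(reference_pairs: Sequence[tuple[float, float]]) -> np.ndarray:
    """Raw ``2**(Ct_total - Ct_mm)`` values for (Ct_mm, Ct_total) reference pairs."""
    if len(reference_pairs) == 0:
        raise ValueError("reference tissue list must be nonempty")
    out = []
    for ct_mm, ct_total in reference_pairs:
        ct_mm, ct_total = parse_ct(ct_mm), parse_ct(ct_total)
        if np.isnan(ct_mm) or np.isnan(ct_total):
            raise ValueError("reference tissue Ct values must be detected")
        out.append(2.0 ** (ct_total - ct_mm))
    return np.asarray(out, dtype=float)


def mouse_fraction(ct_mm_tbp, ct_total_tbp, reference: Sequence[float], clamp: bool = True) -> float:
    """Percentage of mouse cells in a xenograft sample from the TBP pair.

    ``raw = 2**(Ct_total - Ct_mm)`` scaled by ``100 / median(reference raw)``;
    the reference values are the raw N of (typically four) pure mouse
    tissues.  Undetected Mm-TBP means a pure human sample (0%).  Values above
    100 (sampling noise) are clamped with a warning; pass ``clamp=False`` for
    the unclamped scaled value (e.g. when re-scoring the reference tissues
    themselves, whose scaled values straddle 100 by construction).
    """
    reference = np.asarray(list(reference), dtype=float)
    if reference.size == 0:
        raise ValueError("reference must be nonempty")
    ct_total_tbp = parse_ct(ct_total_tbp)
    if np.isnan(ct_total_tbp):
        raise InvalidSampleError("Total-TBP control undetected; sample invalid")
    ct_mm_tbp = parse_ct(ct_mm_tbp)
    if np.isnan(ct_mm_tbp):
        return 0.0
    raw = 2.0 ** (ct_total_tbp - ct_mm_tbp)
    scaled = 100.0 * raw / float(np.median(reference))
    if clamp and scaled > 100.0:
        warnings.warn(f"mouse fraction {scaled:.1f}% clamped to 100%")
        return 100.0
    return float(scaled)


@dataclass
class ExpressionMatrix:
    """Normalized expression values (genes x samples) with sample annotations.

    ``values`` holds anchored N-target values (nonnegative; zeros only via
    the Ct>38 rule).  ``sample_info`` carries per-sample model, response
    label and estimated mouse-cell percentage; ``gene_species`` tags each
    gene as human or murine.
    """

    values: pd.DataFrame
    sample_info: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_species: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.rename_axis("gene").to_csv(path, sep="\t")

    def qc_table(self) -> pd.DataFrame:
        return self.sample_info.copy()


def build_expression_matrix(
    ct_table: pd.DataFrame,
    sample_model: Mapping[str, str] | None = None,
    model_response: Mapping[str, str] | None = None,
    reference_samples: Sequence[str] | None = None,
    basal_ct: float = BASAL_CT,
    zero_ct: float = ZERO_CT,
    ref_control_ct: float | None = None,
) -> ExpressionMatrix:
    """Quantify a long-format Ct table into an annotated expression matrix.

    Replicates are averaged per sample x gene, the cohort reference control
    Ct defaults to the median replicate-averaged Total-TBP Ct, and each
    target is converted with :func:`ntarget`.  Samples listed in
    ``reference_samples`` are treated as pure mouse reference tissues: their
    Mm-TBP/Total-TBP pairs set the contamination scale and they are excluded
    from the matrix.  Samples lacking a usable Total-TBP control are dropped
    with a logged warning.
    """
    df = pd.DataFrame(ct_table)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    bad_tags = set(df["species"].unique()) - set(SPECIES_TAGS)
    if bad_tags:
        raise ValueError(f"unknown species tags: {sorted(bad_tags)}")
    df = df.copy()
    df["ct"] = [parse_ct(v) for v in df["ct"]]

    # groupby mean skips undetected (NaN) replicates; all-undetected stays NaN
    avg = df.groupby(["sample", "gene"], sort=False)["ct"].mean().unstack("gene")
    species = df.drop_duplicates("gene").set_index("gene")["species"]

    reference_samples = list(reference_samples or [])
    if TOTAL_TBP not in avg.columns:
        raise InvalidSampleError("no Total-TBP rows in the Ct table")
    control = avg[TOTAL_TBP]
    invalid = control[control.isna()].index
    for s in invalid:
        logger.warning("sample %s dropped: Total-TBP control undetected", s)
    avg = avg.drop(index=invalid)
    control = control.drop(index=invalid)

    if reference_samples:
        ref_pairs = [(avg.loc[s, MM_TBP], avg.loc[s, TOTAL_TBP]) for s in reference_samples]
        reference_raw = mouse_reference_raw(ref_pairs)
    else:
        reference_raw = np.ones(4)  # unit reference: pure mouse raw N == 1
    tumor_samples = [s for s in avg.index if s not in reference_samples]

    if ref_control_ct is None:
        ref_control_ct = float(control.loc[tumor_samples].median())

    target_genes = [g for g in avg.columns if g not in (TOTAL_TBP, HS_TBP, MM_TBP)]
    ct_t = avg.loc[tumor_samples, target_genes].to_numpy(dtype=float)   # samples x genes
    ct_c = control.loc[tumor_samples].to_numpy(dtype=float)[:, None]
    with np.errstate(invalid="ignore"):
        n = 2.0 ** (basal_ct - ct_t) * 2.0 ** (ref_control_ct - ct_c)
    n[np.isnan(ct_t) | (ct_t > zero_ct)] = 0.0
    values = pd.DataFrame(n.T, index=target_genes, columns=tumor_samples)

    info = pd.DataFrame(index=pd.Index(tumor_samples, name="sample"))
    info["total_tbp_ct"] = control.loc[tumor_samples]
    if MM_TBP in avg.columns:
        info["mouse_pct"] = [
            mouse_fraction(avg.loc[s, MM_TBP], control.loc[s], reference_raw)
            for s in tumor_samples
        ]
    if sample_model:
        info["model"] = [sample_model.get(s) for s in tumor_samples]
        if model_response:
            info["response"] = [model_response.get(m) for m in info["model"]]

    return ExpressionMatrix(
        values=values,
        sample_info=info,
        gene_species=species.reindex(target_genes),
    )


def read_ct_csv(path) -> pd.DataFrame:
    """Read a long-format Ct CSV/TSV (sample, gene, species, ct[, replicate])."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, keep_default_na=True, na_values=[UNDETECTED])
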