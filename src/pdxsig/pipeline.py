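"""End-to-end orchestration: simulate -> growth -> quantify -> signature -> cohort.

One root seed is fanned out deterministically to per-stage child seeds, so a
full run is reproducible and each stage can also be re-run independently
from the intermediate files it reads/writes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth, ihc, qpcr, signature, synthetic
from .config import (
    MM_TBP,
    TOTAL_TBP,
    SelectionConfig,
    SimulationConfig,
    child_seeds,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: Path
    seed: int = 0
    simulation: SimulationConfig | None = None
    selection: SelectionConfig | None = None
    rtvv_threshold: float = growth.RTVV_THRESHOLD
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        sim_seed, sel_seed = child_seeds(self.seed, 2)
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=sim_seed)
        if self.selection is None:
            self.selection = SelectionConfig(seed=sel_seed, alpha=self.alpha)


@dataclass
class RunReport:
    growth_summary: pd.DataFrame
    relapse: pd.DataFrame
    signature_result: signature.SignatureResult
    cluster: signature.ClusterResult
    positivity: pd.DataFrame
    paths: dict = field(default_factory=dict)


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage on synthetic inputs and write per-stage artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    logger.info("stage 1/5: simulate")
    study = synthetic.simulate_growth_study(sim)
    study.measurements.to_csv(out / "growth_measurements.csv", index=False)
    sim_ct = synthetic.simulate_ct_table(sim)
    sim_ct.to_csv(out / "ct_table.csv")
    cohort = synthetic.simulate_cohort(sim)
    cohort.to_csv(out / "cohort.csv", index=False)
    relapse_times = synthetic.simulate_relapse(sim)

    logger.info("stage 2/5: growth response")
    summary = growth.summarize_study(study, rtvv_threshold=config.rtvv_threshold, alpha=config.alpha)
    summary.to_csv(out / "growth_summary.tsv", sep="\t", index=False)
    all_rtvv = pd.concat(
        [growth.rtvv_table(study, m) for m in study.models]
    )
    growth.plot_waterfall(all_rtvv, out / "waterfall.png", threshold=config.rtvv_threshold)
    for m in study.models[:1]:
        growth.plot_growth_curves(study, m, out / f"growth_{m}.png")
    relapse = growth.relapse_summary(relapse_times, followup_end=sim.relapse_followup)
    relapse.to_csv(out / "relapse_summary.tsv", sep="\t", index=False)

    logger.info("stage 3/5: qPCR quantification")
    matrix = qpcr.build_expression_matrix(
        sim_ct.table,
        sample_model=sim_ct.sample_model,
        model_response=sim_ct.model_response,
        reference_samples=sim_ct.reference_samples,
    )
    matrix.to_tsv(out / "expression_matrix.tsv")
    matrix.qc_table().to_csv(out / "sample_qc.tsv", sep="\t")

    logger.info("stage 4/5: signature selection")
    sig = signature.select_signature(matrix, config.selection)
    sig.per_gene.to_csv(out / "per_gene_stats.tsv", sep="\t")
    with open(out / "signature.json", "w") as fh:
        json.dump(sig.to_json_dict(), fh, indent=2, default=str)
    if len(sig.selected) >= 2:
        clus = signature.cluster_samples(sig)
        signature.export_heatmap(sig, out / "heatmap.png")
    else:
        clus = signature.ClusterResult(
            linkage=np.empty((0, 4)),
            labels=pd.Series(dtype=int),
            sample_order=list(matrix.samples),
            crosstab=pd.DataFrame(),
        )

    logger.info("stage 5/5: cohort statistics")
    positivity = ihc.positivity_summary(cohort, group_by="subtype")
    positivity.to_csv(out / "positivity.tsv", sep="\t", index=False)
    km = ihc.km_logrank(
        cohort["survival_time"],
        cohort["event"],
        np.where(
            [ihc.classify_positive(p, i) for p, i in zip(cohort["percent_stained"], cohort["intensity"])],
            "positive", "negative",
        ),
    )
    ihc.plot_km(km, out / "km.png")

    report = RunReport(
        growth_summary=summary,
        relapse=relapse,
        signature_result=sig,
        cluster=clus,
        positivity=positivity,
        paths={"outdir": str(out)},
    )
    _write_report(report, out, config)
    return report


def _write_report(report: RunReport, out: Path, config: RunConfig) -> None:
    lines = ["# pdxsig run report", "", f"seed: {config.seed}", ""]
    lines += ["## Per-model tumor growth inhibition", ""]
    lines.append(report.growth_summary.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    lines += ["", "## Relapse (maintenance arm)", ""]
    lines.append(report.relapse.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    lines.append(f"log-rank p = {report.relapse.attrs.get('logrank_p'):.4g}")
    sig = report.signature_result
    lines += ["", "## Signature", ""]
    lines.append(f"selected genes ({len(sig.selected)}): " + ", ".join(sig.selected))
    for g in sig.selected:
        lines.append(f"  {g}: {sig.per_gene.loc[g, 'direction']}")
    if not report.cluster.crosstab.empty:
        lines += ["", "cluster x response cross-tabulation:", report.cluster.crosstab.to_string()]
    lines += ["", "## Cohort positivity", ""]
    lines.append(report.positivity.to_string(index=False))
    (out / "report.md").write_text("\n".join(lines) + "\n")
    payload = {
        "seed": config.seed,
        "growth": report.growth_summary.to_dict(orient="records"),
        "relapse": report.relapse.to_dict(orient="records"),
        "relapse_logrank_p": report.relapse.attrs.get("logrank_p"),
        "signature": {
            "selected": sig.selected,
            "directions": {g: sig.per_gene.loc[g, "direction"] for g in sig.selected},
        },
        "positivity": report.positivity.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# input validation


GROWTH_COLUMNS = ("mouse", "model", "arm", "day", "a", "b")
CT_COLUMNS = ("sample", "gene", "species", "ct")
COHORT_COLUMNS = ("percent_stained", "intensity", "subtype", "survival_time", "event")


def validate_inputs(
    growth_path=None, ct_path=None, cohort_path=None
) -> list[str]:
    """Schema checks for the three CSV inputs; returns a list of violations."""
    violations: list[str] = []
    if growth_path is not None:
        df = pd.read_csv(growth_path)
        missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
        if missing:
            violations.append(f"growth: missing columns {missing}")
        else:
            if (df["a"] < df["b"]).any():
                rows = df.index[df["a"] < df["b"]].tolist()[:5]
                violations.append(f"growth: a < b at rows {rows}")
            if (df["b"] <= 0).any():
                violations.append("growth: non-positive diameters")
            if (df["day"] < 0).any():
                violations.append("growth: negative days")
            bad_arms = set(df["arm"].unique()) - set(growth.ARMS)
            if bad_arms:
                violations.append(f"growth: unknown arms {sorted(bad_arms)}")
    if ct_path is not None:
        df = qpcr.read_ct_csv(ct_path)
        missing = [c for c in CT_COLUMNS if c not in df.columns]
        if missing:
            violations.append(f"ct: missing columns {missing}")
        else:
            bad = set(df["species"].unique()) - set(qpcr.SPECIES_TAGS)
            if bad:
                violations.append(f"ct: unknown species tags {sorted(bad)}")
            for s, sub in df.groupby("sample"):
                if TOTAL_TBP not in set(sub["gene"]):
                    violations.append(f"ct: sample {s} lacks a Total-TBP control row")
            detected = pd.to_numeric(df["ct"], errors="coerce")
            out_of_range = detected.notna() & ((detected <= 0) | (detected > 45))
            if out_of_range.any():
                violations.append("ct: Ct values outside (0, 45]")
    if cohort_path is not None:
        df = pd.read_csv(cohort_path)
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            violations.append(f"cohort: missing columns {missing}")
        else:
            if ((df["percent_stained"] < 0) | (df["percent_stained"] > 100)).any():
                violations.append("cohort: percent_stained outside [0, 100]")
            if (~df["intensity"].isin([0, 1, 2, 3])).any():
                violations.append("cohort: intensity outside 0..3")
            if (df["survival_time"] < 0).any():
                violations.append("cohort: negative survival times")
            if (~df["event"].isin([0, 1])).any():
                violations.append("cohort: event must be 0/1")
    return violations
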