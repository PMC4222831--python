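"""Resampling-stabilized nested-ANOVA selection of a response gene signature.

Candidate genes measured across replicate tumors of several xenograft models
are tested for association with the model-level response label using a
two-factor ANOVA in which "model" is nested within "response": the response
effect is tested against the model-within-response mean square, so that the
strong within-model correlation of replicate tumors cannot masquerade as a
treatment-response effect.  Selection is stabilized by re-running the test on
resampled subsets (by default 30 subsets of 3 tumors per model, drawn without
replacement, preserving model proportions): a gene enters the signature only
if its Benjamini-Hochberg-adjusted p-value on the full data is below alpha
AND it is significant in every subset.  Selected genes are then used for an
unsupervised Ward / Spearman-distance clustering of the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import SelectionConfig
from .ihc import bh_adjust
from .qpcr import ExpressionMatrix

RESPONSE_LEVELS = ("responding", "non-responding")


# ---------------------------------------------------------------------------
# filtering and preprocessing


def invariance_filter(matrix: ExpressionMatrix, cv_tolerance: float = 1e-6):
    """Drop genes that carry no usable between-model information.

    A gene is removed when (a) its coefficient of variation across all
    samples is below tolerance — including the all-zero / never-detected
    case — or (b) its nonzero expression is confined to the samples of a
    single model.  Returns ``(retained_genes, removal_log)`` where the log
    lists each removed gene with its reason.
    """
    values = matrix.values
    if "model" not in matrix.sample_info.columns:
        raise ValueError("sample_info must carry a 'model' column")
    models = matrix.sample_info["model"].reindex(values.columns)
    retained, removed = [], []
    for gene, row in values.iterrows():
        x = row.to_numpy(dtype=float)
        mean = x.mean()
        cv = np.inf if mean == 0 and x.std() > 0 else (x.std(ddof=0) / mean if mean else 0.0)
        if cv < cv_tolerance:
            removed.append({"gene": gene, "reason": "invariant"})
            continue
        expressed_models = set(models[x > 0])
        if len(expressed_models) <= 1:
            removed.append({"gene": gene, "reason": "single-model"})
            continue
        retained.append(gene)
    log = pd.DataFrame(removed, columns=["gene", "reason"])
    return retained, log


def preprocess(matrix: ExpressionMatrix, config: SelectionConfig, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Log-transform and per-gene standardize expression values.

    Each value becomes ``log(N + pseudocount)`` in ``config.log_base``; each
    gene row is then centered and scaled to unit SD across all samples.  The
    scaling is computed once here — resampled subsets inherit it.  A gene
    that is constant after the log transform raises (the invariance filter
    should have removed it).
    """
    values = matrix.values if genes is None else matrix.values.loc[list(genes)]
    logged = np.log(values.to_numpy(dtype=float) + config.pseudocount) / np.log(config.log_base)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        raise ValueError(f"zero-variance gene(s) after log transform: {list(values.index[flat])}")
    z = (logged - mean) / sd
    return pd.DataFrame(z, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# nested ANOVA


def _check_design(response: np.ndarray, model: np.ndarray) -> None:
    for level in np.unique(response):
        models_in = np.unique(model[response == level])
        if len(models_in) < 2:
            raise ValueError(
                f"response level {level!r} contains a single model; "
                "the response effect is not identifiable"
            )
    for m in np.unique(model):
        levels = np.unique(response[model == m])
        if len(levels) != 1:
            raise ValueError(f"model {m!r} appears in more than one response level")
        if (model == m).sum() < 2:
            raise ValueError(f"model {m!r} has fewer than 2 samples")


def _nested_anova_matrix(X: np.ndarray, response: np.ndarray, model: np.ndarray):
    """Vectorized nested ANOVA over the rows (genes) of ``X``.

    Sum-of-squares decomposition: response (between response levels), model
    within response, residual.  ``F = MS_response / MS_model(response)`` with
    ``df = (a - 1, sum_i(b_i - 1))``; this general weighted form reduces to
    the textbook balanced formulas for balanced designs and remains a valid
    nested linear-model decomposition for unbalanced ones.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[1]
    grand = X.mean(axis=1)
    ss_resp = np.zeros(X.shape[0])
    ss_model = np.zeros(X.shape[0])
    levels = np.unique(response)
    b_total = 0
    for level in levels:
        sel = response == level
        group_mean = X[:, sel].mean(axis=1)
        ss_resp += sel.sum() * (group_mean - grand) ** 2
        for m in np.unique(model[sel]):
            ms = sel & (model == m)
            model_mean = X[:, ms].mean(axis=1)
            ss_model += ms.sum() * (model_mean - group_mean) ** 2
            b_total += 1
    df1 = len(levels) - 1
    df2 = b_total - len(levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_resp / df1) / (ss_model / df2)
    p = np.where(
        ss_model > 0,
        stats.f.sf(np.where(ss_model > 0, F, 0.0), df1, df2),
        np.where(ss_resp > 0, 0.0, 1.0),  # degenerate denominators
    )
    F = np.where(ss_model > 0, F, np.where(ss_resp > 0, np.inf, 0.0))
    return F, p


def nested_anova(values, response_labels, model_labels) -> tuple[float, float]:
    """Nested two-factor ANOVA response test for a single gene.

    ``values`` are per-sample expression levels; ``model_labels`` assigns
    each sample to a xenograft model and ``response_labels`` gives the
    model-level response class.  Returns ``(F, p)`` for the response effect
    tested against model-within-response variation.  All-equal input returns
    ``(0, 1)``.
    """
    y = np.asarray(values, dtype=float)
    response = np.asarray(response_labels)
    model = np.asarray(model_labels)
    if not (len(y) == len(response) == len(model)):
        raise ValueError("values, response and model labels must align")
    _check_design(response, model)
    F, p = _nested_anova_matrix(y[None, :], response, model)
    return float(F[0]), float(p[0])


# ---------------------------------------------------------------------------
# stability subsets and selection


def stability_subsets(sample_info: pd.DataFrame, config: SelectionConfig) -> list[list[str]]:
    """Resampled validation subsets preserving per-model proportions.

    Each of ``config.n_subsets`` subsets draws ``config.samples_per_model``
    samples from every model, without replacement, independently per subset
    from the seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    by_model = {m: list(sub.index) for m, sub in sample_info.groupby("model", sort=True)}
    short = {m: len(s) for m, s in by_model.items() if len(s) < config.samples_per_model}
    if short:
        raise ValueError(f"models with fewer than samples_per_model samples: {short}")
    subsets = []
    for _ in range(config.n_subsets):
        picked: list[str] = []
        for m in sorted(by_model):
            picked.extend(rng.choice(by_model[m], size=config.samples_per_model, replace=False))
        subsets.append(picked)
    return subsets


@dataclass
class SignatureResult:
    """Per-gene statistics and the selected signature."""

    per_gene: pd.DataFrame          # F, p_raw, p_adj, consensus_count, selected, direction
    selected: list[str]
    subsets: list[list[str]]
    removal_log: pd.DataFrame
    standardized: pd.DataFrame      # post-filter standardized matrix
    sample_info: pd.DataFrame
    config: SelectionConfig = field(default_factory=SelectionConfig)

    def to_json_dict(self) -> dict:
        return {
            "selected": self.selected,
            "directions": {
                g: self.per_gene.loc[g, "direction"] for g in self.selected
            },
            "alpha": self.config.alpha,
            "n_subsets": self.config.n_subsets,
            "per_gene": self.per_gene.reset_index().to_dict(orient="records"),
        }


def select_signature(matrix: ExpressionMatrix, config: SelectionConfig) -> SignatureResult:
    """Run the full selection: filter, transform, test, stabilize, adjust.

    A gene is selected iff its BH-adjusted p-value over the retained genes on
    the full data is below ``config.alpha`` and its (raw, by default) p-value
    is below alpha in every resampled subset.  Directions are the sign of the
    responder minus non-responder mean on the standardized scale.
    """
    info = matrix.sample_info
    if "response" not in info.columns or info["response"].isna().any():
        raise ValueError("every sample needs a response annotation")
    retained, removal_log = invariance_filter(matrix, cv_tolerance=config.cv_tolerance)
    if not retained:
        raise ValueError("no genes retained by the invariance filter")
    z = preprocess(matrix, config, genes=retained)
    response = info["response"].reindex(z.columns).to_numpy()
    model = info["model"].reindex(z.columns).to_numpy()
    _check_design(response, model)

    X = z.to_numpy()
    F, p_raw = _nested_anova_matrix(X, response, model)
    p_adj = bh_adjust(p_raw)

    subsets = stability_subsets(info, config)
    consensus = np.zeros(len(retained), dtype=int)
    col_index = {s: i for i, s in enumerate(z.columns)}
    for subset in subsets:
        idx = np.array([col_index[s] for s in subset])
        _, p_sub = _nested_anova_matrix(X[:, idx], response[idx], model[idx])
        if config.subset_adjusted:
            p_sub = bh_adjust(p_sub)
        consensus += (p_sub < config.alpha).astype(int)

    selected_mask = (p_adj < config.alpha) & (consensus == config.n_subsets)
    resp_mean = X[:, response == RESPONSE_LEVELS[0]].mean(axis=1)
    nonresp_mean = X[:, response == RESPONSE_LEVELS[1]].mean(axis=1)
    direction = np.where(resp_mean >= nonresp_mean, "up_in_responders", "down_in_responders")

    per_gene = pd.DataFrame(
        {
            "F": F,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "consensus_count": consensus,
            "selected": selected_mask,
            "direction": direction,
        },
        index=pd.Index(retained, name="gene"),
    )
    return SignatureResult(
        per_gene=per_gene,
        selected=list(per_gene.index[selected_mask]),
        subsets=subsets,
        removal_log=removal_log,
        standardized=z,
        sample_info=info,
        config=config,
    )


# ---------------------------------------------------------------------------
# clustering and export


def spearman_distance(standardized: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample distance ``1 - Spearman rho`` over gene profiles."""
    if standardized.shape[0] < 2:
        raise ValueError("need at least 2 genes to correlate samples")
    arr = standardized.to_numpy()
    if arr.shape[1] == 2:
        r = float(stats.spearmanr(arr[:, 0], arr[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.atleast_2d(stats.spearmanr(arr, axis=0).statistic)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=standardized.columns, columns=standardized.columns)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series          # 2-group cut, per sample
    sample_order: list[str]
    crosstab: pd.DataFrame     # cluster x response


def cluster_samples(result: SignatureResult, genes: Sequence[str] | None = None) -> ClusterResult:
    """Ward-linkage hierarchical clustering on the Spearman sample distance.

    Uses the signature genes by default; the tree is cut into 2 groups and
    cross-tabulated against the response labels.  Ward linkage is applied to
    the correlation distance directly (its Euclidean assumption is accepted
    as the price of the stated combination).
    """
    genes = list(genes) if genes is not None else list(result.selected)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster samples")
    z = result.standardized.loc[genes]
    dist = spearman_distance(z)
    condensed = squareform(dist.to_numpy(), checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    labels = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    labels = pd.Series(labels, index=z.columns, name="cluster")
    order = [z.columns[i] for i in hierarchy.leaves_list(linkage)]
    response = result.sample_info["response"].reindex(z.columns)
    crosstab = pd.crosstab(labels, response)
    return ClusterResult(linkage=linkage, labels=labels, sample_order=order, crosstab=crosstab)


def export_heatmap(result: SignatureResult, path, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Heatmap of standardized signature-gene expression in dendrogram order.

    Writes the image to ``path`` and a TSV twin (same stem, ``.tsv``) whose
    rows/columns match the plotted ordering; the ordered matrix is returned.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = list(genes) if genes is not None else list(result.selected)
    clus = cluster_samples(result, genes=genes)
    z = result.standardized.loc[genes, clus.sample_order]
    gene_link = hierarchy.linkage(z.to_numpy(), method="ward")
    gene_order = [z.index[i] for i in hierarchy.leaves_list(gene_link)]
    ordered = z.loc[gene_order]

    fig, ax = plt.subplots(figsize=(max(6, 0.18 * ordered.shape[1]), max(3, 0.3 * ordered.shape[0])))
    vmax = float(np.abs(ordered.to_numpy()).max())
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(len(gene_order)), gene_order, fontsize=7)
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="standardized log2 expression")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)

    tsv_path = str(path).rsplit(".", 1)[0] + ".tsv"
    ordered.rename_axis("gene").to_csv(tsv_path, sep="\t")
    return ordered
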