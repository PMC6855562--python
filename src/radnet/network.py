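"""Gene-regulatory-network inference by per-gene sparse regression.

The expression of each gene is modeled as a linear combination of its
own copy number and the expression of all other genes. A lasso fit with
cross-validated penalty picks candidate predictors; each predictor
entering the lasso path is assigned a significance via the covariance
test for the lasso (an Exp(1) tail on the drop in covariance at its
entry knot), and only predictors below the selection p cutoff survive.
Local regulators (nearby genes on the same chromosome, which tend to
reflect shared copy-number signal rather than regulation) are pruned,
and the surviving per-gene models are assembled into a signed directed
network whose predictive power is evaluated on held-out samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lars_path
from sklearn.model_selection import KFold

from radnet.annotation import GeneAnnotation

logger = logging.getLogger(__name__)

SIGN_ACTIVATOR = "activator"
SIGN_INHIBITOR = "inhibitor"

CN_PREDICTOR = "__copy_number__"


@dataclass
class NetworkInferenceParams:
    cv_folds: int = 10
    selection_p_cutoff: float = 1e-3
    local_gene_cutoff: int = 50
    min_mean_expression: float = 1.0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.selection_p_cutoff <= 1:
            raise ValueError("selection p cutoff must be in (0, 1]")
        if self.local_gene_cutoff < 0:
            raise ValueError("local gene cutoff must be >= 0")


@dataclass
class GeneModel:
    """Per-gene linear model: intercept, own-copy-number term, regulators.

    ``predictors`` holds (regulator gene id, coefficient, selection
    p-value) triples for nonzero, significant expression predictors;
    coefficients are on the original data scale.
    """

    target: str
    intercept: float = 0.0
    cn_coefficient: float = 0.0
    cn_p_value: float = 1.0
    predictors: list[tuple[str, float, float]] = field(default_factory=list)
    cv_lambda: float = float("nan")

    def __post_init__(self) -> None:
        for g, coef, p in self.predictors:
            if g == self.target:
                raise ValueError("self-loop predictor in gene model")
            if not 0 <= p <= 1:
                raise ValueError("selection p-value outside [0, 1]")
            if coef == 0:
                raise ValueError("zero coefficient stored in gene model")

    @property
    def predictor_ids(self) -> list[str]:
        return [g for g, _, _ in self.predictors]


def filter_expressed_genes(
    expression: pd.DataFrame, min_mean: float = 1.0
) -> list[str]:
    """Keep genes expressed on average at >= ``min_mean`` units per sample.

    Also drops zero-variance rows (constant expression carries no signal
    for regression). Values are expected on a nonnegative count-like
    scale.
    """
    if (expression.to_numpy() < 0).any():
        raise ValueError("expected nonnegative count-like expression values")
    means = expression.mean(axis=1)
    variances = expression.var(axis=1)
    keep = (means >= min_mean) & (variances > 0)
    return list(expression.index[keep])


def _lasso_coefs_at(alphas: np.ndarray, coefs: np.ndarray, alpha: float) -> np.ndarray:
    """Interpolate lasso-path coefficients at a penalty value.

    The lasso path is piecewise linear in alpha between knots; alphas
    are the (decreasing) knot values from :func:`lars_path`.
    """
    if alpha >= alphas[0]:
        return np.zeros(coefs.shape[0])
    if alpha <= alphas[-1]:
        return coefs[:, -1].copy()
    idx = int(np.searchsorted(-alphas, -alpha, side="right"))
    a_hi, a_lo = alphas[idx - 1], alphas[idx]
    t = (a_hi - alpha) / (a_hi - a_lo)
    return coefs[:, idx - 1] * (1 - t) + coefs[:, idx] * t


_MAX_PATH_KNOTS = 150


def _coefs_on_grid(
    alphas: np.ndarray, coefs: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Lasso-path coefficients interpolated at every grid penalty."""
    out = np.zeros((coefs.shape[0], len(grid)))
    for gi, a in enumerate(grid):
        out[:, gi] = _lasso_coefs_at(alphas, coefs, float(a))
    return out


def _cv_lambda(
    x: np.ndarray,
    y: np.ndarray,
    cv_folds: int,
    n_grid: int = 100,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Penalty at minimum cross-validated error along the lasso path.

    The LARS path is piecewise linear in the penalty, so the per-fold
    paths are interpolated onto a common geometric grid and the mean
    squared held-out error is minimized over the grid. Returns
    (alpha at minimum CV error, full-data path alphas, path coefs).
    """
    alphas, _, coefs = lars_path(x, y, method="lasso", max_iter=_MAX_PATH_KNOTS)
    a_min = max(alphas[-1], alphas[0] * 1e-3)
    grid = np.geomspace(alphas[0], a_min, n_grid)
    errs = np.zeros(n_grid)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=0)
    for train, test in kf.split(x):
        a_f, _, c_f = lars_path(
            x[train], y[train], method="lasso", max_iter=_MAX_PATH_KNOTS
        )
        c_grid = _coefs_on_grid(a_f, c_f, grid)
        resid = y[test][:, np.newaxis] - x[test] @ c_grid
        errs += (resid**2).mean(axis=0)
    return float(grid[int(np.argmin(errs))]), alphas, coefs


def _covariance_test_pvalues(
    x: np.ndarray, y: np.ndarray, alphas: np.ndarray, coefs: np.ndarray,
    sigma2: float, needed: set[int] | None = None,
) -> dict[int, float]:
    """Covariance-test p-value for each predictor entering the lasso path.

    At the knot where predictor j enters, the test statistic is the drop
    in covariance between the full lasso fit at the next knot and the
    lasso restricted to the previously active set, scaled by the noise
    variance; under the null it is asymptotically Exp(1), so
    p = exp(-T). Only the first entry of each predictor is scored.
    """
    pvals: dict[int, float] = {}
    for k in range(len(alphas) - 1):
        if needed is not None and needed <= set(pvals):
            break
        act_k = set(np.flatnonzero(coefs[:, k]))
        act_next = set(np.flatnonzero(coefs[:, k + 1]))
        entered = sorted(act_next - act_k)
        if not entered:
            continue
        alpha_next = alphas[k + 1]
        b_full = coefs[:, k + 1]
        cov_full = float(y @ (x @ b_full))
        if act_k:
            idx_prev = sorted(act_k)
            x_prev = x[:, idx_prev]
            a_prev, _, c_prev = lars_path(
                x_prev, y, method="lasso", max_iter=_MAX_PATH_KNOTS
            )
            b_prev = _lasso_coefs_at(a_prev, c_prev, alpha_next)
            cov_prev = float(y @ (x_prev @ b_prev))
        else:
            cov_prev = 0.0
        t_stat = (cov_full - cov_prev) / max(sigma2, 1e-12)
        p = float(np.exp(-max(t_stat, 0.0)))
        for j in entered:
            if j not in pvals:
                pvals[j] = p
    return pvals


def fit_gene_model(
    target: str,
    expression: pd.DataFrame,
    copy_number: pd.DataFrame,
    params: NetworkInferenceParams | None = None,
) -> GeneModel:
    """Fit the sparse linear model for one target gene.

    Predictors are the target's own copy number plus all other genes'
    expression, standardized to unit variance. The penalty is chosen by
    cross-validation at the minimum CV error; predictor significance
    comes from the covariance test along the lasso path, and only
    predictors that are active at the CV penalty *and* significant at
    the selection cutoff are kept.

    ``expression`` and ``copy_number`` are genes x samples frames with
    matching sample columns.
    """
    if params is None:
        params = NetworkInferenceParams()
    if target not in expression.index:
        raise ValueError(f"target {target!r} not in expression matrix")
    if target not in copy_number.index:
        raise ValueError(f"target {target!r} not in copy-number matrix")
    samples = expression.columns
    n = len(samples)
    if n < max(30, params.cv_folds * 3):
        raise ValueError(
            f"too few samples ({n}) to fit model for {target!r}"
        )

    others = [g for g in expression.index if g != target]
    names = [CN_PREDICTOR] + others
    x_raw = np.column_stack(
        [copy_number.loc[target, samples].to_numpy(dtype=float)]
        + [expression.loc[g, samples].to_numpy(dtype=float) for g in others]
    )
    y_raw = expression.loc[target, samples].to_numpy(dtype=float)
    if np.var(y_raw) == 0:
        raise ValueError(f"target {target!r} has zero expression variance")

    mu = x_raw.mean(axis=0)
    sd = x_raw.std(axis=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    x = (x_raw - mu) / sd_safe
    x[:, degenerate] = 0.0
    y_mean = y_raw.mean()
    y = y_raw - y_mean

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            alpha_cv, alphas, coefs = _cv_lambda(x, y, params.cv_folds)
        except Exception as exc:  # pragma: no cover - degenerate designs
            raise ValueError(f"degenerate design for target {target!r}: {exc}")

    b_cv = _lasso_coefs_at(alphas, coefs, alpha_cv)
    active = np.flatnonzero(b_cv)

    # noise variance: OLS when feasible, else residuals at the CV penalty
    df = len(active)
    resid = y - x @ b_cv
    if n > x.shape[1] + 1:
        ols_resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        sigma2 = float(ols_resid @ ols_resid) / (n - x.shape[1] - 1)
    else:
        sigma2 = float(resid @ resid) / max(n - df - 1, 1)

    pvals = _covariance_test_pvalues(
        x, y, alphas, coefs, sigma2, needed=set(int(j) for j in active)
    )

    cn_coef = 0.0
    cn_p = 1.0
    predictors: list[tuple[str, float, float]] = []
    for j in active:
        p_j = pvals.get(int(j), 1.0)
        coef_orig = float(b_cv[j] / sd_safe[j])
        if j == 0:
            cn_coef, cn_p = coef_orig, p_j
            continue
        if p_j < params.selection_p_cutoff:
            predictors.append((names[j], coef_orig, p_j))

    intercept = float(
        y_mean - sum(c * mu[names.index(g)] for g, c, _ in predictors)
        - cn_coef * mu[0]
    )
    return GeneModel(
        target=target,
        intercept=intercept,
        cn_coefficient=cn_coef,
        cn_p_value=cn_p,
        predictors=predictors,
        cv_lambda=alpha_cv,
    )


def prune_local_regulators(
    model: GeneModel, annotation: GeneAnnotation, local_gene_cutoff: int = 50
) -> GeneModel:
    """Drop predictors within ``local_gene_cutoff`` genes on the same chromosome.

    Distance is measured as the difference in chromosomal order index;
    predictors on other chromosomes are kept regardless of index
    distance. The copy-number term is untouched.
    """
    ann = annotation.indexed()
    if model.target not in ann.index:
        raise ValueError(f"target {model.target!r} missing from annotation")
    t_chrom = ann.loc[model.target, "chrom"]
    t_order = ann.loc[model.target, "order_index"]
    kept = []
    for g, coef, p in model.predictors:
        if g not in ann.index:
            raise ValueError(f"predictor {g!r} missing from annotation")
        same_chrom = ann.loc[g, "chrom"] == t_chrom
        if same_chrom and abs(int(ann.loc[g, "order_index"]) - int(t_order)) <= local_gene_cutoff:
            continue
        kept.append((g, coef, p))
    return replace(model, predictors=kept)


@dataclass
class RegulatoryNetwork:
    """Directed signed gene regulatory network.

    ``edges`` is a frame with columns regulator, target, coefficient,
    sign, p_value; sign is ``activator`` iff coefficient > 0. ``models``
    optionally keeps the per-gene linear models (needed for prediction;
    permuted null networks carry edges only).
    """

    genes: list[str]
    edges: pd.DataFrame = field(repr=False)
    models: dict[str, GeneModel] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.edges):
            if (self.edges["regulator"] == self.edges["target"]).any():
                raise ValueError("network contains self-loops")
            expected = np.where(
                self.edges["coefficient"] > 0, SIGN_ACTIVATOR, SIGN_INHIBITOR
            )
            if not (self.edges["sign"].to_numpy() == expected).all():
                raise ValueError("edge signs inconsistent with coefficients")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree_tables(self) -> tuple[pd.Series, pd.Series]:
        """(out-degree, in-degree) per gene, zero-filled over the universe."""
        out_deg = self.edges["regulator"].value_counts()
        in_deg = self.edges["target"].value_counts()
        idx = pd.Index(self.genes, name="gene_id")
        return (
            out_deg.reindex(idx, fill_value=0).astype(int),
            in_deg.reindex(idx, fill_value=0).astype(int),
        )

    def adjacency(self, node_weights: pd.Series | None = None) -> pd.DataFrame:
        """Weighted adjacency A[regulator, target] = coefficient * weight(target)."""
        idx = pd.Index(self.genes)
        a = pd.DataFrame(0.0, index=idx, columns=idx)
        if len(self.edges):
            for reg, tgt, coef in zip(
                self.edges["regulator"], self.edges["target"], self.edges["coefficient"]
            ):
                a.loc[reg, tgt] = coef
        if node_weights is not None:
            w = node_weights.reindex(idx, fill_value=0.0).clip(lower=0.0)
            a = a * w.to_numpy()[np.newaxis, :]
        return a


def assemble_network(
    models: list[GeneModel] | dict[str, GeneModel],
    genes: list[str] | None = None,
) -> RegulatoryNetwork:
    """Assemble per-gene models into a signed directed network.

    One edge regulator -> target per surviving expression predictor;
    edge sign follows the coefficient sign.
    """
    if isinstance(models, dict):
        model_map = dict(models)
    else:
        model_map = {m.target: m for m in models}
    rows = []
    for target, model in model_map.items():
        for g, coef, p in model.predictors:
            rows.append(
                {
                    "regulator": g,
                    "target": target,
                    "coefficient": coef,
                    "sign": SIGN_ACTIVATOR if coef > 0 else SIGN_INHIBITOR,
                    "p_value": p,
                }
            )
    edges = pd.DataFrame(
        rows, columns=["regulator", "target", "coefficient", "sign", "p_value"]
    )
    if genes is None:
        genes = sorted(
            set(model_map)
            | set(edges["regulator"].tolist())
            | set(edges["target"].tolist())
        )
    return RegulatoryNetwork(genes=list(genes), edges=edges, models=model_map)


def predict_expression(
    model: GeneModel, expression: pd.DataFrame, copy_number: pd.DataFrame
) -> pd.Series:
    """Predicted expression of a model's target across samples."""
    samples = expression.columns
    pred = np.full(len(samples), model.intercept, dtype=float)
    if model.cn_coefficient != 0.0:
        pred += model.cn_coefficient * copy_number.loc[
            model.target, samples
        ].to_numpy(dtype=float)
    for g, coef, _ in model.predictors:
        pred += coef * expression.loc[g, samples].to_numpy(dtype=float)
    return pd.Series(pred, index=samples, name=model.target)


def evaluate_predictive_power(
    network: RegulatoryNetwork,
    expression: pd.DataFrame,
    copy_number: pd.DataFrame,
) -> pd.Series:
    """Per-gene predictive-power weights on held-out data.

    For each gene with a model, predict its expression from the model
    applied to the held-out predictors and report the Pearson
    correlation between predicted and observed values across samples.
    Genes without a model, with no predictors, or with degenerate
    predictions get weight 0.
    """
    weights = pd.Series(0.0, index=pd.Index(network.genes, name="gene_id"))
    for gene, model in network.models.items():
        if gene not in expression.index:
            continue
        if not model.predictors and model.cn_coefficient == 0.0:
            continue
        missing = [g for g in model.predictor_ids if g not in expression.index]
        if missing:
            logger.warning("model %s skips held-out genes %s", gene, missing[:3])
            continue
        pred = predict_expression(model, expression, copy_number)
        obs = expression.loc[gene, expression.columns].to_numpy(dtype=float)
        if np.std(pred) == 0 or np.std(obs) == 0:
            continue
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = float(stats.pearsonr(pred.to_numpy(), obs)[0])
        weights[gene] = r if np.isfinite(r) else 0.0
    return weights


def infer_network(
    expression: pd.DataFrame,
    copy_number: pd.DataFrame,
    annotation: GeneAnnotation | None = None,
    params: NetworkInferenceParams | None = None,
) -> RegulatoryNetwork:
    """Fit all per-gene models, prune local regulators, assemble the network.

    Local pruning is applied only when an annotation is given and
    ``params.local_gene_cutoff > 0``. Per-target fits are independent, so
    results do not depend on gene order.
    """
    if params is None:
        params = NetworkInferenceParams()
    models = []
    for target in expression.index:
        model = fit_gene_model(target, expression, copy_number, params)
        if annotation is not None and params.local_gene_cutoff > 0:
            model = prune_local_regulators(
                model, annotation, params.local_gene_cutoff
            )
        models.append(model)
    return assemble_network(models, genes=list(expression.index))
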