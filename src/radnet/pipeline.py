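"""Pipeline configuration and the end-to-end driver.

The driver chains copy-number calling -> differential expression ->
network inference (or network loading) -> propagation impact ->
patient transfer, writing every stage table under an output directory
and echoing all parameters and stage counts into a run log. A single
global seed is fanned out to per-stage seeds through numpy's
SeedSequence spawn keys, so runs with the same config and seed are
byte-identical while stages stay statistically independent.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from radnet import io as rio
from radnet.annotation import read_annotation
from radnet.cna import call_copy_number_states, map_segments_to_genes
from radnet.expression import (
    HmmParams,
    average_log_ratio_profile,
    decode_de_states,
    fit_de_hmm,
    impute_row_median,
    quantile_normalize,
    select_direct_candidates,
)
from radnet.network import (
    NetworkInferenceParams,
    evaluate_predictive_power,
    infer_network,
)
from radnet.propagation import (
    PropagationParams,
    compute_impact_matrix,
    permute_network_degree_preserving,
    score_candidate_impacts,
    test_impact_significance,
)
from radnet.survival import consistency_filter, evaluate_marker_candidates

logger = logging.getLogger(__name__)

_STAGE_KEYS = {
    "cna": 0,
    "expression": 1,
    "network": 2,
    "propagation": 3,
    "transfer": 4,
    "simulate": 5,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All file paths and stage parameters of one pipeline run."""

    # inputs
    annotation_path: str = ""
    seg_path: str = ""
    seg_sample: str | None = None
    expression_resistant_path: str = ""
    expression_sensitive_path: str = ""
    cohort_expression_path: str = ""
    cohort_cn_path: str = ""
    validation_expression_path: str | None = None
    validation_cn_path: str | None = None
    clinical_path: str | None = None
    network_path: str | None = None
    marker_genes: list[str] = field(default_factory=list)
    # stage parameters
    cna_cutoff: float = 0.1
    hmm_init_means: tuple[float, float, float] = (-1.25, 0.0, 1.25)
    hmm_max_iter: int = 100
    hmm_tol: float = 1e-4
    cv_folds: int = 10
    selection_p_cutoff: float = 1e-3
    local_gene_cutoff: int = 50
    min_mean_expression: float = 1.0
    expression_filter: bool = False
    holdout_frac: float = 0.25
    max_path_length: int = 5
    n_permutations: int = 10
    q_cutoff: float = 0.01
    min_group_size: int = 8
    alpha: float = 0.05
    exact_max_exhaustive: int = 10**6
    exact_n_montecarlo: int = 10**5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hmm_init_means" in raw:
            raw["hmm_init_means"] = tuple(raw["hmm_init_means"])
        return cls(**raw)

    def echo(self) -> str:
        lines = ["pipeline parameters:"]
        for f in dataclasses.fields(self):
            lines.append(f"  {f.name} = {getattr(self, f.name)!r}")
        return "\n".join(lines)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline and write the result bundle.

    Returns a dict with the candidate table, impact table, marker table
    (None when no clinical table is configured) and the run-log lines.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [config.echo()]

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    # ---- stage: copy-number calling -------------------------------------
    try:
        annotation = read_annotation(config.annotation_path)
        segments = rio.read_seg(config.seg_path)
        gene_ratio = map_segments_to_genes(
            segments, annotation, sample=config.seg_sample
        )
        cn_profile = call_copy_number_states(gene_ratio, cutoff=config.cna_cutoff)
    except Exception as exc:
        raise PipelineError("cna", str(exc)) from exc
    counts = cn_profile.counts
    log(
        f"cna: {len(gene_ratio)} genes mapped; "
        f"{counts['reduced']} reduced, {counts['increased']} increased"
    )
    cn_profile.to_frame().to_csv(out / "cn_calls.tsv", sep="\t")

    # ---- stage: differential expression ----------------------------------
    try:
        res = rio.read_expression(config.expression_resistant_path)
        sens = rio.read_expression(config.expression_sensitive_path)
        joint = pd.concat([res, sens], axis=1)
        joint = quantile_normalize(impute_row_median(joint))
        res_n = joint[res.columns]
        sens_n = joint[sens.columns]
        profile = average_log_ratio_profile(res_n, sens_n, annotation)
        params, history = fit_de_hmm(
            profile,
            init=HmmParams(means=np.asarray(config.hmm_init_means)),
            max_iter=config.hmm_max_iter,
            tol=config.hmm_tol,
        )
        de_calls = decode_de_states(profile, params)
        candidates, cand_counts = select_direct_candidates(cn_profile, de_calls)
    except Exception as exc:
        raise PipelineError("expression", str(exc)) from exc
    de_counts = de_calls.counts
    log(
        f"expression: {de_counts['under']} under, {de_counts['over']} over; "
        f"{cand_counts['same_direction']} same-direction candidates "
        f"({cand_counts['opposite_direction']} opposite-direction excluded)"
    )
    export = de_calls.posteriors.copy()
    export.insert(0, "state", de_calls.state)
    export.insert(
        0, "mean_log2_ratio", profile.set_index("gene_id")["value"]
    )
    export.to_csv(out / "de_calls.tsv", sep="\t", index_label="gene_id")
    candidates.to_csv(out / "direct_candidates.tsv", sep="\t", index=False)

    # ---- stage: network ---------------------------------------------------
    try:
        cohort_expr = rio.read_expression(config.cohort_expression_path)
        cohort_cn = rio.read_expression(config.cohort_cn_path)
        if config.expression_filter:
            from radnet.network import filter_expressed_genes

            kept = filter_expressed_genes(
                cohort_expr, min_mean=config.min_mean_expression
            )
            cohort_expr = cohort_expr.loc[kept]
            cohort_cn = cohort_cn.loc[kept]
        if config.validation_expression_path and config.validation_cn_path:
            # independent validation cohort: train on the full cohort and
            # score predictive power on the external draw
            train_cols = list(cohort_expr.columns)
            val_expr = rio.read_expression(config.validation_expression_path)
            val_cn = rio.read_expression(config.validation_cn_path)
        else:
            rng = np.random.default_rng(stage_seed(config.seed, "network"))
            samples = list(cohort_expr.columns)
            n_holdout = max(int(round(config.holdout_frac * len(samples))), 1)
            holdout = sorted(
                rng.choice(len(samples), size=n_holdout, replace=False).tolist()
            )
            holdout_cols = [samples[i] for i in holdout]
            train_cols = [s for s in samples if s not in set(holdout_cols)]
            val_expr = cohort_expr[holdout_cols]
            val_cn = cohort_cn[holdout_cols]
        if config.network_path:
            network = rio.read_network(
                config.network_path, genes=list(cohort_expr.index)
            )
            log(f"network: loaded {network.n_edges} edges from file")
        else:
            net_params = NetworkInferenceParams(
                cv_folds=config.cv_folds,
                selection_p_cutoff=config.selection_p_cutoff,
                local_gene_cutoff=config.local_gene_cutoff,
                min_mean_expression=config.min_mean_expression,
            )
            network = infer_network(
                cohort_expr[train_cols],
                cohort_cn[train_cols],
                annotation=annotation,
                params=net_params,
            )
            log(
                f"network: inferred {network.n_edges} edges from "
                f"{len(train_cols)} training samples"
            )
        weights = evaluate_predictive_power(network, val_expr, val_cn)
    except Exception as exc:
        raise PipelineError("network", str(exc)) from exc
    n_act = int((network.edges["sign"] == "activator").sum())
    log(
        f"network: {n_act} activator / {network.n_edges - n_act} inhibitor links; "
        f"mean predictive weight {weights.mean():.3f} on {val_expr.shape[1]} "
        "held-out samples"
    )
    rio.write_network(network, out / "network.tsv")
    if network.models:
        rio.write_model_store(network.models, out / "models.json")

    # ---- stage: propagation impact ----------------------------------------
    try:
        if not config.marker_genes:
            raise ValueError("no marker genes configured")
        cand_in_net = [
            g for g in candidates["gene_id"] if g in set(network.genes)
        ]
        signals = profile.set_index("gene_id")["value"]
        prop_params = PropagationParams(max_path_length=config.max_path_length)
        impacts = compute_impact_matrix(
            network, signals, weights, prop_params, candidates=cand_in_net
        )
        original = score_candidate_impacts(impacts, config.marker_genes)
        perm_seed = stage_seed(config.seed, "propagation")
        permuted = {}
        for k in range(config.n_permutations):
            perm_net = permute_network_degree_preserving(network, seed=perm_seed + k)
            perm_impacts = compute_impact_matrix(
                perm_net, signals, weights, prop_params, candidates=cand_in_net
            )
            permuted[f"perm_{k}"] = score_candidate_impacts(
                perm_impacts, config.marker_genes
            )
        impact_table = test_impact_significance(
            original, pd.DataFrame(permuted), q_cutoff=config.q_cutoff
        )
        impact_table = impact_table.join(
            candidates.set_index("gene_id")["direction"], how="left"
        )
    except Exception as exc:
        raise PipelineError("propagation", str(exc)) from exc
    n_sig = int(impact_table["significant"].sum())
    log(
        f"propagation: {len(cand_in_net)} candidates in network; "
        f"{n_sig} significant at q < {config.q_cutoff}"
    )
    impact_table.to_csv(out / "impact_results.tsv", sep="\t", index_label="gene_id")

    drivers = (
        impact_table[impact_table["significant"]]
        .rename_axis("gene_id")
        .reset_index()
    )

    # ---- stage: patient transfer -------------------------------------------
    marker_table = None
    if config.clinical_path:
        try:
            clinical = rio.read_clinical(config.clinical_path)
            driver_candidates = drivers.loc[:, ["gene_id", "direction"]]
            consistent = consistency_filter(
                driver_candidates, cohort_expr, clinical
            )
            irradiated = clinical[clinical["irradiated"].astype(bool)]
            marker_table = evaluate_marker_candidates(
                consistent,
                cohort_expr,
                irradiated,
                min_group_size=config.min_group_size,
                alpha=config.alpha,
                max_exhaustive=config.exact_max_exhaustive,
                n_montecarlo=config.exact_n_montecarlo,
                seed=stage_seed(config.seed, "transfer"),
            )
        except Exception as exc:
            raise PipelineError("transfer", str(exc)) from exc
        n_sel = int(marker_table["selected"].sum()) if len(marker_table) else 0
        log(
            f"transfer: {len(consistent)} of {len(drivers)} drivers consistent; "
            f"{n_sel} markers selected at p < {config.alpha}"
        )
        marker_table.to_csv(out / "marker_table.tsv", sep="\t", index=False)
    else:
        log("transfer: no clinical table configured; stopped after impact stage")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "cn_profile": cn_profile,
        "de_calls": de_calls,
        "candidates": candidates,
        "network": network,
        "weights": weights,
        "impact_table": impact_table,
        "drivers": drivers,
        "marker_table": marker_table,
        "log": log_lines,
    }
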