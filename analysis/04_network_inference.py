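"""Infer the gene regulatory network from the patient cohort.

Fits one lasso model per gene (predictors: the gene's own copy number
plus all other genes' expression) on the patient cohort, keeps
predictors passing the covariance-test significance cutoff, prunes
local regulators, assembles the signed directed network, and scores
per-gene predictive power on the independent validation cohort. Edge
recovery against the planted truth is reported on the undirected
skeleton (the identifiable object for observational data).
"""

import argparse
import time
from pathlib import Path

from radnet.annotation import read_annotation
from radnet.io import read_expression, read_truth_json, write_network
from radnet.network import (
    NetworkInferenceParams,
    evaluate_predictive_power,
    infer_network,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", default="results/bundle")
    ap.add_argument("--out", default="results/network.tsv")
    ap.add_argument("--out-weights", default="results/predictive_weights.tsv")
    ap.add_argument("--p-cutoff", type=float, default=1e-3,
                    help="covariance-test selection cutoff (keep links with "
                         "p approximately zero)")
    ap.add_argument("--local-cutoff", type=int, default=5,
                    help="local-regulator pruning distance, scaled to the "
                         "desk-scale gene density")
    args = ap.parse_args()

    bundle = Path(args.bundle)
    annotation = read_annotation(bundle / "annotation.tsv")
    expr = read_expression(bundle / "cohort_expression.tsv")
    cn = read_expression(bundle / "cohort_copy_number.tsv")
    val_expr = read_expression(bundle / "validation_expression.tsv")
    val_cn = read_expression(bundle / "validation_copy_number.tsv")

    params = NetworkInferenceParams(
        selection_p_cutoff=args.p_cutoff, local_gene_cutoff=args.local_cutoff
    )
    t0 = time.time()
    network = infer_network(expr, cn, annotation, params)
    print(f"inferred {network.n_edges} edges from {expr.shape[1]} patients "
          f"in {time.time() - t0:.0f} s")
    n_act = int((network.edges["sign"] == "activator").sum())
    print(f"  {n_act} activator / {network.n_edges - n_act} inhibitor links")

    weights = evaluate_predictive_power(network, val_expr, val_cn)
    print(f"  mean predictive correlation on the validation cohort: "
          f"{weights.mean():.3f} ({val_expr.shape[1]} samples)")

    write_network(network, args.out)
    weights.to_csv(args.out_weights, sep="\t", header=["weight"])

    truth = read_truth_json(bundle / "truth.json")
    true_und = {frozenset(e[:2]) for e in truth["edges"]}
    found = [
        frozenset(e)
        for e in zip(network.edges["regulator"], network.edges["target"])
    ]
    tp = sum(1 for e in found if e in true_und)
    print(f"  skeleton precision {tp / max(len(found), 1):.2f}, "
          f"recall {len(set(found) & true_und) / len(true_und):.2f} "
          f"against the planted truth")


if __name__ == "__main__":
    main()
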