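"""Score candidate impacts on the radioresistance markers.

Propagates each direct candidate's observed expression log2-ratio along
all network paths (up to length 5, weighted by edge coefficients and
per-gene predictive-power weights), averages absolute impacts over the
marker set, and compares against 10 degree-preserving network
permutations with one-sided t-tests and Benjamini-Hochberg correction.
Candidates significant at q < 0.01 are the nominated drivers.
"""

import argparse
from pathlib import Path

import pandas as pd

from radnet.annotation import read_annotation
from radnet.expression import (
    average_log_ratio_profile,
    impute_row_median,
    quantile_normalize,
)
from radnet.io import read_expression, read_network, read_truth_json
from radnet.propagation import (
    PropagationParams,
    compute_impact_matrix,
    permute_network_degree_preserving,
    score_candidate_impacts,
    test_impact_significance,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", default="results/bundle")
    ap.add_argument("--network", default="results/network.tsv")
    ap.add_argument("--weights", default="results/predictive_weights.tsv")
    ap.add_argument("--candidates", default="results/direct_candidates.tsv")
    ap.add_argument("--out", default="results/impact_results.tsv")
    ap.add_argument("--n-permutations", type=int, default=10)
    ap.add_argument("--q-cutoff", type=float, default=0.01)
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()

    bundle = Path(args.bundle)
    annotation = read_annotation(bundle / "annotation.tsv")
    truth = read_truth_json(bundle / "truth.json")
    markers = truth["markers"]

    cohort_genes = read_expression(bundle / "cohort_expression.tsv").index
    network = read_network(args.network, genes=list(cohort_genes))
    weights = pd.read_csv(args.weights, sep="\t", index_col=0)["weight"]
    candidates = pd.read_csv(args.candidates, sep="\t")

    res = read_expression(bundle / "expr_resistant.tsv")
    sens = read_expression(bundle / "expr_sensitive.tsv")
    joint = quantile_normalize(impute_row_median(pd.concat([res, sens], axis=1)))
    profile = average_log_ratio_profile(
        joint[res.columns], joint[sens.columns], annotation
    )
    signals = profile.set_index("gene_id")["value"]

    cand_ids = [g for g in candidates["gene_id"] if g in set(network.genes)]
    params = PropagationParams(max_path_length=5)
    impacts = compute_impact_matrix(network, signals, weights, params, cand_ids)
    original = score_candidate_impacts(impacts, markers)
    print(f"{len(cand_ids)} candidates scored against {len(markers)} markers; "
          f"truncation tail norm {impacts.tail_norm:.2e}")

    permuted = {}
    for k in range(args.n_permutations):
        perm = permute_network_degree_preserving(network, seed=args.seed + k)
        perm_impacts = compute_impact_matrix(perm, signals, weights, params, cand_ids)
        permuted[f"perm_{k}"] = score_candidate_impacts(perm_impacts, markers)

    table = test_impact_significance(
        original, pd.DataFrame(permuted), q_cutoff=args.q_cutoff
    )
    table = table.join(candidates.set_index("gene_id")["direction"], how="left")
    table.to_csv(args.out, sep="\t", index_label="gene_id")

    sig = table[table["significant"]]
    print(f"{len(sig)} candidates significant at q < {args.q_cutoff}")
    drivers = set(truth["drivers"])
    print(f"planted drivers among significant: {len(drivers & set(sig.index))} "
          f"of {len(drivers)}")


if __name__ == "__main__":
    main()
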