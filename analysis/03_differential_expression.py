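"""Call differentially expressed genes and select direct candidates.

Quantile-normalizes the six replicate arrays jointly, forms the
chromosomally ordered average log2-ratio profile (resistant minus
sensitive), fits the three-state Gaussian HMM by Baum-Welch, decodes
per-gene states from the posteriors, and intersects the expression
calls with the copy-number calls: genes altered in the same direction
on both layers are the direct driver candidates.
"""

import argparse
from pathlib import Path

import pandas as pd

from radnet.annotation import read_annotation
from radnet.cna import call_copy_number_states, map_segments_to_genes
from radnet.expression import (
    average_log_ratio_profile,
    decode_de_states,
    fit_de_hmm,
    impute_row_median,
    quantile_normalize,
    select_direct_candidates,
)
from radnet.io import read_expression, read_seg, read_truth_json


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", default="results/bundle")
    ap.add_argument("--out-calls", default="results/de_calls.tsv")
    ap.add_argument("--out-candidates", default="results/direct_candidates.tsv")
    args = ap.parse_args()

    bundle = Path(args.bundle)
    annotation = read_annotation(bundle / "annotation.tsv")
    res = read_expression(bundle / "expr_resistant.tsv")
    sens = read_expression(bundle / "expr_sensitive.tsv")
    joint = quantile_normalize(impute_row_median(pd.concat([res, sens], axis=1)))
    profile = average_log_ratio_profile(
        joint[res.columns], joint[sens.columns], annotation
    )

    params, history = fit_de_hmm(profile)
    calls = decode_de_states(profile, params)
    counts = calls.counts
    print(f"HMM converged after {len(history)} Baum-Welch iterations; "
          f"state means: {params.means.round(3).tolist()}")
    print(f"{counts['under']} underexpressed, {counts['over']} overexpressed "
          f"of {len(profile)} genes")

    export = calls.posteriors.copy()
    export.insert(0, "state", calls.state)
    export.insert(0, "mean_log2_ratio", profile.set_index("gene_id")["value"])
    export.to_csv(args.out_calls, sep="\t", index_label="gene_id")

    segments = read_seg(bundle / "cellline.seg")
    cn = call_copy_number_states(map_segments_to_genes(segments, annotation))
    candidates, cand_counts = select_direct_candidates(cn, calls)
    candidates.to_csv(args.out_candidates, sep="\t", index=False)
    print(f"{cand_counts['same_direction']} same-direction direct candidates "
          f"({cand_counts['opposite_direction']} opposite-direction excluded)")

    truth = read_truth_json(bundle / "truth.json")
    found = set(candidates["gene_id"]) & set(truth["drivers"])
    print(f"planted drivers among candidates: {len(found)} of "
          f"{len(truth['drivers'])}")


if __name__ == "__main__":
    main()
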