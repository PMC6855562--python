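"""Call gene-level copy-number states from the segmented contrast.

Maps the SEG profile of the resistant-vs-sensitive contrast onto gene
coordinates (overlap-weighted means), trinarizes at the |log2| > 0.1
cutoff, and reports how many genes gained or lost copies — the
desk-scale analogue of contrasting a radioresistant line against its
parental radiosensitive line.
"""

import argparse
from pathlib import Path

from radnet.annotation import read_annotation
from radnet.cna import call_copy_number_states, map_segments_to_genes
from radnet.io import read_seg, read_truth_json


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", default="results/bundle")
    ap.add_argument("--out", default="results/cn_calls.tsv")
    ap.add_argument("--cutoff", type=float, default=0.1)
    args = ap.parse_args()

    bundle = Path(args.bundle)
    annotation = read_annotation(bundle / "annotation.tsv")
    segments = read_seg(bundle / "cellline.seg")
    ratios = map_segments_to_genes(segments, annotation)
    profile = call_copy_number_states(ratios, cutoff=args.cutoff)
    profile.to_frame().to_csv(args.out, sep="\t")

    counts = profile.counts
    n = len(ratios)
    print(f"{counts['reduced']} of {n} genes reduced "
          f"({100 * counts['reduced'] / n:.1f}%), "
          f"{counts['increased']} increased ({100 * counts['increased'] / n:.1f}%)")

    truth = read_truth_json(bundle / "truth.json")
    called = profile.genes_in_state("reduced") | profile.genes_in_state("increased")
    drivers = set(truth["drivers"])
    print(f"planted drivers with called alteration: "
          f"{len(drivers & called)} of {len(drivers)}")
    print(f"wrote per-gene calls to {args.out}")


if __name__ == "__main__":
    main()
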