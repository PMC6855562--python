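"""Gene-level copy-number calling from segmented aCGH profiles.

Segmented log2-ratio profiles (resistant vs. sensitive) are mapped onto
gene coordinates, each gene is assigned a trinary state at a symmetric
log2-ratio cutoff (default 0.1, strict inequalities), and gene-set
overlaps are tested with exact hypergeometric / Fisher statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from radnet.annotation import GeneAnnotation

logger = logging.getLogger(__name__)

STATE_REDUCED = "reduced"
STATE_UNCHANGED = "unchanged"
STATE_INCREASED = "increased"


def map_segments_to_genes(
    segments: pd.DataFrame,
    annotation: GeneAnnotation,
    sample: str | None = None,
) -> pd.Series:
    """Map segment log2-ratios onto genes.

    Each gene receives the overlap-length-weighted mean of the
    log2-ratios of all segments it intersects; genes with no overlapping
    segment are NaN (missing). Coordinates on both sides are 0-based
    half-open (the SEG reader converts).

    Parameters
    ----------
    segments : segment frame (one sample's profile, or pass ``sample``)
    annotation : gene annotation
    sample : restrict the segment frame to this sample id
    """
    seg = segments
    if sample is not None:
        seg = seg[seg["sample"] == sample]
    ann = annotation.table

    seg_chroms = set(seg["chrom"].astype(str))
    ann_chroms = set(ann["chrom"].astype(str))
    only_seg = seg_chroms - ann_chroms
    if only_seg:
        logger.warning(
            "segments on chromosomes absent from annotation: %s",
            sorted(only_seg),
        )
    only_ann = ann_chroms - seg_chroms
    if only_ann and len(seg):
        logger.warning(
            "annotation chromosomes with no segments (genes set missing): %s",
            sorted(only_ann),
        )

    values = pd.Series(np.nan, index=ann["gene_id"], name="log2_ratio")
    if not len(seg):
        return values

    for chrom, seg_c in seg.groupby("chrom"):
        genes_c = ann[ann["chrom"] == chrom]
        if not len(genes_c):
            continue
        s_start = seg_c["start"].to_numpy()
        s_end = seg_c["end"].to_numpy()
        s_ratio = seg_c["log2_ratio"].to_numpy()
        for gene_id, g_start, g_end in zip(
            genes_c["gene_id"], genes_c["start"], genes_c["end"]
        ):
            overlap = np.minimum(s_end, g_end) - np.maximum(s_start, g_start)
            mask = overlap > 0
            if not mask.any():
                continue
            w = overlap[mask].astype(float)
            values[gene_id] = float(np.average(s_ratio[mask], weights=w))
    return values


@dataclass
class GeneCopyNumberProfile:
    """Per-gene copy-number log2-ratios with trinary states.

    state is ``reduced`` iff log2_ratio < -cutoff, ``increased`` iff
    log2_ratio > +cutoff, else ``unchanged`` (strict inequalities);
    missing values are called unchanged.
    """

    log2_ratio: pd.Series = field(repr=False)
    state: pd.Series = field(repr=False)
    cutoff: float = 0.1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        finite = self.log2_ratio.dropna()
        s = self.state[finite.index]
        expect = np.where(
            finite < -self.cutoff,
            STATE_REDUCED,
            np.where(finite > self.cutoff, STATE_INCREASED, STATE_UNCHANGED),
        )
        if not (s.to_numpy() == expect).all():
            raise ValueError("states inconsistent with log2-ratios and cutoff")

    @property
    def counts(self) -> dict[str, int]:
        c = self.state.value_counts()
        return {
            STATE_REDUCED: int(c.get(STATE_REDUCED, 0)),
            STATE_UNCHANGED: int(c.get(STATE_UNCHANGED, 0)),
            STATE_INCREASED: int(c.get(STATE_INCREASED, 0)),
        }

    def genes_in_state(self, state: str) -> set[str]:
        return set(self.state.index[self.state == state])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"log2_ratio": self.log2_ratio, "state": self.state})


def call_copy_number_states(
    log2_ratio: pd.Series, cutoff: float = 0.1
) -> GeneCopyNumberProfile:
    """Trinarize per-gene log2-ratios at a symmetric cutoff.

    Values strictly below -cutoff are ``reduced``, strictly above
    +cutoff ``increased``, everything else (including exact boundary
    values and missing genes) ``unchanged``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n_missing = int(log2_ratio.isna().sum())
    if n_missing:
        logger.info("%d genes without copy-number value called unchanged", n_missing)
    vals = log2_ratio.to_numpy(dtype=float)
    state = np.full(len(vals), STATE_UNCHANGED, dtype=object)
    with np.errstate(invalid="ignore"):
        state[vals < -cutoff] = STATE_REDUCED
        state[vals > cutoff] = STATE_INCREASED
    return GeneCopyNumberProfile(
        log2_ratio=log2_ratio.copy(),
        state=pd.Series(state, index=log2_ratio.index, name="state"),
        cutoff=cutoff,
    )


def set_overlap_fisher(
    set_a: set, set_b: set, universe: set, sided: str = "greater"
) -> tuple[int, float, float]:
    """Exact overlap test of two gene sets within a universe.

    Returns (overlap count, odds ratio, p-value). ``sided='greater'``
    gives the exact hypergeometric over-representation tail (the default
    everywhere enrichment is tested); ``'two'`` the two-sided Fisher
    test.
    """
    if not universe:
        raise ValueError("empty universe")
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    k = len(set_a & set_b)
    a_only = len(set_a) - k
    b_only = len(set_b) - k
    neither = n - k - a_only - b_only
    table = np.array([[k, a_only], [b_only, neither]])
    odds_ratio = stats.contingency.odds_ratio(table, kind="sample").statistic
    if sided == "greater":
        p = float(stats.hypergeom.sf(k - 1, n, len(set_a), len(set_b)))
    elif sided == "two":
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return k, float(odds_ratio), min(max(p, 0.0), 1.0)
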