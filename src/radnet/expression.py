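"""Differential-expression calling with a three-state Gaussian HMM.

Replicate log2-intensity matrices are quantile normalized, collapsed to
a chromosomally ordered average log2-ratio profile (resistant minus
sensitive), and segmented by a three-state HMM with Gaussian emissions
(states: underexpressed, unchanged, overexpressed). State-posterior
decoding assigns each gene its most likely state, and genes whose
expression call matches the direction of an underlying copy-number call
become direct driver candidates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM

from radnet.annotation import GeneAnnotation
from radnet.cna import (
    STATE_INCREASED,
    STATE_REDUCED,
    GeneCopyNumberProfile,
)

logger = logging.getLogger(__name__)

STATE_UNDER = "under"
STATE_UNCHANGED = "unchanged"
STATE_OVER = "over"
STATE_LABELS = (STATE_UNDER, STATE_UNCHANGED, STATE_OVER)

VARIANCE_FLOOR = 1e-4


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization of a genes x samples matrix.

    Every column is forced onto the same distribution: the row-wise mean
    of the sorted columns. Ties within a column receive the mean of the
    reference values at their tied ranks (the classic microarray
    convention). Missing values are an error; impute first with
    :func:`impute_row_median`.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    x = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    ranks = pd.DataFrame(x).rank(method="average").to_numpy() - 1.0
    # average ranks from ties land between integers; interpolate linearly
    out = np.interp(ranks, np.arange(len(mean_sorted)), mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def impute_row_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values by the row (gene) median."""
    med = matrix.median(axis=1)
    out = matrix.copy()
    for col in out.columns:
        mask = out[col].isna()
        out.loc[mask, col] = med[mask]
    if out.isna().any().any():
        raise ValueError("rows with all values missing cannot be imputed")
    return out


def average_log_ratio_profile(
    resistant: pd.DataFrame,
    sensitive: pd.DataFrame,
    annotation: GeneAnnotation,
) -> pd.DataFrame:
    """Chromosomally ordered average log2-ratio profile.

    Per gene, mean(resistant replicates) - mean(sensitive replicates) on
    the log2 scale, ordered by (chrom, start). Genes absent from the
    annotation are excluded with a warning. Returns a frame with columns
    gene_id, chrom, value, indexed in chromosomal order.
    """
    if resistant.shape[1] < 1 or sensitive.shape[1] < 1:
        raise ValueError("need at least one replicate per condition")
    common = resistant.index.intersection(sensitive.index)
    diff = resistant.loc[common].mean(axis=1) - sensitive.loc[common].mean(axis=1)
    ann = annotation.table
    known = ann["gene_id"][ann["gene_id"].isin(diff.index)]
    dropped = set(diff.index) - set(known)
    if dropped:
        logger.warning(
            "%d genes absent from annotation excluded from profile", len(dropped)
        )
    chrom = ann.set_index("gene_id")["chrom"]
    out = pd.DataFrame(
        {
            "gene_id": known.to_numpy(),
            "chrom": chrom[known].to_numpy(),
            "value": diff[known].to_numpy(),
        }
    )
    return out.reset_index(drop=True)


@dataclass
class HmmParams:
    """Parameters of the three-state Gaussian HMM.

    States are labelled (under, unchanged, over) with means sorted
    ascending; emissions are univariate Gaussians. Defaults follow the
    standard initialization: means (-1.25, 0, +1.25), sd 0.5, sticky
    transitions (0.9 self, 0.05 off-diagonal), uniform start.
    """

    means: np.ndarray = field(
        default_factory=lambda: np.array([-1.25, 0.0, 1.25])
    )
    variances: np.ndarray = field(default_factory=lambda: np.full(3, 0.25))
    transmat: np.ndarray = field(
        default_factory=lambda: np.full((3, 3), 0.05) + np.eye(3) * 0.85
    )
    startprob: np.ndarray = field(default_factory=lambda: np.full(3, 1 / 3))

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if self.means.shape != (3,) or self.variances.shape != (3,):
            raise ValueError("means and variances must be length-3")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")


@dataclass
class DifferentialExpressionCalls:
    """Per-gene differential-expression states and posteriors."""

    state: pd.Series = field(repr=False)
    posteriors: pd.DataFrame = field(repr=False)  # columns under/unchanged/over
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        sums = self.posteriors.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("posteriors must sum to 1 per gene")

    @property
    def counts(self) -> dict[str, int]:
        c = self.state.value_counts()
        return {label: int(c.get(label, 0)) for label in STATE_LABELS}

    def genes_in_state(self, state: str) -> set[str]:
        return set(self.state.index[self.state == state])


def _as_sequences(profiles: pd.DataFrame) -> tuple[np.ndarray, list[int]]:
    """Stack per-chromosome sequences for hmmlearn (concatenated + lengths)."""
    lengths = [len(g) for _, g in profiles.groupby("chrom", sort=False)]
    x = profiles["value"].to_numpy(dtype=float).reshape(-1, 1)
    return x, lengths


def _sorted_params(model: GaussianHMM) -> HmmParams:
    """Extract parameters with states relabelled by ascending mean."""
    means = model.means_.ravel()
    order = np.argsort(means)
    variances = model.covars_.reshape(3, -1)[:, 0]
    if (variances < VARIANCE_FLOOR).any():
        logger.warning("variance collapse; floored at %g", VARIANCE_FLOOR)
        variances = np.maximum(variances, VARIANCE_FLOOR)
    return HmmParams(
        means=means[order],
        variances=variances[order],
        transmat=model.transmat_[np.ix_(order, order)],
        startprob=model.startprob_[order],
    )


class _RecordingMonitor(ConvergenceMonitor):
    """Convergence monitor keeping the full log-likelihood trace."""

    def __init__(self, tol: float, n_iter: int) -> None:
        super().__init__(tol, n_iter, verbose=False)
        self.full_history: list[float] = []

    def report(self, log_prob: float) -> None:
        self.full_history.append(float(log_prob))
        super().report(log_prob)


def _build_model(params: HmmParams, n_iter: int, tol: float) -> GaussianHMM:
    model = GaussianHMM(
        n_components=3,
        covariance_type="diag",
        n_iter=n_iter,
        tol=tol,
        init_params="",
        params="stmc",
        # pure maximum-likelihood EM: no covariance prior or floor inside the
        # M-step, so the log-likelihood is exactly monotone; flooring of
        # collapsed variances is applied post-fit instead
        min_covar=1e-12,
        covars_prior=0.0,
        covars_weight=0.0,
    )
    model.startprob_ = params.startprob.copy()
    model.transmat_ = params.transmat.copy()
    model.means_ = params.means.reshape(3, 1).copy()
    model.covars_ = params.variances.reshape(3, 1).copy()
    return model


def fit_de_hmm(
    profiles: pd.DataFrame,
    init: HmmParams | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> tuple[HmmParams, list[float]]:
    """Fit the three-state HMM by Baum-Welch on pooled chromosome sequences.

    ``profiles`` is the output of :func:`average_log_ratio_profile`;
    chromosomes are independent sequences sharing one parameter set.
    Returns the fitted parameters (states relabelled by sorted means)
    and the per-iteration log-likelihood history, which is asserted
    non-decreasing (up to round-off).
    """
    if init is None:
        init = HmmParams()
    if len(profiles) < 30:
        raise ValueError("total sequence length must be >= 30")
    x, lengths = _as_sequences(profiles)
    model = _build_model(init, n_iter=max_iter, tol=tol)
    model.monitor_ = _RecordingMonitor(tol=tol, n_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, lengths)
    hist = model.monitor_.full_history
    diffs = np.diff(hist)
    if len(diffs) and (diffs < -1e-6).any():
        raise AssertionError("Baum-Welch log-likelihood decreased")
    return _sorted_params(model), hist


def decode_de_states(
    profiles: pd.DataFrame, params: HmmParams
) -> DifferentialExpressionCalls:
    """Posterior decoding of per-gene expression states.

    Forward-backward posteriors are computed per chromosome sequence;
    each gene is assigned the argmax state with ties broken toward
    ``unchanged``.
    """
    x, lengths = _as_sequences(profiles)
    model = _build_model(params, n_iter=1, tol=np.inf)
    ll, post = model.score_samples(x, lengths)
    post_df = pd.DataFrame(post, columns=list(STATE_LABELS))
    post_df.index = profiles["gene_id"].to_numpy()
    # argmax with unchanged preferred on exact ties
    pref = post_df[[STATE_UNCHANGED, STATE_UNDER, STATE_OVER]].to_numpy()
    pick = np.argmax(pref, axis=1)
    labels = np.array([STATE_UNCHANGED, STATE_UNDER, STATE_OVER], dtype=object)
    state = pd.Series(
        labels[pick], index=post_df.index, name="state"
    )
    return DifferentialExpressionCalls(
        state=state, posteriors=post_df, log_likelihood=float(ll)
    )


DIRECTION_UP = "up"
DIRECTION_DOWN = "down"


def select_direct_candidates(
    cn: GeneCopyNumberProfile, de: DifferentialExpressionCalls
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Genes whose expression call matches the copy-number direction.

    ``up`` candidates have increased copy number and overexpression;
    ``down`` candidates reduced copy number and underexpression. Genes
    altered in copy number with an expression call in the opposite
    direction are counted but excluded. Returns (candidate frame,
    counts) with counts keys same_direction / opposite_direction.
    """
    common = cn.state.index.intersection(de.state.index)
    cn_state = cn.state[common]
    de_state = de.state[common]
    up = (cn_state == STATE_INCREASED) & (de_state == STATE_OVER)
    down = (cn_state == STATE_REDUCED) & (de_state == STATE_UNDER)
    opposite = ((cn_state == STATE_INCREASED) & (de_state == STATE_UNDER)) | (
        (cn_state == STATE_REDUCED) & (de_state == STATE_OVER)
    )
    rows = []
    for g in common[up | down]:
        rows.append(
            {
                "gene_id": g,
                "direction": DIRECTION_UP if up[g] else DIRECTION_DOWN,
                "cn_state": cn_state[g],
                "de_state": de_state[g],
            }
        )
    candidates = pd.DataFrame(
        rows, columns=["gene_id", "direction", "cn_state", "de_state"]
    )
    counts = {
        "same_direction": int((up | down).sum()),
        "opposite_direction": int(opposite.sum()),
    }
    return candidates, counts
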