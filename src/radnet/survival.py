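"""Transfer of driver candidates to patient relapse data.

Candidates are first filtered for sign-consistent behavior in irradiated
relapsed patients (an up-candidate should correlate negatively with time
to relapse, a down-candidate positively). Each surviving candidate is
then evaluated as a relapse marker by an optimal-cutoff Kaplan-Meier
split constrained to at least ``min_group_size`` patients per group,
with asymptotic and exact permutational log-rank p-values, conservative
(Benjamini-Hochberg) and liberal (Storey) FDR estimates, a random-gene
baseline, and covariate-adjusted Cox proportional-hazards models.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"


# ---------------------------------------------------------------------------
# log-rank statistic, vectorized over group assignments
# ---------------------------------------------------------------------------

def _logrank_chi2_many(
    times: np.ndarray, events: np.ndarray, membership: np.ndarray
) -> np.ndarray:
    """Log-rank chi-square statistic for many group assignments at once.

    ``membership`` is (n_assignments, n_patients) boolean, True marking
    group 1. Ties in event times are handled with the standard
    hypergeometric variance. Assignments with zero variance (constant
    statistic) get chi2 = 0.
    """
    order = np.argsort(times, kind="mergesort")
    t = np.asarray(times, dtype=float)[order]
    e = np.asarray(events, dtype=float)[order]
    z = np.asarray(membership, dtype=float)[:, order]
    n = len(t)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e, starts)  # events per distinct time
    n_risk = (n - starts).astype(float)

    # group-1 at risk at each distinct time = suffix count
    rev = np.cumsum(z[:, ::-1], axis=1)[:, ::-1]
    n1 = rev[:, starts]
    d1 = np.add.reduceat(z * e, starts, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1 / n_risk
        o_minus_e = (d1 - d * frac).sum(axis=1)
        denom = np.where(n_risk > 1, n_risk - 1, 1.0)
        var_terms = d * frac * (1 - frac) * (n_risk - d) / denom
        var_terms = np.where(n_risk > 1, var_terms, 0.0)
        v = var_terms.sum(axis=1)
    chi2 = np.zeros(len(z))
    ok = v > 0
    chi2[ok] = o_minus_e[ok] ** 2 / v[ok]
    return chi2


def logrank_chi2(
    times: np.ndarray, events: np.ndarray, group1: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, asymptotic p)."""
    group1 = np.asarray(group1, dtype=bool)
    stat = float(_logrank_chi2_many(times, events, group1[np.newaxis, :])[0])
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


# ---------------------------------------------------------------------------
# consistency filter
# ---------------------------------------------------------------------------

def consistency_filter(
    candidates: pd.DataFrame,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Keep candidates whose patient expression behaves consistently.

    Restricted to irradiated patients with an observed relapse, the
    correlation between a candidate's expression and months-to-relapse
    must be strictly negative for up-candidates (overexpressed in the
    radioresistant line) and strictly positive for down-candidates.

    ``candidates`` needs columns gene_id and direction; returns the kept
    rows with an added ``relapse_correlation`` column.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("correlation method must be pearson or spearman")
    mask = clinical["irradiated"].astype(bool) & clinical["event"].astype(bool)
    patients = clinical.index[mask]
    if len(patients) < 3:
        raise ValueError(
            f"need >= 3 relapsed irradiated patients, have {len(patients)}"
        )
    months = clinical.loc[patients, "months"].to_numpy(dtype=float)
    rows = []
    for rec in candidates.itertuples(index=False):
        gene = rec.gene_id
        if gene not in expression.index:
            logger.warning("candidate %s missing from patient expression", gene)
            continue
        x = expression.loc[gene, patients].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(months) == 0:
            continue
        if method == "pearson":
            corr = float(stats.pearsonr(x, months)[0])
        else:
            corr = float(stats.spearmanr(x, months)[0])
        keep = (rec.direction == DIRECTION_UP and corr < 0) or (
            rec.direction == DIRECTION_DOWN and corr > 0
        )
        if keep:
            row = rec._asdict()
            row["relapse_correlation"] = corr
            rows.append(row)
    cols = list(candidates.columns) + ["relapse_correlation"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# optimal-cutoff survival splitting
# ---------------------------------------------------------------------------

@dataclass
class SurvivalSplit:
    """Optimal expression split of a cohort into low/high survival groups."""

    gene_id: str
    feasible: bool
    cutoff: float = float("nan")
    low_patients: list = field(default_factory=list)
    high_patients: list = field(default_factory=list)
    chi2: float = float("nan")
    approx_p: float = float("nan")
    exact_p: float = float("nan")
    exact_mode: str = ""
    min_group_size: int = 8

    def __post_init__(self) -> None:
        if self.feasible:
            if (
                len(self.low_patients) < self.min_group_size
                or len(self.high_patients) < self.min_group_size
            ):
                raise ValueError("split violates the minimum group size")


def optimal_cutoff_logrank(
    expression: pd.Series,
    clinical: pd.DataFrame,
    min_group_size: int = 8,
    gene_id: str | None = None,
) -> SurvivalSplit:
    """Optimal expression cutoff separating early and late relapse.

    Candidate cutoffs are the midpoints between consecutive sorted
    unique expression values; only cutoffs leaving at least
    ``min_group_size`` patients in each group (low = expression <=
    cutoff) are considered. The cutoff minimizing the asymptotic
    log-rank p is returned; ties go to the smaller cutoff. When no
    cutoff is feasible an infeasible split is returned.
    """
    gene_id = gene_id if gene_id is not None else str(expression.name)
    patients = expression.index
    if len(patients) < 2 * min_group_size:
        return SurvivalSplit(gene_id=gene_id, feasible=False,
                             min_group_size=min_group_size)
    x = expression.to_numpy(dtype=float)
    times = clinical.loc[patients, "months"].to_numpy(dtype=float)
    events = clinical.loc[patients, "event"].to_numpy(dtype=bool)

    uniq = np.unique(x)
    if len(uniq) < 2:
        return SurvivalSplit(gene_id=gene_id, feasible=False,
                             min_group_size=min_group_size)
    midpoints = (uniq[:-1] + uniq[1:]) / 2.0
    memberships = x[np.newaxis, :] <= midpoints[:, np.newaxis]
    sizes_low = memberships.sum(axis=1)
    ok = (sizes_low >= min_group_size) & (
        len(patients) - sizes_low >= min_group_size
    )
    if not ok.any():
        return SurvivalSplit(gene_id=gene_id, feasible=False,
                             min_group_size=min_group_size)
    midpoints = midpoints[ok]
    memberships = memberships[ok]
    chi2 = _logrank_chi2_many(times, events, memberships)
    pvals = np.where(chi2 > 0, stats.chi2.sf(chi2, df=1), 1.0)
    best = int(np.argmin(pvals))  # argmin takes the first (smallest cutoff) tie
    low_mask = memberships[best]
    return SurvivalSplit(
        gene_id=gene_id,
        feasible=True,
        cutoff=float(midpoints[best]),
        low_patients=list(patients[low_mask]),
        high_patients=list(patients[~low_mask]),
        chi2=float(chi2[best]),
        approx_p=float(pvals[best]),
        min_group_size=min_group_size,
    )


def exact_logrank_p(
    times: np.ndarray,
    events: np.ndarray,
    low_mask: np.ndarray,
    max_exhaustive: int = 10**7,
    n_montecarlo: int = 10**6,
    seed: int = 0,
    chunk: int = 20000,
) -> tuple[float, str]:
    """Exact permutational log-rank p-value for a two-group split.

    Exhaustive mode enumerates all C(n, n_low) assignments of the group
    labels when that count is at most ``max_exhaustive`` and reports the
    fraction whose statistic is >= the observed one. Otherwise a seeded
    Monte-Carlo estimate over ``n_montecarlo`` random assignments is
    returned (add-one corrected). The mode string is "exhaustive" or
    "montecarlo".
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    low_mask = np.asarray(low_mask, dtype=bool)
    n = len(times)
    k = int(low_mask.sum())
    obs = _logrank_chi2_many(times, events, low_mask[np.newaxis, :])[0]
    tol = 1e-12

    n_total = math.comb(n, k)
    if n_total <= max_exhaustive:
        count = 0
        buf = []
        for combo in itertools.combinations(range(n), k):
            row = np.zeros(n, dtype=bool)
            row[list(combo)] = True
            buf.append(row)
            if len(buf) == chunk:
                stats_ = _logrank_chi2_many(times, events, np.array(buf))
                count += int((stats_ >= obs - tol).sum())
                buf = []
        if buf:
            stats_ = _logrank_chi2_many(times, events, np.array(buf))
            count += int((stats_ >= obs - tol).sum())
        return count / n_total, "exhaustive"

    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_montecarlo:
        size = min(chunk, n_montecarlo - done)
        picks = np.argsort(rng.random((size, n)), axis=1)[:, :k]
        z = np.zeros((size, n), dtype=bool)
        np.put_along_axis(z, picks, True, axis=1)
        stats_ = _logrank_chi2_many(times, events, z)
        count += int((stats_ >= obs - tol).sum())
        done += size
    return (1 + count) / (1 + n_montecarlo), "montecarlo"


# ---------------------------------------------------------------------------
# FDR estimation
# ---------------------------------------------------------------------------

def estimate_fdr(pvalues) -> tuple[np.ndarray, np.ndarray]:
    """Conservative and liberal q-values for a vector of p-values.

    Conservative q-values are Benjamini-Hochberg step-up. Liberal
    q-values follow Storey: the null proportion pi0 is estimated as
    #{p > 0.5} / (0.5 m) (capped at 1) and scales the BH values. Both
    are monotone non-decreasing in p; the liberal estimate is <= the
    conservative one whenever pi0 < 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    lam = 0.5
    pi0 = min(1.0, float((p > lam).mean() / (1 - lam)))
    if pi0 == 0.0:
        pi0 = 1.0 / len(p)  # guard: never claim a zero null proportion
    storey = np.minimum(pi0 * bh, 1.0)
    return bh, storey


# ---------------------------------------------------------------------------
# random-gene baseline
# ---------------------------------------------------------------------------

def random_gene_baseline(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    set_size: int,
    n_draws: int,
    alpha: float = 0.05,
    min_group_size: int = 8,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """How many random genes would pass the survival screen by chance.

    Repeats ``n_draws`` times: draw ``set_size`` genes uniformly without
    replacement, run the constrained optimal-cutoff log-rank split on
    each, and count genes with approximate p < alpha. Returns the mean
    count and a normal-approximation 95% confidence interval of the
    mean.
    """
    universe = list(expression.index)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_draws, dtype=float)
    for i in range(n_draws):
        genes = rng.choice(universe, size=set_size, replace=False)
        c = 0
        for g in genes:
            split = optimal_cutoff_logrank(
                expression.loc[g, clinical.index],
                clinical,
                min_group_size=min_group_size,
                gene_id=str(g),
            )
            if split.feasible and split.approx_p < alpha:
                c += 1
        counts[i] = c
    mean = float(counts.mean())
    if n_draws > 1:
        half = 1.96 * float(counts.std(ddof=1)) / math.sqrt(n_draws)
    else:
        half = float("nan")
    return mean, (mean - half, mean + half)


# ---------------------------------------------------------------------------
# Cox proportional-hazards with covariates
# ---------------------------------------------------------------------------

def cox_covariate_model(
    clinical: pd.DataFrame,
    group_flag: pd.Series,
    covariates: tuple[str, ...] = ("age", "t_stage", "gleason", "psa"),
) -> dict[str, pd.DataFrame]:
    """Cox PH fits with and without the candidate group assignment.

    ``group_flag`` is a boolean per-patient series (e.g. high-expression
    group from a survival split). Returns a dict with keys
    ``covariates_only`` and ``with_group``, each a coefficient table
    (coef, p per term) from a partial-likelihood fit.
    """
    from lifelines import CoxPHFitter

    events = clinical["event"].astype(bool)
    if int(events.sum()) == 0:
        raise ValueError("cohort has no observed events")
    covariates = tuple(covariates)
    n_terms = len(covariates) + 1
    if int(events.sum()) < n_terms:
        raise ValueError("fewer events than model terms")
    base = clinical.loc[:, ["months", "event"] + list(covariates)].copy()
    base["event"] = base["event"].astype(int)

    def _fit(df: pd.DataFrame) -> pd.DataFrame:
        cph = CoxPHFitter(penalizer=0.0)
        cph.fit(df, duration_col="months", event_col="event")
        return cph.summary.loc[:, ["coef", "se(coef)", "z", "p"]]

    out = {"covariates_only": _fit(base)}
    with_group = base.copy()
    with_group["group"] = group_flag.reindex(clinical.index).astype(float)
    out["with_group"] = _fit(with_group)
    return out


# ---------------------------------------------------------------------------
# marker-table assembly
# ---------------------------------------------------------------------------

def evaluate_marker_candidates(
    candidates: pd.DataFrame,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    min_group_size: int = 8,
    alpha: float = 0.05,
    exact: bool = True,
    max_exhaustive: int = 10**6,
    n_montecarlo: int = 10**5,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the constrained optimal-cutoff screen on a candidate table.

    ``clinical`` should already be restricted to the cohort of interest
    (typically the irradiated patients). Returns one row per candidate
    with the split, asymptotic and (optionally) exact p-values, and
    conservative/liberal q-values over the screened set; ``selected``
    marks candidates with a feasible split and approximate p < alpha.
    """
    rows = []
    for i, rec in enumerate(candidates.itertuples(index=False)):
        gene = rec.gene_id
        if gene not in expression.index:
            logger.warning("candidate %s missing from expression; skipped", gene)
            continue
        expr = expression.loc[gene, clinical.index]
        split = optimal_cutoff_logrank(
            expr, clinical, min_group_size=min_group_size, gene_id=gene
        )
        row = {
            "gene_id": gene,
            "direction": getattr(rec, "direction", ""),
            "feasible": split.feasible,
            "cutoff": split.cutoff,
            "n_low": len(split.low_patients),
            "n_high": len(split.high_patients),
            "approx_p": split.approx_p,
            "exact_p": float("nan"),
            "exact_mode": "",
        }
        if split.feasible and exact:
            low_mask = np.array(
                [p in set(split.low_patients) for p in clinical.index]
            )
            times = clinical["months"].to_numpy(dtype=float)
            events = clinical["event"].to_numpy(dtype=bool)
            p_exact, mode = exact_logrank_p(
                times, events, low_mask,
                max_exhaustive=max_exhaustive,
                n_montecarlo=n_montecarlo,
                seed=seed + i,
            )
            row["exact_p"] = p_exact
            row["exact_mode"] = mode
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        feas = table["feasible"] & table["approx_p"].notna()
        q_cons = np.full(len(table), np.nan)
        q_lib = np.full(len(table), np.nan)
        if feas.any():
            bh, storey = estimate_fdr(table.loc[feas, "approx_p"].to_numpy())
            q_cons[feas.to_numpy()] = bh
            q_lib[feas.to_numpy()] = storey
        table["q_conservative"] = q_cons
        table["q_liberal"] = q_lib
        table["selected"] = feas & (table["approx_p"] < alpha)
    return table
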