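"""Synthetic ground truth for the radioresistance driver pipeline.

The generator emulates the statistical structure the analysis assumes:

* a sparse signed gene regulatory network W (regulator -> target linear
  coefficients) whose spectral radius is rescaled below 1 so the
  simultaneous linear system is solvable;
* gene dosage: each gene's expression responds to its own copy number
  with coefficient beta, and perturbations spread through W, i.e.
  cohort expression solves x = (I - W^T)^-1 (beta * c + eps);
* a resistant/sensitive cell-line pair whose contrast carries broad and
  focal copy-number segments, with planted driver genes inside focal
  alterations and marker genes downstream of the drivers;
* proportional-hazards relapse times whose log-hazard is linear in the
  (standardized) driver expression, with administrative censoring.

Everything is seeded; fixing the seed reproduces all outputs
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from radnet.annotation import GeneAnnotation
from radnet.io import SEG_COLUMNS

CELLLINE_SAMPLE = "resistant_vs_sensitive"

#: strong-signal study conditions for recovery benchmarks: tighter coupling
#: than the moderate defaults and more exogenous copy-number variation, so
#: regulatory effects sit well above the noise floor while differential
#: expression stays confined to a minority of genes (radius much above 0.6
#: would spread alteration effects over most of the genome, which breaks the
#: quantile-normalization assumption that arrays share one distribution)
STRONG_SIGNAL = {
    "spectral_radius": 0.7,
    "cna_sd": 0.5,
    "segment_prob": 0.4,
}


@dataclass
class GroundTruthNetwork:
    """Generative truth: annotation, signed coefficient matrix, dosage terms."""

    annotation: GeneAnnotation
    edge_weights: np.ndarray = field(repr=False)  # W[i, j]: gene i -> gene j
    cn_coefficients: np.ndarray = field(repr=False)
    noise_sd: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = self.annotation.n_genes
        if self.edge_weights.shape != (n, n):
            raise ValueError("edge weight matrix shape mismatch")
        if np.diag(self.edge_weights).any():
            raise ValueError("diagonal of W must be zero")
        if self.spectral_radius >= 1:
            raise ValueError("spectral radius of W must be < 1")
        if (self.noise_sd <= 0).any():
            raise ValueError("noise sd must be positive")

    @property
    def genes(self) -> list[str]:
        return self.annotation.gene_ids

    @property
    def n_genes(self) -> int:
        return self.annotation.n_genes

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.edge_weights))))

    @property
    def density(self) -> float:
        n = self.n_genes
        return float((self.edge_weights != 0).sum() / (n * (n - 1)))

    def true_edges(self) -> set[tuple[str, str, int]]:
        """(regulator, target, sign) triples of the planted network."""
        genes = self.genes
        rows, cols = np.nonzero(self.edge_weights)
        return {
            (genes[i], genes[j], int(np.sign(self.edge_weights[i, j])))
            for i, j in zip(rows, cols)
        }


@dataclass
class SyntheticTruthRecord:
    """Planted drivers, markers and hazard links for one simulation."""

    drivers: dict[str, str]  # gene -> direction ("up"/"down")
    markers: set[str]
    hazard_coefficients: dict[str, float]
    seed: int
    edges: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.drivers) & set(self.markers):
            raise ValueError("drivers and markers must be disjoint")
        if set(self.hazard_coefficients) != set(self.drivers):
            raise ValueError("hazard coefficients must cover exactly the drivers")


def _place_genes(
    n_genes: int, n_chromosomes: int, rng: np.random.Generator
) -> GeneAnnotation:
    """Distribute genes over chromosomes with strictly increasing coordinates."""
    per_chrom = np.full(n_chromosomes, n_genes // n_chromosomes)
    per_chrom[: n_genes % n_chromosomes] += 1
    rows = []
    g = 0
    for c, count in enumerate(per_chrom, start=1):
        pos = 10_000
        for _ in range(count):
            length = int(rng.integers(5_000, 100_000))
            gap = int(rng.integers(10_000, 200_000))
            rows.append((f"G{g:04d}", f"chr{c}", pos, pos + length))
            pos += length + gap
            g += 1
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return GeneAnnotation.from_frame(frame)


def generate_ground_truth_network(
    n_genes: int,
    n_chromosomes: int = 10,
    density: float = 0.02,
    frac_inhibitor: float = 0.03,
    seed: int = 0,
    spectral_radius: float = 0.5,
    weight_range: tuple[float, float] = (0.4, 0.9),
    noise_sd: float = 0.25,
    cn_coefficient_range: tuple[float, float] = (0.8, 1.2),
) -> GroundTruthNetwork:
    """Generate a sparse signed ground-truth network.

    ``density`` is the fraction of the n(n-1) possible directed edges
    that are nonzero; ``frac_inhibitor`` of them carry negative weights.
    W is rescaled to the requested spectral radius (< 1) so cohort
    expression can be solved from the simultaneous linear model.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not 0 < density < 0.2:
        raise ValueError("density must lie in (0, 0.2)")
    if not 0 <= frac_inhibitor <= 1:
        raise ValueError("frac_inhibitor must lie in [0, 1]")
    if not 0 < spectral_radius < 1:
        raise ValueError("spectral radius target must lie in (0, 1)")
    n_possible = n_genes * (n_genes - 1)
    n_edges = int(round(density * n_possible))
    if n_edges < 1:
        raise ValueError("density infeasible: yields zero edges")

    rng = np.random.default_rng(seed)
    annotation = _place_genes(n_genes, n_chromosomes, rng)

    flat = rng.choice(n_possible, size=n_edges, replace=False)
    # map flat off-diagonal index -> (row, col) skipping the diagonal
    rows = flat // (n_genes - 1)
    cols = flat % (n_genes - 1)
    cols = cols + (cols >= rows)
    w = np.zeros((n_genes, n_genes))
    magnitudes = rng.uniform(*weight_range, size=n_edges)
    signs = np.where(rng.random(n_edges) < frac_inhibitor, -1.0, 1.0)
    w[rows, cols] = magnitudes * signs

    radius = float(np.max(np.abs(np.linalg.eigvals(w))))
    if radius > 0:
        w *= spectral_radius / radius
    return GroundTruthNetwork(
        annotation=annotation,
        edge_weights=w,
        cn_coefficients=rng.uniform(*cn_coefficient_range, size=n_genes),
        noise_sd=np.full(n_genes, float(noise_sd)),
    )


def make_truth_record(
    truth: GroundTruthNetwork,
    n_drivers: int = 4,
    n_markers: int = 4,
    hazard_scale: float = 1.5,
    frac_down: float = 0.5,
    seed: int = 0,
) -> SyntheticTruthRecord:
    """Pick planted drivers and downstream markers from the truth network.

    Drivers are chosen among the genes with the largest out-degree so
    their alterations actually propagate; markers are drawn from the
    union of the drivers' direct targets (excluding drivers). Hazard
    coefficients are +hazard_scale for up-drivers and -hazard_scale for
    down-drivers, so the planted direction matches the consistency
    expectations (high expression of an up-driver means faster relapse).
    """
    rng = np.random.default_rng(seed)
    w = truth.edge_weights
    genes = np.array(truth.genes)
    out_deg = (w != 0).sum(axis=1)
    in_deg = (w != 0).sum(axis=0)
    # prefer upstream hubs: low in-degree first (their planted expression
    # shift cannot be cancelled by incoming regulation), then high out-degree
    order = np.lexsort((-out_deg, in_deg))
    eligible = order[out_deg[order] > 0]
    if len(eligible) < n_drivers:
        raise ValueError("not enough connected genes to plant drivers")
    driver_idx = eligible[:n_drivers]
    n_down = int(round(frac_down * n_drivers))
    directions = np.array(["down"] * n_down + ["up"] * (n_drivers - n_down))
    rng.shuffle(directions)
    drivers = {genes[i]: d for i, d in zip(driver_idx, directions)}

    target_pool = set()
    for i in driver_idx:
        target_pool.update(np.flatnonzero(w[i] != 0))
    target_pool -= set(driver_idx)
    if len(target_pool) < n_markers:
        raise ValueError("not enough downstream genes to pick markers")
    # every driver gets at least one of its direct targets as a marker
    # (round-robin while markers remain), then fill from the pooled targets
    marker_idx: set[int] = set()
    for i in driver_idx:
        if len(marker_idx) >= n_markers:
            break
        own = [
            j
            for j in np.flatnonzero(w[i] != 0)
            if j not in marker_idx and j in target_pool
        ]
        if own:
            marker_idx.add(int(rng.choice(own)))
    remaining = sorted(target_pool - marker_idx)
    if len(marker_idx) < n_markers:
        extra = rng.choice(
            remaining, size=n_markers - len(marker_idx), replace=False
        )
        marker_idx.update(int(j) for j in extra)
    markers = set(genes[sorted(marker_idx)])
    hazards = {
        g: (hazard_scale if d == "up" else -hazard_scale)
        for g, d in drivers.items()
    }
    edges = [[r, t, s] for r, t, s in sorted(truth.true_edges())]
    return SyntheticTruthRecord(
        drivers=drivers,
        markers=markers,
        hazard_coefficients=hazards,
        seed=seed,
        edges=edges,
    )


def _solve_expression(
    truth: GroundTruthNetwork, cn: np.ndarray, eps: np.ndarray
) -> np.ndarray:
    """Solve x = (I - W^T)^-1 (beta * c + eps), column per sample."""
    n = truth.n_genes
    a = np.eye(n) - truth.edge_weights.T
    rhs = truth.cn_coefficients[:, np.newaxis] * cn + eps
    lu = lu_factor(a)
    return lu_solve(lu, rhs)


def simulate_patient_cohort(
    truth: GroundTruthNetwork,
    n_patients: int = 300,
    cna_sd: float = 0.3,
    segment_prob: float = 0.3,
    baseline: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a patient cohort from the truth network.

    Per patient, each chromosome carries with probability
    ``segment_prob`` one altered segment (a random contiguous gene
    block) whose log2-ratio shift is N(0, cna_sd^2); other genes have
    copy-number 0. Expression solves the simultaneous linear model with
    per-gene Gaussian noise, on top of a constant baseline intensity.

    Returns (expression genes x patients, copy-number genes x patients,
    clinical skeleton with covariates but no survival columns).
    """
    if truth.spectral_radius >= 1:
        raise ValueError("spectral radius of W must be < 1")
    rng = np.random.default_rng(seed)
    n = truth.n_genes
    ann = truth.annotation.table
    chrom_blocks = [
        (g["order_index"].min(), g["order_index"].max())
        for _, g in ann.groupby("chrom", sort=False)
    ]
    cn = np.zeros((n, n_patients))
    for p in range(n_patients):
        for lo, hi in chrom_blocks:
            if rng.random() >= segment_prob:
                continue
            a = int(rng.integers(lo, hi + 1))
            b = int(rng.integers(a, hi + 1))
            cn[a : b + 1, p] = rng.normal(0.0, cna_sd)
    eps = rng.normal(0.0, truth.noise_sd[:, np.newaxis], size=(n, n_patients))
    x = baseline + _solve_expression(truth, cn, eps)

    patients = [f"P{p:04d}" for p in range(n_patients)]
    genes = truth.genes
    expr = pd.DataFrame(x, index=genes, columns=patients)
    cn_df = pd.DataFrame(cn, index=genes, columns=patients)
    clinical = pd.DataFrame(
        {
            "age": np.round(rng.normal(65, 8, size=n_patients), 1),
            "t_stage": rng.integers(1, 5, size=n_patients),
            "gleason": rng.integers(6, 11, size=n_patients),
            "psa": np.round(rng.lognormal(2.0, 0.6, size=n_patients), 2),
        },
        index=pd.Index(patients, name="patient_id"),
    )
    return expr, cn_df, clinical


def simulate_cellline_pair(
    truth: GroundTruthNetwork,
    record: SyntheticTruthRecord,
    broad_frac: float = 0.15,
    focal_count: int = 4,
    focal_magnitude: float = 0.5,
    broad_magnitude: float = 0.3,
    n_replicates: int = 3,
    replicate_sd: float = 0.1,
    baseline: float = 8.0,
    seed: int = 0,
) -> dict:
    """Simulate the resistant-vs-sensitive cell-line contrast.

    The copy-number contrast carries one focal alteration per planted
    driver (signed by the driver's direction), ``focal_count``
    additional decoy focal alterations on non-driver genes, and broad
    altered segments covering about ``broad_frac`` of the remaining
    genome. Expression shifts are the dosage effects of the altered
    genes propagated through the network; each condition gets
    ``n_replicates`` replicate arrays with Gaussian replicate noise.

    Returns a dict with keys ``segments`` (SEG frame, 0-based half-open,
    sample "resistant_vs_sensitive"), ``expression_resistant``,
    ``expression_sensitive`` (genes x replicates), ``gene_cn`` (planted
    per-gene log2-ratios) and ``altered_genes``.
    """
    if not 0 <= broad_frac < 1:
        raise ValueError("broad_frac must lie in [0, 1)")
    if focal_count > truth.n_genes:
        raise ValueError("focal_count exceeds the gene count")
    rng = np.random.default_rng(seed)
    ann = truth.annotation.table
    n = truth.n_genes
    gene_index = {g: i for i, g in enumerate(truth.genes)}

    cn = np.zeros(n)
    taken = np.zeros(n, dtype=bool)

    def _magnitude(center: float) -> float:
        # continuous spread of segment magnitudes, as in real contrasts
        return float(rng.uniform(center - 0.1, center + 0.1))

    # focal alterations over each planted driver, signed by direction
    for gene, direction in sorted(record.drivers.items()):
        i = gene_index[gene]
        sign = 1.0 if direction == "up" else -1.0
        cn[i] = sign * _magnitude(focal_magnitude)
        taken[i] = True

    # decoy focal alterations on non-driver, non-marker genes
    protected = set(record.drivers) | set(record.markers)
    free = [i for i in range(n) if not taken[i] and truth.genes[i] not in protected]
    decoys = rng.choice(free, size=min(focal_count, len(free)), replace=False)
    for i in decoys:
        cn[i] = float(rng.choice([-1.0, 1.0])) * _magnitude(focal_magnitude)
        taken[i] = True

    # broad segments on contiguous gene blocks of the remaining genome
    if broad_frac > 0:
        target = int(broad_frac * n)
        placed = 0
        chrom_blocks = [
            (g["order_index"].min(), g["order_index"].max())
            for _, g in ann.groupby("chrom", sort=False)
        ]
        attempts = 0
        while placed < target and attempts < 100:
            attempts += 1
            lo, hi = chrom_blocks[int(rng.integers(0, len(chrom_blocks)))]
            span = int(rng.integers(3, max(4, (hi - lo) // 2 + 1)))
            a = int(rng.integers(lo, max(lo + 1, hi - span + 1)))
            block = np.arange(a, min(a + span, hi + 1))
            block = block[~taken[block]]
            # keep markers copy-number neutral so DE markers are network-driven
            block = np.array(
                [i for i in block if truth.genes[i] not in protected], dtype=int
            )
            if not len(block):
                continue
            sign = float(rng.choice([-1.0, 1.0]))
            cn[block] = sign * _magnitude(broad_magnitude)
            taken[block] = True
            placed += len(block)

    # SEG records: per chromosome, runs of constant log2-ratio
    ordered = ann.sort_values("order_index")
    seg_rows = []
    for chrom, g in ordered.groupby("chrom", sort=False):
        idx = g["order_index"].to_numpy()
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        vals = cn[idx]
        run_start = 0
        for k in range(1, len(idx) + 1):
            if k == len(idx) or vals[k] != vals[run_start]:
                seg_start = int(starts[run_start]) - 1000
                seg_end = int(ends[k - 1]) + 1000
                seg_rows.append(
                    (
                        CELLLINE_SAMPLE,
                        chrom,
                        max(seg_start, 0),
                        seg_end,
                        k - run_start,
                        float(vals[run_start]),
                    )
                )
                run_start = k
    segments = pd.DataFrame(seg_rows, columns=SEG_COLUMNS)

    # expression: dosage effects propagated through the network
    shift = _solve_expression(truth, cn[:, np.newaxis], np.zeros((n, 1)))[:, 0]
    base = baseline + rng.normal(0.0, 1.0, size=n)
    res_cols = [f"resistant_{r + 1}" for r in range(n_replicates)]
    sens_cols = [f"sensitive_{r + 1}" for r in range(n_replicates)]
    res = (
        base[:, np.newaxis]
        + shift[:, np.newaxis]
        + rng.normal(0.0, replicate_sd, size=(n, n_replicates))
    )
    sens = base[:, np.newaxis] + rng.normal(
        0.0, replicate_sd, size=(n, n_replicates)
    )
    genes = truth.genes
    return {
        "segments": segments,
        "expression_resistant": pd.DataFrame(res, index=genes, columns=res_cols),
        "expression_sensitive": pd.DataFrame(sens, index=genes, columns=sens_cols),
        "gene_cn": pd.Series(cn, index=genes, name="log2_ratio"),
        "altered_genes": {genes[i] for i in np.flatnonzero(cn != 0)},
    }


def simulate_relapse_times(
    expression: pd.DataFrame,
    record: SyntheticTruthRecord,
    clinical_skeleton: pd.DataFrame,
    baseline_hazard: float = 0.02,
    censor_frac: float = 0.4,
    n_irradiated: int | None = None,
    radiation_frac: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw relapse times whose log-hazard is linear in driver expression.

    Event times are exponential with rate
    baseline_hazard * exp(sum_d hc_d * z_d) where z_d is the driver's
    expression standardized across patients. Censoring is
    administrative at the empirical (1 - censor_frac) quantile of the
    drawn times. The radiation flag marks a random subset of
    ``n_irradiated`` patients (default: round(radiation_frac * n)).
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must lie in [0, 1)")
    missing = [g for g in record.drivers if g not in expression.index]
    if missing:
        raise ValueError(f"drivers missing from expression: {missing}")
    rng = np.random.default_rng(seed)
    patients = expression.columns
    n = len(patients)
    log_hr = np.zeros(n)
    for gene, hc in sorted(record.hazard_coefficients.items()):
        x = expression.loc[gene].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        log_hr += hc * z
    rate = baseline_hazard * np.exp(log_hr)
    t = rng.exponential(1.0 / rate)
    if censor_frac > 0:
        c_admin = float(np.quantile(t, 1 - censor_frac))
    else:
        c_admin = float(np.max(t))
    event = t <= c_admin
    months = np.minimum(t, c_admin)

    if n_irradiated is None:
        n_irradiated = int(round(radiation_frac * n))
    irradiated = np.zeros(n, dtype=bool)
    irradiated[rng.choice(n, size=n_irradiated, replace=False)] = True

    clinical = clinical_skeleton.loc[patients].copy()
    clinical["months"] = np.round(months, 3)
    clinical["event"] = event
    clinical["irradiated"] = irradiated
    return clinical


def edge_recovery(
    truth: GroundTruthNetwork, network, undirected: bool = True
) -> dict[str, float]:
    """Recovery of the planted edges by an inferred network.

    Per-gene sparse regression identifies the conditional-dependence
    skeleton; the direction of an edge is not identifiable from
    observational data, so by default precision and recall are measured
    on the undirected skeleton. ``sign_agreement`` is the fraction of
    recovered true *directed* edges whose coefficient sign matches the
    planted sign.
    """
    true_dir = {(r, t): s for r, t, s in truth.true_edges()}
    true_und = {frozenset(e) for e in true_dir}
    found = list(zip(network.edges["regulator"], network.edges["target"]))
    coefs = network.edges["coefficient"].to_numpy()
    if not found:
        return {"precision": 0.0, "recall": 0.0, "sign_agreement": float("nan")}
    if undirected:
        tp = sum(1 for e in found if frozenset(e) in true_und)
        recovered = {frozenset(e) for e in found if frozenset(e) in true_und}
        precision = tp / len(found)
        recall = len(recovered) / len(true_und)
    else:
        tp = sum(1 for e in found if e in true_dir)
        precision = tp / len(found)
        recall = tp / len(true_dir)
    n_true_dir = 0
    n_sign_ok = 0
    for (r, t), c in zip(found, coefs):
        if (r, t) in true_dir:
            n_true_dir += 1
            n_sign_ok += int(np.sign(c) == true_dir[(r, t)])
    sign_agreement = n_sign_ok / n_true_dir if n_true_dir else float("nan")
    return {
        "precision": float(precision),
        "recall": float(recall),
        "sign_agreement": float(sign_agreement),
    }


def write_synthetic_bundle(
    out_dir,
    n_genes: int = 300,
    n_chromosomes: int = 10,
    n_patients: int = 400,
    n_validation: int = 100,
    density: float = 0.006,
    n_drivers: int = 4,
    n_markers: int = 4,
    seed: int = 0,
    strong_signal: bool = True,
):
    """Write a complete synthetic input bundle for the pipeline.

    Generates the truth network, planted drivers/markers, the cell-line
    pair, the patient cohort and relapse times, plus an independent
    validation cohort (a fresh draw from the same truth, standing in for
    the external cell-line panel used to score predictive power), and
    writes every interchange file (annotation, SEG, replicate
    expression, cohort matrices, clinical table, truth JSON) under
    ``out_dir``. Returns (truth, record, paths dict). ``strong_signal``
    applies the :data:`STRONG_SIGNAL` study conditions.

    The default density (0.6%, about 1.8 regulators per gene) keeps the
    planted coefficients strong: with the spectral radius fixed below 1,
    per-edge weight scales inversely with connectivity, and denser
    desk-scale networks would push every edge under the detection floor.
    """
    from pathlib import Path

    from radnet import io as rio
    from radnet.annotation import write_annotation

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net_kwargs = {}
    cohort_kwargs = {}
    if strong_signal:
        net_kwargs["spectral_radius"] = STRONG_SIGNAL["spectral_radius"]
        cohort_kwargs["cna_sd"] = STRONG_SIGNAL["cna_sd"]
        cohort_kwargs["segment_prob"] = STRONG_SIGNAL["segment_prob"]
    truth = generate_ground_truth_network(
        n_genes=n_genes,
        n_chromosomes=n_chromosomes,
        density=density,
        seed=seed,
        **net_kwargs,
    )
    record = make_truth_record(
        truth, n_drivers=n_drivers, n_markers=n_markers, seed=seed
    )
    pair = simulate_cellline_pair(truth, record, seed=seed + 1)
    expr, cn, skeleton = simulate_patient_cohort(
        truth, n_patients=n_patients, seed=seed + 2, **cohort_kwargs
    )
    clinical = simulate_relapse_times(expr, record, skeleton, seed=seed + 3)
    val_expr, val_cn, _ = simulate_patient_cohort(
        truth, n_patients=n_validation, seed=seed + 4, **cohort_kwargs
    )

    paths = {
        "annotation": out / "annotation.tsv",
        "seg": out / "cellline.seg",
        "expression_resistant": out / "expr_resistant.tsv",
        "expression_sensitive": out / "expr_sensitive.tsv",
        "cohort_expression": out / "cohort_expression.tsv",
        "cohort_cn": out / "cohort_copy_number.tsv",
        "validation_expression": out / "validation_expression.tsv",
        "validation_cn": out / "validation_copy_number.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
    }
    write_annotation(truth.annotation, paths["annotation"])
    rio.write_seg(pair["segments"], paths["seg"])
    rio.write_expression(pair["expression_resistant"], paths["expression_resistant"])
    rio.write_expression(pair["expression_sensitive"], paths["expression_sensitive"])
    rio.write_expression(expr, paths["cohort_expression"])
    rio.write_expression(cn, paths["cohort_cn"])
    rio.write_expression(val_expr, paths["validation_expression"])
    rio.write_expression(val_cn, paths["validation_cn"])
    rio.write_clinical(clinical, paths["clinical"])
    rio.write_truth_json(record, paths["truth"])
    return truth, record, paths
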