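"""Readers and writers for the interchange formats.

SEG files are tab-separated with header
``sample  chrom  start  end  n_probes  log2_ratio`` and 1-based
inclusive coordinates, as produced by segmentation tools such as
DNAcopy. Internally segments are carried as a DataFrame with 0-based
half-open coordinates; conversion happens only here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_probes", "log2_ratio"]


class SegFormatError(ValueError):
    """Raised for malformed SEG content, with the offending line number."""


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file into a segment frame (0-based half-open internally).

    Malformed lines (wrong field count, non-numeric coordinates,
    end < start) raise :class:`SegFormatError` naming the line.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            return pd.DataFrame(columns=SEG_COLUMNS)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise SegFormatError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(fields)}"
                )
            sample, chrom, start, end, n_probes, ratio = fields
            try:
                start_i, end_i = int(start), int(end)
                n_probes_i = int(n_probes)
                ratio_f = float(ratio)
            except ValueError as exc:
                raise SegFormatError(f"{path}: line {lineno}: {exc}") from exc
            if end_i < start_i:
                raise SegFormatError(
                    f"{path}: line {lineno}: end {end_i} < start {start_i}"
                )
            rows.append((sample, chrom, start_i - 1, end_i, n_probes_i, ratio_f))
    return pd.DataFrame(rows, columns=SEG_COLUMNS)


def write_seg(segments: pd.DataFrame, path) -> None:
    """Write a segment frame as SEG (converting back to 1-based inclusive)."""
    out = segments.loc[:, SEG_COLUMNS].copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read an expression TSV: gene rows, sample columns, header row."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV (patient_id index, months/event/irradiated...)."""
    t = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("event", "irradiated"):
        if col in t.columns:
            t[col] = t[col].astype(bool)
    return t


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="patient_id")


def write_network(network, path) -> None:
    """Write a regulatory network as an edge-list TSV.

    Columns: regulator, target, coefficient, sign, p_value; decimal text
    at full (repr) precision so a round-trip is exact.
    """
    edges = network.edges
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tcoefficient\tsign\tp_value\n")
        for row in edges.itertuples(index=False):
            fh.write(
                f"{row.regulator}\t{row.target}\t{row.coefficient!r}\t"
                f"{row.sign}\t{row.p_value!r}\n"
            )


def read_network(path, genes=None):
    """Read an edge-list TSV back into a :class:`RegulatoryNetwork`.

    Validates that the sign column is consistent with the coefficient
    sign. ``genes`` optionally fixes the gene universe; otherwise it is
    the union of regulators and targets.
    """
    from radnet.network import RegulatoryNetwork

    edges = pd.read_csv(
        path,
        sep="\t",
        dtype={"regulator": str, "target": str, "sign": str},
    )
    if len(edges):
        expected = np.where(edges["coefficient"] > 0, "activator", "inhibitor")
        bad = edges.index[edges["sign"] != expected]
        if len(bad):
            raise ValueError(
                f"{path}: sign column inconsistent with coefficient sign "
                f"at rows {list(bad[:5])}"
            )
    if genes is None:
        genes = sorted(set(edges["regulator"]) | set(edges["target"]))
    return RegulatoryNetwork(genes=list(genes), edges=edges, models={})


def write_model_store(models: dict, path) -> None:
    """Serialize per-gene linear models as JSON.

    ``models`` maps target gene id -> GeneModel; the JSON keeps the
    intercept, copy-number term and the (regulator, coefficient,
    p-value) triples at full float precision.
    """
    payload = {
        target: {
            "intercept": m.intercept,
            "cn_coefficient": m.cn_coefficient,
            "cn_p_value": m.cn_p_value,
            "cv_lambda": m.cv_lambda,
            "predictors": [[g, c, p] for g, c, p in m.predictors],
        }
        for target, m in models.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_model_store(path) -> dict:
    """Load a model-store JSON back into GeneModel objects."""
    from radnet.network import GeneModel

    payload = json.loads(Path(path).read_text())
    return {
        target: GeneModel(
            target=target,
            intercept=d["intercept"],
            cn_coefficient=d["cn_coefficient"],
            cn_p_value=d.get("cn_p_value", 1.0),
            cv_lambda=d.get("cv_lambda", float("nan")),
            predictors=[(g, c, p) for g, c, p in d["predictors"]],
        )
        for target, d in payload.items()
    }


def write_truth_json(record, path) -> None:
    """Serialize a synthetic truth record for test harnesses."""
    payload = {
        "drivers": dict(record.drivers),
        "markers": sorted(record.markers),
        "hazard_coefficients": dict(record.hazard_coefficients),
        "seed": record.seed,
        "edges": record.edges,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
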