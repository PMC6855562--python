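"""Shared fixtures: small synthetic objects generated at test time."""

import logging

import numpy as np
import pandas as pd
import pytest

from radnet.annotation import GeneAnnotation
from radnet.network import RegulatoryNetwork, SIGN_ACTIVATOR, SIGN_INHIBITOR
from radnet.synthetic import (
    GroundTruthNetwork,
    generate_ground_truth_network,
    make_truth_record,
    simulate_cellline_pair,
    simulate_patient_cohort,
)

logging.getLogger("hmmlearn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def truth100():
    """100-gene ground-truth network, moderate coupling."""
    return generate_ground_truth_network(
        n_genes=100, density=0.02, frac_inhibitor=0.1, seed=1
    )


@pytest.fixture(scope="session")
def record100(truth100):
    return make_truth_record(truth100, n_drivers=4, n_markers=4, seed=1)


@pytest.fixture(scope="session")
def cellline100(truth100, record100):
    return simulate_cellline_pair(truth100, record100, seed=2)


@pytest.fixture(scope="session")
def cohort100(truth100):
    """Small patient cohort (100 genes x 120 patients)."""
    return simulate_patient_cohort(truth100, n_patients=120, seed=3)


@pytest.fixture()
def toy_annotation():
    """Five genes on two chromosomes."""
    return GeneAnnotation.from_frame(
        pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d", "e"],
                "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
                "start": [100, 500, 900, 100, 400],
                "end": [200, 600, 1000, 250, 480],
            }
        )
    )


def make_network(edge_list, genes=None):
    """Build a RegulatoryNetwork from (regulator, target, coefficient) triples."""
    edges = pd.DataFrame(edge_list, columns=["regulator", "target", "coefficient"])
    edges["sign"] = np.where(
        edges["coefficient"] > 0, SIGN_ACTIVATOR, SIGN_INHIBITOR
    )
    edges["p_value"] = 0.0
    if genes is None:
        genes = sorted(set(edges["regulator"]) | set(edges["target"]))
    return RegulatoryNetwork(genes=list(genes), edges=edges)


@pytest.fixture()
def make_net():
    return make_network
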