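import numpy as np
import pandas as pd
import pytest

import epicoord as ec
from epicoord.datatypes import MethylationDataset, SimulationConfig


def make_annotation(n_probes, chromosome="chr1", start=10_000, spacing=100,
                    genes=None, flags=None):
    """Minimal valid annotation table on one chromosome."""
    ids = pd.Index([f"cg{i:05d}" for i in range(n_probes)], name="probe_id")
    return pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": start + np.arange(n_probes) * spacing,
            "island_relation": "open_sea",
            "gene": genes if genes is not None else "",
            "flags": flags if flags is not None else [frozenset()] * n_probes,
        },
        index=ids,
    )


def make_dataset(values, groups, annotation=None, scale="M"):
    """Wrap a raw array into a MethylationDataset."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    ann = annotation if annotation is not None else make_annotation(n_probes)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    return MethylationDataset(
        values=pd.DataFrame(values, index=ann.index[:n_probes], columns=samples),
        group=pd.Series(list(groups), index=samples),
        annotation=ann,
        scale=scale,
    )


def null_dataset(rng, n_probes=100, n_case=10, n_control=10, annotation=None):
    vals = rng.normal(size=(n_probes, n_case + n_control))
    return make_dataset(vals, ["case"] * n_case + ["control"] * n_control,
                        annotation=annotation)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated methylome with ground truth, shared across tests."""
    cfg = SimulationConfig(
        seed=42, n_probes=800, n_cases=25, n_controls=40, n_dmps=80,
        n_coordinated_dmps=40, n_hyperedge_cpgs=150,
    )
    annotation = ec.generate_probe_annotation(cfg)
    dataset, truth = ec.simulate_methylome(annotation, cfg)
    return cfg, annotation, dataset, truth


@pytest.fixture(scope="session")
def small_sim_zscored(small_sim):
    cfg, annotation, dataset, truth = small_sim
    z, _ = ec.zscore_normalize(ec.beta_to_m(dataset))
    return cfg, annotation, z, truth
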