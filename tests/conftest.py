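import numpy as np
import pandas as pd
import pytest

import coresponse as cr


@pytest.fixture()
def toy_table() -> cr.OtuTable:
    """2 OTUs x 2 samples counts table."""
    frame = pd.DataFrame([[3.0, 0.0], [1.0, 2.0]],
                         index=["otuA", "otuB"], columns=["s1", "s2"])
    return cr.OtuTable(frame, "counts")


@pytest.fixture()
def bs_design() -> cr.SampleDesign:
    """One compartment, 3 FI + 3 DI replicates."""
    rows = []
    for trt in ("FI", "DI"):
        for rep in (1, 2, 3):
            rows.append((f"BS-{trt}-{rep}", "BS", trt, rep))
    frame = pd.DataFrame([(c, t, r) for _, c, t, r in rows],
                         index=[s for s, *_ in rows],
                         columns=["compartment", "treatment", "replicate"])
    return cr.SampleDesign(frame)


@pytest.fixture(scope="session")
def planted_community():
    """Default-scale community with one positive and one negative module."""
    return cr.generate_paired_design(
        seed=11, module_spec=[cr.ModuleSpec(6, 1, 0.95), cr.ModuleSpec(6, -1, 0.95)]
    )


@pytest.fixture(scope="session")
def small_network():
    """A small inferred network shared by metrics/network tests."""
    table, taxonomy, design, truth = cr.generate_paired_design(
        n_bacteria=40, n_fungi=10, module_spec=[cr.ModuleSpec(4, 1, 1.0)],
        zero_rate=0.2, seed=5,
    )
    filtered = cr.filter_prevalence(cr.to_relative(table), design,
                                    "compartment", 4)["BS"]
    ratios = cr.compute_ratios(filtered, design, "BS")
    net = cr.build_network(ratios, taxonomy,
                           cr.NetworkConfig(seed=5, n_perm=200, n_boot=0))
    return net, table, taxonomy, design, truth, filtered
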