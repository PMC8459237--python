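import numpy as np
import pandas as pd
import pytest

import venttraits as vt


@pytest.fixture(scope="session")
def toy_specs():
    return [
        vt.TraitSpec("size", "ordered", ("small", "medium", "large")),
        vt.TraitSpec("feeding", "categorical", ("grazer", "predator")),
    ]


@pytest.fixture(scope="session")
def toy_traits(toy_specs):
    data = pd.DataFrame(
        {"size": ["small", "small", "large"],
         "feeding": ["grazer", "predator", "predator"]},
        index=["sp1", "sp2", "sp3"])
    return vt.TraitTable(data, toy_specs)


def make_abundance(times, counts, taxa, temps=None, epoch="post_eruption"):
    """Build an AbundanceTable from parallel lists (helper for many tests)."""
    temps = temps if temps is not None else [2.5] * len(times)
    records = [
        vt.SampleRecord(f"s{i}", "sandwich", epoch,
                        None if epoch == "pre_eruption" else float(t),
                        float(temps[i]))
        for i, t in enumerate(times)]
    frame = pd.DataFrame(counts, index=[r.sample_id for r in records],
                         columns=taxa)
    return vt.AbundanceTable(records, frame)


@pytest.fixture(scope="session")
def reference_fixture(tmp_path_factory):
    """The synthetic reconstruction of the study system, written as CSVs."""
    d = tmp_path_factory.mktemp("reffix")
    vt.write_reference_fixture(d, seed=1)
    return d


@pytest.fixture(scope="session")
def reference_run(reference_fixture, tmp_path_factory):
    """Full pipeline results on the reconstruction (shared across tests)."""
    out = tmp_path_factory.mktemp("refout")
    cfg = vt.RunConfig(
        definitions_file=str(reference_fixture / "trait_definitions.csv"),
        modalities_file=str(reference_fixture / "species_modalities.csv"),
        counts_file=str(reference_fixture / "counts.csv"),
        metadata_file=str(reference_fixture / "sample_metadata.csv"),
        out_dir=str(out), n_rand=199, seed=1)
    return vt.run_pipeline(cfg)
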