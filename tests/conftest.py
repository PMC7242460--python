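import numpy as np
import pandas as pd
import pytest

import refstab as rs


def make_aggregated(ct_array, genes, samples) -> rs.AggregatedCt:
    """Wrap a plain mean-Ct array as an AggregatedCt (zero replicate SD)."""
    ct_array = np.asarray(ct_array, dtype=float)
    idx = pd.Index(genes, name="gene")
    cols = pd.Index(samples, name="sample")
    return rs.AggregatedCt(
        genes=list(genes),
        samples=list(samples),
        mean_ct=pd.DataFrame(ct_array, index=idx, columns=cols),
        rep_sd=pd.DataFrame(0.0, index=idx, columns=cols),
    )


def random_quantities(rng, n_genes, n_samples, spread=1.0) -> rs.QuantityMatrix:
    """A random positive quantity matrix calibrated to max 1 per gene."""
    genes = [f"G{i:02d}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    ct = 20.0 + spread * rng.standard_normal((n_genes, n_samples))
    return rs.relative_quantities(make_aggregated(ct, genes, samples))


@pytest.fixture
def toy_qm() -> rs.QuantityMatrix:
    """Three genes: A and B perfectly co-regulated, C constant across samples."""
    ct = [[20.0, 21.0, 22.0], [25.0, 26.0, 27.0], [30.0, 30.0, 30.0]]
    return rs.relative_quantities(make_aggregated(ct, ["A", "B", "C"], ["s1", "s2", "s3"]))


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default synthetic study written to disk once per session."""
    spec = rs.default_spec(seed=1)
    table, meta, truth = rs.generate_dataset(spec)
    d = tmp_path_factory.mktemp("dataset")
    rs.write_ct_table(table, d / "ct.csv")
    meta.to_csv(d / "meta.csv", index=False)
    return {
        "dir": d,
        "ct_path": d / "ct.csv",
        "meta_path": d / "meta.csv",
        "table": table,
        "meta": meta,
        "truth": truth,
        "spec": spec,
    }
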