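import numpy as np
import pytest

from spadom import SyntheticSpec, generate, preprocess, build_knn_graph


@pytest.fixture(scope="session")
def small_slide():
    """A small preprocessed synthetic slide with its graph and SVG truth."""
    ds, truth = generate(SyntheticSpec(
        n_rows=12, n_cols=25, k_domains=3, n_marker_genes_per_domain=8,
        n_background_genes=60, seed=11,
    ))
    pp = preprocess(ds)
    g = build_knn_graph(pp.coords, k=6)
    return {"raw": ds, "ds": pp, "graph": g, "truth_svgs": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tabular_paths(tmp_path):
    """Hand-written 3-spot, 2-gene tabular fixture."""
    expr = tmp_path / "expr.csv"
    expr.write_text("spot_id,geneA,geneB\ns1,1.0,0.0\ns2,2.0,3.0\ns3,0.5,4.0\n")
    coords = tmp_path / "coords.csv"
    coords.write_text("spot_id,x,y\ns1,0.0,0.0\ns2,1.0,0.0\ns3,0.0,1.0\n")
    return {"expr": str(expr), "coords": str(coords)}
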