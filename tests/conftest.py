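import numpy as np
import pytest

import grefde
from grefde.rank_products import rank_product_analysis


@pytest.fixture(scope="session")
def sim_default():
    """Study-shaped default simulation, seed 1."""
    config = grefde.default_config(1)
    arrayset, truth = grefde.simulate_experiment(config)
    arrayset.spots["flag"] = grefde.assign_flags(
        arrayset.spots[arrayset.indicator_columns].to_numpy(bool)
    )
    return config, arrayset, truth


@pytest.fixture(scope="session")
def norm_default(sim_default):
    _, arrayset, truth = sim_default
    normalized = grefde.normalize_set(arrayset)
    return normalized, truth


@pytest.fixture(scope="session")
def weights_default(norm_default):
    normalized, _ = norm_default
    flags = normalized.spots["flag"].to_numpy(float)
    weight_table = grefde.estimate_spot_weights(normalized, flags)
    spot_w = weight_table.weight_of(flags)
    array_w = grefde.estimate_array_weights(normalized, spot_w)
    return weight_table, spot_w, array_w


@pytest.fixture(scope="session")
def fit_default(norm_default, weights_default):
    normalized, truth = norm_default
    _, spot_w, array_w = weights_default
    rho = grefde.estimate_duplicate_correlation(normalized).rho
    fit = grefde.fit_genewise(
        normalized, spot_weights=spot_w, array_weights=array_w.weights, rho=rho
    )
    ebayes = grefde.ebayes_moderate(fit)
    return fit, ebayes, rho


@pytest.fixture(scope="session")
def rp_default(norm_default):
    normalized, _ = norm_default
    return {
        c: rank_product_analysis(normalized, c, n_perm=300, seed=1000 + i)
        for i, c in enumerate(("BvA", "CvA"))
    }


def make_normalized(mg_cube, strains_per_array, duplicate_arity=2, flags=None):
    """Build a NormalizedSet directly from a (genes, arrays, dups) cube."""
    import pandas as pd
    from grefde.normalization import NormalizedSet

    n_genes, n_arrays, arity = mg_cube.shape
    gene_ids = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    counts = {}
    rows = []
    design_rows = []
    for j in range(n_arrays):
        s = strains_per_array[j]
        counts[s] = counts.get(s, 0) + 1
        aid = f"{s}{counts[s]}"
        design_rows.append({"array_id": aid, "strain": s, "replicate": counts[s]})
        for d in range(arity):
            for g in range(n_genes):
                rows.append(
                    {
                        "array_id": aid,
                        "gene_id": gene_ids[g],
                        "duplicate_index": d + 1,
                        "block": 1,
                        "A": 10.0,
                        "Mg": mg_cube[g, j, d],
                    }
                )
    spots = pd.DataFrame(rows)
    if flags is not None:
        spots["flag"] = np.asarray(flags, float)
    design = pd.DataFrame(design_rows)
    return NormalizedSet(spots=spots, design=design, duplicate_arity=arity)
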