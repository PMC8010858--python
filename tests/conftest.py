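import numpy as np
import pandas as pd
import pytest

from twinwell.params import GenerativeParams
from twinwell.simulate import simulate_families


@pytest.fixture(scope="session")
def mirror_df():
    """Small study-like dataset (all five zygosity groups, siblings,
    wave-level missingness, PGS effects)."""
    params = GenerativeParams.study_mirror(n_pairs=300)
    return simulate_families(params, seed=42)


@pytest.fixture(scope="session")
def recovery_df():
    """Complete twin-pair data at the final-model generating values."""
    params = GenerativeParams.recovery_benchmark(n_pairs=2000)
    return simulate_families(params, seed=7, include_truth=True)


def ae_pair_frame(n_mz, n_dz, a1, a2, e1, e2, r_a, r_e, seed, var_names=("v1", "v2")):
    """Direct bivariate AE twin-pair generator, independent of the
    package's family simulator (oracle for SEM tests)."""
    rng = np.random.default_rng(seed)
    rows = []
    off = 0
    for zyg, c, n in (("MZF", 1.0, n_mz), ("DZF", 0.5, n_dz)):
        if n == 0:
            continue
        share = np.array([[1, c], [c, 1]])
        ra_m = np.array([[1, r_a], [r_a, 1]])
        re_m = np.array([[1, r_e], [r_e, 1]])
        w, v = np.linalg.eigh(np.kron(share, ra_m))
        a = (rng.standard_normal((n, 4)) @ (v * np.sqrt(np.clip(w, 0, None))).T).reshape(n, 2, 2)
        e = np.einsum("ntk,jk->ntj", rng.standard_normal((n, 2, 2)), np.linalg.cholesky(re_m))
        y1 = a1 * a[:, :, 0] + e1 * e[:, :, 0]
        y2 = a2 * a[:, :, 1] + e2 * e[:, :, 1]
        for m, role in enumerate(("twin1", "twin2")):
            rows.append(
                pd.DataFrame(
                    {
                        "family_id": np.arange(off, off + n),
                        "zygosity": zyg,
                        "role": role,
                        "sex": "F",
                        var_names[0]: y1[:, m],
                        var_names[1]: y2[:, m],
                    }
                )
            )
        off += n
    return pd.concat(rows, ignore_index=True)
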