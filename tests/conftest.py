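import numpy as np
import pandas as pd
import pytest

from vadpop.simulate import FrequencyModelConfig, gen_background_frequencies


def make_freq_table(freqs, snp_ids=None, groups=None) -> pd.DataFrame:
    """Build a frequency table from an n-by-K array, for direct fixtures."""
    f = np.atleast_2d(np.asarray(freqs, dtype=float))
    n, k = f.shape
    groups = groups or [f"G{j + 1}" for j in range(k)]
    out = pd.DataFrame(
        {
            "snp_id": snp_ids or [f"snp{i}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1),
            "allele_ref": "A",
            "allele_eff": "B",
        }
    )
    for j, g in enumerate(groups):
        out[f"freq_{g}"] = f[:, j]
    return out


@pytest.fixture(scope="session")
def small_background() -> pd.DataFrame:
    """A 200-SNP, 5-group Balding-Nichols background (fixed seed)."""
    cfg = FrequencyModelConfig(
        n_groups=5, fst_background=0.05, n_background=200, seed=42
    )
    return gen_background_frequencies(cfg)
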