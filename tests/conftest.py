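import numpy as np
import pandas as pd
import pytest

from ntmr import SimConfig, simulate_cohort


def true_weight_table(cohort, flip_col: bool = True) -> pd.DataFrame:
    """Weight table carrying the simulator's true effects (already aligned)."""
    tab = cohort.snp_meta[["id", "chrom", "pos", "ea", "oa", "weight"]].copy()
    if flip_col:
        tab["flip"] = False
    return tab


def dosage_frame(cohort, which: str) -> pd.DataFrame:
    arr = {
        "nt": cohort.maternal_nontransmitted,
        "transmitted": cohort.maternal_transmitted,
        "maternal": cohort.maternal_genotype,
        "paternal": cohort.paternal_genotype,
        "child": cohort.offspring_genotype,
    }[which]
    return pd.DataFrame(np.asarray(arr, dtype=float), index=cohort.family_ids,
                        columns=cohort.snp_meta["id"])


@pytest.fixture(scope="session")
def base_cohort():
    """Moderate cohort under the central study conditions."""
    cfg = SimConfig(n_trios=5000, n_snps=100, beta_m={"y": 0.1}, gamma_p=0.0,
                    seed=101)
    cohort, pheno = simulate_cohort(cfg)
    return cfg, cohort, pheno


@pytest.fixture(scope="session")
def nt_instrument(base_cohort):
    from ntmr import score

    _, cohort, _ = base_cohort
    sv = score(dosage_frame(cohort, "nt"), true_weight_table(cohort))
    return sv.score
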