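import numpy as np
import pytest
from hypothesis import settings

from ithshift.simulate import SimConfig, simulate_case

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ithshift.types import CaseTable, ReadCountMatrix, SampleMeta, VariantSite


def make_case(
    presence,
    vafs=None,
    depth=100,
    case_id="PCRC01",
    caller_flag=None,
    normal_alt=None,
):
    """Construct a CaseTable from a presence pattern.

    ``presence``: (n_variants, n_samples) 0/1; variant reads are derived
    from ``vafs`` (defaults to 0.4 where present).
    """
    presence = np.asarray(presence, dtype=bool)
    n_var, n_smp = presence.shape
    vafs = np.asarray(vafs, dtype=float) if vafs is not None else 0.4 * presence
    samples = [
        SampleMeta(f"{case_id}_{j+1}{'A' if j % 2 else 'C'}", case_id, "PCRC",
                   "adenoma" if j % 2 else "carcinoma")
        for j in range(n_smp)
    ]
    variants = [
        VariantSite(chrom=str(1 + i % 22), pos=1000 * (i + 1), ref="C", alt="T")
        for i in range(n_var)
    ]
    d = np.full((n_var, n_smp), depth, dtype=int)
    b = np.round(vafs * d).astype(int)
    flag = presence.copy() if caller_flag is None else np.asarray(caller_flag, bool)
    nd = np.full(n_var, depth, dtype=int)
    na = np.zeros(n_var, dtype=int) if normal_alt is None else np.asarray(normal_alt)
    counts = ReadCountMatrix(d, b, nd, na, flag)
    return CaseTable(samples, variants, counts)


@pytest.fixture(scope="session")
def small_sim():
    """One simulated darwinian case with deep coverage and high purity, so
    presence detection is near-perfect."""
    cfg = SimConfig(
        n_pcrc_cases=1,
        n_acrc_cases=0,
        pcrc_samples_per_case=(5, 5),
        stage_means={"adenoma": 120.0, "carcinoma": 120.0, "ACRC": 120.0},
        tumor_content=(0.85, 0.95),
        mean_depth=1000.0,
        normal_error_rate=0.0,
        caller_fn_rate=0.0,
        private_ccf=(0.3, 0.5),
        shared_ccf=(0.6, 0.9),
        seed=20,
    )
    return simulate_case(cfg, 0)
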