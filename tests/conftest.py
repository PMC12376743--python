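import numpy as np
import pytest

from mmrspect import signatures, simulate, spectra


@pytest.fixture(scope="session")
def sigs():
    return signatures.load_signature_matrix()


@pytest.fixture(scope="session")
def default_cohort(sigs):
    """The default study-like synthetic study, simulated once per session."""
    cfg = simulate.study_config(seed=1)
    genome, tracks, mutations, meta = simulate.simulate_study(cfg, sigs)
    return {"cfg": cfg, "genome": genome, "tracks": tracks,
            "mutations": mutations, "meta": meta}


@pytest.fixture(scope="session")
def cohort_group_spectra(default_cohort):
    genome = default_cohort["genome"]
    muts = default_cohort["mutations"]
    out = {}
    for group in ("dMutLalpha", "dMutSalpha"):
        sel = muts[muts["sample"].str.startswith(group)]
        out[group] = spectra.build_spectrum(sel, genome, group)
    return out


@pytest.fixture()
def toy_genome():
    from mmrspect.core_io import ReferenceGenome
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    return ReferenceGenome({"1": seq})
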