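import numpy as np
import pytest

from sfsdfe import (
    ModelSpec,
    OptimizerOptions,
    PolarisedSFS,
    PolarisedSFSSet,
    SampleFrame,
    TypeModel,
)

# Most fitting tests share n=50 so the per-n tau interpolator is built once
# per session.
N_SHARED = 50


@pytest.fixture(scope="session")
def frame50():
    return SampleFrame(n=N_SHARED, m=1e6, region_label="selected")


@pytest.fixture(scope="session")
def snp_c2_spec():
    return ModelSpec(types={"snp": TypeModel(dfe="discrete", n_classes=2, error_model="free")})


@pytest.fixture(scope="session")
def snp_c2_truth():
    return {
        "snp.class1.theta": 0.005,
        "snp.class1.gamma": -5.0,
        "snp.class1.epsilon": 0.05,
        "snp.class2.theta": 0.01,
        "snp.class2.gamma": -20.0,
        "snp.class2.epsilon": 0.01,
    }


@pytest.fixture(scope="session")
def indel_discrete_spec():
    return ModelSpec(
        types={
            "ins": TypeModel(dfe="discrete", n_classes=1, error_model="free"),
            "del": TypeModel(dfe="discrete", n_classes=1, error_model="free"),
        }
    )


@pytest.fixture(scope="session")
def indel_discrete_truth():
    return {
        "ins.class1.theta": 5e-4,
        "ins.class1.gamma": -5.0,
        "ins.class1.epsilon": 0.02,
        "del.class1.theta": 1e-3,
        "del.class1.gamma": -15.0,
        "del.class1.epsilon": 0.02,
    }


@pytest.fixture
def fast_options():
    return OptimizerOptions(n_starts=3, seed=0)


def make_sfs(n: int, m: float, counts, vtype: str = "snp", region: str = "selected") -> PolarisedSFS:
    return PolarisedSFS(
        frame=SampleFrame(n=n, m=m, region_label=region),
        variant_type=vtype,
        counts=np.asarray(counts, dtype=float),
    )


def make_set(*sfs_list) -> PolarisedSFSSet:
    return PolarisedSFSSet(entries={(s.frame.region_label, s.variant_type): s for s in sfs_list})
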