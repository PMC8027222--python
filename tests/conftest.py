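import numpy as np
import pandas as pd
import pytest

from sipflow.ingest import ExperimentBundle, make_sample_table
from sipflow.nbglm import DesignMatrix, GLMFit
from sipflow.pipeline import PipelineConfig, run_dataset, run_integration
from sipflow.simulate import SimConfig, simulate_experiment


def one_timepoint_samples(reps: int = 3) -> pd.DataFrame:
    rows = []
    for cond in ("control", "treated"):
        for r in range(1, reps + 1):
            rows.append({"sample_id": f"t15_{cond}_r{r}", "dataset": "d1",
                         "mating_type": "MTplus", "timepoint": "15min",
                         "condition": cond, "replicate": r})
    return make_sample_table(pd.DataFrame(rows))


def fake_fit(beta: np.ndarray, cov: np.ndarray) -> GLMFit:
    """GLMFit with prescribed coefficients/covariance for direct test of the
    Wald-based p-value formulas."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 2:
        cov = np.broadcast_to(cov, (beta.shape[0],) + cov.shape).copy()
    G, p = beta.shape
    se = np.sqrt(np.diagonal(cov, axis1=1, axis2=2))
    X = np.eye(p)
    design = DesignMatrix(colnames=[f"c{j}" for j in range(p)], X=X,
                          offsets=np.zeros(p))
    return GLMFit(beta=beta, se=se, mu=np.ones((G, p)), deviance=np.zeros(G),
                  converged=np.ones(G, bool), dispersion=np.full(G, 0.1),
                  cov=cov, design=design)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig().scaled(800)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_experiment(small_cfg)


@pytest.fixture(scope="session")
def small_run(small_sim):
    bundle_plus, bundle_minus, truth = small_sim
    cfg = PipelineConfig()
    res_plus = run_dataset(bundle_plus, cfg)
    res_minus = run_dataset(bundle_minus, cfg)
    cls = run_integration(res_plus, res_minus, cfg)
    return {"plus": res_plus, "minus": res_minus, "classification": cls,
            "truth": truth, "cfg": cfg}


@pytest.fixture(scope="session")
def default_sim():
    """Study-scale simulation (10,000 genes), counts only."""
    return simulate_experiment(SimConfig())


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full workflow on the study-scale simulation."""
    bundle_plus, bundle_minus, truth = default_sim
    cfg = PipelineConfig()
    res_plus = run_dataset(bundle_plus, cfg)
    res_minus = run_dataset(bundle_minus, cfg)
    cls = run_integration(res_plus, res_minus, cfg)
    return {"plus": res_plus, "minus": res_minus, "classification": cls,
            "truth": truth, "cfg": cfg}
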