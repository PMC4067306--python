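import numpy as np
import pytest

from arhohmm.model import ARHMM, AREmissionModel, StateSpace, TransitionModel


def make_random_model(rng: np.random.Generator, N: int, L: int, P: int) -> ARHMM:
    """Random valid AR(P)-HMM(L) with Dirichlet rows and mild AR coefficients."""
    pi = rng.dirichlet(np.ones(N))
    A = [rng.dirichlet(np.ones(N), size=N**d) for d in range(1, L + 1)]
    em = AREmissionModel(
        mu=rng.normal(0.0, 1.0, N),
        sigma=rng.uniform(0.5, 1.5, N),
        coef=rng.normal(0.0, 0.3, (N, P)),
    )
    labels = ("=", "-", "+")[:N] if N <= 3 else tuple(f"s{i}" for i in range(N))
    return ARHMM(StateSpace(labels), TransitionModel(pi=pi, A=A), em)


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture
def profile_tsv(tmp_path):
    path = tmp_path / "profiles.tsv"
    path.write_text(
        "# chromosome-ordered log-ratios\n"
        "gene\tchrom\tpos\tlog_ratio\tsample\n"
        "GA\tchr1\t100\t0.5\tS1\n"
        "GB\tchr1\t200\t-1.2\tS1\n"
        "GC\tchr1\t300\t2.0\tS1\n"
    )
    return path
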