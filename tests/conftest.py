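import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phagecomp.composition import METRIC_NAMES
from phagecomp.profiles import build_profiles, profiles_to_frame
from phagecomp.structure import ViennaEngine
from phagecomp.synth import BenchmarkConfig, build_benchmark_cohorts

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: master seed for the shared benchmark fixtures
BENCHMARK_SEED = 20240918
#: windowing used for desk-scale profile building (see docs/methods.md)
BENCHMARK_PROFILE_KW = dict(k=120, step=250, n_controls=25)


@pytest.fixture(scope="session")
def engine():
    return ViennaEngine()


@pytest.fixture(scope="session")
def benchmark_cohorts():
    """Default synthetic benchmark: 5 families x 30 natural-like + 50 generated-like."""
    return build_benchmark_cohorts(BenchmarkConfig(seed=BENCHMARK_SEED))


@pytest.fixture(scope="session")
def benchmark_frame(engine, benchmark_cohorts):
    """Profiles table for the benchmark (the expensive, folding-heavy fixture)."""
    natural, generated, _ = benchmark_cohorts
    profiles = build_profiles([natural, generated], engine, seed=BENCHMARK_SEED, **BENCHMARK_PROFILE_KW)
    return profiles_to_frame(profiles)


def metric_frame(
    n_natural: int,
    n_generated: int,
    seed: int = 0,
    shift: dict | None = None,
    families: list[str] | None = None,
) -> pd.DataFrame:
    """Numeric stand-in profiles (no folding): plausible metric scales with an
    optional additive shift applied to the generated rows."""
    rng = np.random.default_rng(seed)
    n = n_natural + n_generated
    data = {}
    for m in METRIC_NAMES:
        if m == "gc":
            data[m] = rng.normal(0.5, 0.03, n)
        elif m == "median_mfe":
            data[m] = rng.normal(-30.0, 3.0, n)
        elif m == "median_mfed":
            data[m] = rng.normal(0.03, 0.01, n)
        else:
            data[m] = rng.normal(1.0, 0.1, n)
    frame = pd.DataFrame(data, index=[f"s{i:04d}" for i in range(n)])
    frame["provenance"] = ["natural"] * n_natural + ["generated"] * n_generated
    for m, delta in (shift or {}).items():
        frame.loc[frame["provenance"] == "generated", m] += delta
    if families is not None:
        fam = [families[i % len(families)] for i in range(n_natural)] + [None] * n_generated
        frame["family"] = fam
    else:
        frame["family"] = None
    return frame
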