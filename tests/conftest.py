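import numpy as np
import pandas as pd
import pytest

from divehmm import srkw
from divehmm.simulate import (
    GeneratorConfig,
    LogNormalSpec,
    StateEmissionSpec,
    generate_dive_dataset,
)


def make_feature_frame(rng, T, deployment="a", sex="F", year=2010,
                       age_class="adult"):
    """Random but schema-valid feature rows for oracle tests."""
    return pd.DataFrame({
        "deployment_id": deployment,
        "dive_index": range(T),
        "start_s": np.arange(T, dtype=float),
        "duration_s": rng.lognormal(3, 0.5, T),
        "max_depth_m": rng.lognormal(1, 1, T),
        "jerk_peak": rng.lognormal(1, 1, T),
        "roll_med_deg": rng.lognormal(1, 1, T),
        "heading_var": rng.uniform(0.01, 0.9, T),
        "buzz": rng.integers(0, 2, T),
        "slow_click": rng.integers(0, 2, T),
        "sex": sex,
        "age_class": age_class,
        "year": year,
    })


def lognormal_spec(median, spread=1.3):
    return LogNormalSpec(median, median / spread, median * spread)


def separated_emissions(n_states, depth_medians, buzz=None, slow=None):
    """Well-separated state emissions (identical across sexes)."""
    specs = []
    for j in range(n_states):
        d = depth_medians[j]
        b = 0.5 if buzz is None else buzz[j]
        s = 0.5 if slow is None else slow[j]
        specs.append(StateEmissionSpec(
            max_depth={x: lognormal_spec(d) for x in "FM"},
            jerk_peak={x: lognormal_spec(3.0 * 8**j) for x in "FM"},
            roll={x: lognormal_spec(4.0 * 6**j) for x in "FM"},
            heading_variance={x: lognormal_spec(0.01 * 4**j) for x in "FM"},
            buzz_prob={x: b for x in "FM"},
            slow_click_prob={x: s for x in "FM"},
            duration={x: lognormal_spec(30.0 + 40.0 * j) for x in "FM"},
        ))
    return specs


def chain_config(n_states, n_dives, transition, seed=0, n_deployments=4,
                 pi=None):
    deps = [f"d{i:02d}" for i in range(n_deployments)]
    return GeneratorConfig(
        n_states=n_states,
        deployments=deps,
        sex={d: ("F" if i % 2 == 0 else "M") for i, d in enumerate(deps)},
        age_class={d: ("adult" if i % 2 else "juvenile")
                   for i, d in enumerate(deps)},
        year={d: [2010, 2012, 2014][i % 3] for i, d in enumerate(deps)},
        transition_matrix={"F": np.asarray(transition, float),
                           "M": np.asarray(transition, float)},
        initial_distribution=(np.full(n_states, 1.0 / n_states)
                              if pi is None else np.asarray(pi, float)),
        seed=seed,
        dives_per_deployment=(n_dives, n_dives),
    )


def sticky_matrix(n_states, stay=0.8):
    off = (1.0 - stay) / (n_states - 1)
    return np.full((n_states, n_states), off) + np.eye(n_states) * (stay - off)


@pytest.fixture(scope="session")
def reference_emissions():
    return srkw.reference_emissions()


@pytest.fixture(scope="session")
def reference_table():
    """Dive-level dataset at the 13-deployment reference design."""
    cfg = srkw.reference_config(seed=1)
    table, truth = generate_dive_dataset(cfg, srkw.reference_emissions())
    return table, truth


@pytest.fixture(scope="session")
def separated_3state_fit():
    """One well-separated 3-state dataset and its EM fit, shared across
    recovery-oriented tests."""
    from divehmm.hmm import em_fit

    P = sticky_matrix(3, 0.7)
    cfg = chain_config(3, 750, P, seed=21)
    emissions = separated_emissions(3, [2.0, 20.0, 200.0],
                                    buzz=[0.1, 0.5, 0.9],
                                    slow=[0.8, 0.4, 0.1])
    table, truth = generate_dive_dataset(cfg, emissions)
    fit = em_fit(table, 3, transition_covariate=None, n_restarts=3,
                 max_iter=500, tol=1e-7, seed=5)
    return {"table": table, "truth": truth, "fit": fit, "P": P,
            "emissions": emissions}
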