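import math

import numpy as np
import pytest
from scipy import stats

from bopmeta.observations import Observation, ObservationSet

Z95 = stats.norm.ppf(0.975)


def make_obs(obs_id, study_id, y, s, overlap_group=None, covariates=None, **kw):
    """Observation constructed directly from a log effect and log SE."""
    return Observation(
        obs_id=obs_id,
        study_id=study_id,
        measure=kw.pop("measure", "RR"),
        effect=math.exp(y),
        ci_lower=math.exp(y - Z95 * s),
        ci_upper=math.exp(y + Z95 * s),
        log_effect=y,
        log_se=s,
        raw_log_se=kw.pop("raw_log_se", s),
        covariates=covariates or {},
        overlap_group=overlap_group,
        **kw,
    )


def make_set(ys, ses, study_ids=None, covariates=None, **kw):
    """ObservationSet from parallel arrays; one study per row by default."""
    n = len(ys)
    study_ids = study_ids or [f"s{i}" for i in range(n)]
    obs = [
        make_obs(
            f"o{i:03d}", study_ids[i], float(ys[i]), float(ses[i]),
            covariates={k: int(v[i]) for k, v in (covariates or {}).items()},
        )
        for i in range(n)
    ]
    return ObservationSet(obs, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def four_obs_set():
    """Small well-formed set: 3 studies, one overlapping pair."""
    return ObservationSet(
        [
            make_obs("a1", "A", 0.40, 0.20, overlap_group="Ag"),
            make_obs("a2", "A", 0.30, 0.25, overlap_group="Ag"),
            make_obs("b1", "B", 0.35, 0.15),
            make_obs("c1", "C", 0.50, 0.30),
        ],
        outcome="toy",
    )
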