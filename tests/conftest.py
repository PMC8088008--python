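import numpy as np
import pandas as pd
import pytest

from gestage import CohortTable, SyntheticConfig, generate_cohort


def noiseless_config(n=300, seed=0, **kwargs):
    base = dict(
        n_participants=n,
        seed=seed,
        crl_noise_sd_cm=0.0,
        lmp_bias_days=0.0,
        lmp_noise_sd_days=0.0,
        gross_error_frac=0.0,
    )
    base.update(kwargs)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(noiseless_config())


@pytest.fixture(scope="session")
def default_cohort():
    """Default-noise synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticConfig(n_participants=800, seed=7))


def cohort_from_xy(crl, ga, participant_ids=None, **covariates):
    """Minimal cohort wrapping (CRL, GA) points, for denoise/fpreg tests."""
    crl = np.asarray(crl, dtype=float)
    ga = np.asarray(ga, dtype=float)
    n = len(crl)
    pids = (
        list(participant_ids)
        if participant_ids is not None
        else [f"X{i:05d}" for i in range(n)]
    )
    obs = pd.DataFrame(
        {
            "participant_id": pids,
            "scan_index": 1,
            "scan_date": pd.NaT,
            "lmp_date": pd.NaT,
            "crl_cm": crl,
            "ga_lmp_weeks": ga,
        }
    )
    for name, values in covariates.items():
        obs[name] = values
    return CohortTable.from_frames(obs, provenance="fixture")


def brute_force_dbscan(points, eps, min_points):
    """Independent O(n^2) DBSCAN oracle (same tie-break semantics)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    nb = [np.flatnonzero(d2[i] <= eps**2) for i in range(n)]
    core = np.array([len(x) >= min_points for x in nb])
    cid = 0
    for i in range(n):
        if core[i] and labels[i] == -1:
            stack = [i]
            labels[i] = cid
            while stack:
                j = stack.pop()
                for k in nb[j]:
                    if core[k] and labels[k] == -1:
                        labels[k] = cid
                        stack.append(k)
            cid += 1
    for i in range(n):
        if not core[i]:
            core_nb = [j for j in nb[i] if core[j]]
            if core_nb:
                labels[i] = labels[min(core_nb)]
    return labels
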