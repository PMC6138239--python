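import numpy as np
import pytest

from metpk import nlme, pk, simulate

# Population estimates for once-daily immediate-release metformin in severe
# CKD, used throughout as the reference parameter set.
REF = dict(K=0.119, ka=0.65, cl_over_f=29.6)


@pytest.fixture(scope="session")
def ref_params():
    return pk.PKParameters(dose=250.0, tau=24.0, **REF)


@pytest.fixture(scope="session")
def default_trial():
    """One 18-patient synthetic trial at the default study conditions."""
    return simulate.generate_cohort(seed=20260923)


@pytest.fixture(scope="session")
def large_cohort_fit():
    """Fit on a 102-patient cohort at the reference truth, with the truth."""
    truth = simulate.PopulationTruth(breakdown_enabled=False, violation_rate=0.0)
    design = simulate.TrialDesign(n_per_cohort=34)
    trial = simulate.generate_cohort(design, truth, seed=77)
    return nlme.fit_poppk(trial.concentrations), truth


@pytest.fixture(scope="session")
def plain_fit(default_trial):
    """Plain-variant population fit of the default trial (shared: fits are slow)."""
    return nlme.fit_poppk(default_trial.concentrations, variant="plain")


def make_fit(
    K=REF["K"],
    ka=REF["ka"],
    clearance=REF["cl_over_f"],
    cov=None,
    variant="plain",
):
    """A PopPKFit assembled from explicit estimates, for tests that need a
    fit object without paying for an actual fit."""
    import pandas as pd

    if cov is None:
        # SEs reconstructed from the reference 95% CIs: K (0.11, 0.13),
        # ka (0.45, 0.86), Cl/F (23.8, 35.4); treated as uncorrelated.
        se = np.array([0.0051, 0.1046, 2.959 if variant == "plain" else 1.99])
        cov = np.diag(se**2)
    name = "cl_over_f" if variant == "plain" else "cl_over_f_ratio"
    return nlme.PopPKFit(
        model_variant=variant,
        fixed_effects={"K": K, "ka": ka, name: clearance},
        fixed_cov=np.asarray(cov, dtype=float),
        random_effect_sd=(11.56, 0.395),
        random_effect_correlation=0.785,
        residual_sd=0.095,
        blups=pd.DataFrame(),
        log_likelihood=0.0,
        n_parameters=7,
        n_observations=102,
        n_patients=18,
        aic=np.nan,
        bic=np.nan,
        converged=True,
        theta_internal=np.concatenate(
            [np.log([K, ka, clearance, 11.56, 0.395]), [np.arctanh(0.785)], np.log([0.095])]
        ),
    )
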