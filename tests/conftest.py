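"""Shared fixtures: seeded synthetic datasets and derived products.

Everything is generated at test time; session scope keeps the expensive
pieces (deconvolution of the full lab design, bootstrap training) single-run.
"""

from __future__ import annotations

import numpy as np

import pytest

from phospec import bands, pcr, preprocess, synthetic

LAB_SEED = 1


@pytest.fixture(scope="session")
def lab_data():
    """Default seeded lab design: 234 spectra + 78-plant ground truth."""
    return synthetic.simulate_lab_dataset(LAB_SEED)


@pytest.fixture(scope="session")
def lab_processed(lab_data):
    sset, _ = lab_data
    processed, dispersion = preprocess.run_preprocess(sset)
    return processed, dispersion


@pytest.fixture(scope="session")
def lab_profiles(lab_data, lab_processed):
    """Quantified profiles of the processed lab set, merged with ground truth."""
    _, truth = lab_data
    processed, _ = lab_processed
    profiles = bands.quantify_set(processed)
    return profiles.merge(truth, on="plant_id", suffixes=("", "_truth"))


@pytest.fixture(scope="session")
def lab_profiles_unnormalized(lab_data):
    """Profiles quantified without max-normalization: absolute-area oracle scale."""
    sset, truth = lab_data
    cfg = preprocess.PreprocessConfig(normalization_scope="none")
    processed, _ = preprocess.run_preprocess(sset, cfg)
    profiles = bands.quantify_set(processed)
    return profiles.merge(truth, on="plant_id", suffixes=("", "_truth"))


@pytest.fixture(scope="session")
def lab_training_matrix(lab_data):
    """Baseline-corrected, replicate-averaged (unnormalized) regression input."""
    sset, _ = lab_data
    cfg = preprocess.PreprocessConfig(normalization_scope="none")
    processed, _ = preprocess.run_preprocess(sset, cfg)
    return processed


@pytest.fixture(scope="session")
def trained_model(lab_training_matrix):
    """Default bootstrap-trained P model (6000 resamples) + CV diagnostics."""
    processed = lab_training_matrix
    targets = processed.metadata["p_conc_uM"].astype(float)
    model, cv = pcr.bootstrap_train(
        processed, targets, pcr.BootstrapConfig(n_resamples=6000, seed=7)
    )
    return model, cv


@pytest.fixture(scope="session")
def field_data():
    """Default seeded field season: 300 spectra + plant-timepoint truth table."""
    return synthetic.simulate_field_dataset(LAB_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def held_out_r2(lab_training_matrix):
    """R^2 of predicted vs true log10 medium P on a 20% held-out plant split."""
    processed = lab_training_matrix
    targets = processed.metadata["p_conc_uM"].astype(float)
    rng = np.random.default_rng(0)
    plants = list(processed.sample_ids)
    rng.shuffle(plants)
    n_train = int(0.8 * len(plants))
    train, test = plants[:n_train], plants[n_train:]
    model, _ = pcr.bootstrap_train(
        processed.select(train),
        targets.loc[train],
        pcr.BootstrapConfig(n_resamples=2000, seed=3),
    )
    pred = pcr.predict_available(model, processed.select(test))
    y_true = np.log10(targets.loc[test].to_numpy())
    y_pred = np.log10(pred.to_numpy())
    ss_res = np.sum((y_true - y_pred) ** 2)
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    return 1.0 - ss_res / ss_tot


NULL_FIELD = synthetic.FieldParams(
    pi_mult_low=(1.0,) * 5,
    pi_mult_high=(1.0,) * 5,
    po_mult_low=(1.0,) * 5,
    po_mult_high=(1.0,) * 5,
    lignin_mult=(1.0,) * 5,
    cellulose_mult=(1.0,) * 5,
    latent_p_log_sd=0.0,
)
NULL_GEN = synthetic.GeneratorConfig(plant_log_sd=0.0)


@pytest.fixture(scope="session")
def null_family_rejection_rate():
    """Familywise rejection rate of the pairwise family under a seasonal null."""
    from phospec import season

    fam_rej = 0
    for seed in range(200):
        table = synthetic.simulate_field_truth(seed, NULL_FIELD, NULL_GEN)
        comps = season.pairwise_timepoints(table, "amp_Po", site="high-P-site")
        fam_rej += any(c.p_adjusted < 0.05 for c in comps)
    return fam_rej / 200


@pytest.fixture(scope="session")
def association_hit_rate():
    """Fraction of field seeds with a significantly positive Pi/Po-biomass rank correlation."""
    from phospec import season

    hits = 0
    for seed in range(100):
        table = synthetic.simulate_field_truth(seed)
        t5 = table[table["timepoint"] == "T5"]
        r = season.ratio_biomass_association(
            t5["true_pi_po_ratio"], t5["second_year_biomass_g"]
        )
        hits += (r.coefficient > 0.0) and (r.p_value < 0.05)
    return hits / 100
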