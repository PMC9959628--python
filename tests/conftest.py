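import pytest

from pirads_cde import (
    GeneratorConfig,
    default_rule_table,
    design_from_study,
    generate_study,
    load_schema,
)


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture(scope="session")
def rule_table():
    return default_rule_table()


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared across tests (seed fixed)."""
    return generate_study(GeneratorConfig(seed=20230219))


@pytest.fixture(scope="session")
def default_design(default_study):
    return design_from_study(default_study)


def make_complete_report(**overrides):
    """A fully populated, schema-valid lesion report (PZ-style lesion).

    Base values describe a focal, homogeneous, moderately hypointense,
    circumscribed round lesion with marked diffusion restriction.
    """
    values = {
        "lesion_dim_max": "≥5",
        "lesion_location": "PZ",
        "t2w_present_and_adequate": "YES",
        "t2w_abnormality": "YES",
        "t2w_invasive": "NO",
        "t2w_signal_intensity_type": "Hypointense",
        "t2w_signal_intensity": "Moderate",
        "t2w_uniformity": "Homogeneous",
        "t2w_focality": "YES",
        "t2w_shape": "Lenticular",
        "t2w_shape_category": "Round",
        "t2w_margin": "Well_Defined",
        "t2w_margin_category": "Circumscribed",
        "adc_present_and_adequate": "YES",
        "adc_abnormality": "YES",
        "adc_invasive": "NO",
        "adc_signal_intensity_type": "Hypointense",
        "adc_signal_intensity": "Marked",
        "adc_focality": "YES",
        "adc_shape": "Lenticular",
        "adc_shape_category": "Round",
        "dwi_present_and_adequate": "YES",
        "dwi_abnormality": "YES",
        "dwi_invasive": "NO",
        "dwi_signal_intensity_type": "Hyperintense",
        "dwi_signal_intensity": "Marked",
        "dwi_focality": "YES",
        "dwi_shape": "Lenticular",
        "dwi_shape_category": "Round",
        "dce_present_and_adequate": "YES",
        "dce_abnormality": "YES",
        "dce_enhancement": "Positive_DCE",
        "dce_corresponds_to": "DWI",
        "dce_bph_features": "NO",
    }
    values.update(overrides)
    from pirads_cde import LesionReport

    return LesionReport(lesion_id="L1", rater_id="R1", session=1, values=values)
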