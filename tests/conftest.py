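import pytest

from smilecurves import TemplateParams, build_template, ideal_landmarks, make_smile


@pytest.fixture(scope="session")
def default_params():
    return TemplateParams()


@pytest.fixture(scope="session")
def default_geometry(default_params):
    return build_template(default_params)


@pytest.fixture(scope="session")
def ideal_ls(default_geometry):
    """Landmark export of the default template (no lips)."""
    return ideal_landmarks(default_geometry)


@pytest.fixture(scope="session")
def ideal_smile():
    """Ideal synthetic smile with lips (consonant arc, medium lip line)."""
    return make_smile("ideal")
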