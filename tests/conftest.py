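import json

import pytest

from radalign import GuidelineKB, SimulationSpec, make_cases, make_kb
from radalign.kb import load_kb

#: Miniature guideline snapshot mirroring the real structure: a topic with
#: multiple variants (only one canonical), a no-imaging topic, and siblings.
FIXTURE_KB = {
    "version_date": "2024-06",
    "study_vocabulary": [
        {"name": "None", "is_no_imaging": True},
        "CTA pulmonary arteries with IV contrast",
        "V/Q scan lung",
        "Radiography trauma series",
        "CT head without IV contrast",
        "US abdomen",
    ],
    "topics": [
        {
            "name": "Suspected Pulmonary Embolism",
            "panel": "Cardiac",
            "variants": [
                {"description": "Low or intermediate pretest probability with a negative D-dimer. Initial imaging.",
                 "canonical": False, "studies": ["None"]},
                {"description": "Low or intermediate pretest probability with a positive D-dimer. Initial imaging.",
                 "canonical": False, "studies": ["CTA pulmonary arteries with IV contrast"]},
                {"description": "High pretest probability. Initial imaging.",
                 "canonical": True,
                 "studies": ["CTA pulmonary arteries with IV contrast", "V/Q scan lung"]},
                {"description": "Pregnant patient. Initial imaging.",
                 "canonical": False,
                 "studies": ["CTA pulmonary arteries with IV contrast", "V/Q scan lung"]},
            ],
        },
        {
            "name": "Chronic cough",
            "panel": "Thoracic",
            "variants": [
                {"description": "Chronic cough. Initial imaging.", "canonical": True,
                 "studies": ["CT head without IV contrast"]},
            ],
        },
        {
            "name": "Major Blunt Trauma",
            "panel": "Trauma",
            "variants": [
                {"description": "Initial imaging.", "canonical": True,
                 "studies": ["Radiography trauma series"]},
            ],
        },
        {
            "name": "Penetrating Torso Trauma",
            "panel": "Trauma",
            "variants": [
                {"description": "Initial imaging.", "canonical": True,
                 "studies": ["Radiography trauma series"]},
            ],
        },
        {
            "name": "Clinically insignificant joint sprain",
            "panel": "Musculoskeletal",
            "variants": [
                {"description": "No imaging warranted.", "canonical": True,
                 "studies": ["None"]},
            ],
        },
    ],
}


@pytest.fixture(scope="session")
def kb_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("kb") / "kb.json"
    path.write_text(json.dumps(FIXTURE_KB), encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def kb(kb_path) -> GuidelineKB:
    return load_kb(kb_path)


@pytest.fixture(scope="session")
def sim_spec() -> SimulationSpec:
    return SimulationSpec(n_topics=6, n_studies=8, n_sibling_pairs=1)


@pytest.fixture(scope="session")
def synth_kb(sim_spec) -> GuidelineKB:
    return make_kb(sim_spec, seed=11)


@pytest.fixture(scope="session")
def synth_cases(synth_kb):
    return make_cases(synth_kb, n_per_topic=10, seed=12)
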