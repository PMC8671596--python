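"""Shared fixtures: the phantom template and a quantified recovery cohort.

The heavy fixtures are session-scoped so the full simulated-cohort
pipeline runs once and is reused by the pipeline, normalization and
end-to-end recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from centipet import phantom_sim, pipeline


@pytest.fixture(scope="session")
def template():
    return phantom_sim.make_template()


@pytest.fixture(scope="session")
def recovery_cohort(template):
    """10-subject phantom cohort quantified along the MRI and CT routes.

    Ground-truth CL spans -10..140 around the CL 16 positivity cutoff;
    deformation amplitude 4 mm, default noise, fixed seed.
    """
    config = pipeline.CohortConfig(n_subjects=10, seed=20240, routes=("MRI", "CT"))
    tmpl, subjects = pipeline.simulate_cohort(config, tmpl=template)
    quant, normalized = pipeline.run_quantify(subjects, tmpl, config.routes)
    truth = {s.subject_id: s.truth for s in subjects}
    return {
        "config": config,
        "subjects": subjects,
        "truth": truth,
        "quant": quant,
        "normalized": normalized,
    }


@pytest.fixture(scope="session")
def warp_battery(template):
    """MRI- and CT-derived warps for 5 random phantoms plus ground truth."""
    from centipet.image_core import Volume
    from centipet.spatial_normalization import estimate_warp, segment_tissues

    out = []
    for seed in (301, 302, 303, 304, 305):
        truth = phantom_sim.synthesize_subject(
            template, seed, deform_amp_mm=4.0, rigid_amp=(0.0, 0.0)
        )
        mods = phantom_sim.render_modalities(truth, template)
        entry = {"truth": truth}
        for route, key in (("MRI", "mri"), ("CT", "ct")):
            anat = mods[key].with_data(mods[key].data, frame="template")
            post = segment_tissues(anat, template.priors, route)
            entry[route] = estimate_warp(post, template)
        out.append(entry)
    return out


@pytest.fixture(scope="session")
def brain_mask(template):
    return (template.priors["GM"].data + template.priors["WM"].data) > 0.1
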