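"""Shared fixtures: small synthetic specs and a session-scoped classifier."""

from __future__ import annotations

import dataclasses

import pytest

from fociscope import synthetic
from fociscope.pipeline import train_classifier_from_synthetic


def small_spec(region: str, **overrides) -> synthetic.FieldSpec:
    """A shrunken field spec for fast tests (fewer cells, smaller frame)."""
    classes = tuple(
        dataclasses.replace(c, count_per_field=(max(1, c.count_per_field[0] // 3),
                                                max(1, c.count_per_field[1] // 3)))
        for c in synthetic.default_cell_classes(region)
    )
    base = dict(
        image_shape_px=(160, 160),
        n_planes=4,
        cell_classes=classes,
        focus_diameter_px=(2, 5) if region == "frontal_cortex" else (2, 3),
    )
    base.update(overrides)
    return synthetic.default_field_spec(region, **base)


@pytest.fixture(scope="session")
def frontal_spec() -> synthetic.FieldSpec:
    return synthetic.default_field_spec("frontal_cortex")


@pytest.fixture(scope="session")
def cerebellum_spec() -> synthetic.FieldSpec:
    return synthetic.default_field_spec("cerebellum")


@pytest.fixture(scope="session")
def trained_classifier():
    """Nucleus classifier trained once on 10 labeled synthetic fields."""
    return train_classifier_from_synthetic("frontal_cortex", n_fields=10, seed=123)
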