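"""Accessors for the packaged data fixtures.

Ships the Denver II-Jimma chart in two editions (the 126-item standardization
edition including the later-dropped toilet-going item PS26, and the final
125-item edition), the published milestone-age norms table with its
similar/earlier/later comparison flags, and a synthetic LMS growth reference
used by tests and the cohort simulator (real WHO tables plug in for real use).
"""

from __future__ import annotations

from importlib import resources

from .instrument import Instrument, LmsReference, NormsTable, read_instrument, read_lms_reference, read_norms


def _data_path(name: str):
    return resources.files("milenorm.data").joinpath(name)


def load_final_instrument() -> Instrument:
    """The final 125-item chart (36 adapted items: 17 PS, 10 FM, 8 LA, 1 GM)."""
    with resources.as_file(_data_path("instrument_final.csv")) as p:
        return read_instrument(p, name="Denver II-Jimma (final)")


def load_standardization_instrument() -> Instrument:
    """The 126-item chart used during standardization (includes PS26)."""
    with resources.as_file(_data_path("instrument_standardization.csv")) as p:
        return read_instrument(p, name="Denver II-Jimma (standardization)")


def load_jimma_norms() -> NormsTable:
    """Published milestone ages (months) for all 126 items, with 90%-age flags.

    One printed row (GM3) was non-monotone across percentiles; its 50% age is
    regularized to 2.0 months so the table satisfies the monotonicity
    invariant every norms table must obey.
    """
    with resources.as_file(_data_path("jimma_norms.csv")) as p:
        return read_norms(p)


def load_synthetic_lms() -> LmsReference:
    """Synthetic smooth LMS tables (weight-for-age, MUAC-for-age, both sexes).

    These are not WHO reference values; they exist so the screening and
    simulation machinery is exercisable without redistributing WHO tables.
    """
    with resources.as_file(_data_path("lms_synthetic.csv")) as p:
        return read_lms_reference(p)
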