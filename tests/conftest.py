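import numpy as np
import pandas as pd
import pytest

from patternshift import (
    ProcessSeries,
    QuestionnaireSchema,
    SyntheticSpec,
    default_schema,
    locf_impute,
    simulate_process,
)


@pytest.fixture(scope="session")
def tpq():
    return default_schema()


@pytest.fixture
def two_item_schema():
    return QuestionnaireSchema(
        items=("a1", "a2"),
        factor_of={"a1": "A", "a2": "A"},
        factors=("A",),
        scale_min=0.0,
        scale_max=100.0,
    )


def make_series(values, schema=None, level="item", channels=None):
    """Build a ProcessSeries from a channels x days array (NaN = missing)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_ch, n_days = values.shape
    if schema is None:
        items = tuple(f"i{k}" for k in range(n_ch))
        schema = QuestionnaireSchema(
            items=items,
            factor_of={it: "F" for it in items},
            factors=("F",),
        )
    return ProcessSeries(
        case_id="t",
        days=np.arange(1, n_days + 1),
        channels=channels or tuple(schema.items)[:n_ch],
        values=values,
        missing_mask=np.isnan(values),
        schema=schema,
        level=level,
    )


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def default_case():
    """One imputed default synthetic case (planted transition at day 60)."""
    series, truth = simulate_process(SyntheticSpec(seed=11))
    return locf_impute(series), truth


def long_table(case_id, records):
    return pd.DataFrame(records, columns=["case_id", "day", "item_id", "value"]).assign(
        case_id=case_id
    )
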