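import pandas as pd
import pytest

from crece import RiskCategory, default_instrument
from crece.validity import build_contingency


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


def make_published_pairs():
    """The 39 (screening, reference) category pairs implied by the published
    comparison table: 22 concordant low, 1 low-screen/moderate-reference,
    5 moderate-screen/low-reference, 11 concordant moderate."""
    low, mod = RiskCategory.LOW, RiskCategory.MODERATE
    return (
        [(low, low)] * 22
        + [(low, mod)] * 1
        + [(mod, low)] * 5
        + [(mod, mod)] * 11
    )


@pytest.fixture(scope="session")
def published_pairs():
    return make_published_pairs()


@pytest.fixture(scope="session")
def published_table(published_pairs):
    return build_contingency(published_pairs)


@pytest.fixture()
def unanimous_panel():
    """7 experts rating one item 4 on every dimension (combined CVI 1.0)."""
    rows = [
        {"item_id": "Q1", "expert_id": f"e{e}", "dimension": d, "rating": 4}
        for e in range(7)
        for d in ("relevancy", "clarity", "simplicity")
    ]
    return pd.DataFrame(rows)
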