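import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_well_frame(fc_by_gene: dict[str, list[float]],
                    yfp_fc_by_gene: dict[str, list[float]] | None = None,
                    included: bool = True) -> pd.DataFrame:
    """Build a normalized well table directly from per-gene fold-changes.

    One replicate per listed fold-change; bypasses simulation so
    aggregation oracles can be asserted exactly.
    """
    rows = []
    for gene, fcs in fc_by_gene.items():
        yfps = (yfp_fc_by_gene or {}).get(gene, fcs)
        for rep, (fc, yfp) in enumerate(zip(fcs, yfps), start=1):
            rows.append({
                "plate_id": "P001",
                "well": f"A{rep}",
                "replicate": rep,
                "sirna_id": gene,
                "role": "sample",
                "cell_count": 800,
                "mcherry_mean": 500.0 * fc,
                "yfp_mean": 300.0 * yfp,
                "mcherry_fc": fc,
                "yfp_fc": yfp,
                "included": included,
            })
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
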