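import numpy as np
import pandas as pd
import pytest

from pdmorph import LongTable, Region, RegionSpec, SyntheticConfig


def make_table(rows, regions=None):
    """Build a LongTable from a list of row dicts, filling defaults."""
    regions = regions or {"vol": Region("volume", "cm3")}
    defaults = dict(
        group="CTRL", sex="M", education=12.0, baseline_age=65.0, icv=1450.0,
        converter_label="NA", cognitive_status="NORMAL", mean_thickness=2.5,
    )
    full = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        d.setdefault("age_at_visit", d["baseline_age"] + d["time_from_baseline"])
        for name in regions:
            d.setdefault(name, 100.0)
        full.append(d)
    return LongTable(pd.DataFrame(full), regions)


@pytest.fixture
def tiny_table():
    """3 subjects x 2 visits, one volume region."""
    rows = []
    for sid, grp in [("S1", "CTRL"), ("S2", "PDN"), ("S3", "PDCI")]:
        for j, t in enumerate([0.0, 1.1]):
            rows.append(dict(subject_id=sid, group=grp, visit_index=j,
                             time_from_baseline=t, vol=100.0 - 2 * j))
    return make_table(rows)


def small_config(n=12, seed=0, **region_kw):
    """A one-region generator config small enough for fast tests."""
    spec = RegionSpec(
        region_kw.pop("kind", "volume"), region_kw.pop("units", "cm3"),
        region_kw.pop("beta", np.array([100.0, -1.0, -2.0, -0.5, -3.0, 0.5, -0.2, 0.05])),
        region_kw.pop("random_cov", np.array([[4.0, 0.1], [0.1, 0.04]])),
        region_kw.pop("residual_sd", 0.5),
    )
    mt = RegionSpec("thickness", "mm", np.array([2.5, -0.007, 0, 0, 0, 0, -0.004, 0.001]),
                    np.array([[0.01, 0], [0, 2.5e-5]]), 0.02)
    return SyntheticConfig(
        n_per_group={"CTRL": n, "PDN": n, "PDCI": n},
        visit_times=[0.0, 1.1, 2.4, 3.2, 3.9],
        retention={g: [1.0, 0.75, 0.32, 0.20, 0.05] for g in ("CTRL", "PDN", "PDCI")},
        age_mean_sd={"CTRL": (65.1, 6.7), "PDN": (65.9, 8.3), "PDCI": (68.9, 7.7)},
        education_mean_sd={"CTRL": (16.1, 4.0), "PDN": (13.8, 2.7), "PDCI": (13.0, 2.9)},
        sex_prob_male={"CTRL": 0.56, "PDN": 0.70, "PDCI": 0.70},
        icv_mean_sd=(1459.3, 130.0),
        regions={"reg": spec},
        mean_thickness=mt,
        seed=seed,
    )
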