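import pandas as pd
import pytest
from shapely.geometry import box

from waterdisparity.attribution import ServiceArea, TractRecord
from waterdisparity.benchmarks import BenchmarkTable, Contaminant


@pytest.fixture(scope="session")
def simple_benchmarks() -> BenchmarkTable:
    return BenchmarkTable(
        contaminants={
            "A": Contaminant("A", 1.0, "µg/L"),
            "B": Contaminant("B", 10.0, "µg/L"),
            "HAA5": Contaminant("HAA5", 0.1, "µg/L"),
            "HAA9": Contaminant("HAA9", 0.06, "µg/L"),
            "RAD": Contaminant("RAD", 0.05, "pCi/L"),
        },
        aliases={"NITRATE_NITRITE": "NITRATE"},
    )


def make_records(rows) -> pd.DataFrame:
    """rows: (pwsid, contaminant, date, value-or-None, unit)."""
    return pd.DataFrame(
        [
            {
                "pwsid": p,
                "contaminant_id": c,
                "sample_date": d,
                "value": v,
                "unit": u,
                "nondetect": int(v is None),
            }
            for p, c, d, v, u in rows
        ]
    )


@pytest.fixture
def unit_tract() -> TractRecord:
    return TractRecord("T0", box(0, 0, 1, 1), 1000, {"sub": 300})


def make_system(pwsid, minx, miny, maxx, maxy, reported=1000) -> ServiceArea:
    return ServiceArea(pwsid, box(minx, miny, maxx, maxy), reported)
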