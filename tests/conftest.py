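import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from prrscreen import (  # noqa: E402
    AEReport,
    AgeStratum,
    ReportSet,
    Sex,
)


@pytest.fixture
def tiny_reportset() -> ReportSet:
    """Four reports spanning exposure/event combinations for drug D, PT P."""
    return ReportSet(
        [
            AEReport("r1", Sex.FEMALE, 45.0, frozenset({"d"}), frozenset({"P"})),
            AEReport("r2", Sex.FEMALE, 50.0, frozenset({"d"}), frozenset()),
            AEReport("r3", Sex.FEMALE, 70.0, frozenset(), frozenset({"P"})),
            AEReport("r4", Sex.FEMALE, None, frozenset(), frozenset()),
        ]
    )


def write_three_tables(tmp_path, demo_rows, drug_rows, reac_rows):
    """Write canonical CSV tables from row tuples; returns the three paths."""
    demo = tmp_path / "demo.csv"
    drug = tmp_path / "drug.csv"
    reac = tmp_path / "reac.csv"
    demo.write_text(
        "report_id,age_years,sex\n"
        + "".join(f"{r},{a},{s}\n" for r, a, s in demo_rows)
    )
    drug.write_text(
        "report_id,drugname\n" + "".join(f"{r},{d}\n" for r, d in drug_rows)
    )
    reac.write_text(
        "report_id,pt\n" + "".join(f"{r},{p}\n" for r, p in reac_rows)
    )
    return demo, drug, reac
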