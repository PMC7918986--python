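"""Exposure-sample reading, LOD handling, QC filtering, and summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pumprisk.errors import DataError, DomainError, SchemaError
from pumprisk.exposure import (
    COMPOUNDS,
    QCConfig,
    QCReason,
    compare_to_limits,
    descriptive_stats,
    estimate_fill_time,
    qc_filter,
    read_samples,
    substitute_lod,
    write_qc_report,
)

from conftest import make_sample

HEADER = (
    "consumer_id,"
    + ",".join(f"{c}_ppb" for c in COMPOUNDS)
    + ","
    + ",".join(f"lod_{c}_ppb" for c in COMPOUNDS)
    + ",initial_vacuum_mmHg,final_vacuum_mmHg,fills_per_month,temperature_c,leaked"
)


def _row(cid="C001", benzene="3.24", final="14.6", fills="2"):
    lods = ",".join("0.5" for _ in COMPOUNDS)
    return f"{cid},{benzene},9.5,2.0,7.3,480.0,{lods},30.0,{final},{fills},20.1,0"


def _write_csv(tmp_path, rows, header=HEADER):
    path = tmp_path / "samples.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestReadSamples:
    def test_row_count_and_values(self, tmp_path):
        path = _write_csv(tmp_path, [_row(f"C{i:03d}") for i in range(32)])
        samples = read_samples(path)
        assert len(samples) == 32
        assert samples[0].measurements["benzene"].value == 3.24
        assert samples[0].fills_per_month == 2
        assert not samples[0].measurements["benzene"].censored

    def test_censored_cell_sets_flag_and_lod(self, tmp_path):
        path = _write_csv(tmp_path, [_row(benzene="<LOD")])
        (s,) = read_samples(path)
        m = s.measurements["benzene"]
        assert m.censored and m.value is None and m.lod == 0.5

    def test_missing_column_names_it(self, tmp_path):
        header = HEADER.replace(",final_vacuum_mmHg", "")
        rows = [_row().replace(",14.6", "")]
        with pytest.raises(SchemaError, match="final_vacuum_mmHg"):
            read_samples(_write_csv(tmp_path, rows, header=header))

    def test_non_numeric_concentration_reports_row(self, tmp_path):
        path = _write_csv(tmp_path, [_row(), _row(cid="C002", benzene="oops")])
        with pytest.raises(DataError, match="row 1"):
            read_samples(path)


class TestLodSubstitution:
    def test_censored_replaced_by_lod_over_sqrt2(self, tmp_path):
        path = _write_csv(tmp_path, [_row(benzene="<LOD")])
        (s,) = read_samples(path)
        out = substitute_lod(s)
        assert out.measurements["benzene"].value == pytest.approx(0.5 / math.sqrt(2))
        # uncensored compounds untouched
        assert out.measurements["toluene"].value == 9.5

    def test_idempotent(self):
        s = make_sample()
        once = substitute_lod(s)
        twice = substitute_lod(once)
        assert all(
            once.measurements[c].value == twice.measurements[c].value for c in COMPOUNDS
        )

    def test_degenerate_lod_is_an_error(self):
        s = make_sample()
        bad = s.measurements | {
            "benzene": type(s.measurements["benzene"])(None, censored=True, lod=0.0)
        }
        from dataclasses import replace

        with pytest.raises(DataError):
            substitute_lod(replace(s, measurements=bad))


class TestFillTime:
    @pytest.mark.parametrize(
        "initial,final,expected",
        [(30.0, 14.6, 3.08), (30.0, 0.0, 6.0), (30.0, 30.0, 0.0)],
    )
    def test_vacuum_decay_rule(self, initial, final, expected):
        assert estimate_fill_time(initial, final) == pytest.approx(expected)

    def test_vacuum_increase_rejected(self):
        with pytest.raises(DataError):
            estimate_fill_time(10.0, 11.0)

    @given(
        initial=st.floats(1.0, 40.0),
        drop=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_vacuum_drop(self, initial, drop):
        full = estimate_fill_time(initial, initial - drop * initial)
        assert estimate_fill_time(initial, initial) == 0.0
        assert full == pytest.approx(drop * initial / 5.0)


class TestQCFilter:
    def test_clean_set_keeps_everything(self):
        samples = [make_sample(f"C{i:03d}") for i in range(5)]
        result = qc_filter(samples)
        assert result.excluded == [] and len(result.kept) == 5

    def test_injected_outlier_and_leak_are_excluded(self):
        samples = [make_sample(f"C{i:03d}", benzene=3.0 * (1 + 0.1 * i)) for i in range(32)]
        samples.append(make_sample("LEAKY", leaked=True))
        samples.append(make_sample("DIRTY", benzene=3000.0))
        result = qc_filter(samples)
        assert len(result.kept) == 32
        reasons = {s.consumer_id: r for s, r in result.excluded}
        assert reasons == {
            "LEAKY": QCReason.LEAK,
            "DIRTY": QCReason.CONTAMINATION_OUTLIER,
        }

    def test_unused_canister_flagged(self):
        samples = [make_sample("A"), make_sample("B", final_vacuum=30.0)]
        result = qc_filter(samples)
        assert [(s.consumer_id, r) for s, r in result.excluded] == [("B", QCReason.UNUSED)]

    @given(st.integers(0, 10), st.booleans())
    @settings(max_examples=25, deadline=None)
    def test_partition_property(self, n, with_leak):
        samples = [make_sample(f"C{i}") for i in range(n)]
        if with_leak and n:
            samples[0] = make_sample("C0", leaked=True)
        result = qc_filter(samples)
        assert len(result.kept) + len(result.excluded) == n
        all_ids = {s.consumer_id for s in samples}
        out_ids = {s.consumer_id for s in result.kept} | {
            s.consumer_id for s, _ in result.excluded
        }
        assert out_ids == all_ids

    def test_report_written(self, tmp_path):
        result = qc_filter([make_sample("A", leaked=True)])
        path = tmp_path / "qc.csv"
        write_qc_report(result, path)
        assert path.read_text().splitlines() == ["consumer_id,reason", "A,LEAK"]

    def test_configurable_threshold(self):
        samples = [make_sample(f"C{i}", benzene=3.0) for i in range(10)]
        samples.append(make_sample("HOT", benzene=40.0))
        strict = qc_filter(samples, QCConfig(outlier_factor=10.0))
        lax = qc_filter(samples, QCConfig(outlier_factor=100.0))
        assert any(s.consumer_id == "HOT" for s, _ in strict.excluded)
        assert not lax.excluded


class TestDescriptiveStats:
    def test_degenerate_constant(self):
        stats = descriptive_stats([make_sample(str(i)) for i in range(4)], "benzene")
        assert stats.geometric_mean == pytest.approx(3.24)
        assert stats.geometric_sd == pytest.approx(1.0)
        assert stats.n == 4

    def test_two_point_brute_force(self):
        samples = [make_sample("A", benzene=1.0), make_sample("B", benzene=100.0)]
        stats = descriptive_stats(samples, "benzene")
        logs = [math.log(1.0), math.log(100.0)]
        mean = sum(logs) / 2
        sd = math.sqrt(sum((x - mean) ** 2 for x in logs) / (2 - 1))
        assert stats.geometric_mean == pytest.approx(10.0)
        assert stats.geometric_sd == pytest.approx(math.exp(sd))
        assert (stats.min, stats.max) == (1.0, 100.0)

    def test_recovers_generating_geometry(self):
        rng = np.random.default_rng(7)
        vals = np.exp(rng.normal(np.log(3.24), np.log(2.72), 2000))
        samples = [make_sample(str(i), benzene=v) for i, v in enumerate(vals)]
        stats = descriptive_stats(samples, "benzene")
        assert stats.geometric_mean == pytest.approx(3.24, rel=0.05)
        assert stats.geometric_sd == pytest.approx(2.72, rel=0.05)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_multiplicative_scaling(self, c):
        base = [1.0, 5.0, 20.0]
        s1 = descriptive_stats([make_sample(str(i), benzene=v) for i, v in enumerate(base)], "benzene")
        s2 = descriptive_stats(
            [make_sample(str(i), benzene=c * v) for i, v in enumerate(base)], "benzene"
        )
        assert s2.geometric_mean == pytest.approx(c * s1.geometric_mean)
        assert s2.geometric_sd == pytest.approx(s1.geometric_sd)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            descriptive_stats([make_sample("A")], "benzene")
        with pytest.raises(DomainError):
            descriptive_stats(
                [make_sample("A", benzene=0.0), make_sample("B")], "benzene"
            )


class TestLimits:
    def test_one_high_sample_pattern(self):
        samples = [make_sample(str(i), benzene=3.0) for i in range(31)]
        samples.append(make_sample("HI", benzene=150.0))
        counts = compare_to_limits(samples)
        assert counts == {"REL": 31, "PEL": 32}

    def test_boundary_is_strict(self):
        counts = compare_to_limits([make_sample("A", benzene=100.0)])
        assert counts["REL"] == 0

    def test_all_zero_toluene_below(self):
        samples = [make_sample(str(i), benzene=0.001) for i in range(3)]
        counts = compare_to_limits(samples)
        assert counts == {"REL": 3, "PEL": 3}
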