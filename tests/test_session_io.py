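"""Session model, bundle round trips, epoch derivation, half-open slicing."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ictal.session import (
    ContinuousSignal,
    CoverageError,
    EmptySliceError,
    EventSeries,
    ExcludedSeizure,
    IntegrityError,
    SeizureAnnotation,
    Session,
    ValidationError,
    derive_epochs,
    load_session,
    slice_signal,
    write_session,
)


def _bundle_digest(path: Path, skip=("truth.json",)) -> str:
    h = hashlib.sha256()
    for f in sorted(Path(path).iterdir()):
        if f.name in skip:
            continue
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()


def _random_session(rng: np.random.Generator) -> Session:
    n_signals = rng.integers(1, 4)
    signals = {}
    for i in range(n_signals):
        name = f"sig{i}"
        signals[name] = ContinuousSignal(
            name=name,
            samples=rng.standard_normal(int(rng.integers(5, 400))),
            rate_hz=float(rng.choice([1.0, 250.0, 1000.0])),
            t0_s=float(rng.uniform(0, 2)),
            units="uV",
        )
    events = {
        "sound": EventSeries(name="sound", times_s=np.sort(rng.uniform(0, 300, 5))),
        "lick": EventSeries(name="lick", times_s=np.array([])),
    }
    return Session(
        session_id="rt",
        signals=signals,
        events=events,
        annotation=SeizureAnnotation(
            stim_on_s=100.0, stim_off_s=102.0, end_ipsi_s=110.0, end_contra_s=None
        ),
        meta={"animal_id": "mX", "note": "generated"},
    )


class TestRoundTrip:
    @given(seed=st.integers(0, 2**16))
    def test_load_write_identity(self, seed, tmp_path_factory):
        """load(write(s)) reproduces every value, name and metadata exactly."""
        tmp = tmp_path_factory.mktemp("rt")
        s = _random_session(np.random.default_rng(seed))
        write_session(s, tmp / "b")
        s2 = load_session(tmp / "b")
        assert s2.session_id == s.session_id
        assert s2.meta == s.meta
        assert s2.annotation == s.annotation
        assert set(s2.signals) == set(s.signals)
        for name in s.signals:
            a, b = s.signals[name], s2.signals[name]
            assert np.array_equal(a.samples, b.samples)
            assert (a.rate_hz, a.t0_s, a.units) == (b.rate_hz, b.t0_s, b.units)
        for name in s.events:
            assert np.array_equal(s.events[name].times_s, s2.events[name].times_s)

    def test_write_load_write_bytes_identical(self, tmp_path):
        s = _random_session(np.random.default_rng(3))
        write_session(s, tmp_path / "a")
        write_session(load_session(tmp_path / "a"), tmp_path / "b")
        assert _bundle_digest(tmp_path / "a") == _bundle_digest(tmp_path / "b")

    def test_empty_events_written_as_header_only(self, tmp_path, tiny_session):
        s = tiny_session
        s.events["lick"] = EventSeries(name="lick", times_s=np.array([]))
        s.events["sound"] = EventSeries(name="sound", times_s=np.array([]))
        write_session(s, tmp_path / "b")
        assert (tmp_path / "b" / "events.csv").read_text() == "name,time_s\n"

    def test_nan_sample_refused(self):
        with pytest.raises(ValidationError):
            ContinuousSignal(name="x", samples=np.array([1.0, np.nan]), rate_hz=1.0)

    def test_non_increasing_events_refused(self):
        with pytest.raises(ValidationError):
            EventSeries(name="sound", times_s=np.array([5.0, 4.0]))

    def test_missing_file_and_length_mismatch(self, tmp_path, tiny_session):
        write_session(tiny_session, tmp_path / "b")
        meta = (tmp_path / "b" / "meta.json").read_text()
        (tmp_path / "b" / "meta.json").write_text(meta.replace('"n_samples": 250', '"n_samples": 99'))
        with pytest.raises(IntegrityError):
            load_session(tmp_path / "b")
        (tmp_path / "b" / "ofc_lfp.csv").unlink()
        from ictal.session import LoadError

        with pytest.raises(LoadError):
            load_session(tmp_path / "b")


class TestDeriveEpochs:
    def test_standard_arithmetic(self):
        ep = derive_epochs(
            SeizureAnnotation(stim_on_s=100, stim_off_s=102, end_ipsi_s=110, end_contra_s=112)
        )
        assert ep.baseline == (40.0, 100.0)
        assert ep.ictal == (102.0, 112.0)
        assert ep.early_postictal == (112.0, 142.0)
        assert ep.late_postictal == (142.0, 202.0)

    def test_short_seizure_excluded(self):
        with pytest.raises(ExcludedSeizure):
            derive_epochs(
                SeizureAnnotation(stim_on_s=100, stim_off_s=102, end_ipsi_s=106.0)
            )

    def test_sham_uses_matched_duration(self):
        ep = derive_epochs(
            SeizureAnnotation(
                stim_on_s=100, stim_off_s=102, is_sham=True, sham_duration_s=8.0
            )
        )
        assert ep.ictal == (102.0, 110.0)

    def test_sham_and_seizure_epoch_lengths_match(self):
        sz = derive_epochs(
            SeizureAnnotation(stim_on_s=100, stim_off_s=102, end_ipsi_s=110.0)
        )
        sham = derive_epochs(
            SeizureAnnotation(stim_on_s=100, stim_off_s=102, is_sham=True, sham_duration_s=8.0)
        )
        for (_, a), (_, b) in zip(sz.items(), sham.items()):
            assert (a[1] - a[0]) == pytest.approx(b[1] - b[0])

    def test_baseline_before_session_start_errors(self):
        with pytest.raises(CoverageError):
            derive_epochs(
                SeizureAnnotation(stim_on_s=100, stim_off_s=102, end_ipsi_s=110.0),
                session_start_s=50.0,
            )

    @pytest.mark.parametrize("end_ipsi,end_contra,expect_end", [(110, 112, 112), (115, 108, 115), (110, None, 110)])
    def test_ictal_end_is_max_channel_end(self, end_ipsi, end_contra, expect_end):
        ep = derive_epochs(
            SeizureAnnotation(
                stim_on_s=100, stim_off_s=102, end_ipsi_s=end_ipsi, end_contra_s=end_contra
            )
        )
        assert ep.ictal[1] == expect_end


class TestSliceSignal:
    def test_half_open_bounds(self):
        sig = ContinuousSignal(name="s", samples=np.arange(10.0), rate_hz=1.0)
        out = slice_signal(sig, (2.0, 4.0))
        assert np.array_equal(out.samples, [2.0, 3.0])
        assert out.t0_s == 2.0

    def test_full_span_identity(self):
        sig = ContinuousSignal(name="s", samples=np.arange(10.0), rate_hz=1.0)
        out = slice_signal(sig, (0.0, 10.0))
        assert np.array_equal(out.samples, sig.samples)

    def test_subsample_interval_at_1khz(self):
        sig = ContinuousSignal(name="s", samples=np.arange(10.0), rate_hz=1000.0)
        out = slice_signal(sig, (0.0005, 0.0015))
        assert np.array_equal(out.samples, [1.0])

    def test_empty_slice_errors(self):
        sig = ContinuousSignal(name="s", samples=np.arange(10.0), rate_hz=1.0)
        with pytest.raises(EmptySliceError):
            slice_signal(sig, (100.0, 101.0))

    @given(
        cuts=st.lists(st.floats(0.01, 9.99), min_size=1, max_size=4, unique=True),
        rate=st.sampled_from([1.0, 3.0, 250.0]),
    )
    def test_partition_reconstructs_signal(self, cuts, rate):
        """Concatenating slices over any partition rebuilds the samples exactly."""
        n = int(10 * rate)
        sig = ContinuousSignal(name="s", samples=np.arange(float(n)), rate_hz=rate)
        edges = [0.0] + sorted(cuts) + [n / rate]
        parts = []
        for a, b in zip(edges, edges[1:]):
            try:
                parts.append(slice_signal(sig, (a, b)).samples)
            except EmptySliceError:
                pass
        assert np.array_equal(np.concatenate(parts), sig.samples)
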