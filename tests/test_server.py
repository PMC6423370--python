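"""Collation server: authentication, idempotent ingestion, device health
classification, uptime/storage accounting, and read-only view assembly."""

from datetime import timedelta

import pytest
from hypothesis import given, settings, strategies as st

from phenosync.agent import build_payload
from phenosync.models import DeviceMode, StatusColor
from phenosync.server import ClockSkewError, CollationServer, storage_percent

from conftest import START, dt, make_field, reading, scored_image, status

KEY = b"key-dev-a"


def signed_doc(n_readings=24, with_image=True, key=KEY):
    """A complete device-side payload assembled from a scratch local store."""
    local, _ = make_field()
    local.record_status(status("dev-a", dt(2017, 5, 1, 23)))
    local.record_readings([reading("dev-a", h, 12.0 + h) for h in range(n_readings)])
    if with_image:
        local.record_image(
            scored_image("dev-a", dt(2017, 5, 1, 12), is_representative=True)
        )
    payload = build_payload(local, "dev-a", since=dt(2017, 4, 30, 23, 59))
    return payload.to_document(key)


class TestAuthentication:
    def test_valid_payload_accepted(self, server):
        assert server.authenticate_payload(signed_doc()) is None

    def test_tampered_body_rejected_store_untouched(self, server):
        doc = signed_doc()
        doc["readings"][0]["value"] += 1.0
        before = server.store.content_checksum()
        rejection = server.authenticate_payload(doc)
        assert rejection.reason == "auth_failure"
        ack = server.handle_sync(doc)
        assert ack == {"accepted": False, "reason": "auth_failure"}
        assert server.store.content_checksum() == before

    def test_wrong_key_rejected(self, server):
        rejection = server.authenticate_payload(signed_doc(key=b"wrong"))
        assert rejection.reason == "auth_failure"

    def test_unknown_device_rejected(self, server):
        doc = signed_doc()
        doc["device_id"] = "ghost"
        assert server.authenticate_payload(doc).reason == "unknown_device"


class TestIngestion:
    def test_report_counts_readings_and_image(self, server):
        report = server.ingest_payload(signed_doc())
        assert report.readings_inserted == 24
        assert report.image_stored is True
        assert report.status_recorded is True
        assert report.ack_through == dt(2017, 5, 1, 23)

    def test_replay_changes_nothing(self, server):
        doc = signed_doc()
        server.ingest_payload(doc)
        checksum = server.store.content_checksum()
        report = server.ingest_payload(doc)
        assert report.readings_inserted == 0
        assert report.image_stored is False
        assert report.status_recorded is True
        assert server.store.content_checksum() == checksum

    def test_empty_delta_records_status_only(self, server):
        report = server.ingest_payload(signed_doc(n_readings=0, with_image=False))
        assert (report.readings_inserted, report.image_stored) == (0, False)
        assert report.status_recorded

    def test_malformed_document_rejected_atomically(self, server):
        doc = signed_doc()
        doc["readings"][3]["variable"] = "not_a_sensor"
        before = server.store.content_checksum()
        result = server.ingest_payload(doc)
        assert result.reason == "malformed"
        assert server.store.content_checksum() == before

    @settings(max_examples=30, deadline=None)
    @given(replays=st.lists(st.integers(0, 3), min_size=0, max_size=10))
    def test_any_replay_augmented_sequence_yields_same_store(self, replays):
        """Final store state depends on the set of payloads, not on how
        often or in what order they are replayed."""
        docs = []
        for day in range(4):
            local, _ = make_field()
            local.record_status(status("dev-a", dt(2017, 5, 1 + day, 23)))
            local.record_readings(
                [reading("dev-a", day * 24 + h, float(h)) for h in range(24)]
            )
            payload = build_payload(
                local, "dev-a", since=dt(2017, 5, 1 + day) - timedelta(seconds=1)
            )
            docs.append(payload.to_document(KEY))
        base_store, _ = make_field()
        base = CollationServer(base_store)
        for d in docs:
            base.handle_sync(d)
        augmented_store, _ = make_field()
        augmented = CollationServer(augmented_store)
        for d in docs:
            augmented.handle_sync(d)
        for i in replays:
            augmented.handle_sync(docs[i])
        assert augmented_store.content_checksum() == base_store.content_checksum()


class TestClassification:
    def test_recent_operating_is_green(self, server):
        server.store.record_status(status("dev-a", dt(2017, 5, 1, 12, 0)))
        cls = server.classify_device_status("dev-a", dt(2017, 5, 1, 12, 10))
        assert cls.color == StatusColor.GREEN

    def test_three_cadences_of_silence_is_amber(self, server):
        # cadence 30 min, amber beyond 2 cadences, red beyond 6
        server.store.record_status(status("dev-a", dt(2017, 5, 1, 12, 0)))
        cls = server.classify_device_status("dev-a", dt(2017, 5, 1, 13, 30))
        assert cls.color == StatusColor.AMBER

    def test_long_silence_is_red(self, server):
        server.store.record_status(status("dev-a", dt(2017, 5, 1, 12, 0)))
        cls = server.classify_device_status("dev-a", dt(2017, 5, 1, 15, 1))
        assert cls.color == StatusColor.RED

    def test_error_mode_is_red_regardless_of_recency(self, server):
        server.store.record_status(status("dev-a", dt(2017, 5, 1, 12), mode="error"))
        cls = server.classify_device_status("dev-a", dt(2017, 5, 1, 12, 1))
        assert cls.color == StatusColor.RED

    def test_idle_mode_is_amber(self, server):
        server.store.record_status(status("dev-a", dt(2017, 5, 1, 12), mode="idle"))
        cls = server.classify_device_status("dev-a", dt(2017, 5, 1, 12, 1))
        assert cls.color == StatusColor.AMBER

    def test_no_contact_ever_is_red(self, server):
        assert server.classify_device_status("dev-a", dt(2017, 5, 2)).color == \
            StatusColor.RED

    @settings(max_examples=50, deadline=None)
    @given(
        minutes=st.lists(st.integers(0, 600), min_size=2, max_size=20),
        mode=st.sampled_from(["operating", "idle"]),
    )
    def test_monotone_in_silence(self, minutes, mode):
        """Growing silence never improves the color."""
        rank = {StatusColor.GREEN: 0, StatusColor.AMBER: 1, StatusColor.RED: 2}
        store, _ = make_field()
        server = CollationServer(store)
        store.record_status(status("dev-a", dt(2017, 5, 1, 12), mode=mode))
        colors = [
            rank[
                server.classify_device_status(
                    "dev-a", dt(2017, 5, 1, 12) + timedelta(minutes=m)
                ).color
            ]
            for m in sorted(minutes)
        ]
        assert colors == sorted(colors)


class TestAccounting:
    def test_uptime_is_latest_capture_minus_boot(self, server):
        server.store.record_image(
            scored_image("dev-a", START + timedelta(days=5), is_representative=True)
        )
        assert server.compute_uptime("dev-a") == timedelta(days=5)

    def test_no_images_means_zero_uptime(self, server):
        assert server.compute_uptime("dev-a") == timedelta(0)

    def test_capture_before_boot_is_clock_skew(self, server):
        server.store.record_image(
            scored_image("dev-a", START - timedelta(hours=1))
        )
        with pytest.raises(ClockSkewError):
            server.compute_uptime("dev-a")

    @pytest.mark.parametrize(
        "free,total,expected",
        [(8.0, 32.0, 25.0), (64.0, 64.0, 100.0), (0.0, 64.0, 0.0),
         (21.3, 64.0, 33.3)],
    )
    def test_storage_percent(self, free, total, expected):
        assert storage_percent(free, total) == expected


class TestViews:
    def test_grid_view_counts_and_unmonitored_marking(self, server):
        server.store.record_status(status("dev-a", dt(2017, 5, 1, 12)))
        view = server.assemble_grid_view("exp", dt(2017, 5, 1, 12, 10))
        assert len(view["plots"]) == 9
        monitored = [p for p in view["plots"] if p["monitored"]]
        assert len(monitored) == 3
        assert all(p["status_color"] is None for p in view["plots"]
                   if not p["monitored"])

    def test_error_device_cell_is_red(self, server):
        server.store.record_status(status("dev-a", dt(2017, 5, 1, 12), mode="error"))
        view = server.assemble_grid_view("exp", dt(2017, 5, 1, 12, 5))
        cell = next(p for p in view["plots"] if p["device_id"] == "dev-a")
        assert cell["status_color"] == "red"

    def test_views_are_pure_and_read_only(self, server):
        server.store.record_status(status("dev-a", dt(2017, 5, 1, 12)))
        server.store.record_readings([reading("dev-a", h, 1.0) for h in range(4)])
        before = server.store.content_checksum()
        v1 = server.assemble_grid_view("exp", dt(2017, 5, 1, 13))
        v2 = server.assemble_grid_view("exp", dt(2017, 5, 1, 13))
        d1 = server.assemble_device_view("dev-a", dt(2017, 5, 1), dt(2017, 5, 1, 4))
        assert v1 == v2
        assert d1 is not None
        assert server.store.content_checksum() == before

    def test_device_view_hourly_series_with_explicit_gaps(self, server):
        server.store.record_status(status("dev-a", dt(2017, 5, 3, 0)))
        hours = [h for h in range(48) if h not in (10, 11, 12)]  # 3-h gap
        server.store.record_readings([reading("dev-a", h, float(h)) for h in hours])
        view = server.assemble_device_view(
            "dev-a", dt(2017, 4, 30, 23), dt(2017, 5, 2, 23)
        )
        series = view["series"]["ambient_temp_C"]
        assert len(series) == 48
        missing = [p for p in series if p["value"] is None]
        assert len(missing) == 3

    def test_range_before_first_reading_is_empty_but_valid(self, server):
        server.store.record_status(status("dev-a", dt(2017, 5, 1, 0)))
        view = server.assemble_device_view(
            "dev-a", dt(2017, 1, 1), dt(2017, 1, 2)
        )
        assert view["series"] == {}
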