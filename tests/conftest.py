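"""Shared fixtures: synthetic genomes, a Range-capable HTTP test server,
and a guard that keeps the whole suite off the network.

Only loopback sockets are permitted (the HTTP range-request tests run
against a local server); any attempt to reach a non-loopback host fails
the test that made it.
"""

from __future__ import annotations

import http.server
import os
import socket
import threading

import pytest

from variome.analyses import Site
from variome.fixtures import FixtureSpec, PlantedSite, generate_fixture

_LOOPBACK = {"127.0.0.1", "::1", "localhost"}
_real_connect = socket.socket.connect


def _guarded_connect(self, address):
    host = address[0] if isinstance(address, tuple) else address
    if isinstance(host, str) and host not in _LOOPBACK and not os.path.exists(str(host)):
        raise RuntimeError(f"network access to {host!r} blocked during tests")
    return _real_connect(self, address)


@pytest.fixture(autouse=True, scope="session")
def no_external_network():
    socket.socket.connect = _guarded_connect
    yield
    socket.socket.connect = _real_connect


class _RangeHandler(http.server.SimpleHTTPRequestHandler):
    """Static file handler with HTTP Range support (stdlib's lacks it)."""

    def log_message(self, *args):  # quiet
        pass

    def do_GET(self):
        path = self.translate_path(self.path)
        if not os.path.isfile(path):
            self.send_error(404)
            return
        with open(path, "rb") as fh:
            data = fh.read()
        range_header = self.headers.get("Range")
        if range_header and range_header.startswith("bytes=") and not getattr(
            self.server, "ignore_ranges", False
        ):
            spec = range_header[len("bytes="):]
            start_s, _, end_s = spec.partition("-")
            start = int(start_s)
            end = int(end_s) if end_s else len(data) - 1
            end = min(end, len(data) - 1)
            if start >= len(data):
                self.send_response(416)
                self.send_header("Content-Range", f"bytes */{len(data)}")
                self.end_headers()
                return
            chunk = data[start : end + 1]
            self.send_response(206)
            self.send_header("Content-Range", f"bytes {start}-{end}/{len(data)}")
            self.send_header("Content-Length", str(len(chunk)))
            self.end_headers()
            self.wfile.write(chunk)
        else:
            self.send_response(200)
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)


@pytest.fixture
def range_server(tmp_path):
    """(base_url, serve_dir) for a loopback HTTP server with Range support."""
    handler = lambda *a, **k: _RangeHandler(*a, directory=str(tmp_path), **k)
    server = http.server.ThreadingHTTPServer(("127.0.0.1", 0), handler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    yield f"http://127.0.0.1:{server.server_port}", tmp_path, server
    server.shutdown()


FIG2_SITE = Site("chr7", 141672604, "T", "C", "rs10246939")


@pytest.fixture(scope="session")
def trio_fixture(tmp_path_factory):
    """A 3-sample fixture with a planted chr7:141672604 T>C heterozygote."""
    out = tmp_path_factory.mktemp("trio")
    spec = FixtureSpec(
        seed=11,
        n_variants=800,
        samples=["NA12877", "NA12878", "NA12882"],
        planted_sites=[
            PlantedSite.make("chr7", 141672604, "T", "C", ["0/0", "0/1", "0/1"],
                             "rs10246939"),
            PlantedSite.make("chr19", 45411941, "T", "C", ["0/1", "0/0", "0/1"],
                             "rs429358"),
            PlantedSite.make("chr19", 45412079, "C", "T", ["0/0", "0/0", "0/1"],
                             "rs7412"),
        ],
    )
    gz, tbi, plain = generate_fixture(spec, out)
    return {"spec": spec, "gz": gz, "tbi": tbi, "plain": plain}


@pytest.fixture(scope="session")
def trio_session(trio_fixture):
    from variome.source import GenomeSession

    return GenomeSession.open_local(trio_fixture["gz"])
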