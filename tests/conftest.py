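"""Shared fixtures: a minimal ABIF writer and canned simulated studies."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from daex.synthetic import SimulationConfig, simulate_peak_table

# ---------------------------------------------------------------------------
# minimal ABIF container writer (test harness only — the package never writes
# AB1; this produces just the records the reader needs)
# ---------------------------------------------------------------------------

_HEAD = ">H4sI2H3I"  # after the 4-byte "ABIF" marker
_DIR = ">4sI2H4I"


def _entry(name: str, number: int, code: int, elem_size: int, n_elem: int, data: bytes):
    return (name.encode(), number, code, elem_size, n_elem, data)


def write_abif(
    path,
    sequence: str,
    channels: dict[str, list[int]],
    positions: list[int],
    dye_order: str = "GATC",
    sample_id: str = "specimen",
    omit: set[str] | None = None,
) -> None:
    """Write an ABIF file with DATA9-12, PLOC2, PBAS2, FWO_1 and SMPL1.

    ``channels`` maps base -> intensity series; they are stored in
    ``dye_order`` so the reader must resolve the mapping via FWO_1.
    Records named in ``omit`` are dropped (for error-path tests).
    """
    omit = omit or set()

    def shorts(values):
        return struct.pack(f">{len(values)}h", *[int(v) for v in values])

    entries = []
    for k, base in enumerate(dye_order):
        entries.append(_entry(f"DATA", 9 + k, 4, 2, len(channels[base]), shorts(channels[base])))
    entries.append(_entry("PLOC", 2, 4, 2, len(positions), shorts(positions)))
    entries.append(_entry("PBAS", 2, 2, 1, len(sequence), sequence.encode()))
    entries.append(_entry("FWO_", 1, 2, 1, len(dye_order), dye_order.encode()))
    sample = bytes([len(sample_id)]) + sample_id.encode()
    entries.append(_entry("SMPL", 1, 18, 1, len(sample), sample))
    entries = [e for e in entries if f"{e[0].decode()}{e[1]}" not in omit]

    header_size = 128
    blobs = []
    offset = header_size
    for *_head, data in entries:
        if len(data) > 4:
            blobs.append((offset, data))
            offset += len(data)
    dir_offset = offset

    out = bytearray(b"ABIF")
    out += struct.pack(
        _HEAD, 101, b"tdir", 1, 1023, 28, len(entries), 28 * len(entries), dir_offset
    )
    out += b"\x00" * (header_size - len(out))
    blob_iter = iter(blobs)
    dir_bytes = bytearray()
    for name, number, code, elem_size, n_elem, data in entries:
        if len(data) > 4:
            data_offset, _ = next(blob_iter)
            out += data
            dir_bytes += struct.pack(_DIR, name, number, code, elem_size, n_elem, len(data), data_offset, 0)
        else:
            inline = struct.unpack(">I", data.ljust(4, b"\x00"))[0]
            dir_bytes += struct.pack(_DIR, name, number, code, elem_size, n_elem, len(data), inline, 0)
    out += dir_bytes
    path.write_bytes(bytes(out))


@pytest.fixture
def abif_writer():
    return write_abif


# ---------------------------------------------------------------------------
# canned studies
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Noise-free study: effects and direction biases only, no dropout."""
    return SimulationConfig(
        noise_sd=0.0, missing_direction_rate=0.0, bias_f=0.3, bias_r=-0.2, seed=11
    )


@pytest.fixture(scope="session")
def noisy_peaks():
    """One realistic simulated study (default design, seed 5)."""
    return simulate_peak_table(SimulationConfig(seed=5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
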