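"""Shared fixtures and helpers: synthetic EDF writing, small recordings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from frandr.ieeg_io import ContactInfo, Recording

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def write_edf16(path, data_uv, rate, labels, phys_dim="uV", rates=None):
    """Minimal synthetic EDF/EDF+ (16-bit) writer for test inputs.

    Test-only helper: the package itself never writes EDF.  ``rates`` may
    give a per-channel sampling rate to fabricate malformed mixed-rate files.
    """
    data = np.asarray(data_uv, dtype=np.float64)
    n_sig = data.shape[0]
    rates = rates if rates is not None else [int(rate)] * n_sig
    n_rec = data.shape[1] // int(rate)
    pmax = max(1.0, float(np.abs(data).max()) * 1.01)
    dmin, dmax = -32768, 32767

    def pad(s, n):
        s = str(s)[:n]
        return s + " " * (n - len(s))

    hdr = (pad("0", 8) + pad("X X X X", 80) + pad("Startdate 01-JAN-2020", 80)
           + pad("01.01.20", 8) + pad("00.00.00", 8) + pad(str(256 * (1 + n_sig)), 8)
           + pad("", 44) + pad(str(n_rec), 8) + pad("1", 8) + pad(str(n_sig), 4))
    sig = "".join(pad(lab, 16) for lab in labels)
    sig += "".join(pad("synthetic", 80) for _ in labels)
    sig += "".join(pad(phys_dim, 8) for _ in labels)
    sig += "".join(pad(f"{-pmax:.6g}", 8) for _ in labels)
    sig += "".join(pad(f"{pmax:.6g}", 8) for _ in labels)
    sig += "".join(pad(str(dmin), 8) for _ in labels)
    sig += "".join(pad(str(dmax), 8) for _ in labels)
    sig += "".join(pad("", 80) for _ in labels)
    sig += "".join(pad(str(int(r)), 8) for r in rates)
    sig += "".join(pad("", 32) for _ in labels)
    scale = (dmax - dmin) / (2 * pmax)
    with open(path, "wb") as fh:
        fh.write(hdr.encode("ascii"))
        fh.write(sig.encode("ascii"))
        for r in range(n_rec):
            for ch in range(n_sig):
                seg = data[ch, r * rates[ch]:(r + 1) * rates[ch]]
                dig = np.round((seg + pmax) * scale + dmin).astype("<i2")
                fh.write(dig.tobytes())


def make_contacts(shank="AHL", n=8, region="hippocampus", hemisphere="left",
                  soz=False):
    return [
        ContactInfo(label=f"{shank}{i}", shank_id=shank, index_on_shank=i,
                    region=region, hemisphere=hemisphere, soz=soz)
        for i in range(1, n + 1)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """Referential recording: two 4-contact shanks, 2 s at 2 kHz."""
    contacts = make_contacts("AHL", 4) + make_contacts("AR", 4, region="amygdala",
                                                       hemisphere="right")
    samples = rng.normal(0, 30, (8, 4000))
    return Recording(samples=samples, rate=2000.0, channels=contacts,
                     montage="referential")
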