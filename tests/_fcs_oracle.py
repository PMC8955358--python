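"""Independent minimal FCS parser used only as a cross-implementation oracle.

Deliberately shares no code with cytobench.fcsio: offsets are unpacked
with struct-style slicing, the TEXT segment is tokenised with a regular
expression, and the data block is decoded with the array module.  It
supports exactly the subset the writer claims to emit (FCS 3.1, $MODE L,
$DATATYPE F, little-endian) so any disagreement indicates a writer bug.
"""

from __future__ import annotations

import array
import re


def parse_fcs_minimal(path):
    """Return (keywords, events) where events is a list of row tuples."""
    blob = open(path, "rb").read()
    assert blob[:6] == b"FCS3.1", "oracle: version string"
    fields = [blob[10 + 8 * i : 18 + 8 * i].decode() for i in range(6)]
    text_begin, text_end, data_begin, data_end = (int(f) for f in fields[:4])
    text = blob[text_begin : text_end + 1].decode("ascii")
    delim = text[0]
    # split on single delimiters only; doubled delimiters are literals
    token_re = re.compile(
        "((?:[^{d}]|{d}{d})*){d}".format(d=re.escape(delim))
    )
    tokens = [m.group(1).replace(delim * 2, delim) for m in token_re.finditer(text[1:])]
    assert len(tokens) % 2 == 0, "oracle: odd token count"
    kw = dict(zip(tokens[::2], tokens[1::2]))
    assert kw["$DATATYPE"] == "F" and kw["$BYTEORD"] == "1,2,3,4"
    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    arr = array.array("f")
    arr.frombytes(blob[data_begin : data_begin + 4 * n_par * n_tot])
    import sys

    if sys.byteorder == "big":  # stored little-endian
        arr.byteswap()
    rows = [tuple(arr[i * n_par : (i + 1) * n_par]) for i in range(n_tot)]
    return kw, rows
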